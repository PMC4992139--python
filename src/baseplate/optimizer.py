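"""Global search of the symmetry parameters.

A genetic algorithm explores the 9-gene symmetry genome; each offspring
is additionally *basin-hopped* — randomly perturbed, locally minimized
with a bounded derivative-free simplex search (the hybrid target has
flat-bottom kinks, so no gradients), and Metropolis-accepted.  Elitism
makes the per-generation best energy non-increasing, and all randomness
flows through a single seeded generator, so a run is bit-reproducible.

A brute-force grid oracle over two free genes is provided to certify the
search on reduced problems.

Defaults follow the intended production scale (population 64, 200
generations, 20 hops of 200 local evaluations); tests and the bundled
pipeline presets use much smaller, explicitly stated budgets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import OptimizerError

log = logging.getLogger(__name__)

#: default per-gene mutation scale: 0.05 rad on the three rotation genes,
#: 1 Å on translations and lattice genes (matched to ~33 Å lattices)
DEFAULT_MUTATION_SIGMA = (0.05, 0.05, 0.05, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass
class GAConfig:
    population_size: int = 64
    generations: int = 200
    tournament_size: int = 3
    crossover_rate: float = 0.7
    blend_alpha: float = 0.5
    mutation_sigma: tuple[float, ...] = DEFAULT_MUTATION_SIGMA
    elitism_count: int = 2
    hop_iterations: int = 20
    hop_temperature: float = 1.0
    local_minimizer_budget: int = 200
    seed: int = 0
    top_k: int = 128
    distinct_threshold: float = 0.5

    def __post_init__(self):
        if self.population_size < 4:
            raise OptimizerError("population_size must be >= 4")
        if not (0 <= self.elitism_count < self.population_size):
            raise OptimizerError("elitism_count must be < population_size")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise OptimizerError("crossover_rate must lie in [0, 1]")


@dataclass
class OptimizationTrace:
    best_energy: list[float] = field(default_factory=list)
    median_energy: list[float] = field(default_factory=list)
    best_vector: np.ndarray | None = None
    n_evaluations: int = 0
    seed: int = 0


class _CountedObjective:
    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn
        self.count = 0

    def __call__(self, vec: np.ndarray) -> float:
        self.count += 1
        return float(self.fn(vec))


def _clip(vec: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    clipped = np.clip(vec, bounds[:, 0], bounds[:, 1])
    if not np.array_equal(clipped, vec):
        log.debug("clipped genome back into bounds")
    return clipped


def local_minimize(start: np.ndarray, objective: Callable, bounds: np.ndarray,
                   budget: int) -> tuple[np.ndarray, float]:
    """Bounded, budgeted Nelder-Mead step of the basin hop."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # maxfev reached is expected
        res = minimize(objective, start, method="Nelder-Mead",
                       bounds=[tuple(b) for b in bounds],
                       options={"maxfev": max(budget, len(start) + 2),
                                "xatol": 1e-4, "fatol": 1e-10})
    x = _clip(np.asarray(res.x, dtype=float), bounds)
    return x, float(res.fun)


def basin_hop(start: np.ndarray, objective: Callable, config: GAConfig,
              bounds: Sequence[Sequence[float]],
              rng: np.random.Generator | None = None) -> tuple[np.ndarray, float]:
    """Perturb -> locally minimize -> Metropolis-accept, ``hop_iterations`` times.

    Returns the best point ever visited (including the start), so the
    returned energy never exceeds the start energy.
    """
    bounds = np.asarray(bounds, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sigma = np.asarray(config.mutation_sigma, dtype=float)
    cur = _clip(np.asarray(start, dtype=float), bounds)
    e_cur = float(objective(cur))
    best, e_best = cur.copy(), e_cur
    for _ in range(config.hop_iterations):
        cand = _clip(cur + rng.normal(size=cur.shape) * sigma, bounds)
        x, e = local_minimize(cand, objective, bounds, config.local_minimizer_budget)
        if not np.isfinite(e):
            continue
        if e < e_best:
            best, e_best = x.copy(), e
        delta = e - e_cur
        if delta < 0 or rng.random() < np.exp(-delta / max(config.hop_temperature, 1e-12)):
            cur, e_cur = x, e
    return best, e_best


def _tournament(rng, pop, energies, k):
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmin(energies[idx])]]


def _select_distinct(archive: list[tuple[np.ndarray, float]], k: int,
                     threshold: float) -> list[tuple[np.ndarray, float]]:
    """Lowest-energy individuals, greedily filtered for genome distinctness."""
    chosen: list[tuple[np.ndarray, float]] = []
    for vec, e in sorted(archive, key=lambda t: t[1]):
        if all(np.linalg.norm(vec - c[0]) > threshold for c in chosen):
            chosen.append((vec, e))
        if len(chosen) >= k:
            break
    return chosen


def run_ga(config: GAConfig, objective: Callable[[np.ndarray], float],
           bounds: Sequence[Sequence[float]],
           checkpoint_path: str | Path | None = None
           ) -> tuple[OptimizationTrace, list[tuple[np.ndarray, float]]]:
    """Genetic algorithm with basin-hopped offspring.

    Returns the trace and the ``top_k`` lowest-energy distinct
    individuals seen anywhere during the run.
    """
    bounds = np.asarray(bounds, dtype=float)
    n_genes = len(bounds)
    if not np.all(np.isfinite(bounds)):
        raise OptimizerError("bounds must be finite")
    rng = np.random.default_rng(config.seed)
    counted = _CountedObjective(objective)

    def draw() -> np.ndarray:
        return rng.uniform(bounds[:, 0], bounds[:, 1])

    def evaluate_or_redraw(vec: np.ndarray) -> tuple[np.ndarray, float]:
        for _ in range(20):
            e = counted(vec)
            if np.isfinite(e):
                return vec, e
            log.warning("non-finite objective; individual discarded")
            vec = draw()
        return vec, np.inf

    pop = []
    energies = []
    for _ in range(config.population_size):
        v, e = evaluate_or_redraw(draw())
        pop.append(v)
        energies.append(e)
    pop = np.array(pop)
    energies = np.array(energies)
    if not np.any(np.isfinite(energies)):
        raise OptimizerError("entire initial generation is non-finite")

    archive: list[tuple[np.ndarray, float]] = [(p.copy(), e) for p, e in zip(pop, energies)]
    trace = OptimizationTrace(seed=config.seed)
    sigma = np.asarray(config.mutation_sigma, dtype=float)
    if sigma.shape != (n_genes,):
        sigma = np.full(n_genes, float(sigma.flat[0])) if sigma.size == 1 else sigma
        if sigma.shape != (n_genes,):
            raise OptimizerError("mutation_sigma length does not match genome")

    for gen in range(config.generations):
        order = np.argsort(energies)
        elites = pop[order[:config.elitism_count]].copy()
        elite_e = energies[order[:config.elitism_count]].copy()
        children = []
        child_e = []
        while len(children) < config.population_size - config.elitism_count:
            p1 = _tournament(rng, pop, energies, config.tournament_size)
            p2 = _tournament(rng, pop, energies, config.tournament_size)
            if rng.random() < config.crossover_rate:
                # BLX-alpha blend crossover
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                span = hi - lo
                child = rng.uniform(lo - config.blend_alpha * span,
                                    hi + config.blend_alpha * span)
            else:
                child = p1.copy()
            child = _clip(child + rng.normal(size=n_genes) * sigma, bounds)
            if config.hop_iterations > 0:
                child, e = basin_hop(child, counted, config, bounds, rng)
                if not np.isfinite(e):
                    child, e = evaluate_or_redraw(draw())
            else:
                child, e = evaluate_or_redraw(child)
            children.append(child)
            child_e.append(e)
            archive.append((child.copy(), e))
        pop = np.vstack([elites, np.array(children)])
        energies = np.concatenate([elite_e, np.array(child_e)])
        if not np.any(np.isfinite(energies)):
            raise OptimizerError(f"generation {gen}: all individuals non-finite")
        finite = energies[np.isfinite(energies)]
        trace.best_energy.append(float(finite.min()))
        trace.median_energy.append(float(np.median(finite)))
        log.debug("generation %d: best %.6g median %.6g", gen,
                  trace.best_energy[-1], trace.median_energy[-1])
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, gen, pop, energies, config.seed)

    top = _select_distinct(archive, config.top_k, config.distinct_threshold)
    trace.best_vector = top[0][0].copy()
    trace.n_evaluations = counted.count
    return trace, top


def grid_oracle(objective: Callable[[np.ndarray], float],
                free_genes: tuple[int, int], fixed: np.ndarray,
                grid_1: np.ndarray, grid_2: np.ndarray
                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Exhaustive minimum over a 2-D grid with the other genes frozen.

    Returns (arg-min genome, minimum energy, full score table with shape
    (len(grid_1), len(grid_2))).
    """
    if len(grid_1) == 0 or len(grid_2) == 0:
        raise OptimizerError("grid_oracle: empty grid")
    i, j = free_genes
    table = np.empty((len(grid_1), len(grid_2)))
    best = None
    best_e = np.inf
    for a, g1 in enumerate(grid_1):
        for b, g2 in enumerate(grid_2):
            vec = np.asarray(fixed, dtype=float).copy()
            vec[i] = g1
            vec[j] = g2
            e = float(objective(vec))
            table[a, b] = e
            if e < best_e:
                best, best_e = vec, e
    return best, best_e, table


def save_checkpoint(path: str | Path, generation: int, pop: np.ndarray,
                    energies: np.ndarray, seed: int) -> None:
    Path(path).write_text(json.dumps({
        "generation": generation,
        "population": pop.tolist(),
        "energies": energies.tolist(),
        "seed": seed,
    }))


def load_checkpoint(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
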