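"""Ambiguous distance restraints and the hybrid energy function.

A cross peak in a long-mixing 13C-13C correlation spectrum reports
spatial proximity between two carbons, but chemical-shift overlap makes
the assignment ambiguous: every atom pair whose assigned shifts fall
inside a matching window around the peak is a candidate.  A restraint is
satisfied through the r^-6 sum-averaged *effective distance*

    d_eff = ( sum_k d_k^-6 )^(-1/6)

over all candidate pair instances k — intra-chain and against every
symmetry image — mirroring how all candidate pairs contribute to the
observed cross-peak intensity.  Adding an instance can only decrease
d_eff, so ambiguity never creates spurious violations.

The hybrid target summed by :func:`total_energy`:

* restraint term  : flat-bottom quadratic on d_eff above the upper bound
* pigment term    : nearest Mg-Mg kept below a cutoff, ring normals kept
                    in the baseplate plane
* clash term      : soft-sphere repulsion between heavy atoms of
                    different chains (the monomer itself is rigid input)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import RestraintError, InsufficientPigmentsError
from .structure_io import (MonomerStructure, PigmentConvention, PigmentSite,
                           extract_pigment_site)
from .symmetry import (Assembly, SymmetryImage, SymmetryParams,
                       bounding_sphere, expand_assembly)

AtomRef = tuple[int, str]  # (residue_number, atom_name)
PairOption = tuple[AtomRef, AtomRef]

#: default flat-bottom upper bound for 200 ms DARR cross peaks, Å
DEFAULT_UPPER_BOUND = 7.0

#: full chemical-shift matching window, p.p.m. (max deviation = half of it)
DEFAULT_WINDOW_PPM = 1.35

_BACKBONE_SET = frozenset({"C", "CA", "CB"})


# ---------------------------------------------------------------------------
# Input tables


@dataclass
class ChemicalShiftTable:
    """Assigned 13C shifts keyed by (residue_number, atom_name)."""

    entries: list[tuple[int, str, str, float]]  # (res_num, res_name, atom_name, ppm)

    def __post_init__(self):
        keys = [(r, a) for r, _, a, _ in self.entries]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise RestraintError(f"duplicate (residue, atom) shift keys: {dupes}")
        for r, rn, a, ppm in self.entries:
            if not np.isfinite(ppm):
                raise RestraintError(f"non-finite shift for residue {r} atom {a}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemicalShiftTable":
        df = pd.read_csv(path, sep="\t")
        return cls([(int(r.residue_number), str(r.residue_name),
                     str(r.atom_name), float(r.shift)) for r in df.itertuples()])

    @classmethod
    def from_nmrstar(cls, path: str | Path) -> "ChemicalShiftTable":
        """Minimal NMR-STAR reader: the _Atom_chem_shift loop only."""
        lines = Path(path).read_text().splitlines()
        tags: list[str] = []
        entries = []
        in_loop = False
        reading = False
        for ln in lines:
            s = ln.strip()
            if s == "loop_":
                in_loop, reading, tags = True, False, []
            elif in_loop and s.startswith("_"):
                tags.append(s.split(".")[-1] if "." in s else s)
            elif in_loop and s in ("stop_",):
                in_loop = reading = False
            elif in_loop and tags and s and not s.startswith("#"):
                reading = True
                if not {"Comp_index_ID", "Comp_ID", "Atom_ID", "Val"} <= set(tags):
                    continue
                tok = s.split()
                if len(tok) < len(tags):
                    continue
                row = dict(zip(tags, tok))
                try:
                    entries.append((int(row["Comp_index_ID"]), row["Comp_ID"],
                                    row["Atom_ID"], float(row["Val"])))
                except ValueError:
                    continue
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["residue_number", "residue_name",
                                            "atom_name", "shift"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class Peak2D:
    id: str
    shift_1: float
    shift_2: float
    intensity: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.shift_1) and np.isfinite(self.shift_2)):
            raise RestraintError(f"peak {self.id}: non-finite shift")


def read_peaks_tsv(path: str | Path) -> list[Peak2D]:
    """TSV with columns id, w1, w2[, intensity] (Sparky-style export)."""
    df = pd.read_csv(path, sep="\t")
    peaks = []
    for row in df.itertuples():
        inten = float(row.intensity) if "intensity" in df.columns else None
        peaks.append(Peak2D(str(row.id), float(row.w1), float(row.w2), inten))
    return peaks


# ---------------------------------------------------------------------------
# Restraints


@dataclass
class AmbiguousRestraint:
    """One cross peak's candidate atom pairs with an upper distance bound."""

    peak_id: str
    options: list[PairOption]
    upper_bound: float = DEFAULT_UPPER_BOUND
    weight: float = 1.0

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise RestraintError(f"restraint {self.peak_id}: upper bound must be positive")
        seen = set()
        dedup = []
        for a, b in self.options:
            a = (int(a[0]), str(a[1]))
            b = (int(b[0]), str(b[1]))
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                dedup.append(key)
        if not dedup:
            raise RestraintError(f"restraint {self.peak_id}: no options")
        self.options = dedup

    def to_dict(self) -> dict:
        return {"peak_id": self.peak_id,
                "options": [[list(a), list(b)] for a, b in self.options],
                "upper_bound": self.upper_bound,
                "weight": self.weight}

    @classmethod
    def from_dict(cls, d: dict) -> "AmbiguousRestraint":
        opts = [((int(a[0]), str(a[1])), (int(b[0]), str(b[1])))
                for a, b in d["options"]]
        return cls(d["peak_id"], opts, float(d["upper_bound"]), float(d.get("weight", 1.0)))


def save_restraints(restraints: Sequence[AmbiguousRestraint], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in restraints], indent=1))


def load_restraints(path: str | Path) -> list[AmbiguousRestraint]:
    return [AmbiguousRestraint.from_dict(d) for d in json.loads(Path(path).read_text())]


def default_allowed_atoms(residue_name: str, atom_name: str) -> bool:
    """C' and CA of all residues; CB additionally for Ser/Thr."""
    if atom_name in ("C", "CA"):
        return True
    return atom_name == "CB" and residue_name in ("SER", "THR")


def _is_trivial(restraint: AmbiguousRestraint) -> bool:
    """True when covalent geometry alone bounds every option below U.

    Conservative rule: every option is an intra-residue pair or a
    sequential (|i-j| = 1) backbone pair.
    """
    for (r1, a1), (r2, a2) in restraint.options:
        if r1 == r2:
            continue
        if abs(r1 - r2) == 1 and a1 in _BACKBONE_SET and a2 in _BACKBONE_SET:
            continue
        return False
    return True


def compile_restraints(peaks: Sequence[Peak2D], shifts: ChemicalShiftTable,
                       window_ppm: float = DEFAULT_WINDOW_PPM,
                       allowed_atoms: Callable[[str, str], bool] = default_allowed_atoms,
                       upper_bound: float = DEFAULT_UPPER_BOUND,
                       remove_trivial: bool = True) -> tuple[list[AmbiguousRestraint], dict]:
    """Match peaks against the shift table within a symmetric window.

    A candidate atom matches a peak dimension when its assigned shift
    deviates by at most ``window_ppm / 2``.  Peaks with no candidate pair
    are reported unmatched; restraints whose every option is fixed by
    covalent geometry are dropped (countable, disable with
    ``remove_trivial=False``).
    """
    if window_ppm <= 0:
        raise RestraintError("window_ppm must be positive")
    half = window_ppm / 2.0
    cands = [(r, rn, a, ppm) for r, rn, a, ppm in shifts.entries if allowed_atoms(rn, a)]
    restraints = []
    unmatched = []
    n_trivial = 0
    for pk in peaks:
        opts = []
        for r1, rn1, a1, p1 in cands:
            if abs(pk.shift_1 - p1) > half:
                continue
            for r2, rn2, a2, p2 in cands:
                if abs(pk.shift_2 - p2) > half:
                    continue
                if (r1, a1) == (r2, a2):
                    continue
                opts.append(((r1, a1), (r2, a2)))
        if not opts:
            unmatched.append(pk.id)
            continue
        rst = AmbiguousRestraint(pk.id, opts, upper_bound=upper_bound)
        if remove_trivial and _is_trivial(rst):
            n_trivial += 1
            continue
        restraints.append(rst)
    report = {
        "n_restraints": len(restraints),
        "n_unmatched": len(unmatched),
        "unmatched_peaks": unmatched,
        "n_trivial_removed": n_trivial,
        "mean_options": (float(np.mean([len(r.options) for r in restraints]))
                         if restraints else 0.0),
    }
    return restraints, report


# ---------------------------------------------------------------------------
# Pigment sites of an assembly


def assembly_pigment_sites(assembly: Assembly,
                           convention: PigmentConvention | None = None,
                           images: Sequence[SymmetryImage] | None = None,
                           site_energy: float = 12500.0,
                           dipole_strength: float = 37.0) -> list[PigmentSite]:
    """Pigment sites of (a subset of) the assembly's images.

    The local-frame site is extracted once and propagated through each
    image's rigid operator, so this is exact and cheap.
    """
    local = extract_pigment_site(assembly.template, convention,
                                 site_energy=site_energy,
                                 dipole_strength=dipole_strength)
    sites = []
    for img in (images if images is not None else assembly.images):
        R, t = img.operator(assembly.params)
        sites.append(PigmentSite(
            mg_position=R @ local.mg_position + t,
            ring_normal=R @ local.ring_normal,
            qy_dipole_direction=R @ local.qy_dipole_direction,
            site_energy=site_energy,
            dipole_strength=dipole_strength,
        ))
    return sites


# ---------------------------------------------------------------------------
# Energies


@dataclass
class Weights:
    """Component weights and geometric parameters of the hybrid target."""

    restraint: float = 1.0
    pigment: float = 1.0
    clash: float = 0.1
    mg_cutoff: float = 15.0   # Å; nearest Mg-Mg must stay below this
    mg_weight: float = 1.0
    normal_weight: float = 1.0
    clash_rmin: float = 2.8   # Å, heavy-atom soft-sphere radius

    def __post_init__(self):
        if min(self.restraint, self.pigment, self.clash) < 0:
            raise RestraintError("component weights must be non-negative")


@dataclass
class EnergyBreakdown:
    restraint_energy: float
    pigment_energy: float
    clash_energy: float
    total: float
    effective_distances: dict[str, float] = field(default_factory=dict)
    violations: list[tuple[str, float]] = field(default_factory=list)  # (peak_id, excess Å)


def effective_distance(restraint: AmbiguousRestraint, assembly: Assembly,
                       images: Sequence[SymmetryImage] | None = None) -> float:
    """r^-6 sum-averaged distance over every option instance.

    Instances: the intra-chain pairing on the reference chain, plus both
    orientations of each option against every listed image.
    """
    index = assembly.template.atom_index()
    ref = assembly.coords[assembly.reference_index()]
    if images is None:
        images = [im for im in assembly.images if im != SymmetryImage(0, (0, 0))]
    inv6 = 0.0
    count = 0
    for (ra, aa), (rb, ab) in restraint.options:
        try:
            i = index[(ra, aa)]
            j = index[(rb, ab)]
        except KeyError as exc:
            raise RestraintError(
                f"restraint {restraint.peak_id}: option atom {exc.args[0]} "
                "absent from structure") from None
        if i != j:
            d = np.linalg.norm(ref[i] - ref[j])
            inv6 += d ** -6
            count += 1
        for img in images:
            other = assembly.image_coords(img)
            for p, q in ((i, j), (j, i)):
                d = np.linalg.norm(ref[p] - other[q])
                if d > 1e-9:
                    inv6 += d ** -6
                    count += 1
    if count == 0:
        raise RestraintError(f"restraint {restraint.peak_id}: no resolvable instance")
    return float(inv6 ** (-1.0 / 6.0))


def restraint_energy(restraints: Sequence[AmbiguousRestraint], assembly: Assembly,
                     images: Sequence[SymmetryImage] | None = None) -> tuple[float, dict, list]:
    """Flat-bottom quadratic sum; returns (energy, d_eff map, violations)."""
    energy = 0.0
    deffs = {}
    violations = []
    for r in restraints:
        d = effective_distance(r, assembly, images)
        deffs[r.peak_id] = d
        excess = max(0.0, d - r.upper_bound)
        if excess > 0:
            violations.append((r.peak_id, excess))
            energy += r.weight * excess ** 2
    return energy, deffs, violations


def pigment_constraint_energy(sites: Sequence[PigmentSite],
                              mg_cutoff: float = 15.0,
                              mg_weight: float = 1.0,
                              normal_weight: float = 1.0,
                              reference_indices: Sequence[int] | None = None) -> float:
    """Mg proximity + ring-orientation penalty.

    First term: quadratic penalty when the nearest Mg-Mg distance (taken
    as the minimum over reference pigments of their nearest-neighbour
    distance) exceeds ``mg_cutoff``.  Second term: sum over reference
    sites of (ring_normal . z)^2, zero when every ring plane contains the
    baseplate normal.
    """
    if len(sites) < 2:
        raise InsufficientPigmentsError("pigment constraint needs >= 2 pigment sites")
    mg = np.array([s.mg_position for s in sites])
    refs = list(reference_indices) if reference_indices is not None else list(range(len(sites)))
    d = np.sqrt(((mg[:, None, :] - mg[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    d_min = float(d[refs].min())
    e_mg = mg_weight * max(0.0, d_min - mg_cutoff) ** 2
    e_norm = normal_weight * float(sum(sites[i].ring_normal[2] ** 2 for i in refs))
    return e_mg + e_norm


def clash_energy(assembly: Assembly, r_min: float = 2.8) -> float:
    """Soft-sphere repulsion between heavy atoms of *different* chains.

    Spatial binning via a k-d tree; equals the all-pairs double loop to
    machine precision because only pairs below ``r_min`` contribute.
    """
    heavy = assembly.template.heavy_mask()
    n_heavy = int(heavy.sum())
    pts = assembly.coords[:, heavy, :].reshape(-1, 3)
    chain_of = np.repeat(np.arange(assembly.n_chains), n_heavy)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=r_min, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    inter = chain_of[pairs[:, 0]] != chain_of[pairs[:, 1]]
    pairs = pairs[inter]
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    return float(((r_min - d) ** 2).sum())


# ---------------------------------------------------------------------------
# Fast evaluator + public total_energy


class EnergyModel:
    """Precompiled hybrid-energy evaluator for one monomer + restraint set.

    Resolves every restraint option to template atom indices once, then
    evaluates the full breakdown per parameter vector.  This is the
    objective the global search calls thousands of times.
    """

    def __init__(self, monomer: MonomerStructure,
                 restraints: Sequence[AmbiguousRestraint],
                 weights: Weights | None = None,
                 extent: tuple[int, int] = (1, 1),
                 convention: PigmentConvention | None = None,
                 prune_cutoff: float = DEFAULT_UPPER_BOUND + 2.0):
        self.monomer = monomer
        self.restraints = list(restraints)
        self.weights = weights or Weights()
        self.extent = extent
        self.convention = convention
        index = monomer.atom_index()
        self._ri = []   # option atom indices i
        self._rj = []
        self._rid = []  # restraint ordinal per option
        for k, r in enumerate(self.restraints):
            for (ra, aa), (rb, ab) in r.options:
                if (ra, aa) not in index or (rb, ab) not in index:
                    missing = (ra, aa) if (ra, aa) not in index else (rb, ab)
                    raise RestraintError(
                        f"restraint {r.peak_id}: option references absent atom {missing}")
                self._ri.append(index[(ra, aa)])
                self._rj.append(index[(rb, ab)])
                self._rid.append(k)
        self._ri = np.array(self._ri, dtype=int)
        self._rj = np.array(self._rj, dtype=int)
        self._rid = np.array(self._rid, dtype=int)
        self._ubounds = np.array([r.upper_bound for r in self.restraints])
        self._rweights = np.array([r.weight for r in self.restraints])
        self._center, self._radius = bounding_sphere(monomer)
        # fixed (not bound-dependent) so calibrated bounds reproduce exactly;
        # images beyond it contribute r^-6 terms below float noise
        self._prune_cutoff = float(prune_cutoff)
        try:
            self._local_site = extract_pigment_site(monomer, convention)
        except Exception:
            self._local_site = None
        self.n_evaluations = 0

    # -- internals --------------------------------------------------------
    def _restraint_terms(self, assembly: Assembly, ops) -> tuple[float, dict, list]:
        if not self.restraints:
            return 0.0, {}, []
        ref_idx = assembly.reference_index()
        ref = assembly.coords[ref_idx]
        n_r = len(self.restraints)
        # intra-chain instances
        ok = self._ri != self._rj
        d0 = np.linalg.norm(ref[self._ri[ok]] - ref[self._rj[ok]], axis=1)
        inv6 = np.bincount(self._rid[ok], weights=np.clip(d0, 1e-6, None) ** -6,
                           minlength=n_r)
        # neighbour pruning by bounding spheres
        centers = np.array([R @ self._center + t for R, t in ops])
        sep = np.linalg.norm(centers - centers[ref_idx], axis=1)
        keep = [g for g in range(len(ops))
                if g != ref_idx and sep[g] <= 2 * self._radius + self._prune_cutoff]
        if keep:
            others = assembly.coords[keep]                       # (g, atoms, 3)
            diff1 = ref[None, self._ri] - others[:, self._rj]
            diff2 = ref[None, self._rj] - others[:, self._ri]
            d1sq = np.einsum("gka,gka->gk", diff1, diff1)
            d2sq = np.einsum("gka,gka->gk", diff2, diff2)
            contrib = (np.clip(d1sq, 1e-12, None) ** -3
                       + np.clip(d2sq, 1e-12, None) ** -3).sum(axis=0)
            inv6 = inv6 + np.bincount(self._rid, weights=contrib, minlength=n_r)
        deff = np.where(inv6 > 0, inv6 ** (-1.0 / 6.0), np.inf)
        excess = np.clip(deff - self._ubounds, 0.0, None)
        energy = float((self._rweights * excess ** 2).sum())
        deffs = {r.peak_id: float(d) for r, d in zip(self.restraints, deff)}
        violations = [(r.peak_id, float(e))
                      for r, e in zip(self.restraints, excess) if e > 0]
        return energy, deffs, violations

    def _pigment_term(self, assembly: Assembly, ops) -> float:
        if self._local_site is None:
            return 0.0
        w = self.weights
        mg = np.array([R @ self._local_site.mg_position + t for R, t in ops])
        ref_cell = [i for i, im in enumerate(assembly.images) if im.cell_index == (0, 0)]
        d = np.sqrt(((mg[ref_cell][:, None, :] - mg[None, :, :]) ** 2).sum(-1))
        for row, i in enumerate(ref_cell):
            d[row, i] = np.inf
        d_min = float(d.min())
        normals_z = np.array([(R @ self._local_site.ring_normal)[2] for R, t in ops])
        e = w.mg_weight * max(0.0, d_min - w.mg_cutoff) ** 2
        e += w.normal_weight * float((normals_z[ref_cell] ** 2).sum())
        return e

    # -- public -----------------------------------------------------------
    def evaluate(self, params: SymmetryParams) -> EnergyBreakdown:
        self.n_evaluations += 1
        assembly = expand_assembly(self.monomer, params, *self.extent)
        ops = assembly.operators
        e_rest, deffs, violations = self._restraint_terms(assembly, ops)
        e_pig = self._pigment_term(assembly, ops)
        e_clash = clash_energy(assembly, self.weights.clash_rmin)
        w = self.weights
        total = w.restraint * e_rest + w.pigment * e_pig + w.clash * e_clash
        return EnergyBreakdown(e_rest, e_pig, e_clash, total, deffs, violations)

    def objective(self, vec: np.ndarray) -> float:
        """Genome-space objective; invalid genomes map to +inf."""
        from .symmetry import vector_to_params
        from .errors import ParameterError
        try:
            params = vector_to_params(vec)
        except ParameterError:
            return np.inf
        return self.evaluate(params).total


def total_energy(params: SymmetryParams, monomer: MonomerStructure,
                 restraints: Sequence[AmbiguousRestraint],
                 weights: Weights | None = None,
                 extent: tuple[int, int] = (1, 1)) -> EnergyBreakdown:
    """Expand the assembly and evaluate the full hybrid energy breakdown."""
    return EnergyModel(monomer, restraints, weights, extent).evaluate(params)
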