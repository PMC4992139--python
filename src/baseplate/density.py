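"""Low-resolution density: MRC I/O, rasterization, correlation, rigid fitting.

The map is a regular 3D grid of real values with a per-axis voxel size
and an origin in Å; values are indexed ``[ix, iy, iz]`` (x first).  A
model is compared with a map by rasterizing every heavy atom as an
isotropic Gaussian whose FWHM equals the nominal resolution and whose
integral is proportional to the atomic number, then taking the Pearson
correlation over voxels — scale- and offset-free, which is what a
low-resolution overlay can actually constrain.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DensityError
from .optimizer import GAConfig, basin_hop
from .restraints import EnergyModel, Weights
from .structure_io import MonomerStructure
from .symmetry import Assembly, SymmetryParams, expand_assembly, params_to_vector, vector_to_params

ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "MG": 12,
                  "FE": 26, "ZN": 30, "CL": 17, "NA": 11}


@dataclass
class DensityMap:
    values: np.ndarray          # (nx, ny, nz)
    voxel_size: np.ndarray      # per-axis Å
    origin: np.ndarray          # Å position of voxel (0,0,0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise DensityError("density values must be a 3D grid")
        if np.any(self.voxel_size <= 0):
            raise DensityError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise DensityError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.voxel_size[i] * np.arange(self.shape[i])
                     for i in range(3))

    def integral(self) -> float:
        return float(self.values.sum() * np.prod(self.voxel_size))


# ---------------------------------------------------------------------------
# MRC2014 mode 2


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC2014 mode-2 map, normalizing axis order to x-fastest."""
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise DensityError(f"{path}: truncated MRC header")
    ints = struct.unpack("<10i", raw[0:40])
    nc, nr, ns, mode = ints[0], ints[1], ints[2], ints[3]
    if mode != 2:
        raise DensityError(f"unsupported MRC mode {mode} (only mode 2 / float32)")
    ncstart, nrstart, nsstart = ints[4], ints[5], ints[6]
    mx, my, mz = ints[7], ints[8], ints[9]
    cella = struct.unpack("<3f", raw[40:52])
    mapc, mapr, maps = struct.unpack("<3i", raw[64:76])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    origin_words = struct.unpack("<3f", raw[196:208])
    offset = 1024 + nsymbt
    count = nc * nr * ns
    data = np.frombuffer(raw[offset:offset + 4 * count], dtype="<f4").reshape(ns, nr, nc)
    # file dims (section, row, column) map to crystal axes (maps, mapr, mapc)
    axis_of_dim = [maps - 1, mapr - 1, mapc - 1]
    perm = [axis_of_dim.index(t) for t in (0, 1, 2)]
    values = np.ascontiguousarray(np.transpose(data, perm))
    m_per_axis = np.array([mx, my, mz], dtype=float)
    voxel = np.array(cella) / np.where(m_per_axis > 0, m_per_axis, 1)
    origin = np.array(origin_words, dtype=float)
    if np.all(origin == 0.0):
        start_of_dim = [nsstart, nrstart, ncstart]
        starts = np.empty(3)
        for dim, ax in enumerate(axis_of_dim):
            starts[ax] = start_of_dim[dim]
        origin = starts * voxel
    return DensityMap(values, voxel, origin)


def write_mrc(dmap: DensityMap, path: str | Path) -> None:
    """Write MRC2014 mode 2 with the canonical column=x, row=y, section=z order."""
    nx, ny, nz = dmap.shape
    vals = np.asarray(dmap.values, dtype="<f4")
    cella = (nx * dmap.voxel_size[0], ny * dmap.voxel_size[1], nz * dmap.voxel_size[2])
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(vals.min()), float(vals.max()),
                     float(vals.mean()))
    struct.pack_into("<i", header, 88, 1)      # ISPG
    struct.pack_into("<i", header, 92, 0)      # NSYMBT
    struct.pack_into("<4s", header, 208, b"MAP ")
    struct.pack_into("<4B", header, 212, 0x44, 0x44, 0x00, 0x00)  # little-endian
    struct.pack_into("<f", header, 216, float(vals.std()))
    struct.pack_into("<3f", header, 196, *dmap.origin)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vals.transpose(2, 1, 0).tobytes())


# ---------------------------------------------------------------------------
# Rasterization


def _atoms_of(obj) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom positions and atomic-number weights of a structure/assembly."""
    if isinstance(obj, Assembly):
        heavy = obj.template.heavy_mask()
        z = np.array([ATOMIC_NUMBERS.get(a.element.upper(), 6)
                      for a, h in zip(obj.template.atoms, heavy) if h], dtype=float)
        pos = obj.coords[:, heavy, :].reshape(-1, 3)
        return pos, np.tile(z, obj.n_chains)
    if isinstance(obj, MonomerStructure):
        atoms = [a for a in obj.atoms if a.is_heavy]
        if not atoms:
            raise DensityError("no heavy atoms to rasterize")
        pos = np.array([a.position for a in atoms])
        z = np.array([ATOMIC_NUMBERS.get(a.element.upper(), 6) for a in atoms], float)
        return pos, z
    raise DensityError(f"cannot rasterize object of type {type(obj).__name__}")


def _rasterize(positions: np.ndarray, weights: np.ndarray, shape, voxel, origin,
               sigma: float) -> np.ndarray:
    """Sum of separable normalized Gaussians on the given grid.

    Vectorized over atoms: every atom gets the same (2k+1)-voxel window
    per axis, out-of-grid window cells are clipped to the border with
    zero weight, and all contributions land in one bincount.
    """
    shape = tuple(int(s) for s in shape)
    voxel = np.asarray(voxel, dtype=float)
    origin = np.asarray(origin, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    norm = (2.0 * np.pi * sigma ** 2) ** -1.5
    # per-axis window half-width in voxels (4 sigma support)
    k = np.maximum(np.ceil(4.0 * sigma / voxel).astype(int), 1)
    gauss = []   # per axis: (n, 2k+1) weights
    idx = []     # per axis: (n, 2k+1) voxel indices, clipped
    valid = []   # per axis: (n, 2k+1) in-grid mask
    for ax in range(3):
        center = (positions[:, ax] - origin[ax]) / voxel[ax]
        base = np.floor(center).astype(int)
        offs = np.arange(-k[ax], k[ax] + 1)
        ii = base[:, None] + offs[None, :]
        ok = (ii >= 0) & (ii < shape[ax])
        x = origin[ax] + ii * voxel[ax] - positions[:, ax, None]
        g = np.exp(-x ** 2 / (2.0 * sigma ** 2))
        g[~ok] = 0.0
        idx.append(np.clip(ii, 0, shape[ax] - 1))
        gauss.append(g)
        valid.append(ok)
    wx = weights[:, None, None, None] * norm \
        * gauss[0][:, :, None, None] \
        * gauss[1][:, None, :, None] \
        * gauss[2][:, None, None, :]
    flat = (idx[0][:, :, None, None] * (shape[1] * shape[2])
            + idx[1][:, None, :, None] * shape[2]
            + idx[2][:, None, None, :])
    flat = np.broadcast_to(flat, wx.shape)
    vals = np.bincount(flat.ravel(), weights=wx.ravel(),
                       minlength=shape[0] * shape[1] * shape[2])
    return vals.reshape(shape)


def synthetic_density(obj, resolution: float, voxel: float | Sequence[float],
                      padding: float = 10.0) -> DensityMap:
    """Rasterize a structure or assembly as a Gaussian-atom density map.

    Each heavy atom contributes an isotropic Gaussian with
    sigma = resolution / (2 sqrt(2 ln 2)) and integral equal to its
    atomic number, so the map integral approximates the total electron
    count (up to grid truncation).
    """
    voxel3 = np.broadcast_to(np.asarray(voxel, dtype=float), (3,))
    if resolution < 2 * voxel3.max():
        raise DensityError("resolution must be at least twice the voxel size")
    positions, weights = _atoms_of(obj)
    if len(positions) == 0:
        raise DensityError("empty structure")
    sigma = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lo = positions.min(axis=0) - padding
    hi = positions.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel3[i])) + 1 for i in range(3))
    vals = _rasterize(positions, weights, shape, voxel3, lo, sigma)
    return DensityMap(vals, voxel3, lo)


def rasterize_like(reference: DensityMap, obj, resolution: float) -> DensityMap:
    """Rasterize a model on the exact grid of an existing map."""
    positions, weights = _atoms_of(obj)
    sigma = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = _rasterize(positions, weights, reference.shape, reference.voxel_size,
                      reference.origin, sigma)
    return DensityMap(vals, reference.voxel_size.copy(), reference.origin.copy())


# ---------------------------------------------------------------------------
# Correlation and fitting


def _resample_onto(target: DensityMap, source: DensityMap) -> np.ndarray:
    """Trilinear resampling of ``source`` values onto ``target``'s grid."""
    ax = target.axes()
    grids = np.meshgrid(*ax, indexing="ij")
    coords = [(grids[i] - source.origin[i]) / source.voxel_size[i] for i in range(3)]
    return ndimage.map_coordinates(source.values.astype(float), coords, order=1,
                                   mode="constant", cval=0.0)


def cross_correlation(map_a: DensityMap, map_b, resolution: float | None = None,
                      mask_threshold: float | None = None) -> float:
    """Pearson correlation between two maps (or a map and a model).

    A model (Assembly/MonomerStructure) is rasterized on ``map_a``'s grid
    first (requires ``resolution``).  When the grids differ, ``map_b`` is
    resampled by trilinear interpolation.  The optional mask keeps only
    voxels of ``map_a`` above the threshold.
    """
    if not isinstance(map_b, DensityMap):
        if resolution is None:
            raise DensityError("resolution required to rasterize a model")
        map_b = rasterize_like(map_a, map_b, resolution)
    a = map_a.values.astype(float)
    if map_b.shape == map_a.shape and np.allclose(map_b.voxel_size, map_a.voxel_size) \
            and np.allclose(map_b.origin, map_a.origin):
        b = map_b.values.astype(float)
    else:
        b = _resample_onto(map_a, map_b)
    if mask_threshold is not None:
        keep = a > mask_threshold
        a, b = a[keep], b[keep]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DensityError("cross-correlation undefined for zero-variance input")
    return float(a @ b / (na * nb))


def rigid_fit_scan(assembly: Assembly, dmap: DensityMap,
                   translations: Sequence[Sequence[float]],
                   rotations_deg: Sequence[float],
                   resolution: float) -> tuple[dict, pd.DataFrame]:
    """Exhaustive rigid placement scan (rotations about z x translations).

    Returns the arg-max placement and the full score table.  Ties break
    toward the earlier grid entry, so the scan is deterministic.
    """
    positions, weights = _atoms_of(assembly)
    sigma = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rows = []
    best = None
    for ang in rotations_deg:
        th = np.radians(ang)
        R = np.array([[np.cos(th), -np.sin(th), 0.0],
                      [np.sin(th), np.cos(th), 0.0],
                      [0.0, 0.0, 1.0]])
        rotated = positions @ R.T
        for t in translations:
            t = np.asarray(t, dtype=float)
            vals = _rasterize(rotated + t, weights, dmap.shape, dmap.voxel_size,
                              dmap.origin, sigma)
            model_map = DensityMap(vals, dmap.voxel_size.copy(), dmap.origin.copy())
            try:
                cc = cross_correlation(dmap, model_map)
            except DensityError:
                cc = -np.inf
            rows.append({"rotation_deg": float(ang), "tx": t[0], "ty": t[1],
                         "tz": t[2], "cc": cc})
            if best is None or cc > best["cc"]:
                best = rows[-1]
    return best, pd.DataFrame(rows)


def density_restrained_refine(params: SymmetryParams, monomer: MonomerStructure,
                              restraints, dmap: DensityMap,
                              weights: Weights | None = None,
                              config: GAConfig | None = None,
                              bounds=None,
                              w_cc: float = 1.0,
                              resolution: float = 19.1,
                              extent: tuple[int, int] = (1, 1)
                              ) -> tuple[SymmetryParams, dict]:
    """Basin-hop the combined target: hybrid energy + w_cc * (1 - CC).

    With ``w_cc = 0`` this reduces exactly to a plain basin hop on the
    hybrid energy (same seed, same trajectory).  The returned combined
    objective never exceeds the initial one.
    """
    model = EnergyModel(monomer, restraints, weights, extent)
    start = params_to_vector(params)
    if bounds is None:
        width = np.array([0.3] * 3 + [3.0] * 3 + [3.0, 3.0, 3.0])
        bounds = np.stack([start - width, start + width], axis=1)
    cfg = config or GAConfig(hop_iterations=5, local_minimizer_budget=100)

    if w_cc == 0.0:
        objective = model.objective
    else:
        def objective(vec):
            e = model.objective(vec)
            if not np.isfinite(e):
                return np.inf
            assembly = expand_assembly(monomer, vector_to_params(vec), *extent)
            try:
                cc = cross_correlation(dmap, assembly, resolution=resolution)
            except DensityError:
                cc = 0.0
            return e + w_cc * (1.0 - cc)

    e0 = float(objective(start))
    vec, e = basin_hop(start, objective, cfg, bounds)
    refined = vector_to_params(vec)
    info = {"initial_objective": e0, "final_objective": e}
    if w_cc != 0.0:
        assembly = expand_assembly(monomer, refined, *extent)
        info["final_cc"] = cross_correlation(dmap, assembly, resolution=resolution)
    return refined, info


def downsample(dmap: DensityMap, factor: int = 2) -> DensityMap:
    """Block-average the map by an integer factor (cheap multi-resolution).

    Useful to accelerate correlation scoring during refinement; the
    voxel size grows by the factor and trailing voxels that do not fill
    a block are dropped.
    """
    if factor < 1:
        raise DensityError("downsample factor must be >= 1")
    if factor == 1:
        return dmap
    nx, ny, nz = (s // factor for s in dmap.shape)
    if min(nx, ny, nz) < 2:
        raise DensityError("map too small to downsample")
    v = dmap.values[:nx * factor, :ny * factor, :nz * factor].astype(float)
    v = v.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    return DensityMap(v, dmap.voxel_size * factor, dmap.origin.copy())
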