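"""Exciton-theory forward spectra for pigment arrays.

Each pigment contributes one Qy transition (site energy in cm^-1,
dipole strength in Debye^2, dipole direction near the ring plane).  The
excitonic Hamiltonian couples sites through the point-dipole interaction

    V_ij = f * 5.04 cm^-1 * kappa_ij * sqrt(D_i D_j) / r_nm^3
    kappa = mu_i . mu_j - 3 (mu_i . r)(mu_j . r)

(unit dipole directions, centre separation in nm, f an empirical
screening factor).  Diagonalization yields exciton states whose dipole
strengths, isotropic rotational strengths, and orientation-resolved
rotational strengths generate absorption, CD, ACD and LD band shapes.

The isotropic rotational strength of state k is

    R_k = pi * nu0 * sum_{i<j} c_ki c_kj  r_ij . (mu_i x mu_j) * 1e-8

(r in Å, mu in Debye; nu0 is the mean site wavenumber in cm^-1 — a
constant prefactor, so the point-dipole sum rule sum_k R_k = 0 holds
exactly; the state-energy variation it neglects is of order V/nu0,
well below 1%.  The 1e-8 converts Å to cm, leaving R in Debye^2-like
units — only relative magnitudes matter here).  Oriented (ACD)
rotational strength is the quadratic form R_k(n) = n^T T_k n of a
symmetric tensor normalized so its uniform sphere average recovers R_k.

Vibronic progressions are out of scope; an empirical Gaussian lineshape
stands in for the full vibronic band shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SpectraError
from .structure_io import PigmentSite

#: point-dipole prefactor, cm^-1 per Debye^2/nm^3
DIPOLE_COUPLING_CONSTANT = 5.04

_ANGSTROM_TO_CM = 1e-8


def point_dipole_coupling(site_i: PigmentSite, site_j: PigmentSite,
                          screening: float = 1.0) -> float:
    """Excitonic coupling between two pigment sites, cm^-1."""
    r = site_j.mg_position - site_i.mg_position
    dist = float(np.linalg.norm(r))
    if dist <= 2.0:
        raise SpectraError(
            f"sites {dist:.2f} Å apart: point-dipole approximation invalid")
    if dist < 10.0:
        warnings.warn(f"point-dipole coupling at {dist:.1f} Å is approximate",
                      stacklevel=2)
    rhat = r / dist
    mi = site_i.qy_dipole_direction
    mj = site_j.qy_dipole_direction
    kappa = float(mi @ mj - 3.0 * (mi @ rhat) * (mj @ rhat))
    r_nm = dist / 10.0
    return (screening * DIPOLE_COUPLING_CONSTANT * kappa
            * np.sqrt(site_i.dipole_strength * site_j.dipole_strength) / r_nm ** 3)


@dataclass
class ExcitonResult:
    """Eigenstates of the exciton Hamiltonian (energies ascending)."""

    energies: np.ndarray            # cm^-1
    coefficients: np.ndarray        # (k, i), orthonormal rows
    dipole_vectors: np.ndarray      # (k, 3), Debye
    dipole_strengths: np.ndarray    # Debye^2
    rotational_strengths: np.ndarray          # isotropic
    rotational_tensors: np.ndarray  # (k, 3, 3), n^T T n = oriented R

    def oriented_rotational_strengths(self, axis: np.ndarray) -> np.ndarray:
        n = np.asarray(axis, dtype=float)
        n = n / np.linalg.norm(n)
        return np.einsum("a,kab,b->k", n, self.rotational_tensors, n)


def exciton_states(sites: Sequence[PigmentSite], screening: float = 1.0) -> ExcitonResult:
    """Diagonalize the point-dipole exciton Hamiltonian of a pigment set."""
    if len(sites) == 0:
        raise SpectraError("exciton_states needs at least one site")
    n = len(sites)
    H = np.zeros((n, n))
    for i, s in enumerate(sites):
        H[i, i] = s.site_energy
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H[i, j] = H[j, i] = point_dipole_coupling(sites[i], sites[j], screening)
    energies, vecs = np.linalg.eigh(H)
    coeffs = vecs.T  # rows are states
    mu_site = np.array([np.sqrt(s.dipole_strength) * s.qy_dipole_direction for s in sites])
    pos = np.array([s.mg_position for s in sites])
    mu_state = coeffs @ mu_site
    d_state = (mu_state ** 2).sum(axis=1)
    # pairwise chirality terms r_ij . (mu_i x mu_j), and the tensor version
    cross = np.cross(mu_site[:, None, :], mu_site[None, :, :])  # (i, j, 3)
    rij = pos[None, :, :] - pos[:, None, :]                     # r_j - r_i
    scalar_ij = (rij * cross).sum(-1)                           # (i, j)
    sym_ij = 0.5 * (np.einsum("ija,ijb->ijab", rij, cross)
                    + np.einsum("ija,ijb->ijab", cross, rij))
    R = np.empty(n)
    T = np.empty((n, 3, 3))
    # constant prefactor (mean site energy) keeps the sum rule exact
    pref = np.pi * float(np.mean([s.site_energy for s in sites])) * _ANGSTROM_TO_CM
    for k in range(n):
        cc = np.outer(coeffs[k], coeffs[k])
        # sum over i<j == half the full sum (both terms symmetric in i,j)
        R[k] = 0.5 * pref * (cc * scalar_ij).sum()
        T[k] = 1.5 * pref * np.einsum("ij,ijab->ab", cc, sym_ij)
    return ExcitonResult(energies=energies, coefficients=coeffs,
                         dipole_vectors=mu_state, dipole_strengths=d_state,
                         rotational_strengths=R, rotational_tensors=T)


# ---------------------------------------------------------------------------
# Band shapes


@dataclass
class Spectrum:
    axis: np.ndarray
    values: np.ndarray
    kind: str                 # absorption | CD | LD | ACD
    axis_unit: str = "nm"     # nm | cm-1
    truncated: bool = False

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        d = np.diff(self.axis)
        if len(self.axis) != len(self.values) or not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("spectrum axis must be strictly monotone and match values")

    def in_nm(self) -> "Spectrum":
        if self.axis_unit == "nm":
            return self
        ax = 1e7 / self.axis
        order = np.argsort(ax)
        return Spectrum(ax[order], self.values[order], self.kind, "nm", self.truncated)

    def write(self, path: str | Path) -> None:
        header = f"# {self.axis_unit} {self.kind}"
        body = "\n".join(f"{a:.6f} {v:.8e}" for a, v in zip(self.axis, self.values))
        Path(path).write_text(header + "\n" + body + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum":
        lines = Path(path).read_text().splitlines()
        unit, kind = "nm", "CD"
        if lines and lines[0].startswith("#"):
            tok = lines[0][1:].split()
            if len(tok) >= 2:
                unit, kind = tok[0], tok[1]
            lines = lines[1:]
        data = np.array([[float(x) for x in ln.split()[:2]] for ln in lines if ln.strip()])
        return cls(data[:, 0], data[:, 1], kind, unit)


@dataclass
class AxisSpec:
    start: float
    stop: float
    n: int = 512
    unit: str = "nm"

    def grid(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n)


def simulate_spectra(result: ExcitonResult, fwhm_cm: float = 250.0,
                     axis: AxisSpec | None = None,
                     order_parameter: float = 1.0,
                     orientation_axis: Sequence[float] = (0.0, 0.0, 1.0)
                     ) -> dict[str, Spectrum]:
    """Gaussian-broadened absorption, CD, ACD, LD on a common axis.

    ACD uses light propagating along ``orientation_axis``; LD weights are
    D_k * S * (3 cos^2 theta_k - 1)/2 with theta_k the angle between the
    state dipole and the orientation axis.  Band areas on a wavenumber
    axis equal the corresponding strengths.
    """
    if fwhm_cm <= 0:
        raise SpectraError("fwhm must be positive")
    axis = axis or AxisSpec(720.0, 880.0, 512, "nm")
    grid = axis.grid()
    nu = 1e7 / grid if axis.unit == "nm" else grid
    sigma = fwhm_cm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-((nu[None, :] - result.energies[:, None]) ** 2) / (2 * sigma ** 2))
    g /= sigma * np.sqrt(2 * np.pi)
    truncated = bool(np.any((result.energies < nu.min() - 2 * fwhm_cm)
                            | (result.energies > nu.max() + 2 * fwhm_cm)))
    if truncated:
        warnings.warn("some exciton bands fall outside the requested axis", stacklevel=2)
    n_axis = np.asarray(orientation_axis, dtype=float)
    n_axis = n_axis / np.linalg.norm(n_axis)
    d = result.dipole_strengths
    mu = result.dipole_vectors
    cos2 = np.zeros(len(d))
    ok = d > 1e-12
    cos2[ok] = (mu[ok] @ n_axis) ** 2 / d[ok]
    ld_w = d * order_parameter * (3.0 * cos2 - 1.0) / 2.0
    r_axis = result.oriented_rotational_strengths(n_axis)
    out = {}
    for kind, weights in (("absorption", d), ("CD", result.rotational_strengths),
                          ("ACD", r_axis), ("LD", ld_w)):
        vals = weights @ g
        out[kind] = Spectrum(grid, vals, kind, axis.unit, truncated)
    return out


# ---------------------------------------------------------------------------
# Shape comparison (the candidate filter)


@dataclass
class ShapeMatch:
    signs_match: bool
    zero_crossing_delta: float   # nm
    rms_normalized: float
    passes: bool = False         # signs match and crossing within tolerance


def _principal_zero_crossing(axis: np.ndarray, values: np.ndarray) -> float | None:
    """Zero crossing between the global maximum and global minimum lobes."""
    imax = int(np.argmax(values))
    imin = int(np.argmin(values))
    if values[imax] <= 0 or values[imin] >= 0:
        return None
    lo, hi = sorted((imax, imin))
    for i in range(lo, hi):
        v0, v1 = values[i], values[i + 1]
        if v0 == 0.0:
            return float(axis[i])
        if v0 * v1 < 0:
            return float(axis[i] - v0 * (axis[i + 1] - axis[i]) / (v1 - v0))
    return None


def _lobe_signs(values: np.ndarray, threshold: float = 0.05) -> list[int]:
    signs = []
    for v in values:
        if abs(v) < threshold:
            continue
        s = 1 if v > 0 else -1
        if not signs or signs[-1] != s:
            signs.append(s)
    return signs


def compare_spectra(calculated: Spectrum, observed: Spectrum,
                    tolerance_nm: float = 10.0, n_grid: int = 512) -> ShapeMatch:
    """Shape agreement: lobe sign sequence, sign-inversion point, rms.

    Both spectra are linearly resampled onto a common wavelength grid
    over their overlap and normalized to unit maximum magnitude.
    """
    calc = calculated.in_nm()
    obs = observed.in_nm()
    lo = max(calc.axis.min(), obs.axis.min())
    hi = min(calc.axis.max(), obs.axis.max())
    if hi <= lo:
        raise SpectraError("spectra do not overlap on the wavelength axis")
    grid = np.linspace(lo, hi, n_grid)
    vc = np.interp(grid, calc.axis, calc.values)
    vo = np.interp(grid, obs.axis, obs.values)
    for v in (vc, vo):
        m = np.abs(v).max()
        if m > 0:
            v /= m
    signs_match = _lobe_signs(vc) == _lobe_signs(vo)
    zc = _principal_zero_crossing(grid, vc)
    zo = _principal_zero_crossing(grid, vo)
    if zc is None and zo is None:
        delta = 0.0
    elif zc is None or zo is None:
        delta = np.inf
    else:
        delta = abs(zc - zo)
    rms = float(np.sqrt(((vc - vo) ** 2).mean()))
    return ShapeMatch(signs_match=signs_match, zero_crossing_delta=float(delta),
                      rms_normalized=rms,
                      passes=bool(signs_match and delta <= tolerance_nm))
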