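"""Synthetic fixtures: an ideal helical monomer with a pseudo-pigment, a
ground-truth lattice, restraints derived from it, and a matching density
map.  Every stage of the engine is testable against these bundles
without any deposited data.

The generator states a world and sticks to it: the *small* preset is a
12-residue helix on a 20 Å lattice (fast enough for full search
recovery in minutes); the *paperlike* preset mirrors the printed
baseplate geometry — a ~33 Å lattice in both directions with an ~81°
inter-vector angle, a ~25° helix criss-cross, and the dimer's pigment
centres 15.0 Å apart along the rod axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityMap, synthetic_density, write_mrc
from .errors import BaseplateError
from .restraints import (AmbiguousRestraint, EnergyModel, Weights,
                         save_restraints)
from .structure_io import (AtomRecord, MonomerStructure, ONE_TO_THREE,
                           write_pdb, StructureEnsemble)
from .symmetry import Assembly, SymmetryParams, expand_assembly

# ideal backbone geometry (Å, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.4}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position d with |cd|=length, angle(b,c,d), torsion(a,b,c,d)."""
    th = np.radians(angle_deg)
    ph = np.radians(torsion_deg)
    d_local = length * np.array([-np.cos(th), np.sin(th) * np.cos(ph),
                                 -np.sin(th) * np.sin(ph)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix_monomer(sequence: str,
                       phi: float = -57.0, psi: float = -47.0,
                       with_pigment: bool = True,
                       his_position: int | None = None,
                       pigment_center: np.ndarray | None = None,
                       ring_radius: float = 2.05,
                       chain_id: str = "A") -> MonomerStructure:
    """Ideal α-helix backbone (N/CA/C/O/CB) plus one pseudo-pigment.

    Built residue-by-residue from fixed phi/psi (default -57/-47 gives a
    ~1.5 Å rise and ~100°/residue twist, i.e. CA(i)-CA(i+1) ≈ 3.8 Å).
    The helix axis is aligned with +x and the centroid moved to the
    origin.  The pseudo-pigment is Mg + four ring nitrogens + two dipole
    marker carbons, ring plane perpendicular to the helix axis (ring
    normal along +x), centred near the designated attachment residue
    unless ``pigment_center`` overrides the position.
    """
    sequence = sequence.upper()
    if len(sequence) < 5:
        raise BaseplateError("sequence must have at least 5 residues")
    for ch in sequence:
        if ch not in ONE_TO_THREE:
            raise BaseplateError(f"invalid residue letter {ch!r}")
    n_res = len(sequence)
    # seed geometry for residue 1
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    C = [_place(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                _BOND["CA-C"], _ANGLE["N-CA-C"], phi)]
    for i in range(1, n_res):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1],
                        _BOND["C-N"], _ANGLE["CA-C-N"], psi))
        CA.append(_place(CA[i - 1], C[i - 1], N[i],
                         _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0))
        C.append(_place(C[i - 1], N[i], CA[i],
                        _BOND["CA-C"], _ANGLE["N-CA-C"], phi))
    O = []
    CB = []
    for i in range(n_res):
        next_n = N[i + 1] if i + 1 < n_res else None
        psi_i = psi
        O.append(_place(N[i], CA[i], C[i], _BOND["C-O"], _ANGLE["CA-C-O"],
                        psi_i + 180.0))
        if sequence[i] != "G":
            prev_c = C[i - 1] if i > 0 else N[i] + np.array([0.0, 1.0, 0.0])
            CB.append(_place(prev_c, N[i], CA[i], _BOND["CA-CB"],
                             _ANGLE["N-CA-CB"], phi + 122.6))
        else:
            CB.append(None)
    # align helix axis with +x (principal axis of the CA trace), centroid at origin
    ca = np.array(CA)
    centroid = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
                                    np.array([axis, vt[2]]))

    def tf(p):
        return rot.apply(p - centroid)

    atoms = []
    for i in range(n_res):
        res3 = ONE_TO_THREE[sequence[i]]
        num = i + 1
        atoms.append(AtomRecord(chain_id, num, res3, "N", "N", tf(N[i])))
        atoms.append(AtomRecord(chain_id, num, res3, "CA", "C", tf(CA[i])))
        atoms.append(AtomRecord(chain_id, num, res3, "C", "C", tf(C[i])))
        atoms.append(AtomRecord(chain_id, num, res3, "O", "O", tf(O[i])))
        if CB[i] is not None:
            atoms.append(AtomRecord(chain_id, num, res3, "CB", "C", tf(CB[i])))
    if with_pigment:
        his = his_position if his_position is not None else (n_res + 1) // 2
        ca_his = tf(CA[his - 1])
        center = (np.asarray(pigment_center, dtype=float)
                  if pigment_center is not None
                  else ca_his + np.array([0.0, -4.5, 0.0]))
        resnum = n_res + 1
        # ring plane xz, ring normal +y: stays in the baseplate plane under
        # any rotation about z, and the ring is flat against the helix row
        ring = {
            "MG": center,
            "NA": center + ring_radius * np.array([1.0, 0.0, 0.0]),
            "NB": center + ring_radius * np.array([0.0, 0.0, 1.0]),
            "NC": center + ring_radius * np.array([-1.0, 0.0, 0.0]),
            "ND": center + ring_radius * np.array([0.0, 0.0, -1.0]),
            "DM1": center + np.array([2.9, 0.0, 1.0]),
            "DM2": center + np.array([-2.9, 0.0, -1.0]),
        }
        for name, pos in ring.items():
            el = "MG" if name == "MG" else ("N" if name.startswith("N") else "C")
            atoms.append(AtomRecord(chain_id, resnum, "PIG", name, el, pos,
                                    is_pigment=True))
    return MonomerStructure(atoms)


# ---------------------------------------------------------------------------
# Restraint derivation


# typical 13C shifts (p.p.m.) per residue type, used by the synthetic
# shift-degeneracy model; jitter around these creates realistic overlap
_CA_SHIFT = {"ALA": 52.5, "ASP": 54.2, "SER": 58.3, "LEU": 55.1, "VAL": 62.2,
             "LYS": 56.9, "THR": 62.1, "GLY": 45.3, "PHE": 57.9, "MET": 55.3,
             "GLU": 56.6, "HIS": 56.0, "ILE": 61.6, "ASN": 53.6, "ARG": 56.5,
             "GLN": 56.2, "TRP": 57.7, "TYR": 58.1, "CYS": 58.2, "PRO": 63.3}
_CB_SHIFT = {"ALA": 19.0, "ASP": 41.1, "SER": 63.8, "LEU": 42.3, "VAL": 32.7,
             "LYS": 32.9, "THR": 69.7, "PHE": 39.5, "MET": 32.9, "GLU": 29.9,
             "HIS": 30.2, "ILE": 38.6, "ASN": 38.7, "ARG": 30.7, "GLN": 29.2,
             "TRP": 29.8, "TYR": 38.8, "CYS": 28.0, "PRO": 31.8}
_C_SHIFT = {"ALA": 177.8, "ASP": 176.4, "SER": 174.6, "LEU": 177.0, "VAL": 175.7,
            "LYS": 176.2, "THR": 174.5, "GLY": 174.0, "PHE": 175.5, "MET": 176.3,
            "GLU": 176.6, "HIS": 174.8, "ILE": 175.8, "ASN": 175.3, "ARG": 176.3}

_MATCH_HALF_WINDOW_PPM = 0.675
_SHIFT_JITTER_PPM = 0.4


def _synthetic_shift(residue_name: str, atom_name: str, rng) -> float:
    if atom_name == "CA":
        base = _CA_SHIFT.get(residue_name, 56.0)
    elif atom_name == "CB":
        base = _CB_SHIFT.get(residue_name, 35.0)
    else:
        base = _C_SHIFT.get(residue_name, 176.0)
    return base + rng.normal(0.0, _SHIFT_JITTER_PPM)


def derive_restraints(assembly_truth: Assembly, cutoff: float = 7.0,
                      ambiguity: bool = True, noise_sigma: float = 0.0,
                      seed: int = 0, upper_bound_floor: float = 0.0,
                      include_sequential: bool = False,
                      max_restraints: int | None = None
                      ) -> list[AmbiguousRestraint]:
    """Emit ambiguous restraints for every close carbon pair at the truth.

    Protein carbon pairs (intra-chain non-sequential, and all inter-image
    pairs involving the reference chain) whose true distance is below the
    cutoff become restraints.  With ``ambiguity`` on, every carbon gets a
    synthetic chemical shift (type-typical value + Gaussian jitter) and
    each restraint's option set is the product of the two shift-matching
    classes — every atom whose shift falls within the matching half
    window of the contact atom's shift — mimicking how cross-peak
    assignment ambiguity actually arises.  Upper bounds are the effective
    distance evaluated at the truth plus |Gaussian noise|, so noiseless
    restraints are satisfied exactly at the truth.
    """
    if cutoff <= 0:
        raise BaseplateError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    template = assembly_truth.template
    carbons = [(i, a) for i, a in enumerate(template.atoms)
               if a.element.upper() == "C" and not a.is_pigment]
    ref_idx = assembly_truth.reference_index()
    ref = assembly_truth.coords[ref_idx]
    # shift-degeneracy classes: atoms whose synthetic shifts overlap
    shift_of = {(a.residue_number, a.atom_name):
                _synthetic_shift(a.residue_name, a.atom_name, rng)
                for _, a in carbons}
    refs = sorted(shift_of)

    def match_class(key: tuple[int, str]) -> list[tuple[int, str]]:
        s = shift_of[key]
        return [k for k in refs if abs(shift_of[k] - s) <= _MATCH_HALF_WINDOW_PPM]

    pair_keys = set()
    for ii, (i, ai) in enumerate(carbons):
        for j, aj in carbons[ii + 1:]:
            sep = abs(ai.residue_number - aj.residue_number)
            if sep <= (0 if include_sequential else 1):
                continue
            if np.linalg.norm(ref[i] - ref[j]) <= cutoff:
                pair_keys.add(frozenset(((ai.residue_number, ai.atom_name),
                                         (aj.residue_number, aj.atom_name))))
    for g, img in enumerate(assembly_truth.images):
        if g == ref_idx:
            continue
        other = assembly_truth.coords[g]
        for i, ai in carbons:
            for j, aj in carbons:
                if np.linalg.norm(ref[i] - other[j]) <= cutoff:
                    pair_keys.add(frozenset(((ai.residue_number, ai.atom_name),
                                             (aj.residue_number, aj.atom_name))))
    if not pair_keys:
        import warnings
        warnings.warn("no carbon pairs under the cutoff; empty restraint list")
        return []

    keys = sorted(pair_keys, key=lambda fs: tuple(sorted(fs)))
    if max_restraints is not None and len(keys) > max_restraints:
        pick = rng.choice(len(keys), size=max_restraints, replace=False)
        keys = [keys[i] for i in sorted(pick)]
    restraints = []
    for k, key in enumerate(keys):
        pair = sorted(key)
        a = pair[0]
        b = pair[1] if len(pair) > 1 else pair[0]
        if ambiguity:
            # x == y is allowed: an atom can contact its own symmetry image
            opts = [(x, y) for x in match_class(a) for y in match_class(b)]
        else:
            opts = [(a, b)]
        restraints.append(AmbiguousRestraint(f"syn{k}", opts, upper_bound=1e6))

    # calibrate bounds with the same evaluator the optimizer uses
    model = EnergyModel(template, restraints, Weights(),
                        extent=_extent_of(assembly_truth))
    breakdown = model.evaluate(assembly_truth.params)
    for r in restraints:
        noise = abs(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0
        r.upper_bound = max(breakdown.effective_distances[r.peak_id] + noise,
                            upper_bound_floor)
    return restraints


def _extent_of(assembly: Assembly) -> tuple[int, int]:
    ms = [im.cell_index[0] for im in assembly.images]
    ns = [im.cell_index[1] for im in assembly.images]
    return max(ms), max(ns)


# ---------------------------------------------------------------------------
# Bundles


@dataclass
class FixtureBundle:
    monomer: MonomerStructure
    true_params: SymmetryParams
    restraints: list[AmbiguousRestraint]
    density: DensityMap
    seed: int
    preset: str
    extent: tuple[int, int]
    resolution: float
    provenance: dict = field(default_factory=dict)

    def truth_assembly(self) -> Assembly:
        return expand_assembly(self.monomer, self.true_params, *self.extent)

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_pdb(StructureEnsemble([self.monomer]), d / "monomer.pdb")
        save_restraints(self.restraints, d / "restraints.json")
        self.true_params.save(d / "truth.json")
        write_mrc(self.density, d / "map.mrc")
        (d / "provenance.json").write_text(json.dumps(self.provenance, indent=1,
                                                      sort_keys=True))


_PRESETS = {
    # sequence, lattice_a, lattice_b, dimer y-offset, rod-axis Mg half-spacing,
    # criss-cross half-angle (deg), map resolution, voxel
    "small": dict(sequence="ADSLVKTATGFL", lattice_a=20.0, lattice_b=(4.0, 29.0),
                  y_offset=8.5, mg_half=4.5, tilt_deg=15.0, pitch_deg=8.0,
                  resolution=10.0, voxel=2.5, cutoff=7.0, max_restraints=140),
    "paperlike": dict(sequence="ADSMLTELFDSLVKATGSHL", lattice_a=33.0,
                      lattice_b=(5.2, 32.6), y_offset=8.5, mg_half=7.5,
                      tilt_deg=12.5, pitch_deg=8.0, resolution=19.1, voxel=3.0,
                      cutoff=7.0, max_restraints=200),
}


def make_fixture_bundle(preset: str = "small", seed: int = 0,
                        noise_sigma: float = 0.0,
                        ambiguity: bool = True) -> FixtureBundle:
    """Deterministic fixture bundle for a named preset.

    The truth places the helix tilted by the preset's criss-cross
    half-angle about z (the C2 partner tilts the other way, giving the
    full criss-cross), offset from the C2 axis in y, with the pigment
    positioned so the two dimer Mg centres sit ``2 * mg_half`` apart
    along the rod (x) axis.
    """
    if preset not in _PRESETS:
        raise BaseplateError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[preset]
    # in-plane criss-cross half-angle plus a small out-of-plane pitch; the
    # pitch breaks the accidental up/down flip near-degeneracy of a purely
    # planar arrangement (real baseplate helices are not perfectly flat)
    rot = Rotation.from_euler("ZY", [p["tilt_deg"], p.get("pitch_deg", 0.0)],
                              degrees=True)  # Rz(tilt) @ Ry(pitch): the ring
    # normal (local +y) stays exactly in the baseplate plane
    x, y, z, w = rot.as_quat()
    quat_wxyz = np.array([w, x, y, z])
    translation = np.array([0.0, p["y_offset"], 0.0])
    params = SymmetryParams(quat_wxyz, translation, p["lattice_a"],
                            np.array(p["lattice_b"]))
    # place the pigment (in the local frame) so the assembly-frame Mg sits at
    # (mg_half, 0, 0): then the C2 image Mg is at (-mg_half, 0, 0).
    target_mg = np.array([p["mg_half"], 0.0, 0.0])
    local_center = rot.inv().apply(target_mg - translation)
    monomer = make_helix_monomer(p["sequence"], pigment_center=local_center)
    extent = (1, 1)
    assembly = expand_assembly(monomer, params, *extent)
    restraints = derive_restraints(assembly, cutoff=p["cutoff"],
                                   ambiguity=ambiguity,
                                   noise_sigma=noise_sigma, seed=seed,
                                   max_restraints=p.get("max_restraints"))
    density = synthetic_density(assembly, resolution=p["resolution"],
                                voxel=p["voxel"], padding=8.0)
    provenance = {
        "preset": preset, "seed": seed, "noise_sigma": noise_sigma,
        "ambiguity": ambiguity, "extent": list(extent), **{
            k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()},
    }
    return FixtureBundle(monomer=monomer, true_params=params,
                         restraints=restraints, density=density, seed=seed,
                         preset=preset, extent=extent,
                         resolution=p["resolution"], provenance=provenance)
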