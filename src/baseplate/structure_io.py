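"""Coordinate I/O, pigment geometry conventions, and validation measurements.

The baseplate convention used throughout the package: coordinates in
Ångström in a right-handed frame, the baseplate plane is xy and the
baseplate normal is +z.  Residue numbering is taken verbatim from the
input file; selections are inclusive ranges.  Heavy atoms are all
non-hydrogen atoms; hydrogens present in input are ignored by every
measurement and scoring operation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DihedralError,
    EnsembleError,
    InsufficientPigmentsError,
    PDBFormatError,
    PDBParseError,
    PigmentDefinitionError,
    SelectionError,
)

#: Residue names recognized as pigments by default (bacteriochlorophyll
#: dialects plus the synthetic pseudo-pigment).
DEFAULT_PIGMENT_RESNAMES = frozenset({"BCL", "BCB", "PIG"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class AtomRecord:
    """One atom: identity plus a position in Å."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    is_pigment: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite or malformed position for atom {self.atom_name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.atom_name}")
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class MonomerStructure:
    """One protein chain plus (usually) one bound pigment residue.

    This is the rigid body that the lattice symmetry replicates.
    """

    atoms: list[AtomRecord]

    @property
    def sequence(self) -> str:
        seq = []
        seen = set()
        for a in self.atoms:
            if a.is_pigment:
                continue
            key = (a.chain_id, a.residue_number)
            if key not in seen:
                seen.add(key)
                seq.append(THREE_TO_ONE.get(a.residue_name, "X"))
        return "".join(seq)

    def coords(self) -> np.ndarray:
        # cached: structures are treated as immutable once built; the
        # optimizer re-expands the same template thousands of times
        c = getattr(self, "_coords", None)
        if c is None:
            c = np.array([a.position for a in self.atoms], dtype=float)
            self._coords = c
        return c

    def with_coords(self, xyz: np.ndarray, chain_id: str | None = None) -> "MonomerStructure":
        xyz = np.asarray(xyz, dtype=float)
        out = []
        for a, p in zip(self.atoms, xyz):
            out.append(replace(a, position=p.copy(),
                               chain_id=chain_id if chain_id is not None else a.chain_id))
        return MonomerStructure(out)

    def atom_index(self) -> dict[tuple[int, str], int]:
        """(residue_number, atom_name) -> position in ``atoms``."""
        return {(a.residue_number, a.atom_name): i for i, a in enumerate(self.atoms)}

    def heavy_mask(self) -> np.ndarray:
        m = getattr(self, "_heavy_mask", None)
        if m is None:
            m = np.array([a.is_heavy for a in self.atoms], dtype=bool)
            self._heavy_mask = m
        return m

    def pigment_residues(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms if a.is_pigment})


@dataclass
class StructureEnsemble:
    """Models sharing identical atom ordering (e.g. an NMR ensemble)."""

    models: list[MonomerStructure]

    def __post_init__(self):
        if not self.models:
            raise EnsembleError("ensemble has no models")
        ref = [(a.atom_name, a.residue_number) for a in self.models[0].atoms]
        for k, m in enumerate(self.models[1:], start=2):
            names = [(a.atom_name, a.residue_number) for a in m.atoms]
            if names != ref:
                raise EnsembleError(
                    f"model {k} atom list differs from model 1 "
                    f"({len(names)} vs {len(ref)} atoms or mismatched names)"
                )


@dataclass
class PigmentSite:
    """Geometric and spectroscopic description of one pigment.

    ``site_energy`` in cm^-1, ``dipole_strength`` in Debye^2; the Qy
    transition dipole lies near the ring plane (checked, not enforced).
    """

    mg_position: np.ndarray
    ring_normal: np.ndarray
    qy_dipole_direction: np.ndarray
    site_energy: float = 12500.0
    dipole_strength: float = 37.0

    def __post_init__(self):
        self.mg_position = np.asarray(self.mg_position, dtype=float)
        self.ring_normal = np.asarray(self.ring_normal, dtype=float)
        self.qy_dipole_direction = np.asarray(self.qy_dipole_direction, dtype=float)
        for v, name in ((self.ring_normal, "ring_normal"),
                        (self.qy_dipole_direction, "qy_dipole_direction")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a unit vector")
        if self.site_energy <= 0:
            raise ValueError("site_energy must be positive")
        if abs(float(self.ring_normal @ self.qy_dipole_direction)) >= 0.3:
            raise ValueError("Qy dipole deviates too far from the ring plane")


@dataclass
class PigmentConvention:
    """Atom-naming convention for extracting a PigmentSite.

    Nomenclature of the ring nitrogens varies between PDB dialects, so
    both the ring-nitrogen names and the dipole axis pair are
    configurable.  The default Qy convention is the NA->NC axis.
    """

    mg_name: str = "MG"
    ring_nitrogens: tuple[str, str, str, str] = ("NA", "NB", "NC", "ND")
    dipole_axis: tuple[str, str] = ("NA", "NC")
    pigment_resnames: frozenset[str] = DEFAULT_PIGMENT_RESNAMES


# ---------------------------------------------------------------------------
# PDB I/O


def _parse_atom_line(line: str, lineno: int, pigment_resnames) -> AtomRecord:
    try:
        atom_name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB convention: atom name columns 13-16, element right-justified in 13-14
        stripped = atom_name.lstrip("0123456789")
        element = stripped[:2].strip() if stripped[:2] in ("MG", "FE", "ZN", "CL", "NA") else stripped[:1]
    return AtomRecord(
        chain_id=chain_id,
        residue_number=res_num,
        residue_name=res_name,
        atom_name=atom_name,
        element=element,
        position=np.array([x, y, z]),
        is_pigment=res_name in pigment_resnames,
    )


def read_pdb(path: str | Path,
             pigment_resnames: Iterable[str] = DEFAULT_PIGMENT_RESNAMES) -> StructureEnsemble:
    """Read a PDB file into an ensemble (one model per MODEL record).

    Files without MODEL records yield a single model.  Pigment residues
    are flagged by a residue-name whitelist.
    """
    pigment_resnames = frozenset(pigment_resnames)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno, pigment_resnames))
    if current or not saw_model:
        if current:
            models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return StructureEnsemble([MonomerStructure(m) for m in models])


def write_pdb(ensemble: StructureEnsemble | MonomerStructure, path: str | Path) -> None:
    """Write an ensemble as PDB with MODEL/ENDMDL per model and TER per chain."""
    if isinstance(ensemble, MonomerStructure):
        ensemble = StructureEnsemble([ensemble])
    lines = []
    for imodel, model in enumerate(ensemble.models, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        serial = 1
        prev_chain = None
        for a in model.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = a.chain_id
            if np.any(np.abs(a.position) >= 10000):
                raise PDBFormatError(
                    f"coordinate overflow for atom {a.atom_name}: {a.position}")
            record = "HETATM" if a.is_pigment else "ATOM  "
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            lines.append(
                f"{record}{serial % 100000:5d} {name:<4s}"
                f" {a.residue_name:<3s} {a.chain_id[:1]}{a.residue_number:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}"
            )
            serial += 1
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pigment geometry


def extract_pigment_site(structure: MonomerStructure,
                         convention: PigmentConvention | None = None,
                         site_energy: float = 12500.0,
                         dipole_strength: float = 37.0) -> PigmentSite:
    """Measure the pigment site geometry of a monomer.

    The ring normal is the unit normal of the least-squares plane through
    the four ring nitrogens; its sign follows the ring-atom ordering
    (cross product of NB-NA and ND-NA), which makes it behave as a proper
    pseudovector under coordinate mirrors.  The Qy dipole direction is
    the unit vector along the configured nitrogen axis (default NA->NC).
    """
    conv = convention or PigmentConvention()
    pig_atoms = {a.atom_name: a.position for a in structure.atoms if a.is_pigment}
    if conv.mg_name not in pig_atoms:
        raise PigmentDefinitionError(f"pigment lacks Mg atom {conv.mg_name!r}")
    missing = [n for n in conv.ring_nitrogens if n not in pig_atoms]
    if missing:
        raise PigmentDefinitionError(f"pigment lacks ring nitrogen(s) {missing}")
    ns = np.array([pig_atoms[n] for n in conv.ring_nitrogens])
    centered = ns - ns.mean(axis=0)
    # smallest principal axis of the 4 nitrogens = plane normal
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    orient = np.cross(ns[1] - ns[0], ns[3] - ns[0])
    if normal @ orient < 0:
        normal = -normal
    normal /= np.linalg.norm(normal)
    a1, a2 = conv.dipole_axis
    dip = pig_atoms[a2] - pig_atoms[a1]
    nrm = np.linalg.norm(dip)
    if nrm < 1e-9:
        raise PigmentDefinitionError("dipole axis atoms coincide")
    dip = dip / nrm
    # project the dipole exactly into the ring plane before the unit check
    dip = dip - (dip @ normal) * normal
    dip /= np.linalg.norm(dip)
    return PigmentSite(
        mg_position=pig_atoms[conv.mg_name].copy(),
        ring_normal=normal,
        qy_dipole_direction=dip,
        site_energy=site_energy,
        dipole_strength=dipole_strength,
    )


# ---------------------------------------------------------------------------
# Dihedrals


def _torsion(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, range (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DihedralError("undefined torsion: collinear atoms")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def backbone_dihedrals(structure: MonomerStructure) -> list[dict]:
    """Backbone phi/psi per residue; chain breaks yield missing (None) angles.

    A break is declared when the peptide C(i)-N(i+1) distance exceeds
    2.5 Å; torsions across it are reported as None rather than fabricated.
    """
    res: dict[int, dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.is_pigment:
            continue
        res.setdefault(a.residue_number, {})[a.atom_name] = a.position
    numbers = sorted(res)
    out = []
    for i in numbers:
        row = {"residue": i, "phi": None, "psi": None}
        r = res[i]
        prev = res.get(i - 1)
        nxt = res.get(i + 1)
        if prev is not None and all(k in prev for k in ("C",)) and all(
                k in r for k in ("N", "CA", "C")):
            if np.linalg.norm(prev["C"] - r["N"]) <= 2.5:
                row["phi"] = _torsion(prev["C"], r["N"], r["CA"], r["C"])
        if nxt is not None and "N" in nxt and all(k in r for k in ("N", "CA", "C")):
            if np.linalg.norm(r["C"] - nxt["N"]) <= 2.5:
                row["psi"] = _torsion(r["N"], r["CA"], r["C"], nxt["N"])
        out.append(row)
    return out


def _arc_distance(a: float, b: float) -> float:
    """Shortest angular distance in degrees between two angles."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def check_dihedral_restraints(dihedrals: list[dict],
                              restraint_table: Sequence[tuple[int, str, float, float]]
                              ) -> dict:
    """Count flat-bottom dihedral violations.

    Each restraint is ``(residue, angle_name, center_deg, halfwidth_deg)``;
    the violation is the shortest-arc distance from the centre minus the
    halfwidth, clipped at zero.  Returns count of violations > 0, their
    mean excess, and the per-restraint list.
    """
    by_res = {d["residue"]: d for d in dihedrals}
    excesses = []
    details = []
    for residue, angle_name, center, halfwidth in restraint_table:
        if angle_name not in ("phi", "psi"):
            raise DihedralError(f"unknown angle name {angle_name!r}")
        if residue not in by_res:
            raise DihedralError(f"residue {residue} absent from structure")
        obs = by_res[residue][angle_name]
        if obs is None:
            details.append((residue, angle_name, None, 0.0))
            continue
        excess = max(0.0, _arc_distance(obs, center) - halfwidth)
        details.append((residue, angle_name, obs, excess))
        if excess > 0:
            excesses.append(excess)
    return {
        "count": len(excesses),
        "mean_excess": float(np.mean(excesses)) if excesses else 0.0,
        "details": details,
    }


# ---------------------------------------------------------------------------
# Assembly measurements


def pairwise_mg_distances(mg_positions: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """All distinct Mg–Mg distances, ascending (Å)."""
    pos = np.asarray(mg_positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise InsufficientPigmentsError("need at least two pigment Mg positions")
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(pos), k=1)
    return np.sort(d[iu])


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal least-squares superposition (rotation + translation).

    Returns the superposed mobile coordinates and the RMSD.
    """
    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    moved = rot.apply(mob_c) + target.mean(axis=0)
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return moved, rmsd


def ensemble_rmsd(ensemble: StructureEnsemble,
                  residue_range: tuple[int, int] | None = None,
                  include_pigment: bool = True,
                  heavy_atoms_only: bool = True) -> float:
    """Average pairwise RMSD (Å) after Kabsch superposition on a selection.

    ``residue_range`` is an inclusive protein residue range; the pigment
    residue is included when ``include_pigment`` is set regardless of the
    range.  Hydrogens are excluded by default.
    """
    if len(ensemble.models) < 2:
        raise EnsembleError("ensemble_rmsd needs at least two models")
    ref = ensemble.models[0]
    mask = []
    for a in ref.atoms:
        if heavy_atoms_only and not a.is_heavy:
            mask.append(False)
        elif a.is_pigment:
            mask.append(include_pigment)
        elif residue_range is None:
            mask.append(True)
        else:
            lo, hi = residue_range
            mask.append(lo <= a.residue_number <= hi)
    mask = np.array(mask, dtype=bool)
    if not mask.any():
        raise SelectionError("selection empty after filtering")
    coords = [m.coords()[mask] for m in ensemble.models]
    rmsds = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            _, r = kabsch_superpose(coords[i], coords[j])
            rmsds.append(r)
    return float(np.mean(rmsds))
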