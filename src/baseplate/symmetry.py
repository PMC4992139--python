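"""C2-dimer + 2D-lattice symmetry: parameterization and expansion.

The searched degrees of freedom are the pose of one rigid monomer in the
dimer frame (rotation + translation), plus two in-plane lattice
translations.  Gauge fixing removes global rotation/translation freedom:
lattice vector **a** lies along +x, **b** is confined to the xy plane,
and the two-fold (C2) axis is +z through the origin — the baseplate
normal.  An image ``(s, m, n)`` places the monomer at

    x -> C2^s (R x + t) + m a + n b

so the full assembly at extent ``(n_a, n_b)`` has
``2 (2 n_a + 1)(2 n_b + 1)`` chains.

The optimizer genome is the 9-vector
``[rx, ry, rz, tx, ty, tz, a, bx, by]`` where ``(rx, ry, rz)`` is the
rotation vector (axis * angle, radians) of the monomer rotation; the
quaternion double cover (q and -q) collapses onto one rotation vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .structure_io import MonomerStructure

C2Z = np.diag([-1.0, -1.0, 1.0])

#: genome layout, stable across checkpoints
VECTOR_ORDER = ("rot_x", "rot_y", "rot_z", "t_x", "t_y", "t_z",
                "lattice_a", "lattice_b_x", "lattice_b_y")


def _quat_wxyz_to_rotation(q: np.ndarray) -> Rotation:
    return Rotation.from_quat([q[1], q[2], q[3], q[0]])  # scipy is xyzw


def _rotation_to_quat_wxyz(rot: Rotation) -> np.ndarray:
    x, y, z, w = rot.as_quat()
    return np.array([w, x, y, z])


@dataclass
class SymmetryParams:
    monomer_rotation: np.ndarray  # unit quaternion, (w, x, y, z)
    monomer_translation: np.ndarray
    lattice_a: float
    lattice_b: np.ndarray  # 2-vector in the xy plane

    def __post_init__(self):
        self.monomer_rotation = np.asarray(self.monomer_rotation, dtype=float)
        self.monomer_translation = np.asarray(self.monomer_translation, dtype=float)
        self.lattice_b = np.asarray(self.lattice_b, dtype=float)
        if self.monomer_rotation.shape != (4,):
            raise ParameterError("quaternion must have 4 components (w, x, y, z)")
        nrm = np.linalg.norm(self.monomer_rotation)
        if abs(nrm - 1.0) > 1e-6:
            raise ParameterError(f"quaternion not normalized (|q| = {nrm:.6f})")
        self.monomer_rotation = self.monomer_rotation / nrm
        if self.lattice_a <= 0:
            raise ParameterError("lattice_a must be positive")
        bl = np.linalg.norm(self.lattice_b)
        if bl <= 0:
            raise ParameterError("lattice_b must be non-zero")
        ang = np.degrees(np.arctan2(abs(self.lattice_b[1]), self.lattice_b[0]))
        if not (30.0 < ang < 150.0):
            raise ParameterError(
                f"angle between lattice vectors is {ang:.1f} deg, outside (30, 150)")

    # -- derived geometry -------------------------------------------------
    @property
    def rotation_matrix(self) -> np.ndarray:
        # cached: the hot path evaluates thousands of parameter sets and
        # every image operator needs this matrix
        R = getattr(self, "_rotmat", None)
        if R is None:
            w, x, y, z = self.monomer_rotation
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ])
            object.__setattr__(self, "_rotmat", R)
        return R

    @property
    def a_vector(self) -> np.ndarray:
        return np.array([self.lattice_a, 0.0, 0.0])

    @property
    def b_vector(self) -> np.ndarray:
        return np.array([self.lattice_b[0], self.lattice_b[1], 0.0])

    def to_dict(self) -> dict:
        return {
            "monomer_rotation_wxyz": self.monomer_rotation.tolist(),
            "monomer_translation": self.monomer_translation.tolist(),
            "lattice_a": float(self.lattice_a),
            "lattice_b": self.lattice_b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryParams":
        return cls(np.array(d["monomer_rotation_wxyz"]),
                   np.array(d["monomer_translation"]),
                   float(d["lattice_a"]), np.array(d["lattice_b"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SymmetryParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SymmetryImage:
    """One symmetry copy: C2 index and lattice cell."""

    c2_index: int
    cell_index: tuple[int, int]

    def operator(self, params: SymmetryParams) -> tuple[np.ndarray, np.ndarray]:
        """(rotation matrix, translation) of this image's rigid transform."""
        R = params.rotation_matrix
        t = params.monomer_translation
        m, n = self.cell_index
        shift = m * params.a_vector + n * params.b_vector
        if self.c2_index:
            return C2Z @ R, C2Z @ t + shift
        return R, t + shift

    def label(self) -> str:
        m, n = self.cell_index
        return f"s{self.c2_index}_m{m:+d}_n{n:+d}"


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class Assembly:
    """Expanded lattice: shared monomer template + per-image coordinates."""

    template: MonomerStructure
    params: SymmetryParams
    images: list[SymmetryImage]
    coords: np.ndarray  # (n_images, n_atoms, 3)
    operators: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_chains(self) -> int:
        return len(self.images)

    def reference_index(self) -> int:
        return self.images.index(SymmetryImage(0, (0, 0)))

    def image_coords(self, image: SymmetryImage) -> np.ndarray:
        return self.coords[self.images.index(image)]

    def chains(self) -> list[MonomerStructure]:
        out = []
        for i, img in enumerate(self.images):
            cid = _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)]
            out.append(self.template.with_coords(self.coords[i], chain_id=cid))
        return out

    def merged(self) -> MonomerStructure:
        """All chains concatenated into one structure (for PDB writing)."""
        atoms = []
        for ch in self.chains():
            atoms.extend(ch.atoms)
        return MonomerStructure(atoms)


def expand_assembly(monomer: MonomerStructure, params: SymmetryParams,
                    n_a: int = 1, n_b: int = 1) -> Assembly:
    """Replicate the monomer over C2 x lattice cells m,n in [-n_a..n_a] x [-n_b..n_b]."""
    X = monomer.coords()
    images = []
    ops = []
    blocks = []
    for s in (0, 1):
        for m in range(-n_a, n_a + 1):
            for n in range(-n_b, n_b + 1):
                img = SymmetryImage(s, (m, n))
                R, t = img.operator(params)
                images.append(img)
                ops.append((R, t))
                blocks.append(X @ R.T + t)
    return Assembly(template=monomer, params=params, images=images,
                    coords=np.array(blocks), operators=ops)


# ---------------------------------------------------------------------------
# Genome encoding


def params_to_vector(params: SymmetryParams) -> np.ndarray:
    rotvec = _quat_wxyz_to_rotation(params.monomer_rotation).as_rotvec()
    return np.concatenate([
        rotvec,
        params.monomer_translation,
        [params.lattice_a],
        params.lattice_b,
    ])


def vector_to_params(vec: np.ndarray) -> SymmetryParams:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (9,):
        raise ParameterError(f"genome must have length 9, got shape {vec.shape}")
    rot = Rotation.from_rotvec(vec[:3])
    return SymmetryParams(
        monomer_rotation=_rotation_to_quat_wxyz(rot),
        monomer_translation=vec[3:6].copy(),
        lattice_a=float(vec[6]),
        lattice_b=vec[7:9].copy(),
    )


# ---------------------------------------------------------------------------
# Pruning and comparison helpers


def bounding_sphere(monomer: MonomerStructure) -> tuple[np.ndarray, float]:
    """Centroid and enclosing radius of the monomer (local frame)."""
    X = monomer.coords()
    c = X.mean(axis=0)
    r = float(np.sqrt(((X - c) ** 2).sum(axis=1).max()))
    return c, r


def neighbor_images(params: SymmetryParams, cutoff: float,
                    monomer: MonomerStructure,
                    n_a: int = 2, n_b: int = 2) -> list[SymmetryImage]:
    """Images whose bounding sphere can approach the reference chain within cutoff.

    Complete by the triangle inequality (center separation <= 2 r + cutoff
    keeps the image); not guaranteed tight.  The reference image (0,(0,0))
    is excluded.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    center, radius = bounding_sphere(monomer)
    ref = SymmetryImage(0, (0, 0))
    Rr, tr = ref.operator(params)
    c_ref = Rr @ center + tr
    keep = []
    for s in (0, 1):
        for m in range(-n_a, n_a + 1):
            for n in range(-n_b, n_b + 1):
                img = SymmetryImage(s, (m, n))
                if img == ref:
                    continue
                R, t = img.operator(params)
                c_img = R @ center + t
                if np.linalg.norm(c_img - c_ref) <= 2 * radius + cutoff:
                    keep.append(img)
    return keep


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Fix the double-cover sign: first non-zero component positive."""
    q = np.asarray(q, dtype=float)
    for comp in q:
        if abs(comp) > 1e-12:
            return q if comp > 0 else -q
    return q


def orientation_error_deg(params: SymmetryParams, truth: SymmetryParams) -> float:
    """Rotation-angle distance to the true monomer orientation (degrees).

    The C2 operation relabels the two dimer positions, so a pose and its
    C2 image describe the same assembly; the error is the minimum over
    that equivalence.
    """
    R = params.rotation_matrix
    Rt = truth.rotation_matrix
    errs = []
    for Req in (Rt, C2Z @ Rt):
        delta = Rotation.from_matrix(R @ Req.T)
        errs.append(np.degrees(delta.magnitude()))
    return float(min(errs))
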