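"""Rigid-body transforms in homogeneous coordinates and the motion-magnitude metric.

Head motion during a PET/MR scan is modelled as a rigid-body transform: a 4x4
homogeneous matrix whose upper-left 3x3 block is a proper rotation and whose
last column carries the translation in millimetres.  Each transform is
generated from six parameters: three rotations (degrees) and three
translations (mm).

Conventions
-----------
* World frame: right-handed RAS with the origin at the scanner's centre of
  field of view (cFOV); +y is anterior, so a point 60 mm in front of the cFOV
  is ``(0, 60, 0)``.
* Rotations are intrinsic, applied in the order x -> y -> z (rx = pitch /
  "nodding", ry = roll, rz = yaw), about the world origin, followed by the
  translation.
* A transform maps reference-space coordinates to moved-space coordinates;
  the displacement of an anatomical point ``p`` is ``T(p) - p``.

The motion magnitude of a transform at a reference point is the Euclidean
norm of that displacement.  The canonical QC point is the frontal cortex
point 60 mm anterior of the cFOV, where head rotations (nodding) produce the
largest displacement; translations displace every point equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "ReferencePoint",
    "FRONTAL_CORTEX",
    "CFOV",
    "make_rigid",
    "from_matrix",
    "identity",
    "compose",
    "invert",
    "apply_to_point",
    "motion_magnitude",
]

#: Intrinsic Euler order used throughout (uppercase = intrinsic in scipy).
ROTATION_ORDER = "XYZ"

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A rigid-body transform: 4x4 homogeneous matrix plus its 6 generators.

    Attributes
    ----------
    params:
        ``(rx, ry, rz, tx, ty, tz)`` — rotations in degrees, translations in
        mm.  The matrix is always regenerated from these, so the two
        representations cannot drift apart.
    matrix:
        The 4x4 homogeneous matrix.  Rotation block is orthonormal with
        determinant +1; bottom row is exactly ``(0, 0, 0, 1)``.
    convention:
        Euler order label, currently always ``"XYZ"`` (intrinsic).
    """

    params: np.ndarray
    matrix: np.ndarray = field(repr=False)
    convention: str = ROTATION_ORDER

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", np.asarray(self.params, dtype=float))
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        self.params.setflags(write=False)
        self.matrix.setflags(write=False)

    @property
    def rotation(self) -> np.ndarray:
        """The 3x3 rotation block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """The translation column in mm."""
        return self.matrix[:3, 3]

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=tol))

    def __call__(self, p) -> np.ndarray:
        return apply_to_point(self, p)


@dataclass(frozen=True)
class ReferencePoint:
    """A named world-space point at which motion magnitude is evaluated."""

    name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"reference point {self.name!r} needs 3 finite coords")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)


#: The QC point 60 mm anterior of the scanner centre of FOV (frontal cortex).
FRONTAL_CORTEX = ReferencePoint("frontal_cortex", (0.0, 60.0, 0.0))
#: The scanner centre of field of view (world origin).
CFOV = ReferencePoint("cFOV", (0.0, 0.0, 0.0))


def _matrix_from_params(params: np.ndarray, convention: str) -> np.ndarray:
    mat = np.eye(4)
    mat[:3, :3] = Rotation.from_euler(convention, params[:3], degrees=True).as_matrix()
    mat[:3, 3] = params[3:]
    return mat


def make_rigid(params, convention: str = ROTATION_ORDER) -> RigidTransform:
    """Build a rigid transform from ``(rx, ry, rz, tx, ty, tz)``.

    Rotations in degrees about the world origin (intrinsic x->y->z order),
    then translation in mm: ``T(p) = R p + t``.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError(f"expected 6 parameters, got shape {params.shape}")
    if not np.all(np.isfinite(params)):
        raise ValueError("rigid-transform parameters must be finite")
    if convention != ROTATION_ORDER:
        raise ValueError(f"unsupported rotation convention {convention!r}")
    return RigidTransform(params, _matrix_from_params(params, convention), convention)


def identity() -> RigidTransform:
    """The identity transform (no motion)."""
    return make_rigid(np.zeros(6))


def from_matrix(matrix, convention: str = ROTATION_ORDER) -> RigidTransform:
    """Build a transform from a 4x4 homogeneous matrix, extracting params.

    The rotation block must be orthonormal with determinant +1 and the bottom
    row ``(0, 0, 0, 1)``.  Euler angles are extracted in the package
    convention; at gimbal lock (|ry| = 90 deg) rx is set to 0, which leaves
    the matrix unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {matrix.shape}")
    rot = matrix[:3, :3]
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation block is not orthonormal")
    if np.linalg.det(rot) < 0:
        raise ValueError("rotation block has negative determinant (reflection)")
    if not np.array_equal(matrix[3], [0.0, 0.0, 0.0, 1.0]):
        raise ValueError("bottom row must be exactly (0, 0, 0, 1)")
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; the chosen angles still reproduce the
        # matrix exactly, which is the invariant we need.
        warnings.simplefilter("ignore")
        angles = Rotation.from_matrix(rot).as_euler(convention, degrees=True)
    params = np.concatenate([angles, matrix[:3, 3]])
    return RigidTransform(params, _matrix_from_params(params, convention), convention)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the transform whose action is *apply b, then a*."""
    return from_matrix(a.matrix @ b.matrix)


def invert(t: RigidTransform) -> RigidTransform:
    """Return the inverse transform: ``compose(t, invert(t))`` is identity."""
    rot = t.rotation.T
    mat = np.eye(4)
    mat[:3, :3] = rot
    mat[:3, 3] = -rot @ t.translation
    return from_matrix(mat)


def apply_to_point(t: RigidTransform, p) -> np.ndarray:
    """Apply ``t`` to a world point (mm): first three rows of ``M @ (p, 1)``."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 3-vector")
    return t.rotation @ p + t.translation


def apply_to_points(t: RigidTransform, pts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`apply_to_point` for an ``(N, 3)`` array."""
    pts = np.asarray(pts, dtype=float)
    return pts @ t.rotation.T + t.translation


def motion_magnitude(t: RigidTransform, ref: ReferencePoint) -> float:
    """Euclidean displacement (mm) of ``ref`` under ``t``.

    For a pure z-rotation by angle theta this is the chord length
    ``2 r sin(theta / 2)`` at radius ``r`` from the axis; for a pure
    translation it is the translation norm at every point.
    """
    return float(np.linalg.norm(apply_to_point(t, ref.coords) - ref.coords))
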