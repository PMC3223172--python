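"""Rigid-transform algebra for tracked-ultrasound coordinate chains.

Every transform in the pipeline — probe calibration (scan plane P to
sensor R), tracker pose (sensor R to tracker T) and fiducial
registration (CT space C to tracker T) — is a proper rigid map:
three Euler rotations plus a translation, all lengths in millimetres.

Convention: fixed axes, column vectors, rotations acting on objects,
applied in the order z, then y, then x.  The composite rotation matrix
is therefore ``R_x(alpha) @ R_y(beta) @ R_z(gamma)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "Point3",
    "PixelCoord",
    "make_transform",
    "compose",
    "invert",
    "pixel_to_plane",
]

_GIMBAL_TOL = 1e-12


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(b: float) -> np.ndarray:
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(g: float) -> np.ndarray:
    c, s = np.cos(g), np.sin(g)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _euler_zyx_to_matrix(gamma: float, beta: float, alpha: float) -> np.ndarray:
    """Fixed-axes z-y-x rotation: z applied first, so R = Rx @ Ry @ Rz."""
    return _rot_x(alpha) @ _rot_y(beta) @ _rot_z(gamma)


def _matrix_to_euler_zyx(rot: np.ndarray) -> tuple[float, float, float]:
    """Extract (gamma, beta, alpha) with R = Rx(alpha) Ry(beta) Rz(gamma).

    At gimbal lock (|beta| = pi/2) alpha is pinned to 0 and the residual
    rotation is folded into gamma, which makes the extraction
    deterministic.
    """
    s_beta = np.clip(rot[0, 2], -1.0, 1.0)
    beta = float(np.arcsin(s_beta))
    c_beta = np.cos(beta)
    if abs(c_beta) < _GIMBAL_TOL:
        alpha = 0.0
        gamma = float(np.arctan2(rot[1, 0], rot[1, 1]))
    else:
        gamma = float(np.arctan2(-rot[0, 1], rot[0, 0]))
        alpha = float(np.arctan2(-rot[1, 2], rot[2, 2]))
    return gamma, beta, alpha


@dataclass(frozen=True)
class Point3:
    """A location in mm within a named coordinate space (P, R, T, A or C)."""

    x: float
    y: float
    z: float
    space: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Point3 components must be finite")
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, float(getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class PixelCoord:
    """0-based pixel index with mm/pixel scale (pixel-centre convention)."""

    row: float
    col: float
    scale: tuple[float, float] = (1.0, 1.0)  # (s_row, s_col) mm per pixel

    def __post_init__(self) -> None:
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError("pixel scale must be strictly positive")


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid map: z-y-x fixed-axes Euler angles + translation.

    ``angles`` is (gamma about z, beta about y, alpha about x) in radians;
    ``translation`` is in mm.  The homogeneous 4x4 matrix is cached.
    """

    angles: tuple[float, float, float]
    translation: tuple[float, float, float]
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if ang.shape != (3,) or t.shape != (3,):
            raise ValueError("angles and translation must be 3-vectors")
        if not (np.all(np.isfinite(ang)) and np.all(np.isfinite(t))):
            raise ValueError("angles and translation must be finite")
        m = np.eye(4)
        m[:3, :3] = _euler_zyx_to_matrix(*ang)
        m[:3, 3] = t
        object.__setattr__(self, "angles", tuple(float(a) for a in ang))
        object.__setattr__(self, "translation", tuple(float(x) for x in t))
        object.__setattr__(self, "_matrix", m)

    # -- core algebra ------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (copy; the cached form is immutable)."""
        return self._matrix.copy()

    @property
    def rotation(self) -> np.ndarray:
        return self._matrix[:3, :3].copy()

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 (or 3x4) homogeneous matrix.

        The rotation block must be orthonormal with determinant +1
        (tolerance 1e-9 on orthonormality, re-orthonormalised by SVD to
        keep long composition chains from drifting).
        """
        m = np.asarray(matrix, dtype=float)
        if m.shape == (3, 4):
            m = np.vstack([m, [0.0, 0.0, 0.0, 1.0]])
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        rot = m[:3, :3]
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation block must have determinant +1")
        if np.max(np.abs(rot @ rot.T - np.eye(3))) > 1e-6:
            raise ValueError("rotation block is not orthonormal")
        u, _, vt = np.linalg.svd(rot)
        rot = u @ vt
        gamma, beta, alpha = _matrix_to_euler_zyx(rot)
        return cls((gamma, beta, alpha), tuple(m[:3, 3]))

    def apply(self, point) -> np.ndarray:
        """Apply to a Point3 or a (3,) / (n, 3) array of mm coordinates."""
        if isinstance(point, Point3):
            p = point.as_array()
        else:
            p = np.asarray(point, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self._matrix[:3, :3].T + self._matrix[:3, 3]
        return out[0] if single else out

    def __call__(self, point) -> np.ndarray:
        return self.apply(point)

    # -- serialization -----------------------------------------------------

    def to_row(self) -> list[float]:
        """12-number row: 9 rotation entries row-major + 3 translation."""
        return [float(v) for v in (*self._matrix[:3, :3].ravel(), *self._matrix[:3, 3])]

    @classmethod
    def from_row(cls, row: Sequence[float]) -> "RigidTransform":
        vals = np.asarray(list(row), dtype=float)
        if vals.size != 12:
            raise ValueError("expected 12 numbers (9 rotation + 3 translation)")
        m = np.eye(4)
        m[:3, :3] = vals[:9].reshape(3, 3)
        m[:3, 3] = vals[9:]
        return cls.from_matrix(m)

    def to_json(self) -> str:
        return json.dumps(
            {"angles_zyx": list(self.angles), "translation": list(self.translation)}
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        obj = json.loads(text)
        return cls(tuple(obj["angles_zyx"]), tuple(obj["translation"]))


def make_transform(
    angles: Iterable[float], translation: Iterable[float]
) -> RigidTransform:
    """Construct a rigid transform from z-y-x fixed-axes Euler angles (rad)
    and a translation (mm)."""
    return RigidTransform(tuple(angles), tuple(translation))


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Return the transform equal to applying ``inner`` first, then ``outer``."""
    return RigidTransform.from_matrix(outer._matrix @ inner._matrix)


def invert(t: RigidTransform) -> RigidTransform:
    rot = t._matrix[:3, :3]
    m = np.eye(4)
    m[:3, :3] = rot.T
    m[:3, 3] = -rot.T @ t._matrix[:3, 3]
    return RigidTransform.from_matrix(m)


def pixel_to_plane(p: PixelCoord) -> Point3:
    """Map an image pixel to its mm location in the scan plane (P space).

    x runs along columns, y along rows, z = 0 in the plane.
    """
    if p.row < 0 or p.col < 0:
        raise ValueError("pixel indices must be non-negative")
    s_row, s_col = p.scale
    return Point3(p.col * s_col, p.row * s_row, 0.0, space="P")


def plane_to_pixel(point: Point3, scale: tuple[float, float]) -> PixelCoord:
    """Inverse of :func:`pixel_to_plane`: nearest pixel to a plane point."""
    s_row, s_col = scale
    return PixelCoord(round(point.y / s_row), round(point.x / s_col), scale)
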