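"""Tracker-to-CT registration from paired fiducials.

Corresponding points picked in the CT stack (C space) and touched with a
tracked stylus (T space) determine the rigid map T T_C by Horn's
closed-form absolute-orientation solution (unit-quaternion formulation).
Fiducial registration error (FRE) is the mean residual distance of the
fitted pairs; target registration error (TRE) is the distance between
corresponding non-fiducial targets after the full transform chain and is
the end-to-end accuracy metric.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import Point3, RigidTransform

__all__ = [
    "FiducialPair",
    "RegistrationResult",
    "horn_registration",
    "fiducial_registration_error",
    "target_registration_error",
    "read_fiducial_pairs",
    "write_fiducial_pairs",
    "DegenerateConfigurationError",
]


class DegenerateConfigurationError(ValueError):
    """Too few pairs or a collinear fiducial configuration."""


@dataclass(frozen=True)
class FiducialPair:
    ct_point: Point3  # C space, mm
    tracked_point: Point3  # T space, mm
    label: str = ""


@dataclass(frozen=True)
class RegistrationResult:
    tracker_from_ct: RigidTransform  # T T_C
    fre_per_pair: tuple[float, ...]  # mm
    mean_fre: float  # mm

    def to_json(self) -> str:
        return json.dumps(
            {
                "tracker_from_ct": {
                    "angles_zyx": list(self.tracker_from_ct.angles),
                    "translation": list(self.tracker_from_ct.translation),
                },
                "fre_per_pair_mm": list(self.fre_per_pair),
                "mean_fre_mm": self.mean_fre,
            }
        )


def _point_arrays(pairs: Sequence[FiducialPair]) -> tuple[np.ndarray, np.ndarray]:
    ct = np.array([p.ct_point.as_array() for p in pairs])
    tr = np.array([p.tracked_point.as_array() for p in pairs])
    return ct, tr


def horn_registration(pairs: Sequence[FiducialPair]) -> RegistrationResult:
    """Closed-form least-squares rigid fit of tracked points to CT points.

    Builds the 4x4 quaternion matrix from the cross-covariance of the
    demeaned point sets; the eigenvector of its largest eigenvalue is the
    optimal unit quaternion.  Requires at least three non-collinear pairs.
    """
    if len(pairs) < 3:
        raise DegenerateConfigurationError(
            f"registration needs >= 3 fiducial pairs, got {len(pairs)}"
        )
    ct, tr = _point_arrays(pairs)
    ct_c = ct - ct.mean(axis=0)
    tr_c = tr - tr.mean(axis=0)
    # collinear (or coincident) fiducials leave a rotation dof unconstrained
    if np.linalg.svd(ct_c, compute_uv=False)[1] < 1e-9:
        raise DegenerateConfigurationError("fiducials are collinear")

    m = ct_c.T @ tr_c  # cross-covariance, CT -> tracker
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(n)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = tr.mean(axis=0) - rot @ ct.mean(axis=0)
    hom = np.eye(4)
    hom[:3, :3] = rot
    hom[:3, 3] = t
    transform = RigidTransform.from_matrix(hom)

    fre = np.linalg.norm(transform.apply(ct) - tr, axis=1)
    return RegistrationResult(
        tracker_from_ct=transform,
        fre_per_pair=tuple(float(v) for v in fre),
        mean_fre=float(fre.mean()),
    )


def fiducial_registration_error(
    reg: RegistrationResult, pairs: Sequence[FiducialPair]
) -> tuple[float, float]:
    """Mean and sample sd (n-1) of the per-pair FRE on any pair set.

    On the fitting set the mean equals ``reg.mean_fre``.
    """
    if not pairs:
        raise ValueError("fiducial pair list is empty")
    ct, tr = _point_arrays(pairs)
    d = np.linalg.norm(reg.tracker_from_ct.apply(ct) - tr, axis=1)
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return float(d.mean()), sd


def target_registration_error(
    predicted: Sequence[Point3] | np.ndarray,
    truth: Sequence[Point3] | np.ndarray,
) -> tuple[list[float], float, float]:
    """Pairwise mm distances between predicted and true target locations.

    Returns (distances, mean, sample sd with n-1).
    """

    def to_arr(pts) -> np.ndarray:
        if isinstance(pts, np.ndarray):
            return np.atleast_2d(np.asarray(pts, dtype=float))
        return np.array([p.as_array() for p in pts])

    p = to_arr(predicted)
    t = to_arr(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth lists differ in length")
    d = np.linalg.norm(p - t, axis=1)
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return [float(v) for v in d], float(d.mean()), sd


# -- fiducial CSV -------------------------------------------------------------

_FID_HEADER = ["label", "ct_x", "ct_y", "ct_z", "tr_x", "tr_y", "tr_z"]


def write_fiducial_pairs(path: str | Path, pairs: Sequence[FiducialPair]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FID_HEADER)
        for p in pairs:
            writer.writerow(
                [
                    p.label,
                    repr(p.ct_point.x), repr(p.ct_point.y), repr(p.ct_point.z),
                    repr(p.tracked_point.x), repr(p.tracked_point.y), repr(p.tracked_point.z),
                ]
            )


def read_fiducial_pairs(path: str | Path) -> list[FiducialPair]:
    pairs = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            pairs.append(
                FiducialPair(
                    ct_point=Point3(
                        float(rec["ct_x"]), float(rec["ct_y"]), float(rec["ct_z"]), "C"
                    ),
                    tracked_point=Point3(
                        float(rec["tr_x"]), float(rec["tr_y"]), float(rec["tr_z"]), "T"
                    ),
                    label=rec.get("label", ""),
                )
            )
    return pairs
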