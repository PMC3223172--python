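"""Single-point (cross-wire) probe calibration.

A fixed point — the crossing of two threads in a water bath — is imaged
from many transducer orientations.  Writing the wire cross as the origin
of an arbitrary space A, every sighting i satisfies

    T_A . T_R(i) . T_P . x_i  =  0

where T_R(i) is the tracked sensor pose (tracker from sensor), T_P the
unknown probe calibration (sensor from scan plane), x_i the mm location
of the cross in the image plane, and T_A translates the tracker origin
to the wire cross.  The nine free parameters (six of T_P, three
translations of T_A) are estimated by Levenberg-Marquardt least squares;
the rotation of T_A is pinned to identity because any rotation about the
target point itself is unidentifiable.  The per-observation residual is
the mm magnitude of the left-hand side, and its average is the
calibration's residual error.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import PixelCoord, RigidTransform, make_transform, pixel_to_plane

__all__ = [
    "TrackedObservation",
    "CalibrationResult",
    "calibrate_single_point",
    "calibration_residuals",
    "read_observation_log",
    "write_observation_log",
    "InsufficientDataError",
    "ConvergenceError",
]

#: Minimum per-axis spread of sensor orientations (radians) below which the
#: beam-direction component of the calibration translation is poorly
#: constrained and the condition flag is raised.
MIN_ANGLE_SPAN = np.deg2rad(10.0)

MAX_ITER = 200
STEP_TOL = 1e-10
COST_TOL = 1e-12


class InsufficientDataError(ValueError):
    """Fewer observations than the problem needs."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best: "CalibrationResult"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class TrackedObservation:
    """One cross-wire sighting: sensor pose, image point and timestamp."""

    sensor_pose: RigidTransform  # tracker-from-sensor, T T_R
    image_point: PixelCoord  # cross location in the US frame
    timestamp: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    probe_calibration: RigidTransform  # sensor-from-plane, R T_P
    wire_offset: tuple[float, float, float]  # translation of A T_T, mm
    residuals: tuple[float, ...]  # per-observation mm magnitudes
    mean_residual: float
    max_residual: float
    min_residual: float
    condition_flag: bool  # True when pose diversity is inadequate

    def to_json(self) -> str:
        return json.dumps(
            {
                "probe_calibration": {
                    "angles_zyx": list(self.probe_calibration.angles),
                    "translation": list(self.probe_calibration.translation),
                },
                "wire_offset": list(self.wire_offset),
                "mean_residual_mm": self.mean_residual,
                "max_residual_mm": self.max_residual,
                "min_residual_mm": self.min_residual,
                "n_observations": len(self.residuals),
                "condition_flag": self.condition_flag,
            }
        )


def _plane_points_mm(observations: Sequence[TrackedObservation]) -> np.ndarray:
    return np.array(
        [pixel_to_plane(o.image_point).as_array() for o in observations]
    )


def _residual_vectors(
    params: np.ndarray,
    poses: Sequence[np.ndarray],
    plane_pts: np.ndarray,
) -> np.ndarray:
    """Stacked 3-vectors T_A(T_Ri(T_P(x_i))) for the 9-parameter model."""
    calib = make_transform(params[:3], params[3:6])
    t_a = params[6:9]
    cm = calib.matrix
    out = np.empty((len(poses), 3))
    for i, pose in enumerate(poses):
        chain = pose @ cm
        out[i] = chain[:3, :3] @ plane_pts[i] + chain[:3, 3] + t_a
    return out.ravel()


def _angle_spans(observations: Sequence[TrackedObservation]) -> np.ndarray:
    ang = np.array([o.sensor_pose.angles for o in observations])
    return ang.max(axis=0) - ang.min(axis=0)


def _initial_guesses(
    observations: Sequence[TrackedObservation],
    plane_pts: np.ndarray,
    initial_guess: Optional[RigidTransform],
) -> list[np.ndarray]:
    """Identity-angle start with a centroid wire offset, then 8 axis-aligned
    restarts for the local LM solver."""
    guesses: list[np.ndarray] = []
    half = np.pi / 2

    def pack(calib: RigidTransform) -> np.ndarray:
        cm = calib.matrix
        pts = np.array(
            [
                o.sensor_pose.matrix[:3, :3] @ (cm[:3, :3] @ p + cm[:3, 3])
                + o.sensor_pose.matrix[:3, 3]
                for o, p in zip(observations, plane_pts)
            ]
        )
        # offset that centres the residual cloud on the wire cross
        return np.concatenate([calib.angles, calib.translation, -pts.mean(axis=0)])

    if initial_guess is not None:
        guesses.append(pack(initial_guess))
    guesses.append(pack(RigidTransform.identity()))
    for angles in [
        (half, 0, 0), (-half, 0, 0), (0, half, 0), (0, -half, 0),
        (0, 0, half), (0, 0, -half), (np.pi, 0, 0), (0, 0, np.pi),
    ]:
        guesses.append(pack(make_transform(angles, (0.0, 0.0, 0.0))))
    return guesses


def calibrate_single_point(
    observations: Sequence[TrackedObservation],
    initial_guess: Optional[RigidTransform] = None,
) -> CalibrationResult:
    """Estimate the probe calibration R T_P from cross-wire sightings.

    Parameters
    ----------
    observations
        At least four sightings of the same fixed point; image points are
        converted to mm via their pixel scale.
    initial_guess
        Optional starting calibration; the default is an identity-angle
        start with multi-start fallback.

    Returns
    -------
    CalibrationResult with the calibration, the wire offset (translation
    of A T_T), per-observation residual magnitudes in mm, and a condition
    flag raised when sensor orientations span less than 10 degrees about
    any axis (the translation along the beam is then unidentifiable).
    """
    if len(observations) < 4:
        raise InsufficientDataError(
            f"single-point calibration needs >= 4 observations, got {len(observations)}"
        )
    plane_pts = _plane_points_mm(observations)
    poses = [o.sensor_pose.matrix for o in observations]
    condition_flag = bool(np.any(_angle_spans(observations) < MIN_ANGLE_SPAN))

    best = None
    for x0 in _initial_guesses(observations, plane_pts, initial_guess):
        sol = least_squares(
            _residual_vectors,
            x0,
            args=(poses, plane_pts),
            method="lm",
            xtol=STEP_TOL,
            ftol=COST_TOL,
            gtol=1e-12,
            max_nfev=MAX_ITER * 10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < max(1e-18, best.cost * (1 + 1e-9)):
            if sol.cost <= best.cost:
                best = sol
            # accept the first converged basin; restarts only matter when
            # LM stalls far from the optimum
            if sol.cost < 1e-16 * max(1, len(observations)):
                break
    assert best is not None

    calib = make_transform(best.x[:3], best.x[3:6])
    res_vec = _residual_vectors(best.x, poses, plane_pts).reshape(-1, 3)
    mags = np.linalg.norm(res_vec, axis=1)
    result = CalibrationResult(
        probe_calibration=calib,
        wire_offset=tuple(best.x[6:9]),
        residuals=tuple(mags),
        mean_residual=float(mags.mean()),
        max_residual=float(mags.max()),
        min_residual=float(mags.min()),
        condition_flag=condition_flag,
    )
    if not best.success:
        raise ConvergenceError(
            f"Levenberg-Marquardt did not converge: {best.message}", result
        )
    return result


def calibration_residuals(
    calibration: CalibrationResult,
    observations: Sequence[TrackedObservation],
) -> list[float]:
    """Residual mm magnitude of each observation under a calibration.

    residual_i = || T_A . T_R(i) . T_P . x_i ||, in input order.
    """
    params = np.concatenate(
        [
            calibration.probe_calibration.angles,
            calibration.probe_calibration.translation,
            calibration.wire_offset,
        ]
    )
    plane_pts = _plane_points_mm(observations)
    poses = [o.sensor_pose.matrix for o in observations]
    vec = _residual_vectors(params, poses, plane_pts).reshape(-1, 3)
    return [float(v) for v in np.linalg.norm(vec, axis=1)]


# -- observation log CSV ----------------------------------------------------

_LOG_HEADER = (
    ["timestamp"]
    + [f"pose_{i}" for i in range(12)]
    + ["row", "col", "s_row", "s_col"]
)


def write_observation_log(
    path: str | Path, observations: Sequence[TrackedObservation]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LOG_HEADER)
        for o in observations:
            writer.writerow(
                [o.timestamp]
                + [repr(v) for v in o.sensor_pose.to_row()]
                + [o.image_point.row, o.image_point.col, *o.image_point.scale]
            )


def read_observation_log(path: str | Path) -> list[TrackedObservation]:
    observations = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            pose = RigidTransform.from_row(
                [float(rec[f"pose_{i}"]) for i in range(12)]
            )
            pix = PixelCoord(
                float(rec["row"]),
                float(rec["col"]),
                (float(rec["s_row"]), float(rec["s_col"])),
            )
            observations.append(
                TrackedObservation(pose, pix, float(rec["timestamp"]))
            )
    return observations
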