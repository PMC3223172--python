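"""Seeded generators for every input the fusion pipeline consumes.

Each generator is a pure function of its parameters and seed and emits
the exact generative ground truth alongside the data, so downstream
modules always have an oracle: cross-wire observation sets with a known
probe calibration, fiducial pairs with a known registration, a mouse-like
CT volume (tumour ellipsoid in a thin fat slab over bone) with its exact
label map, a grid-of-discs dual-modality phantom with known target
centres, and an oscillating bath-floor US sequence with a known stream
lag.

Default tissue values mirror the imaging conditions being emulated:
fat -120 HU, tumour 68 HU, fat pad -97 HU, bone 1000 HU, air -1000 HU,
voxel noise sigma 30 HU; a 1-3 mm fat slab at 0.3 mm voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    PixelCoord,
    Point3,
    RigidTransform,
    compose,
    invert,
    make_transform,
)
from .hu_segmentation import BACKGROUND, BONE, FAT, PROTEIN, CTVolume, LabelMap
from .probe_calibration import TrackedObservation
from .registration import FiducialPair
from .temporal_sync import SignalSeries

__all__ = [
    "PhantomSpec",
    "MotionSpec",
    "HU_DEFAULTS",
    "generate_cross_wire_observations",
    "generate_fiducial_pairs",
    "generate_mouse_phantom",
    "generate_grid_phantom",
    "generate_bath_floor_sequence",
    "simulate_fusion_tre",
]

#: Tissue HU means used throughout the synthetic volumes.
HU_DEFAULTS = {
    "air": -1000.0,
    "fat": -120.0,
    "fat_pad": -97.0,
    "tumor": 68.0,
    "bone": 1000.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model for the mouse-like CT phantom.

    The default builds, inside an air background, a fat slab (thickness
    within the 1-3 mm range of a murine mammary fat pad), a bone
    cylinder beneath it and a tumour ellipsoid embedded in the slab.
    Later primitives overwrite earlier ones.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)  # mm
    slab_thickness: float = 2.0  # mm, fat pad
    slab_z0: float = 4.0  # mm, bottom of the fat slab
    tumor_radii: tuple[float, float, float] = (3.0, 2.5, 0.9)  # mm
    bone_radius: float = 1.5  # mm, cylinder along y under the slab
    hu_means: dict = field(default_factory=lambda: dict(HU_DEFAULTS))
    hu_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n <= 0 for n in self.shape):
            raise ValueError("shape and spacing must be positive")
        if self.hu_sd < 0:
            raise ValueError("hu_sd must be non-negative")


@dataclass(frozen=True)
class MotionSpec:
    """Sinusoidal transducer motion for the bath-floor sequence."""

    amplitude: float = 5.0  # mm
    frequency: float = 0.5  # Hz
    rate: float = 10.0  # frames/s
    duration: float = 12.0  # s
    injected_lag: int = 0  # samples by which the sensor stream leads
    noise_sd: float = 0.0  # mm, added to both streams

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        n = int(round(self.rate * self.duration))
        if abs(self.injected_lag) >= n / 4:
            raise ValueError("injected lag must satisfy |lag| < n_samples/4")


def generate_cross_wire_observations(
    true_calibration: RigidTransform,
    n: int = 93,
    angle_span: float = np.deg2rad(60.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    wire_point: Sequence[float] = (120.0, -40.0, 200.0),
    image_scale: tuple[float, float] = (0.1, 0.1),
) -> list[TrackedObservation]:
    """Simulate a tracked transducer sighting one fixed cross-wire point.

    Sensor orientations are drawn uniformly within +/- angle_span per
    axis and image points uniformly over a plausible frame; the sensor
    translation is then solved so the wire constraint holds exactly,
    after which isotropic Gaussian noise of sd ``noise_sd`` (mm) is added
    to the sensor translation.
    """
    if n < 4:
        raise ValueError("need at least 4 observations")
    rng = np.random.default_rng(seed)
    wire = np.asarray(wire_point, dtype=float)
    cal = true_calibration.matrix
    observations = []
    for i in range(n):
        angles = rng.uniform(-angle_span, angle_span, size=3)
        row = rng.uniform(50, 430)
        col = rng.uniform(50, 590)
        pix = PixelCoord(row, col, image_scale)
        p_plane = np.array([col * image_scale[1], row * image_scale[0], 0.0])
        p_sensor = cal[:3, :3] @ p_plane + cal[:3, 3]
        rot = make_transform(angles, (0.0, 0.0, 0.0)).rotation
        # translation that puts the imaged cross exactly on the wire
        t = wire - rot @ p_sensor
        t = t + rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else t
        pose = RigidTransform(tuple(angles), tuple(t))
        observations.append(TrackedObservation(pose, pix, timestamp=i * 0.1))
    return observations


def generate_fiducial_pairs(
    true_registration: RigidTransform,
    n: int = 12,
    extent: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[FiducialPair]:
    """Paired fiducials: CT points uniform in a cube of side ``extent``
    (mm), tracked points mapped through the true tracker-from-CT
    transform plus isotropic Gaussian noise."""
    if n < 3:
        raise ValueError("need at least 3 fiducial pairs")
    rng = np.random.default_rng(seed)
    ct_pts = rng.uniform(-extent / 2, extent / 2, size=(n, 3))
    tr_pts = true_registration.apply(ct_pts)
    if noise_sd > 0:
        tr_pts = tr_pts + rng.normal(0.0, noise_sd, size=tr_pts.shape)
    return [
        FiducialPair(
            Point3(*c, space="C"), Point3(*t, space="T"), label=f"F{i}"
        )
        for i, (c, t) in enumerate(zip(ct_pts, tr_pts))
    ]


def _voxel_centers(shape, spacing):
    ax = [np.arange(shape[d]) * spacing[d] for d in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def generate_mouse_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[CTVolume, LabelMap]:
    """Mouse-like CT phantom: tumour ellipsoid in a fat slab near bone.

    Returns the noisy HU volume and the exact generative label map.
    Primitives are painted in order (slab, bone, tumour), later ones
    overwriting earlier ones; a primitive extending past the grid is
    clipped silently.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = _voxel_centers(spec.shape, spec.spacing)
    labels = np.full(spec.shape, BACKGROUND, dtype=np.uint8)

    # fat slab spanning the full x-y extent
    slab = (z >= spec.slab_z0) & (z < spec.slab_z0 + spec.slab_thickness)
    labels[slab] = FAT

    # bone cylinder along y, centred below the slab
    extent = np.array(spec.shape) * np.array(spec.spacing)
    bone_cz = max(spec.slab_z0 - 2.0 * spec.bone_radius, spec.bone_radius)
    bone = (x - extent[0] / 2) ** 2 + (z - bone_cz) ** 2 <= spec.bone_radius**2
    labels[bone] = BONE

    # tumour ellipsoid embedded mid-slab
    cx, cy = extent[0] / 2, extent[1] / 2
    cz = spec.slab_z0 + spec.slab_thickness / 2
    r1, r2, r3 = spec.tumor_radii
    tumor = (
        ((x - cx) / r1) ** 2 + ((y - cy) / r2) ** 2 + ((z - cz) / r3) ** 2
    ) <= 1.0
    labels[tumor] = PROTEIN

    means = {
        BACKGROUND: spec.hu_means["air"],
        FAT: spec.hu_means["fat"],
        PROTEIN: spec.hu_means["tumor"],
        BONE: spec.hu_means["bone"],
    }
    hu = np.empty(spec.shape, dtype=float)
    for class_id, mean in means.items():
        hu[labels == class_id] = mean
    if spec.hu_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_sd, size=spec.shape)

    volume = CTVolume(hu, spec.spacing)
    return volume, LabelMap(labels, spec.spacing)


def generate_grid_phantom(
    rows: int = 5,
    cols: int = 10,
    pitch: float = 8.0,
    disc_radius: float = 2.0,
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3),
    disc_hu: float = 300.0,
    background_hu: float = 0.0,
    thickness: float = 1.5,
) -> tuple[CTVolume, list[Point3]]:
    """Grid-of-discs dual-modality phantom with known target centres.

    Discs of ``disc_radius`` mm on a rows x cols grid with the given
    pitch, in a thin slab; returns the volume and the exact mm centres
    (the TRE ground truth).
    """
    if pitch <= 2 * disc_radius:
        raise ValueError("pitch must exceed the disc diameter")
    margin = pitch
    extent_x = margin * 2 + (rows - 1) * pitch
    extent_y = margin * 2 + (cols - 1) * pitch
    extent_z = 3 * thickness
    shape = tuple(
        int(np.ceil(e / s)) for e, s in zip((extent_x, extent_y, extent_z), spacing)
    )
    x, y, z = _voxel_centers(shape, spacing)
    hu = np.full(shape, background_hu, dtype=float)
    z0 = extent_z / 2
    in_slab = np.abs(z - z0) <= thickness / 2
    centers = []
    for i in range(rows):
        for j in range(cols):
            cx, cy = margin + i * pitch, margin + j * pitch
            disc = ((x - cx) ** 2 + (y - cy) ** 2 <= disc_radius**2) & in_slab
            hu[disc] = disc_hu
            centers.append(Point3(cx, cy, z0, space="C"))
    return CTVolume(hu, spacing), centers


def simulate_fusion_tre(
    noise_sd: float = 0.5,
    seed: int = 0,
    n_observations: int = 93,
    n_fiducials: int = 12,
    grid_shape: tuple[int, int] = (5, 10),
) -> dict:
    """Propagate tracker noise through the full calibration chain.

    Simulates the end-to-end accuracy experiment on the grid-of-discs
    phantom: a probe calibration is estimated from noisy cross-wire
    observations, a tracker-to-CT registration from noisy fiducials, and
    each grid target is then imaged with a noisy sensor pose and mapped
    back into CT space through the *estimated* chain.  The distance to
    the true target centre is the target registration error.

    ``noise_sd`` (mm) applies to the sensor translation at every stage:
    calibration observations, fiducial localisation and target imaging.
    Returns calibration/registration single-stage errors and the TRE
    summary over the grid targets.
    """
    from .probe_calibration import calibrate_single_point
    from .registration import horn_registration, target_registration_error

    rng = np.random.default_rng(seed)
    true_cal = make_transform((0.2, -0.1, 0.3), (12.0, -4.0, 3.0))
    true_reg = make_transform((0.1, 0.05, -0.2), (25.0, -10.0, 40.0))

    obs = generate_cross_wire_observations(
        true_cal, n=n_observations, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    cal_result = calibrate_single_point(obs)

    pairs = generate_fiducial_pairs(
        true_reg, n=n_fiducials, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    reg_result = horn_registration(pairs)

    _, centers = generate_grid_phantom(*grid_shape)
    scale = (0.1, 0.1)
    cal_est = cal_result.probe_calibration.matrix
    reg_est_inv = invert(reg_result.tracker_from_ct).matrix
    predicted = []
    for c in centers:
        x_c = c.as_array()
        x_t = true_reg.apply(x_c)
        # image the target at a random pixel with a random probe roll
        pix = PixelCoord(rng.uniform(100, 380), rng.uniform(100, 540), scale)
        x_p = np.array([pix.col * scale[1], pix.row * scale[0], 0.0])
        rot = make_transform(rng.uniform(-0.8, 0.8, size=3), (0, 0, 0)).rotation
        x_r = true_cal.apply(x_p)
        pose_t = x_t - rot @ x_r  # true pose puts the target in-plane
        pose_t_meas = pose_t + rng.normal(0.0, noise_sd, size=3)
        pose_meas = np.eye(4)
        pose_meas[:3, :3] = rot
        pose_meas[:3, 3] = pose_t_meas
        chain = reg_est_inv @ pose_meas @ cal_est
        predicted.append(chain[:3, :3] @ x_p + chain[:3, 3])
    _, tre_mean, tre_sd = target_registration_error(
        np.array(predicted), np.array([c.as_array() for c in centers])
    )
    return {
        "calibration_mean_residual_mm": cal_result.mean_residual,
        "registration_mean_fre_mm": reg_result.mean_fre,
        "n_targets": len(centers),
        "tre_mean_mm": tre_mean,
        "tre_sd_mm": tre_sd,
    }


def generate_bath_floor_sequence(
    motion: MotionSpec = MotionSpec(),
    image_shape: tuple[int, int] = (480, 640),
    scale: float = 0.1,
    seed: int = 0,
    baseline_mm: float = 15.0,
) -> tuple[list[np.ndarray], SignalSeries, SignalSeries]:
    """Oscillating bath-floor US sequence with a known stream lag.

    Each frame shows a bright floor line whose distance below the centre
    row follows a sinusoid; the sensor height series is the same
    sinusoid advanced by ``injected_lag`` samples (the sensor stream
    leads the image stream).  Returns (frames, image timestamp series,
    sensor series); the image series carries the frame timestamps with
    the true floor distances in mm for reference.
    """
    rng = np.random.default_rng(seed)
    n = int(round(motion.rate * motion.duration))
    t = np.arange(n) / motion.rate
    dist_mm = baseline_mm + motion.amplitude * np.sin(
        2 * np.pi * motion.frequency * t
    )
    if motion.noise_sd > 0:
        dist_mm = dist_mm + rng.normal(0.0, motion.noise_sd, size=n)
    # sensor leads by injected_lag samples: sensor[k] = clean(t[k + lag])
    t_sensor = (np.arange(n) + motion.injected_lag) / motion.rate
    sensor_mm = baseline_mm + motion.amplitude * np.sin(
        2 * np.pi * motion.frequency * t_sensor
    )
    if motion.noise_sd > 0:
        sensor_mm = sensor_mm + rng.normal(0.0, motion.noise_sd, size=n)

    center = image_shape[0] // 2
    frames = []
    for d in dist_mm:
        frame = np.zeros(image_shape, dtype=np.uint8)
        row = center + int(round(d / scale))
        if 0 <= row < image_shape[0]:
            frame[row, :] = 255
        frames.append(frame)
    image_series = SignalSeries(t, dist_mm)
    sensor_series = SignalSeries(t, sensor_mm)
    return frames, image_series, sensor_series
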