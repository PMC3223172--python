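"""Mapping ultrasound pixels into CT space and composing fused slices.

A pixel in the tracked scan plane reaches the CT volume through three
rigid maps: probe calibration (plane P to sensor R), the tracked sensor
pose (R to tracker T) and the inverse of the fiducial registration
(T to CT space C):

    x_C = inv(T T_C) . T T_R . R T_P . x_P

The registration step produces tracker-from-CT, so its inverse is
applied explicitly — getting this direction wrong is a classic silent
bug.  The CT (or label) plane co-planar with a given US frame is then
resampled into the frame's pixel grid: trilinear interpolation for HU,
nearest neighbour for tissue class ids, with out-of-volume pixels filled
with air (-1000 HU / background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .geometry import PixelCoord, Point3, RigidTransform, compose, invert, pixel_to_plane
from .hu_segmentation import BACKGROUND, CTVolume, LabelMap, TissueClassTable, DEFAULT_TISSUE_TABLE

__all__ = [
    "USImage",
    "FusedSlice",
    "TABLE_COLORS",
    "map_us_pixel_to_ct",
    "resample_ct_slice",
    "compose_overlay",
    "fuse",
]

AIR_HU = -1000.0

#: RGB values for the published tissue colors.
TABLE_COLORS = {
    "yellow": (255, 255, 0),
    "pink": (255, 105, 180),
    "white": (255, 255, 255),
    "black": (0, 0, 0),
}


@dataclass(frozen=True)
class USImage:
    """One B-mode frame with its pixel scale and acquisition timestamp."""

    intensities: np.ndarray  # 2-D grayscale
    scale: tuple[float, float]  # (s_row, s_col) mm/px
    pose_timestamp: float = 0.0

    def __post_init__(self) -> None:
        img = np.asarray(self.intensities)
        if img.ndim != 2:
            raise ValueError("US image must be 2-D grayscale")
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError("pixel scale must be strictly positive")
        object.__setattr__(self, "intensities", img)


@dataclass(frozen=True)
class FusedSlice:
    us: USImage
    ct_slice: np.ndarray  # HU, same shape as the US frame
    label_slice: np.ndarray  # class ids
    overlay: np.ndarray  # H x W x 3 uint8
    chain: dict  # the three transforms used, JSON-ready


def _chain_matrix(
    calibration: RigidTransform,
    sensor_pose: RigidTransform,
    registration: RigidTransform,
) -> np.ndarray:
    """4x4 plane-to-CT matrix inv(T T_C) @ T T_R @ R T_P."""
    return compose(invert(registration), compose(sensor_pose, calibration)).matrix


def map_us_pixel_to_ct(
    p: PixelCoord,
    calibration: RigidTransform,
    sensor_pose: RigidTransform,
    registration: RigidTransform,
) -> Point3:
    """Map one US pixel into CT space (mm).  Out-of-volume results are legal."""
    m = _chain_matrix(calibration, sensor_pose, registration)
    v = m[:3, :3] @ pixel_to_plane(p).as_array() + m[:3, 3]
    return Point3(*v, space="C")


def _plane_grid_mm(shape: tuple[int, int], scale: tuple[float, float]) -> np.ndarray:
    """(H*W, 3) mm coordinates of every pixel centre in the scan plane."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols * scale[1]
    y = rows * scale[0]
    z = np.zeros_like(x, dtype=float)
    return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1).astype(float)


def resample_ct_slice(
    volume: CTVolume | LabelMap,
    calibration: RigidTransform,
    sensor_pose: RigidTransform,
    registration: RigidTransform,
    shape: tuple[int, int],
    scale: tuple[float, float],
    mode: Literal["hu", "label"] = "hu",
) -> np.ndarray:
    """Resample the CT plane co-planar with a US frame into its pixel grid.

    Every output pixel is pushed through the plane-to-CT chain and the
    volume sampled there: trilinear for HU, nearest neighbour for labels.
    Pixels outside the volume are filled with -1000 HU / background.
    """
    data = volume.voxels if isinstance(volume, CTVolume) else volume.labels
    if data.size == 0:
        raise ValueError("volume is empty")
    m = _chain_matrix(calibration, sensor_pose, registration)
    pts_c = _plane_grid_mm(shape, scale) @ m[:3, :3].T + m[:3, 3]
    origin = volume.origin.as_array()
    spacing = np.asarray(volume.spacing)
    idx = ((pts_c - origin) / spacing).T  # (3, H*W) fractional voxel indices
    if mode == "hu":
        out = ndimage.map_coordinates(
            data.astype(float), idx, order=1, mode="constant", cval=AIR_HU
        )
    elif mode == "label":
        out = ndimage.map_coordinates(
            data, idx, order=0, mode="constant", cval=BACKGROUND
        )
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return out.reshape(shape)


def compose_overlay(
    us: USImage,
    label_slice: np.ndarray,
    table: TissueClassTable = DEFAULT_TISSUE_TABLE,
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend tissue colors over the B-mode frame.

    Background pixels show the US grayscale unmodified; each tissue class
    blends its display color at the given opacity.  Returns H x W x 3
    uint8.
    """
    labels = np.asarray(label_slice)
    if labels.shape != us.intensities.shape:
        raise ValueError("US frame and label slice shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    gray = np.asarray(us.intensities, dtype=float)
    out = np.repeat(gray[:, :, None], 3, axis=2)
    for class_id, (name, _, _, color) in enumerate(table.rows, start=1):
        rgb = np.asarray(TABLE_COLORS[color], dtype=float)
        mask = labels == class_id
        out[mask] = (1.0 - alpha) * out[mask] + alpha * rgb
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def fuse(
    us: USImage,
    volume: CTVolume,
    label_map: LabelMap,
    calibration: RigidTransform,
    sensor_pose: RigidTransform,
    registration: RigidTransform,
    table: TissueClassTable = DEFAULT_TISSUE_TABLE,
    alpha: float = 0.5,
) -> FusedSlice:
    """Produce the co-planar CT slice, label slice and color overlay
    for one tracked US frame."""
    shape = us.intensities.shape
    ct_slice = resample_ct_slice(
        volume, calibration, sensor_pose, registration, shape, us.scale, "hu"
    )
    label_slice = resample_ct_slice(
        label_map, calibration, sensor_pose, registration, shape, us.scale, "label"
    )
    overlay = compose_overlay(us, label_slice, table, alpha)
    chain = {
        "probe_calibration": {
            "angles_zyx": list(calibration.angles),
            "translation": list(calibration.translation),
        },
        "sensor_pose": {
            "angles_zyx": list(sensor_pose.angles),
            "translation": list(sensor_pose.translation),
        },
        "tracker_from_ct": {
            "angles_zyx": list(registration.angles),
            "translation": list(registration.translation),
        },
    }
    return FusedSlice(us, ct_slice, label_slice, overlay, chain)
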