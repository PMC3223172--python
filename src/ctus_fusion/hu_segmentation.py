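"""Hounsfield-unit threshold segmentation of CT volumes.

CT attenuation in Hounsfield units (water = 0, air = -1000) separates
the tissues that matter for acoustic therapy planning: fat sits around
-120 HU, protein-rich soft tissue just above 0, bone far above 300.
Voxels are classified by inclusive range membership:

    fat           -300 to 0 HU   (yellow)
    protein-rich     1 to 300 HU (pink)
    bone           301 to 3000 HU (white)

Anything below -300 HU is background (air); values above 3000 clamp to
bone so the partition is total.  An optional per-slice median filter
(circular footprint) suppresses star artifacts in cone-beam scans before
thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.filters import median as _median_filter
from skimage.morphology import disk as _disk

from .geometry import PixelCoord, Point3

__all__ = [
    "CTVolume",
    "TissueClassTable",
    "LabelMap",
    "DEFAULT_TISSUE_TABLE",
    "segment_hu",
    "tissue_area",
    "roi_mean_hu",
    "hu_histogram_pdf",
    "HistogramPDF",
]

BACKGROUND = 0
FAT = 1
PROTEIN = 2
BONE = 3

CLASS_NAMES = {BACKGROUND: "background", FAT: "fat", PROTEIN: "protein-rich", BONE: "bone"}


@dataclass(frozen=True)
class CTVolume:
    """HU-valued scalar grid with voxel spacing and origin (C space).

    World coordinates are axis-aligned: mm position of voxel (i, j, k) is
    origin + (i, j, k) * spacing.
    """

    voxels: np.ndarray  # 3-D, HU
    spacing: tuple[float, float, float]  # mm
    origin: Point3 = field(default_factory=lambda: Point3(0.0, 0.0, 0.0, "C"))

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("voxels must be a 3-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class LabelMap:
    """Per-voxel tissue class ids, co-registered with its CT volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: Point3 = field(default_factory=lambda: Point3(0.0, 0.0, 0.0, "C"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.uint8))


@dataclass(frozen=True)
class TissueClassTable:
    """Ordered (name, HU low, HU high, display color) ranges.

    Ranges are inclusive on both endpoints, non-overlapping, and tile
    the interval from the lowest low to the highest high; HU below the
    table is background, above it clamps to the last (densest) class.
    """

    rows: tuple[tuple[str, float, float, str], ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        for (n1, _, hi1, _), (n2, lo2, _, _) in zip(rows, rows[1:]):
            if lo2 <= hi1:
                raise ValueError(f"tissue ranges overlap between {n1} and {n2}")
            if lo2 - hi1 > 1:
                raise ValueError(f"gap between {n1} and {n2}: ranges must be contiguous")
        object.__setattr__(self, "rows", rows)

    @property
    def names(self) -> list[str]:
        return [r[0] for r in self.rows]

    def class_id(self, name: str) -> int:
        if name == "background":
            return BACKGROUND
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise ValueError(f"unknown tissue class {name!r}") from None

    def palette(self) -> dict[str, str]:
        out = {"background": "black"}
        out.update({name: color for name, _, _, color in self.rows})
        return out

    def palette_json(self) -> str:
        return json.dumps(self.palette())


#: The published HU ranges and display colors.
DEFAULT_TISSUE_TABLE = TissueClassTable(
    (
        ("fat", -300.0, 0.0, "yellow"),
        ("protein-rich", 1.0, 300.0, "pink"),
        ("bone", 301.0, 3000.0, "white"),
    )
)


def segment_hu(
    volume: CTVolume,
    table: TissueClassTable = DEFAULT_TISSUE_TABLE,
    median_radius: Optional[int] = None,
) -> LabelMap:
    """Threshold a CT volume into a tissue label map.

    When ``median_radius`` is given, each slice (last axis) is median
    filtered with a circular footprint of that pixel radius first — used
    for micro-CT scans whose star artifacts otherwise speckle the labels.

    Class boundaries are midpoints between adjacent printed ranges, so
    the fat/protein cut falls between 0 and 1 HU exactly as printed and
    noninteger HU values classify deterministically.
    """
    hu = volume.voxels.astype(float)
    if median_radius:
        footprint = _disk(median_radius)
        hu = np.stack(
            [
                _median_filter(hu[:, :, k], footprint=footprint, mode="nearest")
                for k in range(hu.shape[2])
            ],
            axis=2,
        )
    lows = [r[1] for r in table.rows]
    highs = [r[2] for r in table.rows]
    # cut below the first class, then midway through each printed gap
    edges = [lows[0]] + [(h + l) / 2.0 for h, l in zip(highs[:-1], lows[1:])]
    labels = np.searchsorted(np.asarray(edges), hu, side="right").astype(np.uint8)
    # values above the last range clamp into the last class already
    return LabelMap(labels, volume.spacing, volume.origin)


def tissue_area(
    label_slice: np.ndarray,
    tissue: str,
    spacing: tuple[float, float],
    table: TissueClassTable = DEFAULT_TISSUE_TABLE,
) -> float:
    """2-D area in mm^2 of one tissue class: pixel count x pixel area."""
    class_id = table.class_id(tissue)
    count = int(np.count_nonzero(np.asarray(label_slice) == class_id))
    return count * spacing[0] * spacing[1]


def roi_mean_hu(
    ct_slice: np.ndarray,
    center: PixelCoord,
    area_mm2: float = 1.0,
) -> tuple[float, float]:
    """Mean and sample sd of HU over a circular ROI of the given area.

    The circle radius is sqrt(area/pi) mm; a pixel belongs to the ROI
    when its centre falls inside the circle.  The circle must lie fully
    within the slice.
    """
    img = np.asarray(ct_slice, dtype=float)
    s_row, s_col = center.scale
    radius = float(np.sqrt(area_mm2 / np.pi))
    cy, cx = center.row * s_row, center.col * s_col
    if (
        cy - radius < -s_row / 2
        or cx - radius < -s_col / 2
        or cy + radius > (img.shape[0] - 0.5) * s_row
        or cx + radius > (img.shape[1] - 0.5) * s_col
    ):
        raise ValueError("ROI circle exits the slice bounds")
    rows = np.arange(img.shape[0])[:, None] * s_row
    cols = np.arange(img.shape[1])[None, :] * s_col
    mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no pixel centres; increase the area")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


@dataclass(frozen=True)
class HistogramPDF:
    """128-bin (by default) HU histogram normalized to a density."""

    bin_edges: np.ndarray  # length bins + 1
    density: np.ndarray  # integrates to 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mass_below(self, hu: float) -> float:
        """Probability mass strictly below a HU threshold."""
        widths = np.diff(self.bin_edges)
        frac = np.clip((hu - self.bin_edges[:-1]) / widths, 0.0, 1.0)
        return float(np.sum(self.density * widths * frac))


def hu_histogram_pdf(
    pixels: Sequence[float] | np.ndarray,
    bins: int = 128,
    hu_range: Optional[tuple[float, float]] = None,
) -> HistogramPDF:
    """Histogram of HU values converted to a probability density.

    Densities satisfy sum(density * binwidth) == 1, the convention used
    to compare tumour-group radiodensity distributions.
    """
    vals = np.asarray(pixels, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("cannot histogram an empty pixel set")
    density, edges = np.histogram(vals, bins=bins, range=hu_range, density=True)
    return HistogramPDF(bin_edges=edges, density=density)
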