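"""Validation statistics for CT-vs-histology tissue quantification.

For each excised tumour a midline sagittal CT slice and the matching
H&E histology slice yield tumour and fat-pad areas; the fat fraction is

    %fat = 100 * A_fat / (A_fat + A_tumor)

computed per modality.  Tumours are grouped by estimated volume
(small < 75 mm^3, medium 75-150 mm^3, large > 150 mm^3) and group means
and sample standard deviations of the fat percentage are compared
between modalities.  Agreement between modalities is summarised by
ordinary least squares (CT area regressed on histology area), and the
fat-versus-tumour-size trend by a second regression.  Tumour volume
comes from an ellipsoid with two measured radii and a third equal to
their mean.  Student's pooled t-test and one-way ANOVA cover the group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AreaRecord",
    "RegressionFit",
    "GroupSummary",
    "SIZE_GROUPS",
    "percent_fat",
    "fit_line",
    "group_summary",
    "ellipsoid_volume",
    "two_sample_ttest",
    "one_way_anova",
    "blinded_roi_average",
    "standard_report",
    "load_reference_areas",
    "records_from_frame",
]

#: Tumour-volume size groups in mm^3 as (low, high, include_low,
#: include_high): [0, 75) small, [75, 150] medium, (150, inf) large — so
#: a 74.9 mm^3 tumour is small and a 147.6 mm^3 tumour is medium.
SIZE_GROUPS = {
    "small": (0.0, 75.0, True, False),
    "medium": (75.0, 150.0, True, True),
    "large": (150.0, np.inf, False, False),
}


@dataclass(frozen=True)
class AreaRecord:
    """One tumour's area measurements from CT and histology."""

    tumor_volume: float  # mm^3
    ct_tumor_area: float  # mm^2
    ct_fat_area: float  # mm^2
    ct_percent_fat: float  # %
    hist_tumor_area: float  # mm^2
    hist_fat_area: float  # mm^2
    hist_percent_fat: float  # %

    def __post_init__(self) -> None:
        areas = (
            self.tumor_volume,
            self.ct_tumor_area,
            self.ct_fat_area,
            self.hist_tumor_area,
            self.hist_fat_area,
        )
        if any(a < 0 for a in areas):
            raise ValueError("volumes and areas must be non-negative")
        for p in (self.ct_percent_fat, self.hist_percent_fat):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percent fat must lie in [0, 100]")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    bounds: tuple[float, float]
    n: int
    mean: float  # %
    sd: float  # % (sample, n-1); 0 and flagged when n == 1
    sd_defined: bool = True


def percent_fat(fat_area: float, tumor_area: float) -> float:
    """Fat percentage of a slice: 100 * A_fat / (A_fat + A_tumor)."""
    if fat_area < 0 or tumor_area < 0:
        raise ValueError("areas must be non-negative")
    total = fat_area + tumor_area
    if total == 0:
        raise ZeroDivisionError("percent fat undefined when both areas are zero")
    return 100.0 * fat_area / total


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares with r^2 = squared Pearson correlation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(xa) == 0:
        raise ValueError("degenerate predictor: x is constant")
    if np.ptp(ya) == 0:
        return RegressionFit(slope=0.0, intercept=float(ya[0]), r_squared=0.0)
    res = stats.linregress(xa, ya)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def group_summary(
    records: Sequence[AreaRecord],
    field: str,
    bounds: tuple[float, float],
    include_lower: bool = True,
    include_upper: bool = True,
) -> GroupSummary:
    """Mean and sample sd of a percent column over a tumour-volume group.

    ``bounds`` is (low, high) in mm^3; endpoint inclusion follows the
    flags (see :data:`SIZE_GROUPS` for the canonical three groups).
    """
    lo, hi = bounds
    vals = []
    for r in records:
        v = r.tumor_volume
        above = v >= lo if include_lower else v > lo
        below = v <= hi if include_upper else v < hi
        if above and below:
            vals.append(getattr(r, field))
    if not vals:
        raise ValueError(f"no records with tumor_volume in {bounds}")
    arr = np.asarray(vals, dtype=float)
    if arr.size == 1:
        return GroupSummary(bounds, 1, float(arr[0]), 0.0, sd_defined=False)
    return GroupSummary(
        bounds, int(arr.size), float(arr.mean()), float(arr.std(ddof=1))
    )


def ellipsoid_volume(r1: float, r2: float) -> float:
    """Tumour volume from two in-slice radii, third radius = their mean.

    V = (4/3) pi r1 r2 (r1 + r2)/2, in mm^3.
    """
    if r1 < 0 or r2 < 0:
        raise ValueError("radii must be non-negative")
    return (4.0 / 3.0) * np.pi * r1 * r2 * (r1 + r2) / 2.0


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test; returns (t, p)."""
    aa, bb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(aa, bb, equal_var=True)
    return float(t), float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Standard one-way ANOVA over >= 2 groups; returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def blinded_roi_average(
    set_a: Sequence[float], set_b: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Average two blinded raters' area measurements.

    Returns the element-wise means (the bias-minimising measurement) and
    the between-rater agreement r^2 from an OLS fit of rater B on A.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size != b.size:
        raise ValueError("rater measurement sets differ in length")
    fit = fit_line(a, b)
    return (a + b) / 2.0, fit.r_squared


def standard_report(records: Sequence[AreaRecord]) -> dict:
    """Group summaries and both regressions for an area table.

    Returns a JSON-serialisable dict: per-modality fat-percentage
    summaries for the three size groups, the CT-on-histology tumour-area
    regression, and the histology fat-area-on-tumour-area regression.
    """
    out: dict = {"groups": {}, "regressions": {}}
    for modality, field in (
        ("histology", "hist_percent_fat"),
        ("ct", "ct_percent_fat"),
    ):
        out["groups"][modality] = {}
        for name, (lo, hi, inc_lo, inc_hi) in SIZE_GROUPS.items():
            g = group_summary(records, field, (lo, hi), inc_lo, inc_hi)
            out["groups"][modality][name] = {
                "n": g.n,
                "mean_percent": g.mean,
                "sd_percent": g.sd if g.sd_defined else None,
            }
    hist_tumor = [r.hist_tumor_area for r in records]
    ct_tumor = [r.ct_tumor_area for r in records]
    hist_fat = [r.hist_fat_area for r in records]
    area_fit = fit_line(hist_tumor, ct_tumor)
    fat_fit = fit_line(hist_tumor, hist_fat)
    out["regressions"]["ct_vs_histology_tumor_area"] = {
        "slope": area_fit.slope,
        "intercept": area_fit.intercept,
        "r_squared": area_fit.r_squared,
    }
    out["regressions"]["hist_fat_vs_tumor_area"] = {
        "slope": fat_fit.slope,
        "intercept": fat_fit.intercept,
        "r_squared": fat_fit.r_squared,
    }
    return out


# -- reference table ----------------------------------------------------------

_COLUMNS = [
    "tumor_volume_mm3",
    "ct_tumor_area_mm2",
    "ct_fat_area_mm2",
    "ct_percent_fat",
    "hist_tumor_area_mm2",
    "hist_fat_area_mm2",
    "hist_percent_fat",
]


def records_from_frame(frame: pd.DataFrame) -> list[AreaRecord]:
    """Validated records from a dataframe with the seven area columns.

    Percent columns may be absent; they are then recomputed from the
    area columns.
    """
    missing = [
        c for c in _COLUMNS
        if c not in frame.columns and not c.endswith("percent_fat")
    ]
    if missing:
        raise ValueError(f"area table missing columns: {missing}")
    records = []
    for idx, row in frame.iterrows():
        try:
            ct_pct = (
                float(row["ct_percent_fat"])
                if "ct_percent_fat" in frame.columns
                else percent_fat(row["ct_fat_area_mm2"], row["ct_tumor_area_mm2"])
            )
            hist_pct = (
                float(row["hist_percent_fat"])
                if "hist_percent_fat" in frame.columns
                else percent_fat(
                    row["hist_fat_area_mm2"], row["hist_tumor_area_mm2"]
                )
            )
            records.append(
                AreaRecord(
                    tumor_volume=float(row["tumor_volume_mm3"]),
                    ct_tumor_area=float(row["ct_tumor_area_mm2"]),
                    ct_fat_area=float(row["ct_fat_area_mm2"]),
                    ct_percent_fat=ct_pct,
                    hist_tumor_area=float(row["hist_tumor_area_mm2"]),
                    hist_fat_area=float(row["hist_fat_area_mm2"]),
                    hist_percent_fat=hist_pct,
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid area record at row {idx}: {exc}") from exc
    return records


def load_reference_areas(path: Optional[str | Path] = None) -> list[AreaRecord]:
    """Load the bundled 12-tumour area table (or a CSV in the same dialect)."""
    if path is None:
        source = resources.files("ctus_fusion.data") / "area_measurements.csv"
        with resources.as_file(source) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
        if frame.empty:
            raise ValueError("area table is empty")
    return records_from_frame(frame)
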