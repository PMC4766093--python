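"""Longitudinal assembly and correlation of K^trans, serum BSE and FLAIR.

Each subject contributes three sparse time series on different
schedules (imaging roughly biweekly, serum weekly).  Series are
interpolated with shape-preserving piecewise cubic Hermite polynomials
(PCHIP) onto a daily grid over the overlapping span, then correlated
pairwise per subject (Pearson).  Cohort-level results are the raw mean
and standard deviation of the per-subject correlations (no Fisher-z
transform) and the mean ± SEM of the interpolated K^trans curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import pearsonr

__all__ = [
    "SubjectTimeline",
    "CohortSummary",
    "pchip_interpolate",
    "pearson_r",
    "correlate_modalities",
    "cohort_summary",
    "peak_day",
    "timelines_from_tidy",
]

DAY_RANGE = (-2, 70)
MODALITIES = ("ktrans", "bse", "flair")


def _clean_series(series: Dict[int, float]) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted (days, values) with missing (None/NaN) entries dropped."""
    items = [
        (int(d), float(v))
        for d, v in series.items()
        if v is not None and np.isfinite(v)
    ]
    items.sort()
    if not items:
        return np.array([], dtype=int), np.array([])
    days, vals = map(np.asarray, zip(*items))
    return days.astype(int), vals.astype(float)


@dataclass(frozen=True)
class SubjectTimeline:
    """Per-subject sparse series: day (0 = ablation) -> value.

    Missing visits are simply absent (or None/NaN) in the mapping.
    """

    subject: str
    ktrans: Dict[int, float]  # 1/min
    bse: Dict[int, float]  # ng/mL
    flair: Dict[int, float]  # mm^2

    def __post_init__(self) -> None:
        for name in MODALITIES:
            days, _ = _clean_series(getattr(self, name))
            if len(days) and (days.min() < DAY_RANGE[0] or days.max() > DAY_RANGE[1]):
                raise ValueError(
                    f"{name} days outside the study window {DAY_RANGE}"
                )

    def series(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        return _clean_series(getattr(self, name))


@dataclass
class CohortSummary:
    """Cohort mean ± SEM K^trans curve and correlation aggregates."""

    grid_days: np.ndarray
    ktrans_mean: np.ndarray
    ktrans_sem: np.ndarray
    per_subject_r: pd.DataFrame  # one row per subject, one column per pair
    r_mean: Dict[str, float]
    r_std: Dict[str, float]


def pchip_interpolate(
    days: Sequence[float], values: Sequence[float], grid: Sequence[float]
) -> np.ndarray:
    """Shape-preserving piecewise-cubic interpolation, exact at knots.

    Extrapolation is refused: the grid must lie within the knot span.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 knots to interpolate")
    if g.min() < d.min() or g.max() > d.max():
        raise ValueError("interpolation grid extends beyond the knot span")
    return PchipInterpolator(d, v, extrapolate=False)(g)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; zero variance is an error."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(pearsonr(xa, ya).statistic)


_PAIRS = (("ktrans", "bse"), ("ktrans", "flair"), ("bse", "flair"))


def correlate_modalities(
    timeline: SubjectTimeline, grid_step: int = 1
) -> Dict[str, Optional[float]]:
    """Pairwise Pearson r between the three modality curves of a subject.

    Each pair of series is PCHIP-interpolated onto a shared daily grid
    over the overlap of their day spans.  A pair with no overlap, fewer
    than 2 knots in either series, or zero variance yields None.
    """
    out: Dict[str, Optional[float]] = {}
    for a, b in _PAIRS:
        key = f"r_{a}_{b}"
        da, va = timeline.series(a)
        db, vb = timeline.series(b)
        if len(da) < 2 or len(db) < 2:
            out[key] = None
            continue
        lo = max(da.min(), db.min())
        hi = min(da.max(), db.max())
        if hi - lo < 2 * grid_step:
            out[key] = None
            continue
        grid = np.arange(lo, hi + 1, grid_step)
        xa = pchip_interpolate(da, va, grid)
        xb = pchip_interpolate(db, vb, grid)
        try:
            out[key] = pearson_r(xa, xb)
        except ValueError:
            out[key] = None
    return out


def peak_day(series: Dict[int, float]) -> int:
    """Day of the series maximum; ties resolve to the earliest day."""
    days, vals = _clean_series(series)
    if len(days) == 0:
        raise ValueError("series has no valid points")
    return int(days[np.argmax(vals)])


def cohort_summary(
    subjects: Sequence[SubjectTimeline], grid_step: int = 1
) -> CohortSummary:
    """Cohort-mean K^trans curve (±SEM) and correlation aggregates.

    The K^trans curve of each subject is interpolated onto the common
    span shared by all subjects; the cohort curve is the across-subject
    mean with SEM = sd/√n per grid day.  Correlations are aggregated as
    the raw mean and sample standard deviation of per-subject r.
    """
    if len(subjects) < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    spans = []
    for s in subjects:
        days, _ = s.series("ktrans")
        if len(days) < 2:
            raise ValueError(f"subject {s.subject} has fewer than 2 ktrans points")
        spans.append((days.min(), days.max()))
    lo = max(a for a, _ in spans)
    hi = min(b for _, b in spans)
    if hi <= lo:
        raise ValueError("subjects share no common ktrans day span")
    grid = np.arange(lo, hi + 1, grid_step)

    curves = np.vstack(
        [pchip_interpolate(*s.series("ktrans"), grid) for s in subjects]
    )
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(len(subjects))

    rows = []
    for s in subjects:
        row: Dict[str, object] = {"subject": s.subject}
        row.update(correlate_modalities(s, grid_step=grid_step))
        rows.append(row)
    per_r = pd.DataFrame(rows).set_index("subject")

    r_mean: Dict[str, float] = {}
    r_std: Dict[str, float] = {}
    for col in per_r.columns:
        vals = per_r[col].dropna().astype(float)
        r_mean[col] = float(vals.mean()) if len(vals) else float("nan")
        r_std[col] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")

    return CohortSummary(
        grid_days=grid,
        ktrans_mean=mean,
        ktrans_sem=sem,
        per_subject_r=per_r,
        r_mean=r_mean,
        r_std=r_std,
    )


def timelines_from_tidy(df: pd.DataFrame) -> list[SubjectTimeline]:
    """Build timelines from a tidy table (subject, day, modality, value)."""
    required = {"subject", "day", "modality", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tidy table is missing columns: {sorted(missing)}")
    bad = set(df["modality"].unique()) - set(MODALITIES)
    if bad:
        raise ValueError(f"unknown modalities: {sorted(bad)}")
    out = []
    for subject, grp in df.groupby("subject", sort=True):
        series = {m: {} for m in MODALITIES}
        for _, row in grp.iterrows():
            series[row["modality"]][int(row["day"])] = float(row["value"])
        out.append(SubjectTimeline(subject=str(subject), **series))
    return out
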