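"""Cohort-level summary statistics for a multi-observer contouring study.

Conventions, chosen once and used everywhere:

* Percentiles use linear interpolation between order statistics (the
  numpy default), so the median of an even-sized sample is the mean of
  the two central values.  Group summaries report the 5-25-50-75-95
  percentiles plus the mean.
* Standard deviations are sample SDs (n − 1 denominator); a singleton
  group has SD 0.
* Inter-observer variability of an OAR is the sample SD of a metric
  pooled over all (patient, observer) records of one group; the headline
  "mean SD" averages those per-OAR SDs unweighted over OARs.
* Percent figures are rounded half-away-from-zero to integers for
  report parity (e.g. −43.75% prints as −44%); unrounded values are kept
  in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import TimingRecord

__all__ = [
    "GroupSummary",
    "TimeSaving",
    "group_summary",
    "observer_variability",
    "mean_variability",
    "percent_change",
    "percent_change_exact",
    "time_saving",
    "quartile_separation",
    "contour_count",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD and the 5/25/50/75/95 percentiles of one group."""

    n: int
    mean: float
    sd: float
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Summarize a non-empty sample of one metric."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    p5, p25, p50, p75, p95 = np.percentile(arr, [5, 25, 50, 75, 95])
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size >= 2 else 0.0,
        p5=float(p5),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p95=float(p95),
    )


def observer_variability(
    records: pd.DataFrame, oar: str, group: str, metric: str
) -> float:
    """Sample SD of a metric pooled over all (patient, observer) records
    of one group for one OAR; NaN when fewer than two finite records exist.

    ``records`` is a tidy frame with at least columns ``oar``, ``group``
    and the metric column.
    """
    cell = records[(records["oar"] == oar) & (records["group"] == group)][metric]
    cell = cell.dropna()
    if len(cell) < 2:
        return float("nan")
    return float(cell.std(ddof=1))


def mean_variability(per_oar_sds: Iterable[float]) -> float:
    """Unweighted mean over OARs of the per-OAR observer SDs."""
    sds = [s for s in per_oar_sds if not math.isnan(s)]
    if not sds:
        raise ValueError("no per-OAR SDs to average")
    return float(np.mean(sds))


def percent_change_exact(reference: float, comparison: float) -> float:
    """Unrounded percent change of ``comparison`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return 100.0 * (comparison - reference) / reference


def percent_change(reference: float, comparison: float) -> int:
    """Signed integer percent change, rounded half-away-from-zero."""
    pct = percent_change_exact(reference, comparison)
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def _minutes(values: Sequence[TimingRecord | float]) -> np.ndarray:
    return np.asarray([getattr(v, "minutes", v) for v in values], dtype=float)


@dataclass(frozen=True)
class TimeSaving:
    """Headline time-saving numbers, with and without AI processing time."""

    median_manual_min: float
    median_adjusted_min: float
    median_saved_min: float
    pct_saved: int
    median_saved_with_processing_min: float
    pct_saved_with_processing: int


def time_saving(
    manual: Sequence[TimingRecord | float],
    adjusted: Sequence[TimingRecord | float],
    processing_min: float,
) -> TimeSaving:
    """Median time saved by adjusting AI contours instead of contouring manually.

    The with-processing variant charges the AI processing/import time to
    the adjusted workflow before differencing.  Savings are signed: if the
    adjusted workflow is slower, the saving is negative.
    """
    if processing_min < 0:
        raise ValueError("processing time must be non-negative")
    man = _minutes(manual)
    adj = _minutes(adjusted)
    if man.size == 0 or adj.size == 0:
        raise ValueError("both timing groups must be non-empty")
    m50 = float(np.median(man))
    a50 = float(np.median(adj))
    return TimeSaving(
        median_manual_min=m50,
        median_adjusted_min=a50,
        median_saved_min=m50 - a50,
        pct_saved=-percent_change(m50, a50),
        median_saved_with_processing_min=m50 - (a50 + processing_min),
        pct_saved_with_processing=-percent_change(m50, a50 + processing_min),
    )


def quartile_separation(
    manual: Sequence[TimingRecord | float], adjusted: Sequence[TimingRecord | float]
) -> bool:
    """True iff the worst quartile of adjusted times beats the best quartile
    of manual times: p75(adjusted) < p25(manual)."""
    man = _minutes(manual)
    adj = _minutes(adjusted)
    if man.size == 0 or adj.size == 0:
        raise ValueError("both timing groups must be non-empty")
    return bool(np.percentile(adj, 75) < np.percentile(man, 25))


def contour_count(
    n_patients: int, n_oars: int, n_observers: int, n_exceptions: int = 0
) -> int:
    """Planned contours minus recorded exceptions."""
    for v in (n_patients, n_oars, n_observers, n_exceptions):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    product = n_patients * n_oars * n_observers
    if n_exceptions > product:
        raise ValueError(f"exceptions ({n_exceptions}) exceed planned contours ({product})")
    return product - n_exceptions
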