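"""Per-subject metric slopes over time and regression slope directionality.

Each subject contributes, per histogram metric, the ordinary least-squares
slope of that metric against days from inclusion (>= 3 visits required).
The slope is reduced to its sign — the regression slope directionality
(RSD), positive or negative — which is the binary covariate entering the
survival models. An exact-zero slope (measure zero on continuous data) is
classified positive and counted in a warning tally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import METRIC_NAMES, HistogramMetrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalTimes:
    """Progression-free and overall survival for one subject (days)."""

    pfs_days: float
    pfs_event: bool
    os_days: float
    os_event: bool

    def __post_init__(self):
        if self.pfs_days > self.os_days:
            raise ValueError(
                f"PFS {self.pfs_days} exceeds OS {self.os_days}"
            )
        if not (self.pfs_days > 0 and self.os_days > 0):
            raise ValueError("survival times must be positive")


@dataclass(frozen=True)
class SubjectSeries:
    """Ordered longitudinal metric observations plus outcome for one subject.

    ``days`` are days from inclusion, strictly increasing, length >= 3.
    ``metrics`` holds one :class:`HistogramMetrics` per visit. ``mgmt`` is
    1/0 for MGMT-promoter methylation positive/negative, None if missing;
    ``treatment`` is 1 for TTFields, 0 for standard therapy.
    """

    subject_id: str
    days: tuple
    metrics: tuple
    survival: SurvivalTimes
    mgmt: int | None = None
    treatment: int = 0

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        if days.size < 3:
            raise ValueError(
                f"subject {self.subject_id}: insufficient timepoints "
                f"({days.size} < 3)"
            )
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"subject {self.subject_id}: days not strictly increasing")
        if len(self.metrics) != days.size:
            raise ValueError(f"subject {self.subject_id}: days/metrics length mismatch")

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics], dtype=float)


@dataclass(frozen=True)
class RsdVector:
    """Per-metric fitted slope and its directionality for one subject.

    ``slopes`` maps metric name -> OLS slope (metric units per day);
    ``directionality`` maps metric name -> "positive" | "negative".
    """

    subject_id: str
    slopes: dict
    directionality: dict
    n_zero_slopes: int = 0

    def indicator(self, name: str) -> int:
        """RSD coded positive=1 / negative=0 (the Cox covariate coding)."""
        return 1 if self.directionality[name] == "positive" else 0


def fit_slope(days, values) -> tuple[float, float, float]:
    """Simple OLS of ``values`` on ``days``: (slope, intercept, r_squared).

    Closed form: slope = sum((t - tbar)(y - ybar)) / sum((t - tbar)^2).
    A constant response gives slope 0 and r^2 defined as 0.

    Raises
    ------
    ValueError
        Fewer than 3 points ("insufficient timepoints") or zero variance
        in the time axis.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("days and values differ in length")
    if t.size < 3:
        raise ValueError(f"insufficient timepoints: {t.size} < 3")
    tc = t - t.mean()
    sst = float(tc @ tc)
    if sst == 0:
        raise ValueError("zero variance in time axis")
    yc = y - y.mean()
    slope = float(tc @ yc) / sst
    intercept = float(y.mean() - slope * t.mean())
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return slope, intercept, 0.0
    resid = y - (intercept + slope * t)
    r_squared = 1.0 - float(resid @ resid) / ss_tot
    return slope, intercept, r_squared


def rsd_from_series(series: SubjectSeries) -> RsdVector:
    """Fit one slope per metric and reduce each to its directionality."""
    slopes, direction = {}, {}
    n_zero = 0
    for name in METRIC_NAMES:
        slope, _, _ = fit_slope(series.days, series.metric_values(name))
        slopes[name] = slope
        if slope == 0.0:
            n_zero += 1
            direction[name] = "positive"
        else:
            direction[name] = "positive" if slope > 0 else "negative"
    if n_zero:
        warnings.warn(
            f"subject {series.subject_id}: {n_zero} exact-zero slope(s) "
            "classified positive", RuntimeWarning, stacklevel=2,
        )
    return RsdVector(series.subject_id, slopes, direction, n_zero_slopes=n_zero)


def rsd_table(cohort) -> pd.DataFrame:
    """Build the cohort design table: one row per subject.

    Columns: subject_id, ``<metric>_rsd`` indicators (positive=1,
    negative=0) for the seven metrics, mgmt (may be NA), treatment, and
    the four survival columns.
    """
    rows = []
    seen = set()
    for series in cohort:
        if series.subject_id in seen:
            raise ValueError(f"duplicate subject_id: {series.subject_id}")
        seen.add(series.subject_id)
        rsd = rsd_from_series(series)
        row = {"subject_id": series.subject_id}
        row.update({f"{m}_rsd": rsd.indicator(m) for m in METRIC_NAMES})
        row["mgmt"] = np.nan if series.mgmt is None else int(series.mgmt)
        row["treatment"] = int(series.treatment)
        row["pfs_days"] = series.survival.pfs_days
        row["pfs_event"] = int(series.survival.pfs_event)
        row["os_days"] = series.survival.os_days
        row["os_event"] = int(series.survival.os_event)
        rows.append(row)
    columns = (["subject_id"] + [f"{m}_rsd" for m in METRIC_NAMES]
               + ["mgmt", "treatment", "pfs_days", "pfs_event", "os_days", "os_event"])
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("subject_id", kind="stable").reset_index(drop=True)


def slopes_table(cohort) -> pd.DataFrame:
    """Diagnostic table of raw fitted slopes: one row per (subject, metric)."""
    rows = []
    for series in cohort:
        for name in METRIC_NAMES:
            slope, intercept, r2 = fit_slope(series.days, series.metric_values(name))
            rows.append({
                "subject_id": series.subject_id, "metric": name,
                "slope_per_day": slope, "intercept": intercept, "r_squared": r2,
                "n_timepoints": len(series.days),
            })
    return pd.DataFrame(rows)


def series_from_tables(metrics_df: pd.DataFrame, survival_df: pd.DataFrame) -> list:
    """Assemble :class:`SubjectSeries` from a wide metrics table + survival table.

    ``metrics_df`` is the output of :func:`adcsurv.features.metrics_table`;
    ``survival_df`` has columns subject_id, pfs_days, pfs_event, os_days,
    os_event and optionally mgmt, treatment.
    """
    surv = survival_df.set_index(survival_df["subject_id"].astype(str))
    cohort = []
    for subject_id, grp in metrics_df.groupby("subject_id", sort=True):
        sid = str(subject_id)
        if sid not in surv.index:
            raise ValueError(f"no survival record for subject {sid}")
        rec = surv.loc[sid]
        grp = grp.sort_values("day")
        metrics = tuple(
            HistogramMetrics(**{k: row[k] for k in METRIC_NAMES},
                             n_voxels=int(row["n_voxels"]))
            for _, row in grp.iterrows()
        )
        mgmt = rec.get("mgmt", np.nan)
        mgmt = None if pd.isna(mgmt) else int(mgmt)
        cohort.append(SubjectSeries(
            subject_id=sid,
            days=tuple(grp["day"].astype(float)),
            metrics=metrics,
            survival=SurvivalTimes(
                pfs_days=float(rec["pfs_days"]), pfs_event=bool(rec["pfs_event"]),
                os_days=float(rec["os_days"]), os_event=bool(rec["os_event"]),
            ),
            mgmt=mgmt,
            treatment=int(rec.get("treatment", 0)),
        ))
    return cohort
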