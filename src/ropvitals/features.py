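"""Per-day physiological feature extraction from monitor traces.

Thirteen feature families are computed per infant per postnatal day:

====================  =========================================================
``mean_spo2``         daily mean oxygen saturation (%)
``mean_hr``           daily mean heart rate (bpm)
``mean_fio2``         daily mean inspired-oxygen fraction
``mean_sf_ratio``     daily mean of the per-sample SpO2/FiO2 ratio
``skew_spo2``         daily sample skewness of SpO2 (unitless)
``skew_hr``           daily sample skewness of heart rate (unitless)
``auc_below_80``      area under the 80% SpO2 line (%·min per day)
``auc_above_95``      area above the 95% SpO2 line (%·min per day)
``pct_time_le_80``    percent of valid time with SpO2 <= 80%
``pct_time_gt_95``    percent of valid time with SpO2 > 95%
``n_desaturations``   desaturation events per day (onset day)
``n_bradycardia``     bradycardia events per day
``n_tachycardia``     tachycardia events per day
====================  =========================================================

Days are postnatal calendar windows [24(d-1), 24d) hours from birth,
1-based. Samples flagged invalid by the monitor are excluded everywhere; a
day without valid samples yields missing cells, never zeros. Skewness uses
the moment estimator ``b1 = g1 * ((n-1)/n)^{3/2}`` (the default of the
widely used R implementation), requiring at least three valid samples with
non-zero variance.

Event counting (desaturations, bradycardias, tachycardias) finds maximal
runs of valid samples beyond a threshold, merges runs separated by less
than ``merge_gap`` seconds, keeps runs lasting at least ``min_duration``
seconds, and assigns each event to the day containing its onset. Default
thresholds (SpO2 < 80%, HR < 100 bpm, HR > 200 bpm, each for >= 10 s) follow
standard neonatal definitions and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import SECONDS_PER_DAY, VitalTrace

__all__ = [
    "EventRule",
    "DEFAULT_EVENT_RULES",
    "FEATURE_FAMILIES",
    "filter_valid",
    "availability",
    "daily_mean",
    "daily_skewness",
    "auc_threshold",
    "pct_time",
    "count_events",
    "build_feature_matrix",
]

log = logging.getLogger(__name__)

FEATURE_FAMILIES = [
    "mean_spo2", "mean_hr", "mean_fio2", "mean_sf_ratio",
    "skew_spo2", "skew_hr",
    "auc_below_80", "auc_above_95",
    "pct_time_le_80", "pct_time_gt_95",
    "n_desaturations", "n_bradycardia", "n_tachycardia",
]


@dataclass(frozen=True)
class EventRule:
    """Threshold-excursion event definition on one signal."""

    signal: str
    comparator: str  # "below" (strict <) or "above" (strict >)
    threshold: float
    min_duration: float = 10.0  # seconds
    merge_gap: float = 10.0  # seconds

    def __post_init__(self):
        if self.comparator not in ("below", "above"):
            raise ValueError("comparator must be 'below' or 'above'")
        if self.min_duration < 0 or self.merge_gap < 0:
            raise ValueError("durations must be non-negative")

    def condition(self, x: np.ndarray) -> np.ndarray:
        return x < self.threshold if self.comparator == "below" else x > self.threshold


DEFAULT_EVENT_RULES: dict[str, EventRule] = {
    "n_desaturations": EventRule("spo2", "below", 80.0),
    "n_bradycardia": EventRule("hr", "below", 100.0),
    "n_tachycardia": EventRule("hr", "above", 200.0),
}


def filter_valid(trace: VitalTrace) -> VitalTrace:
    """Drop invalid samples, keeping the nominal sampling interval."""
    if trace.valid.all():
        return trace
    m = trace.valid
    return VitalTrace(
        infant_id=trace.infant_id,
        t=trace.t[m], spo2=trace.spo2[m], hr=trace.hr[m], fio2=trace.fio2[m],
        valid=trace.valid[m], nominal_dt=trace.nominal_dt,
    )


def availability(trace: VitalTrace, day_start: int, day_end: int) -> float:
    """Fraction of the day window covered by valid samples.

    Valid-sample time (count x nominal interval) divided by the nominal
    window duration; the published inclusion rule excludes infants below
    0.80 over postnatal days 1-14.
    """
    if day_start > day_end:
        raise ValueError("empty availability window")
    lo = (day_start - 1) * SECONDS_PER_DAY
    hi = day_end * SECONDS_PER_DAY
    in_win = (trace.t >= lo) & (trace.t < hi) & trace.valid
    return float(min(1.0, in_win.sum() * trace.nominal_dt / (hi - lo)))


def _day_slice(trace: VitalTrace, signal: str, day: int) -> np.ndarray:
    lo = (day - 1) * SECONDS_PER_DAY
    m = (trace.t >= lo) & (trace.t < lo + SECONDS_PER_DAY) & trace.valid
    return trace.signal(signal)[m]


def daily_mean(trace: VitalTrace, signal: str, day: int) -> float:
    """Arithmetic mean of valid samples in a day (NaN when none).

    For ``signal='sf_ratio'`` the per-sample ratio SpO2[%]/FiO2[fraction] is
    averaged (mean of ratios, not ratio of means).
    """
    x = _day_slice(trace, signal, day)
    return float(np.mean(x)) if len(x) else float("nan")


def _sample_skewness(x: np.ndarray) -> float:
    n = len(x)
    if n < 3:
        return float("nan")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 <= 0:
        return float("nan")
    m3 = np.mean(d * d * d)
    return float(m3 / m2**1.5 * ((n - 1) / n) ** 1.5)


def daily_skewness(trace: VitalTrace, signal: str, day: int) -> float:
    """Moment-based sample skewness of a day's valid samples.

    Zero indicates a symmetric distribution. Returns NaN (with a log entry)
    below three samples or at zero variance.
    """
    x = _day_slice(trace, signal, day)
    out = _sample_skewness(x)
    if np.isnan(out) and len(x):
        log.debug("skewness undefined for infant %s %s day %d (n=%d)",
                  trace.infant_id, signal, day, len(x))
    return out


def auc_threshold(trace: VitalTrace, signal: str, day: int, threshold: float, side: str) -> float:
    """Rectangle-rule area beyond a threshold, in signal-units x minutes.

    ``side='below'`` accumulates ``(threshold - x)+``, ``side='above'``
    accumulates ``(x - threshold)+``, each sample weighted by the nominal
    sampling interval.
    """
    if side not in ("below", "above"):
        raise ValueError("side must be 'below' or 'above'")
    x = _day_slice(trace, signal, day)
    if not len(x):
        return float("nan")
    exc = np.maximum(0.0, threshold - x) if side == "below" else np.maximum(0.0, x - threshold)
    return float(exc.sum() * trace.nominal_dt / 60.0)


def pct_time(trace: VitalTrace, signal: str, day: int, threshold: float, side: str) -> float:
    """Percent of valid time at/below (``<=``) or strictly above a threshold."""
    if side not in ("below", "above"):
        raise ValueError("side must be 'below' or 'above'")
    x = _day_slice(trace, signal, day)
    if not len(x):
        return float("nan")
    hit = x <= threshold if side == "below" else x > threshold
    return float(100.0 * hit.mean())


def _event_onsets(trace: VitalTrace, rule: EventRule) -> np.ndarray:
    """Onset times (seconds) of events on the valid-filtered samples."""
    m = trace.valid
    t = trace.t[m]
    if len(t) == 0:
        return np.empty(0, dtype=np.int64)
    cond = rule.condition(trace.signal(rule.signal)[m])
    dt = trace.nominal_dt
    # maximal runs of consecutive condition-true samples
    edges = np.diff(np.concatenate(([0], cond.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1  # inclusive sample index
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    t_start = t[starts].astype(float)
    t_end = t[ends] + dt  # exclusive end time of the run

    # merge runs separated by less than merge_gap seconds
    keep_start, keep_end = [t_start[0]], [t_end[0]]
    for s, e in zip(t_start[1:], t_end[1:]):
        if s - keep_end[-1] < rule.merge_gap:
            keep_end[-1] = e
        else:
            keep_start.append(s)
            keep_end.append(e)
    t_start = np.array(keep_start)
    t_end = np.array(keep_end)
    dur = t_end - t_start
    return t_start[dur >= rule.min_duration].astype(np.int64)


def count_events(trace: VitalTrace, rule: EventRule, day: int) -> int:
    """Number of events whose onset falls in the given day."""
    onsets = _event_onsets(trace, rule)
    lo = (day - 1) * SECONDS_PER_DAY
    return int(((onsets >= lo) & (onsets < lo + SECONDS_PER_DAY)).sum())


def _infant_features(trace: VitalTrace, rules: dict[str, EventRule], days: int) -> np.ndarray:
    """Vectorised per-day features for one trace: (days, 13) array."""
    out = np.full((days, len(FEATURE_FAMILIES)), np.nan)
    col = {f: j for j, f in enumerate(FEATURE_FAMILIES)}
    m = trace.valid & (trace.t < days * SECONDS_PER_DAY)
    t = trace.t[m]
    if len(t) == 0:
        return out
    day_idx = (t // SECONDS_PER_DAY).astype(np.int64)
    n = np.bincount(day_idx, minlength=days).astype(float)
    has = n > 0
    dt_min = trace.nominal_dt / 60.0

    def daysum(w):
        return np.bincount(day_idx, weights=w, minlength=days)

    spo2 = trace.spo2[m]
    hr = trace.hr[m]
    fio2 = trace.fio2[m]

    for name, x in (("mean_spo2", spo2), ("mean_hr", hr), ("mean_fio2", fio2),
                    ("mean_sf_ratio", spo2 / fio2)):
        with np.errstate(invalid="ignore"):
            out[:, col[name]] = np.where(has, daysum(x) / np.where(has, n, 1), np.nan)

    for name, x in (("skew_spo2", spo2), ("skew_hr", hr)):
        mean = np.where(has, daysum(x) / np.where(has, n, 1), np.nan)
        d = x - mean[day_idx]
        m2 = daysum(d * d) / np.where(has, n, 1)
        m3 = daysum(d * d * d) / np.where(has, n, 1)
        ok = has & (n >= 3) & (m2 > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            skew = m3 / m2**1.5 * ((n - 1) / np.where(n > 0, n, 1)) ** 1.5
        out[:, col[name]] = np.where(ok, skew, np.nan)

    out[has, col["auc_below_80"]] = daysum(np.maximum(0.0, 80.0 - spo2))[has] * dt_min
    out[has, col["auc_above_95"]] = daysum(np.maximum(0.0, spo2 - 95.0))[has] * dt_min
    out[has, col["pct_time_le_80"]] = 100.0 * daysum(spo2 <= 80.0)[has] / n[has]
    out[has, col["pct_time_gt_95"]] = 100.0 * daysum(spo2 > 95.0)[has] / n[has]

    for name in ("n_desaturations", "n_bradycardia", "n_tachycardia"):
        onsets = _event_onsets(trace, rules[name])
        onsets = onsets[onsets < days * SECONDS_PER_DAY]
        counts = np.bincount((onsets // SECONDS_PER_DAY).astype(np.int64), minlength=days)
        out[has, col[name]] = counts[has].astype(float)

    return out


def build_feature_matrix(
    traces: Iterable[VitalTrace],
    rules: dict[str, EventRule] | None = None,
    days: int = 30,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Daily feature matrix for a collection of traces.

    Returns a DataFrame indexed by (infant_id, day 1..``days``) with one
    column per feature family. Cells are NaN where a day has no valid
    samples (or too few for skewness); infants with no valid data at all are
    excluded with a log entry. ``families`` restricts the computed columns.
    """
    rules = {**DEFAULT_EVENT_RULES, **(rules or {})}
    blocks, ids = [], []
    for trace in traces:
        if not trace.valid.any():
            log.warning("infant %s has no valid samples; excluded from feature matrix",
                        trace.infant_id)
            continue
        blocks.append(_infant_features(trace, rules, days))
        ids.append(trace.infant_id)
    if not blocks:
        raise ValueError("no traces with valid data")
    index = pd.MultiIndex.from_product([ids, np.arange(1, days + 1)],
                                       names=["infant_id", "day"])
    df = pd.DataFrame(np.vstack(blocks), index=index, columns=FEATURE_FAMILIES)
    if families is not None:
        df = df[list(families)]
    return df


def matrix_to_tidy(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long format (infant_id, day, feature, value) for text serialization."""
    tidy = matrix.stack().rename("value").reset_index()
    tidy.columns = ["infant_id", "day", "feature", "value"]
    return tidy


def tidy_to_matrix(tidy: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`matrix_to_tidy`, preserving family column order."""
    wide = tidy.pivot_table(index=["infant_id", "day"], columns="feature",
                            values="value", aggfunc="first")
    cols = [f for f in FEATURE_FAMILIES if f in wide.columns]
    return wide[cols]
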