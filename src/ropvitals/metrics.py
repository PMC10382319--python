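"""Confusion-matrix metrics, binomial intervals and model-comparison tests.

Everything downstream of a trained classifier is scored here: sensitivity,
specificity, balanced accuracy, Matthews correlation, predictive values with
Agresti-Coull 95% confidence intervals, two-sided mid-p McNemar tests for
paired model comparison, ROC staircases, and the baseline demographics
comparison table (rank-sum / chi-square / Fisher).

Raw metric values are kept at full precision; rounding to the two decimal
places used in reports happens only in :func:`round_half_away` at the
reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EvaluationResult",
    "confusion_metrics",
    "agresti_coull_interval",
    "mcnemar_midp",
    "roc_points",
    "baseline_table",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (0.675 -> 0.68, not banker's)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


@dataclass
class EvaluationResult:
    """Confusion counts plus the derived metric suite.

    ``n_interval`` is the denominator used for the Agresti-Coull intervals;
    it defaults to the total number of scored subjects.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ppv: float
    npv: float
    mcc: float
    intervals: dict = field(default_factory=dict)
    n_interval: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_row(self) -> dict:
        """Flat dict for tabular reports (full precision)."""
        row = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc, "ppv": self.ppv, "npv": self.npv,
        }
        for name, (lo, hi) in self.intervals.items():
            row[f"{name}_lo"] = lo
            row[f"{name}_hi"] = hi
        return row


def agresti_coull_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull approximate binomial interval, clipped to [0, 1].

    Adds z^2 pseudo-observations (half successes, half failures) before
    applying the Wald formula: with ``z`` the two-sided normal quantile,
    ``n~ = n + z^2``, ``p~ = (successes + z^2/2)/n~`` and half-width
    ``z * sqrt(p~ (1-p~) / n~)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - confidence, method="agresti_coull")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def confusion_metrics(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    n_interval: int | None = None,
    confidence: float = 0.95,
) -> EvaluationResult:
    """Compute the full metric suite from a 2x2 confusion matrix.

    Conventions for degenerate margins: PPV is NaN when no subject is
    predicted positive (NPV likewise), and the Matthews correlation is 0
    whenever any margin of the matrix is empty.

    Intervals for sensitivity, specificity and balanced accuracy use the
    Agresti-Coull formula on ``round(p * n_interval)`` successes out of
    ``n_interval`` (default: total scored subjects), which is how the
    published tables this module reproduces report them.
    """
    counts = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count {k}={v}")
    pos, neg = tp + fn, tn + fp
    if pos < 1 or neg < 1:
        raise ValueError("need at least one true positive-class and one negative-class subject")

    sens = tp / pos
    spec = tn / neg
    bacc = 0.5 * (sens + spec)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)

    n_int = n_interval if n_interval is not None else (pos + neg)
    intervals = {}
    for name, p in (("sensitivity", sens), ("specificity", spec), ("balanced_accuracy", bacc)):
        successes = int(round_half_away(p * n_int, 0))
        intervals[name] = agresti_coull_interval(successes, n_int, confidence)

    return EvaluationResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, balanced_accuracy=bacc,
        ppv=ppv, npv=npv, mcc=mcc,
        intervals=intervals, n_interval=n_int,
    )


def mcnemar_midp(b: int, c: int) -> float:
    """Two-sided mid-p McNemar test on discordant-pair counts ``b`` and ``c``.

    With ``n = b + c``, ``k = max(b, c)`` and ``X ~ Binomial(n, 1/2)``:
    ``p = 2 P(X >= k) - P(X = k)``, capped at 1. No discordant pairs gives
    p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    k = max(b, c)
    p = 2.0 * stats.binom.sf(k - 1, n, 0.5) - stats.binom.pmf(k, n, 0.5)
    return float(min(p, 1.0))


def roc_points(y_true: np.ndarray, probabilities: np.ndarray) -> pd.DataFrame:
    """ROC staircase: one (1-specificity, sensitivity) point per threshold.

    Includes the (0, 0) and (1, 1) endpoints. Thresholds follow the
    positive-if-probability-at-least-threshold rule used throughout.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    pos = int(y.sum())
    neg = int(len(y) - pos)
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both classes")
    # distinct thresholds, descending, plus an unattainable one for (0,0)
    thr = np.concatenate(([np.inf], np.unique(p)[::-1]))
    rows = []
    for t in thr:
        pred = p >= t
        tpr = float((pred & (y == 1)).sum() / pos)
        fpr = float((pred & (y == 0)).sum() / neg)
        rows.append((t, fpr, tpr))
    df = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    if not (df.iloc[-1][["fpr", "tpr"]] == 1.0).all():
        df.loc[len(df)] = [-np.inf, 1.0, 1.0]
    return df


def roc_auc(points: pd.DataFrame) -> float:
    """Area under the staircase by the trapezoid rule on the ROC points."""
    return float(np.trapezoid(points["tpr"].to_numpy(), points["fpr"].to_numpy()))


# variables of the baseline table, in report order
CONTINUOUS_BASELINE = [
    "gestational_age", "birth_weight", "apgar_1min", "apgar_5min",
    "prenatal_steroid_doses",
]
BINARY_BASELINE = [
    "sex", "multiple_birth", "delivery_route", "surfactant", "inotropes",
    "doxapram", "dexamethasone", "rbc_transfusion", "ino", "nec", "sepsis",
    "ivh", "pda",
]


def _fmt_median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.nanpercentile(x.astype(float), [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _fmt_n_pct(x: pd.Series) -> str:
    n = int(x.sum())
    return f"{n} ({100.0 * n / len(x):.0f}%)"


def baseline_table(cohort: pd.DataFrame, outcome: str = "outcome") -> pd.DataFrame:
    """Group-comparison table of demographics and clinical covariates.

    Continuous variables: median (IQR) per group with a Wilcoxon rank-sum
    p-value. Binary variables: n (%) per group; Fisher's exact test when any
    expected cell count is below 5, otherwise a continuity-corrected
    chi-square test.
    """
    groups = cohort[outcome].unique()
    if len(groups) < 2:
        raise ValueError("baseline table needs two outcome groups")
    g0 = cohort[cohort[outcome] == 0]
    g1 = cohort[cohort[outcome] == 1]
    rows = []
    for var in CONTINUOUS_BASELINE:
        if var not in cohort.columns:
            continue
        a, b = g0[var].dropna(), g1[var].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a.unique()) == set(b.unique()):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "variable": var, "type": "continuous",
            "group0": _fmt_median_iqr(a), "group1": _fmt_median_iqr(b),
            "test": "ranksum", "p_value": p,
        })
    for var in BINARY_BASELINE:
        if var not in cohort.columns:
            continue
        table = np.array([
            [int(g0[var].sum()), int(len(g0) - g0[var].sum())],
            [int(g1[var].sum()), int(len(g1) - g1[var].sum())],
        ])
        expected = stats.contingency.expected_freq(table) if table.sum() else None
        if expected is None or (expected < 5).any():
            p = float(stats.fisher_exact(table)[1])
            test = "fisher"
        else:
            p = float(stats.chi2_contingency(table, correction=True)[1])
            test = "chi2"
        rows.append({
            "variable": var, "type": "binary",
            "group0": _fmt_n_pct(g0[var]), "group1": _fmt_n_pct(g1[var]),
            "test": test, "p_value": p,
        })
    return pd.DataFrame(rows)
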