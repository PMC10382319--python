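"""Ten-model classification protocol with imbalance-aware LOOCV.

The outcome (laser-treated retinopathy of prematurity) is rare (~15%), so
training uses random undersampling: inside every training set the majority
class is subsampled without replacement down to the minority-class size.
Models are bagged decision-tree ensembles (random forests, 500 trees by
default); the score for an infant is the ensemble-averaged class-1
probability and the label is ``probability >= threshold`` (default 0.5).

The ten model variants differ only in their feature sets:

1.  all 13 physiological feature families, days 1-30
2.  families with a significant cluster, days 1-30
3.  families with a significant cluster, days 5-15
4.  SpO2/FiO2 ratio only, days 1-30
5.  demographics only (8 columns)
6.  model 3 + demographics
7.  model 4 + demographics
8.  clinical covariates only (10 columns)
9.  model 6 + clinical covariates
10. model 7 + clinical covariates

Leave-one-out cross-validation derives each fold's randomness (undersampling
draw and forest seed) from the master seed and the held-out infant's id, so
predictions do not depend on row order and the held-out infant never
influences training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_FAMILIES
from .metrics import EvaluationResult, confusion_metrics

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "DEMOGRAPHIC_COLS",
    "CLINICAL_COLS",
    "assemble_features",
    "undersample",
    "loocv_evaluate",
    "threshold_sweep",
    "evaluate_predictions",
    "holdout_validate",
    "subgroup_retrain",
]

DEMOGRAPHIC_COLS = [
    "gestational_age", "birth_weight", "sex", "multiple_birth",
    "prenatal_steroid_doses", "delivery_route", "apgar_1min", "apgar_5min",
]
CLINICAL_COLS = [
    "surfactant", "inotropes", "doxapram", "dexamethasone",
    "rbc_transfusion", "ino", "nec", "sepsis", "ivh", "pda",
]


@dataclass(frozen=True)
class ModelSpec:
    """Feature-set definition for one model variant."""

    model_id: int
    name: str
    physio_families: tuple[str, ...] = ()  # ignored when uses_cluster_selection
    day_window: tuple[int, int] | None = None  # None -> no physiological block
    uses_cluster_selection: bool = False
    include_demographics: bool = False
    include_clinical: bool = False


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "all physiological, days 1-30",
                 tuple(FEATURE_FAMILIES), (1, 30)),
    2: ModelSpec(2, "significant physiological, days 1-30",
                 (), (1, 30), uses_cluster_selection=True),
    3: ModelSpec(3, "significant physiological, days 5-15",
                 (), (5, 15), uses_cluster_selection=True),
    4: ModelSpec(4, "SpO2/FiO2 ratio, days 1-30",
                 ("mean_sf_ratio",), (1, 30)),
    5: ModelSpec(5, "demographics only", include_demographics=True),
    6: ModelSpec(6, "significant physiological days 5-15 + demographics",
                 (), (5, 15), uses_cluster_selection=True, include_demographics=True),
    7: ModelSpec(7, "SpO2/FiO2 ratio + demographics",
                 ("mean_sf_ratio",), (1, 30), include_demographics=True),
    8: ModelSpec(8, "clinical only", include_clinical=True),
    9: ModelSpec(9, "significant physiological days 5-15 + demographics + clinical",
                 (), (5, 15), uses_cluster_selection=True,
                 include_demographics=True, include_clinical=True),
    10: ModelSpec(10, "SpO2/FiO2 ratio + demographics + clinical",
                  ("mean_sf_ratio",), (1, 30),
                  include_demographics=True, include_clinical=True),
}


def _significant_families(cluster_results) -> list[str]:
    return [f for f in FEATURE_FAMILIES
            if f in cluster_results and cluster_results[f].significant]


def assemble_features(
    matrix: pd.DataFrame | None,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    cluster_results: dict | None = None,
) -> pd.DataFrame:
    """One-row-per-infant feature table for a model variant.

    Physiological columns are named ``<family>_d<day>`` and span the spec's
    day window; all days inside the window are included for the selected
    families (cluster selection picks families, not individual days).
    Demographic/clinical columns come from the cohort table. Raises when the
    resulting feature set is empty.
    """
    cohort = cohort.set_index("infant_id") if "infant_id" in cohort.columns else cohort
    parts = []
    if spec.day_window is not None:
        if matrix is None:
            raise ValueError("model requires the daily feature matrix")
        if spec.uses_cluster_selection:
            if cluster_results is None:
                raise ValueError("model requires cluster results for feature selection")
            families = _significant_families(cluster_results)
        else:
            families = list(spec.physio_families)
        lo, hi = spec.day_window
        if families:
            sub = matrix.loc[
                (slice(None), slice(lo, hi)), [f for f in families if f in matrix.columns]
            ]
            wide = sub.unstack("day")
            wide.columns = [f"{fam}_d{day:02d}" for fam, day in wide.columns]
            parts.append(wide)
    if spec.include_demographics:
        parts.append(cohort[DEMOGRAPHIC_COLS].astype(float))
    if spec.include_clinical:
        parts.append(cohort[CLINICAL_COLS].astype(float))
    if not parts:
        raise ValueError(f"model {spec.model_id} resolves to an empty feature set")
    table = pd.concat(parts, axis=1, join="outer")
    return table.loc[table.index.intersection(cohort.index)].sort_index()


def undersample(labels: pd.Series, rng: np.random.Generator) -> np.ndarray:
    """Balanced index subset: full minority class + matched majority sample."""
    y = labels.astype(int)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("undersampling needs both classes")
    minority = counts.idxmin()
    n_min = int(counts.min())
    keep = list(y.index[y == minority])
    majority_idx = y.index[y != minority].to_numpy()
    keep.extend(rng.choice(majority_idx, size=n_min, replace=False))
    return np.array(sorted(keep))


_FULL_TRAIN_TAG = 2**32 - 1  # fold tag for whole-training-set fits


def _fold_rng(seed: int, infant_id: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence([seed, _FULL_TRAIN_TAG if infant_id < 0 else int(infant_id)])
    rng = np.random.default_rng(ss)
    rf_seed = int(ss.generate_state(1)[0] % (2**31))
    return rng, rf_seed


def _fit_forest(X: pd.DataFrame, y: pd.Series, rng: np.random.Generator,
                rf_seed: int, n_estimators: int) -> tuple[RandomForestClassifier, pd.Series]:
    """Impute medians, undersample, fit. Returns the forest and the medians."""
    medians = X.median()
    Xf = X.fillna(medians).fillna(0.0)
    idx = undersample(y, rng)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=rf_seed, n_jobs=1)
    clf.fit(Xf.loc[idx], y.loc[idx])
    return clf, medians


def _score(clf: RandomForestClassifier, X: pd.DataFrame, medians: pd.Series) -> np.ndarray:
    Xf = X.fillna(medians).fillna(0.0)
    proba = clf.predict_proba(Xf)
    return proba[:, list(clf.classes_).index(1)]


def loocv_evaluate(
    table: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.5,
    n_estimators: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out cross-validated predictions.

    Returns one row per infant: ``y_true``, ensemble-averaged ``probability``,
    ``y_pred`` at the given threshold, and the fold id. Undersampling happens
    inside each fold, after the held-out infant is removed.
    """
    ids = table.index.sort_values()
    y = labels.loc[ids].astype(int)
    if len(ids) < 10:
        raise ValueError("LOOCV needs at least 10 infants")
    if y.nunique() < 2:
        raise ValueError("LOOCV needs both classes")
    rows = []
    for fold, infant in enumerate(ids):
        Xtr = table.drop(index=infant).loc[ids.drop(infant)]
        ytr = y.drop(index=infant)
        if ytr.nunique() < 2:
            raise ValueError(f"fold for infant {infant} has a single-class training set")
        rng, rf_seed = _fold_rng(seed, infant)
        clf, medians = _fit_forest(Xtr, ytr, rng, rf_seed, n_estimators)
        prob = float(_score(clf, table.loc[[infant]], medians)[0])
        rows.append({"infant_id": infant, "y_true": int(y.loc[infant]),
                     "probability": prob, "y_pred": int(prob >= threshold),
                     "fold": fold})
    return pd.DataFrame(rows).set_index("infant_id")


def evaluate_predictions(
    predictions: pd.DataFrame,
    threshold: float = 0.5,
    n_interval: int | None = None,
) -> EvaluationResult:
    """Confusion-matrix metric suite from a prediction set at a threshold."""
    y = predictions["y_true"].to_numpy()
    pred = (predictions["probability"].to_numpy() >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return confusion_metrics(tp, fp, fn, tn, n_interval=n_interval)


def threshold_sweep(predictions: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Sensitivity/specificity across probability thresholds.

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold under the ``probability >= threshold`` labelling rule.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    y = predictions["y_true"].to_numpy()
    p = predictions["probability"].to_numpy()
    pos = (y == 1).sum()
    neg = (y == 0).sum()
    rows = []
    for thr in np.asarray(thresholds, dtype=float):
        pred = p >= thr
        rows.append({
            "threshold": thr,
            "sensitivity": float((pred & (y == 1)).sum() / pos) if pos else float("nan"),
            "specificity": float((~pred & (y == 0)).sum() / neg) if neg else float("nan"),
        })
    return pd.DataFrame(rows)


def holdout_validate(
    train_table: pd.DataFrame,
    train_labels: pd.Series,
    test_table: pd.DataFrame,
    test_labels: pd.Series,
    threshold: float = 0.5,
    n_estimators: int = 500,
    seed: int = 0,
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Train once on the full training set, score the independent test set.

    Train and test infants must be disjoint; the test set must be non-empty.
    Returns the metric suite (intervals over the test-set size) and the
    test-set prediction table.
    """
    if len(test_table) == 0:
        raise ValueError("empty test set")
    overlap = train_table.index.intersection(test_table.index)
    if len(overlap):
        raise ValueError(f"train/test overlap: {list(overlap)[:5]}")
    ids = train_table.index.sort_values()
    rng, rf_seed = _fold_rng(seed, -1)
    clf, medians = _fit_forest(train_table.loc[ids], train_labels.loc[ids].astype(int),
                               rng, rf_seed, n_estimators)
    cols = train_table.columns
    prob = _score(clf, test_table[cols], medians)
    pred = pd.DataFrame({
        "y_true": test_labels.loc[test_table.index].astype(int),
        "probability": prob,
        "y_pred": (prob >= threshold).astype(int),
        "fold": -1,
    }, index=test_table.index)
    return evaluate_predictions(pred, threshold), pred


def subgroup_retrain(
    matrix: pd.DataFrame | None,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    cluster_results: dict | None = None,
    ga_max_weeks: float = 28.0,
    threshold: float = 0.5,
    n_estimators: int = 500,
    seed: int = 0,
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Re-run the LOOCV protocol on infants with gestational age <= cutoff."""
    coh = cohort.set_index("infant_id") if "infant_id" in cohort.columns else cohort
    sub = coh[coh["gestational_age"] <= ga_max_weeks]
    if sub["outcome"].nunique() < 2:
        raise ValueError("subgroup does not retain both outcome classes")
    sub_matrix = None
    if matrix is not None:
        keep = matrix.index.get_level_values("infant_id").isin(sub.index)
        sub_matrix = matrix[keep]
    table = assemble_features(sub_matrix, sub.reset_index(), spec, cluster_results)
    pred = loocv_evaluate(table, sub["outcome"], threshold=threshold,
                          n_estimators=n_estimators, seed=seed)
    return evaluate_predictions(pred, threshold), pred
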