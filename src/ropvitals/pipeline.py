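"""End-to-end analysis pipeline: simulate -> extract -> cluster -> classify.

Reproduces the study protocol on a synthetic cohort:

1. generate the cohort and traces;
2. randomly 1:1 split infants into training and test sets *before*
   exclusions (the split precedes the inclusion filter by design);
3. apply the inclusion filter (gestational age <= 32 weeks, birth weight
   <= 1500 g, >= 80% monitor-data availability over postnatal days 1-14),
   logging every exclusion with a reason code;
4. extract the daily feature matrix per set;
5. baseline demographics comparison in the training set;
6. cluster-permutation scan of all feature families in the training set;
7. train/evaluate the configured model variants with LOOCV in the training
   set, sweep thresholds for the two best, validate them on the held-out
   test set, and retrain on the combined data.

Randomness is hierarchical: every stage derives its own seed from the
master seed and a fixed stage tag, so any stage can be re-run in isolation
and two runs with the same config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .classify import (MODEL_SPECS, assemble_features, evaluate_predictions,
                       holdout_validate, loocv_evaluate, threshold_sweep)
from .cluster import cluster_scan, scan_to_frame
from .features import availability, build_feature_matrix
from .metrics import baseline_table, mcnemar_midp, round_half_away
from .synthetic import (DEFAULT_EFFECT_WINDOWS, EffectWindow, GeneratorConfig,
                        generate_cohort)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "split_cohort", "apply_inclusion", "run_pipeline"]

# stage tags for the seed hierarchy: stage_seed = SeedSequence([master, tag])
STAGE_SIMULATE, STAGE_SPLIT, STAGE_CLUSTER, STAGE_MODEL, STAGE_COMBINED = 11, 12, 13, 14, 15


def stage_seed(master: int, tag: int, extra: int = 0) -> int:
    return int(np.random.SeedSequence([master, tag, extra]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the study conditions."""

    out_dir: str = "ropvitals_run"
    seed: int = 0
    n_infants: int = 269
    prevalence: float = 0.15
    sampling_interval: int = 60
    days: int = 30
    effect_windows: tuple = DEFAULT_EFFECT_WINDOWS
    missingness_rate: float = 0.02
    low_availability_fraction: float = 0.2
    split_ratio: float = 0.5
    ga_max_weeks: float = 32.0
    bw_max_grams: float = 1500.0
    min_availability: float = 0.8
    availability_days: tuple[int, int] = (1, 14)
    models: tuple[int, ...] = tuple(range(1, 11))
    best_models: tuple[int, ...] = (6, 7)
    n_permutations: int = 5000
    alpha: float = 0.05
    alpha_cluster: float = 0.05
    n_estimators: int = 500
    threshold: float = 0.5
    write_traces: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "effect_windows" in raw:
            raw["effect_windows"] = tuple(EffectWindow(*w) for w in raw["effect_windows"])
        for key in ("availability_days", "models", "best_models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_infants=self.n_infants, prevalence=self.prevalence,
            sampling_interval=self.sampling_interval, days=self.days,
            effect_windows=self.effect_windows,
            missingness_rate=self.missingness_rate,
            low_availability_fraction=self.low_availability_fraction,
            seed=stage_seed(self.seed, STAGE_SIMULATE),
        )


def split_cohort(cohort: pd.DataFrame, ratio: float = 0.5, seed: int = 0):
    """Random disjoint, exhaustive train/test partition of infant ids."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("split ratio must lie in (0, 1)")
    ids = cohort["infant_id"].to_numpy()
    if len(ids) == 0:
        raise ValueError("empty cohort")
    perm = np.random.default_rng(seed).permutation(ids)
    n_train = int(np.floor(len(ids) * ratio + 0.5))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def apply_inclusion(
    cohort: pd.DataFrame,
    traces: dict,
    ga_max_weeks: float = 32.0,
    bw_max_grams: float = 1500.0,
    min_availability: float = 0.8,
    availability_days: tuple[int, int] = (1, 14),
):
    """Apply the inclusion filter; returns (kept cohort, exclusion log).

    Exclusion reasons (first matching, in order): gestational age above the
    cutoff, birth weight above the cutoff, monitor-data availability below
    the minimum over the availability window.
    """
    reasons = []
    lo, hi = availability_days
    for row in cohort.itertuples(index=False):
        if row.gestational_age > ga_max_weeks:
            reasons.append((row.infant_id, "gestational_age"))
        elif row.birth_weight > bw_max_grams:
            reasons.append((row.infant_id, "birth_weight"))
        elif availability(traces[row.infant_id], lo, hi) < min_availability:
            reasons.append((row.infant_id, "availability"))
    exclusions = pd.DataFrame(reasons, columns=["infant_id", "reason"])
    kept = cohort[~cohort["infant_id"].isin(exclusions["infant_id"])].reset_index(drop=True)
    return kept, exclusions


def model_comparison_table(predictions: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise two-sided mid-p McNemar tests between model prediction sets.

    For every model pair the discordant-pair counts are formed over all
    infants (accuracy), the laser infants only (sensitivity) and the
    non-laser infants only (specificity), matching how paired model
    comparisons are reported alongside the metric table.
    """
    rows = []
    ids = sorted(predictions)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pa, pb = predictions[a], predictions[b]
            common = pa.index.intersection(pb.index)
            ca = pa.loc[common, "y_pred"] == pa.loc[common, "y_true"]
            cb = pb.loc[common, "y_pred"] == pb.loc[common, "y_true"]
            y = pa.loc[common, "y_true"]
            for scope, mask in (("accuracy", np.ones(len(common), bool)),
                                ("sensitivity", (y == 1).to_numpy()),
                                ("specificity", (y == 0).to_numpy())):
                disc_a = int((ca[mask] & ~cb[mask]).sum())
                disc_b = int((~ca[mask] & cb[mask]).sum())
                rows.append({"model_a": a, "model_b": b, "scope": scope,
                             "b": disc_a, "c": disc_b,
                             "p_value": mcnemar_midp(disc_a, disc_b)})
    return pd.DataFrame(rows)


def _eval_row(result, model_id: int, dataset: str) -> dict:
    row = {"model": model_id, "dataset": dataset}
    row.update(result.to_row())
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory artefacts (cohort, split, feature
    matrices, cluster results, evaluation tables, manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in dataclasses.asdict(config).items()},
                      "stages": {}}

    def stage_done(name):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 2)}
        log.info("stage %-16s done at %.1fs", name, time.time() - t0)

    # 1. simulate
    cohort, trace_list = generate_cohort(config.generator_config())
    traces = {tr.infant_id: tr for tr in trace_list}
    io.write_cohort(cohort, out / "cohort.csv")
    if config.write_traces:
        io.write_traces(trace_list, out / "traces.csv")
    stage_done("simulate")

    # 2. split before exclusions
    train_ids, test_ids = split_cohort(cohort, config.split_ratio,
                                       stage_seed(config.seed, STAGE_SPLIT))
    pd.DataFrame({
        "infant_id": np.concatenate([train_ids, test_ids]),
        "dataset": ["train"] * len(train_ids) + ["test"] * len(test_ids),
    }).to_csv(out / "split.csv", index=False)

    # 3. inclusion filter per set
    sets, exclusion_frames = {}, []
    for name, ids in (("train", train_ids), ("test", test_ids)):
        part = cohort[cohort["infant_id"].isin(ids)]
        kept, excl = apply_inclusion(
            part, traces, config.ga_max_weeks, config.bw_max_grams,
            config.min_availability, config.availability_days)
        excl.insert(0, "dataset", name)
        sets[name] = kept
        exclusion_frames.append(excl)
    exclusions = pd.concat(exclusion_frames, ignore_index=True)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    manifest["cohort"] = {
        "n_total": int(len(cohort)),
        "n_excluded": int(len(exclusions)),
        "exclusions_by_reason": exclusions["reason"].value_counts().to_dict(),
        "n_train": int(len(sets["train"])), "n_test": int(len(sets["test"])),
        "n_laser_train": int(sets["train"]["outcome"].sum()),
        "n_laser_test": int(sets["test"]["outcome"].sum()),
    }
    stage_done("inclusion")

    # 4. features
    matrices = {}
    for name in ("train", "test"):
        keep = [traces[i] for i in sets[name]["infant_id"]]
        matrices[name] = build_feature_matrix(keep, days=config.days)
        io.write_feature_matrix(matrices[name], out / f"features_{name}.csv")
    stage_done("features")

    # 5. baseline table (training set)
    baseline = baseline_table(sets["train"])
    baseline.to_csv(out / "baseline_table.csv", index=False)
    stage_done("baseline")

    # 6. cluster scan (training set)
    labels_train = sets["train"].set_index("infant_id")["outcome"]
    clusters = cluster_scan(matrices["train"], labels_train,
                            n_perm=config.n_permutations,
                            seed=stage_seed(config.seed, STAGE_CLUSTER),
                            alpha_cluster=config.alpha_cluster, alpha=config.alpha)
    scan_to_frame(clusters).to_csv(out / "clusters.csv", index=False)
    stage_done("clusters")

    # 7. models
    eval_rows, sweep_frames = [], []
    predictions = {}
    labels_test = sets["test"].set_index("infant_id")["outcome"]
    for mid in config.models:
        spec = MODEL_SPECS[mid]
        table = assemble_features(matrices["train"], sets["train"], spec, clusters)
        pred = loocv_evaluate(table, labels_train, threshold=config.threshold,
                              n_estimators=config.n_estimators,
                              seed=stage_seed(config.seed, STAGE_MODEL, mid))
        predictions[mid] = pred
        pred.to_csv(out / f"predictions_model{mid}.csv")
        eval_rows.append(_eval_row(evaluate_predictions(pred, config.threshold),
                                   mid, "train_loocv"))
        if mid in config.best_models:
            sweep = threshold_sweep(pred)
            sweep.insert(0, "model", mid)
            sweep_frames.append(sweep)
            test_table = assemble_features(matrices["test"], sets["test"], spec, clusters)
            test_table = test_table.reindex(columns=table.columns)
            res, test_pred = holdout_validate(
                table, labels_train, test_table, labels_test,
                threshold=config.threshold, n_estimators=config.n_estimators,
                seed=stage_seed(config.seed, STAGE_MODEL, mid))
            eval_rows.append(_eval_row(res, mid, "test"))
            test_pred.to_csv(out / f"predictions_model{mid}_test.csv")
            # combined retrain: LOOCV over training and test infants together
            combined_cohort = pd.concat([sets["train"], sets["test"]], ignore_index=True)
            combined_matrix = pd.concat([matrices["train"], matrices["test"]]).sort_index()
            combined_table = assemble_features(combined_matrix, combined_cohort, spec, clusters)
            combined_labels = combined_cohort.set_index("infant_id")["outcome"]
            comb_pred = loocv_evaluate(
                combined_table, combined_labels, threshold=config.threshold,
                n_estimators=config.n_estimators,
                seed=stage_seed(config.seed, STAGE_COMBINED, mid))
            eval_rows.append(_eval_row(evaluate_predictions(comb_pred, config.threshold),
                                       mid, "combined_loocv"))
    evals = pd.DataFrame(eval_rows)
    evals.to_csv(out / "model_evals.csv", index=False)
    comparisons = model_comparison_table(predictions)
    comparisons.to_csv(out / "model_comparisons.csv", index=False)
    if sweep_frames:
        pd.concat(sweep_frames, ignore_index=True).to_csv(
            out / "threshold_curves.csv", index=False)
    stage_done("models")

    manifest["leakage_audit"] = {
        "train_test_id_overlap": sorted(
            set(sets["train"]["infant_id"]) & set(sets["test"]["infant_id"]))
    }
    manifest["seed_hierarchy"] = {
        "master": config.seed,
        "simulate": stage_seed(config.seed, STAGE_SIMULATE),
        "split": stage_seed(config.seed, STAGE_SPLIT),
        "cluster": stage_seed(config.seed, STAGE_CLUSTER),
        "models": {m: stage_seed(config.seed, STAGE_MODEL, m) for m in config.models},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # human-readable report with 2-dp rounding
    report_lines = ["model  dataset          bacc  sens  spec   mcc"]
    for row in eval_rows:
        report_lines.append(
            f"{row['model']:>5}  {row['dataset']:<15}"
            f"{round_half_away(row['balanced_accuracy']):>6.2f}"
            f"{round_half_away(row['sensitivity']):>6.2f}"
            f"{round_half_away(row['specificity']):>6.2f}"
            f"{round_half_away(row['mcc']):>6.2f}")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    return {"cohort": cohort, "sets": sets, "exclusions": exclusions,
            "matrices": matrices, "clusters": clusters, "baseline": baseline,
            "evals": evals, "comparisons": comparisons,
            "predictions": predictions, "manifest": manifest}
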