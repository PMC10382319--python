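"""Delimited-text serialization of traces, cohorts and feature matrices.

All tabular interchange is plain CSV with headers. Trace files are
long-format: one row per sample with columns ``infant_id, t_seconds, spo2,
hr, fio2, valid`` (valid as 0/1). The feature matrix travels tidy:
``infant_id, day, feature, value``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .features import matrix_to_tidy, tidy_to_matrix
from .synthetic import VitalTrace

TRACE_COLUMNS = ["infant_id", "t_seconds", "spo2", "hr", "fio2", "valid"]


def traces_to_frame(traces: Iterable[VitalTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "infant_id": tr.infant_id, "t_seconds": tr.t,
            "spo2": tr.spo2, "hr": tr.hr, "fio2": tr.fio2,
            "valid": tr.valid.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]


def write_traces(traces: Iterable[VitalTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.3f")


def read_traces(path: str | Path) -> list[VitalTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file lacks columns {sorted(missing)}")
    out = []
    for infant_id, g in df.groupby("infant_id", sort=True):
        g = g.sort_values("t_seconds")
        out.append(VitalTrace(
            infant_id=int(infant_id),
            t=g["t_seconds"].to_numpy(np.int64),
            spo2=g["spo2"].to_numpy(float),
            hr=g["hr"].to_numpy(float),
            fio2=g["fio2"].to_numpy(float),
            valid=g["valid"].to_numpy().astype(bool),
        ))
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix_to_tidy(matrix).to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return tidy_to_matrix(pd.read_csv(path))
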