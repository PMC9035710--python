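"""Plain-text persistence: session CSV, cohort CSV, fit-report JSON, and
JSON/YAML config loading. All formats round-trip exactly."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .hbi import HBIResults
from .task import MISS, Session, TaskConfig, TrialRecord

SESSION_COLUMNS = [
    "trial", "correct_image", "choice", "outcome", "points_delta",
    "cumulative", "criterion_met", "maintained_k", "reversed_after",
    "learning_event",
]

COHORT_COLUMNS = [
    "subject", "alpha_pos", "alpha_neg", "beta", "correct", "reversals",
    "mean_trials_to_criterion", "perseverative", "regressive", "misses",
    "choline_mM", "gpcpc_mM", "naa_mM",
]


class SchemaError(ValueError):
    """A loaded table does not match the expected schema."""


def save_session(session: Session, path: Union[str, Path]) -> None:
    session.to_dataframe().to_csv(path, index=False)


def load_session(
    path: Union[str, Path], config: TaskConfig, subject: str = ""
) -> Session:
    df = pd.read_csv(Path(path), keep_default_na=False)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"session CSV {path}: missing columns {sorted(missing)}")
    trials = []
    for i, row in df.iterrows():
        choice = row["choice"]
        choice = MISS if choice == "" else str(choice)
        if choice is not MISS and choice not in ("A", "B"):
            raise SchemaError(f"session CSV {path}: bad choice {choice!r} in row {i}")
        trials.append(
            TrialRecord(
                trial_index=int(row["trial"]),
                correct_image=str(row["correct_image"]),
                choice=choice,
                outcome=str(row["outcome"]),
                points_delta=int(row["points_delta"]),
                cumulative_points=int(row["cumulative"]),
                criterion_met=_to_bool(row["criterion_met"], "criterion_met", i),
                maintained_count=int(row["maintained_k"]),
                reversed_after=_to_bool(row["reversed_after"], "reversed_after", i),
                learning_event=int(row["learning_event"]),
            )
        )
    name = subject or Path(path).stem
    return Session(subject=name, config=config, trials=trials)


def _to_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise SchemaError(f"column {column!r}, row {row}: not a boolean: {value!r}")


def save_cohort(table: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns {sorted(missing)}")
    table[COHORT_COLUMNS].to_csv(path, index=False)


def load_cohort(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort CSV {path}: missing columns {sorted(missing)}")
    return df


def fit_report(results: HBIResults) -> dict:
    """JSON-serialisable fit report: group posteriors (unconstrained and
    back-transformed), frequencies, EP/PXP, argmax counts, trace."""
    return {
        "models": results.model_names,
        "group_means_unconstrained": {k: list(v) for k, v in results.group_means.items()},
        "group_variances": {k: list(v) for k, v in results.group_variances.items()},
        "group_params_constrained": {k: list(v) for k, v in results.group_params.items()},
        "mean_subject_params": {
            k: list(v) for k, v in results.subject_param_means.items()
        },
        "frequencies": list(results.frequencies),
        "exceedance": list(results.exceedance),
        "pxp": list(results.pxp),
        "null_prob": results.null_prob,
        "argmax_counts": [int(c) for c in results.argmax_counts],
        "responsibilities": results.responsibilities.tolist(),
        "converged": bool(results.converged),
        "n_iter": int(results.n_iter),
        "trace": [float(x) for x in results.trace],
    }


def subject_params_frame(results: HBIResults, subjects=None) -> pd.DataFrame:
    """Per-subject posterior parameter estimates (constrained and
    unconstrained) and model responsibilities, long format (one row per
    subject x model)."""
    n = results.responsibilities.shape[0]
    names = subjects if subjects is not None else [f"S{i + 1:03d}" for i in range(n)]
    rows = []
    for j, model in enumerate(results.model_names):
        for i in range(n):
            p = results.subject_params[model][i]
            row = {"subject": names[i], "model": model,
                   "responsibility": float(results.responsibilities[i, j])}
            row.update({k: getattr(p, k) for k in p.__dataclass_fields__})
            theta = p.to_unconstrained()
            for k, v in zip(p.__dataclass_fields__, theta):
                row[f"u_{k}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)


def save_fit_report(results: HBIResults, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(fit_report(results), indent=2))


def load_fit_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: Union[str, Path], cls):
    """Build a TaskConfig or CohortConfig from a JSON or YAML mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a mapping")
    if cls is CohortConfig and isinstance(data.get("task"), dict):
        data = dict(data)
        data["task"] = TaskConfig(**data["task"])
    try:
        return cls(**data)
    except TypeError as exc:
        raise SchemaError(f"config {path}: {exc}") from exc


def save_config(config, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
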