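"""Subject-table I/O and serialization of analysis artifacts.

Lets users run the matching-order diagnostics on their own subject-level
data: a CSV with one row per subject, named covariate columns, and strictly
binary treatment and outcome columns.  Rows with missing values in any
declared analysis column are dropped (complete-case) with the drop count
reported.  Categorical covariates are expanded to indicator codes for the
logistic propensity fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohorts import Cohort, CovariateSpec, ScenarioConfig
from .estimation import EffectEstimate
from .matching import MatchedSet

__all__ = [
    "SubjectTable",
    "read_subject_table",
    "subject_table_to_cohort",
    "write_cohort",
    "read_cohort",
    "write_matched_set",
    "read_matched_set",
    "estimates_to_frame",
    "scenario_from_mapping",
    "load_scenario",
]


@dataclass
class SubjectTable:
    """Validated subject-level analysis table."""

    ids: np.ndarray
    covariates: np.ndarray          # design columns after indicator expansion
    covariate_names: list[str]
    treatment: np.ndarray
    outcome: np.ndarray
    n_dropped: int = 0


def read_subject_table(
    path: str | Path,
    covariate_columns: list[str],
    treatment_column: str = "treatment",
    outcome_column: str = "outcome",
    id_column: str | None = "id",
    categorical: list[str] | None = None,
) -> SubjectTable:
    """Read and validate a subject CSV.

    ``categorical`` names covariate columns to expand into indicator codes
    (first level dropped).  Raises on missing columns, non-binary treatment
    or outcome, or an empty file; rows with missing values in any analysis
    column are dropped and counted.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty subject table")
    needed = list(covariate_columns) + [treatment_column, outcome_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    n0 = len(df)
    df = df.dropna(subset=needed)
    n_dropped = n0 - len(df)
    if df.empty:
        raise ValueError(f"{path}: no complete-case rows remain")
    for col in (treatment_column, outcome_column):
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: column {col!r} must be strictly 0/1, saw {sorted(vals)[:5]}")

    categorical = categorical or []
    design = pd.get_dummies(
        df[covariate_columns],
        columns=[c for c in categorical if c in covariate_columns],
        drop_first=True,
        dtype=float,
    )
    ids = (df[id_column].to_numpy() if id_column and id_column in df.columns
           else np.arange(len(df)))
    return SubjectTable(
        ids=ids,
        covariates=design.to_numpy(dtype=float),
        covariate_names=list(design.columns),
        treatment=df[treatment_column].to_numpy(dtype=np.int8),
        outcome=df[outcome_column].to_numpy(dtype=np.int8),
        n_dropped=n_dropped,
    )


def subject_table_to_cohort(table: SubjectTable) -> Cohort:
    """View a single-covariate subject table as a Cohort (true PS unknown: nan)."""
    if table.covariates.shape[1] != 1:
        raise ValueError("cohort view requires exactly one covariate column")
    return Cohort(
        covariate=table.covariates[:, 0],
        treatment=table.treatment,
        outcome=table.outcome,
        true_propensity=np.full(len(table.treatment), np.nan),
        seed_record=-1,
    )


# ---------------------------------------------------------------------------
# cohort round-trip

_COHORT_COLUMNS = ["id", "x", "treatment", "outcome", "true_ps"]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame({
        "id": np.arange(cohort.n),
        "x": cohort.covariate,
        "treatment": cohort.treatment,
        "outcome": cohort.outcome,
        "true_ps": cohort.true_propensity,
    }).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns and c != "true_ps"]
    if missing:
        raise ValueError(f"{path}: missing cohort column(s) {missing}")
    true_ps = (df["true_ps"].to_numpy(float) if "true_ps" in df.columns
               else np.full(len(df), np.nan))       # user data: truth unknown
    return Cohort(
        covariate=df["x"].to_numpy(float),
        treatment=df["treatment"].to_numpy(np.int8),
        outcome=df["outcome"].to_numpy(np.int8),
        true_propensity=true_ps,
        seed_record=-1,
    )


# ---------------------------------------------------------------------------
# matched sets and estimates

def write_matched_set(ms: MatchedSet, logit_ps: np.ndarray, path: str | Path) -> None:
    """One CSV row per matched pair: set_id, treated_id, control_id, distance."""
    rows = []
    for t_idx in sorted(ms.pairs):
        for c_idx in ms.pairs[t_idx]:
            rows.append({
                "set_id": t_idx,
                "treated_id": t_idx,
                "control_id": c_idx,
                "distance": abs(float(logit_ps[t_idx]) - float(logit_ps[c_idx])),
            })
    pd.DataFrame(rows, columns=["set_id", "treated_id", "control_id", "distance"]) \
        .to_csv(path, index=False, float_format="%.17g")


def read_matched_set(path: str | Path) -> dict[int, list[int]]:
    df = pd.read_csv(path)
    pairs: dict[int, list[int]] = {}
    for _, row in df.iterrows():
        pairs.setdefault(int(row["treated_id"]), []).append(int(row["control_id"]))
    return pairs


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": e.method,
        "or_hat": e.or_hat,
        "log_or": e.log_or,
        "se_model": e.se_model,
        "se_robust": e.se_robust,
        "ci_model_l": e.ci_model[0], "ci_model_u": e.ci_model[1],
        "ci_robust_l": e.ci_robust[0], "ci_robust_u": e.ci_robust[1],
        "df_robust": e.df_robust,
        "converged": e.converged,
        "unstable": e.unstable,
        "n_subjects": e.n_subjects,
    } for e in estimates])


# ---------------------------------------------------------------------------
# scenario configs

def scenario_from_mapping(m: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML/JSON mapping (field names mirror the config)."""
    known = {"covariate", "pg", "c_target", "pe", "true_or", "n", "ratio", "caliper_fraction"}
    unknown = set(m) - known
    if unknown:
        raise KeyError(f"unknown scenario key(s): {sorted(unknown)}")
    kwargs = dict(m)
    if "covariate" in kwargs:
        kwargs["covariate"] = CovariateSpec(kwargs["covariate"])
    return ScenarioConfig(**kwargs)


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of scenario fields")
    return scenario_from_mapping(data)
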