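"""Dataset readers/writers and run configuration.

Two CSV schemas are understood:

``simulated``
    columns ``W1, W2, A, Y`` and optionally ``true_ps``;
``nsw``
    the classic job-training evaluation layout: ``treat`` plus the eight
    baseline covariates ``age, educ, black, hispan, married, nodegree,
    re74, re75`` and the outcome ``re78`` (real earnings in 1978, kept in
    dollars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic import StudyData

__all__ = ["read_study_csv", "write_study_csv", "RunConfig", "NSW_COVARIATES"]

NSW_COVARIATES = ("age", "educ", "black", "hispan", "married", "nodegree", "re74", "re75")
_NSW_BINARY = ("treat", "black", "hispan", "married", "nodegree")


def read_study_csv(path, schema: str = "simulated") -> StudyData:
    """Load a study table from CSV under the given schema."""
    df = pd.read_csv(path)
    if schema == "simulated":
        required = ["W1", "W2", "A", "Y"]
        _check_columns(df, required)
        _check_binary(df, ["A"])
        return StudyData(
            covariates=df[["W1", "W2"]].copy(),
            treatment=df["A"].to_numpy(),
            outcome=df["Y"].to_numpy(),
            true_propensity=df["true_ps"].to_numpy() if "true_ps" in df.columns else None,
        )
    if schema == "nsw":
        required = ["treat", *NSW_COVARIATES, "re78"]
        _check_columns(df, required)
        _check_binary(df, list(_NSW_BINARY))
        return StudyData(
            covariates=df[list(NSW_COVARIATES)].copy(),
            treatment=df["treat"].to_numpy(),
            outcome=df["re78"].to_numpy(),
        )
    raise ValueError(f"unknown schema {schema!r}; choose 'simulated' or 'nsw'")


def _check_columns(df: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")


def _check_binary(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        vals = set(pd.unique(df[c]))
        if not vals <= {0, 1}:
            raise ValueError(f"column {c!r} must be binary 0/1, found values {sorted(vals)[:5]}")


def write_study_csv(data: StudyData, path) -> None:
    """Write a study to CSV (simulated schema; ``true_ps`` kept if present)."""
    data.to_frame().to_csv(path, index=False)


@dataclass
class RunConfig:
    """A fully explicit, serialisable description of one evaluation run."""

    scenario: str = "good"
    reps: int = 1000
    n: int = 1000
    seed: int = 1
    n_subclasses: int = 10
    ensemble_learners: tuple = ("glm", "glm_interactions", "knn")
    ensemble_folds: int = 5
    ga_pop_size: int = 16
    ga_generations: int = 10
    ps_bounds: tuple = (0.005, 0.995)
    tmle_variant: str = "iterative"
    output_dir: str = "results"

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["ensemble_learners"] = list(self.ensemble_learners)
        d["ps_bounds"] = list(self.ps_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "ensemble_learners" in d:
            d["ensemble_learners"] = tuple(d["ensemble_learners"])
        if "ps_bounds" in d:
            d["ps_bounds"] = tuple(d["ps_bounds"])
        return cls(**d)
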