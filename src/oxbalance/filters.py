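"""Sequential cohort exclusion pipeline with attrition logging.

Participants are dropped, in order, when they (1) are missing any OBS
component or model covariate, (2) fall outside the adult age range
(20–84 years; ages ≥85 are top-coded in the source surveys and excluded,
and the analytic samples this mirrors contain adults only), (3) are
pregnant, (4) have a dietary recall below the minimum quality criteria, or
(5) report an implausible energy intake (men <800 or >4200 kcal/d, women
<500 or >3500 kcal/d — exclusive bounds, so a value exactly at a bound is
retained).  A row violating several criteria is counted once, at the first
violated step, matching sequential flowchart semantics; the pipeline is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import OBSSchema, SchemaError, load_default_schema

__all__ = [
    "AttritionLog",
    "ExclusionFilter",
    "apply_exclusions",
    "DEFAULT_COVARIATES",
    "ENERGY_BOUNDS",
]

#: covariate columns whose missingness triggers step 1 (besides components)
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "ethnicity",
    "education",
    "pir",
    "energy",
    "crp",
    "ltl",
)

#: sex → (lower, upper) plausible energy intake, kcal/d, exclusive bounds
ENERGY_BOUNDS: dict[str, tuple[float, float]] = {
    "male": (800.0, 4200.0),
    "female": (500.0, 3500.0),
}

ADULT_AGE_RANGE = (20, 84)

STEP_NAMES = (
    "missing_data",
    "age_out_of_range",
    "pregnant",
    "recall_below_minimum",
    "implausible_energy",
)


@dataclass
class AttritionLog:
    """Ordered per-step record of removals: (step, removed, remaining)."""

    steps: list[tuple[str, int, int]]

    @property
    def removed_total(self) -> int:
        return sum(r for _, r, _ in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _violation_masks(
    cohort: pd.DataFrame, check_columns: list[str]
) -> dict[str, np.ndarray]:
    """Boolean per-step violation masks evaluated on the full table."""
    miss = cohort[check_columns].isna().any(axis=1).to_numpy()

    age = cohort["age"].to_numpy(dtype=float)
    lo, hi = ADULT_AGE_RANGE
    age_bad = np.where(np.isnan(age), False, (age < lo) | (age > hi))

    pregnant = cohort["pregnant"].fillna(False).to_numpy(dtype=bool)
    recall_bad = (cohort["recall_status"] == "below_minimum").to_numpy()

    energy = cohort["energy"].to_numpy(dtype=float)
    energy_bad = np.zeros(len(cohort), dtype=bool)
    for sex, (elo, ehi) in ENERGY_BOUNDS.items():
        m = (cohort["sex"] == sex).to_numpy()
        energy_bad |= m & ((energy < elo) | (energy > ehi))

    return {
        "missing_data": miss,
        "age_out_of_range": age_bad,
        "pregnant": pregnant,
        "recall_below_minimum": recall_bad,
        "implausible_energy": energy_bad,
    }


def apply_exclusions(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the five exclusion steps in order; return (filtered, log).

    The missingness check covers the schema's component columns plus
    ``covariates``.  Raises :class:`~oxbalance.schema.SchemaError` naming the
    first required column absent from the table.
    """
    schema = schema or load_default_schema()
    check_columns = list(schema.names) + [c for c in covariates if c not in schema.names]
    required = check_columns + ["pregnant", "recall_status"]
    for col in required:
        if col not in cohort.columns:
            raise SchemaError(f"cohort is missing required column {col!r}")

    masks = _violation_masks(cohort, check_columns)
    keep = np.ones(len(cohort), dtype=bool)
    steps: list[tuple[str, int, int]] = []
    for name in STEP_NAMES:
        hit = keep & masks[name]
        keep &= ~hit
        steps.append((name, int(hit.sum()), int(keep.sum())))
    return cohort.loc[keep].copy(), AttritionLog(steps=steps)


class ExclusionFilter(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`apply_exclusions`.

    After ``transform`` the attrition log is available as ``attrition_log_``.
    """

    def __init__(
        self,
        schema: OBSSchema | None = None,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ):
        self.schema = schema
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None) -> "ExclusionFilter":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered, log = apply_exclusions(X, self.schema, self.covariates)
        self.attrition_log_ = log
        return filtered
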