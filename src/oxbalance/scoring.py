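"""OBS point assignment and score aggregation.

Scoring conventions
-------------------
* Tertile groups use half-open intervals: value < t1 → low group,
  t1 ≤ value < t2 → middle group, value ≥ t2 → high group.  A value exactly
  at a boundary therefore lands in the upper of the two adjacent groups.
* Antioxidant components score 0/1/2 points from the low to the high group;
  prooxidant components score the reverse (2/1/0).
* Alcohol ignores tertiles: nondrinkers (exactly 0 g/d) score 2, nonheavy
  drinkers 1, and heavy drinkers (≥30 g/d men, ≥15 g/d women) score 0.
* Quantile cuts (tertiles here, OBS quartiles in :func:`assign_quartiles`,
  weighted medians in :mod:`oxbalance.survey`) are all the same statistic:
  the cut at probability ``p`` is the smallest observed value whose
  cumulative normalized weight strictly exceeds ``p``.  Combined with the
  half-open groups above this splits evenly divisible data into exactly
  equal groups and sends boundary ties to the upper group.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import (
    SEXES,
    AlcoholRule,
    ComponentSpec,
    CutpointSet,
    OBSSchema,
    SchemaError,
    Sex,
    load_default_cutpoints,
    load_default_schema,
)

__all__ = [
    "DegenerateDistributionError",
    "weighted_quantile_cut",
    "compute_tertiles",
    "compute_cutpoints",
    "assign_component_points",
    "compute_obs",
    "assign_quartiles",
    "OBSScorer",
]


class DegenerateDistributionError(ValueError):
    """Too few distinct values (or too much mass on one value) to form cuts."""


# ---------------------------------------------------------------------------
# quantile machinery
# ---------------------------------------------------------------------------


def weighted_quantile_cut(
    values: Sequence[float],
    p: float,
    weights: Sequence[float] | None = None,
) -> float:
    """Smallest observed value whose cumulative normalized weight exceeds p.

    With equal weights this reduces to the inverse empirical CDF evaluated
    just past ``p``; ties at exactly ``p`` roll over to the next value, which
    is what makes tertile/quartile groups equal-sized on evenly divisible
    unweighted data under the half-open grouping convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateDistributionError("no values")
    if np.isnan(v).any():
        raise ValueError("values contain NaN")
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise ValueError("weights must match values in length")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / total
    # strict inequality with a relative tolerance so exact ties (e.g. a
    # cumulative share of exactly 1/3 at p=1/3) reliably roll upward
    exceeded = cum > p * (1 + 1e-12) + 1e-15
    idx = int(np.argmax(exceeded)) if exceeded.any() else v.size - 1
    return float(v[idx])


def _cuts(values, ps: Iterable[float], weights=None) -> tuple[float, ...]:
    return tuple(weighted_quantile_cut(values, p, weights) for p in ps)


def compute_tertiles(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Tertile boundaries (t1, t2) for one sex's component values.

    Requires at least 3 distinct values and strictly ascending cuts;
    otherwise the distribution cannot support three groups.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v[~np.isnan(v)]).size < 3:
        raise DegenerateDistributionError(
            "need at least 3 distinct values to form tertiles"
        )
    t1, t2 = _cuts(v, (1 / 3, 2 / 3), weights)
    if not t1 < t2:
        raise DegenerateDistributionError(
            f"degenerate tertile boundaries (t1={t1}, t2={t2})"
        )
    return t1, t2


def compute_cutpoints(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    weights: Sequence[float] | None = None,
) -> CutpointSet:
    """Sex-specific tertile cutpoints for every tertile-scored component.

    ``weights`` (aligned with ``cohort``) switches to survey-weighted
    quantiles; the default is unweighted.
    """
    schema = schema or load_default_schema()
    w = None if weights is None else np.asarray(weights, dtype=float)
    entries: dict[tuple[str, Sex], tuple[float, float]] = {}
    for sex in SEXES:
        mask = (cohort["sex"] == sex).to_numpy()
        if not mask.any():
            raise SchemaError(f"cohort has no {sex} participants")
        for comp in schema:
            if comp.rule != "sex_tertile":
                continue
            if comp.name not in cohort.columns:
                raise SchemaError(f"cohort is missing component column {comp.name!r}")
            vals = cohort.loc[mask, comp.name].to_numpy(dtype=float)
            entries[(comp.name, sex)] = compute_tertiles(
                vals, None if w is None else w[mask]
            )
    return CutpointSet(entries=entries, provenance="computed_from_data")


# ---------------------------------------------------------------------------
# point assignment
# ---------------------------------------------------------------------------

_POINTS_BY_GROUP = {"antioxidant": (0, 1, 2), "prooxidant": (2, 1, 0)}


def assign_component_points(
    value: float,
    sex: Sex,
    spec: ComponentSpec,
    cutpoints: CutpointSet | None = None,
    alcohol_rule: AlcoholRule | None = None,
) -> int:
    """Points (0, 1 or 2) for one component value."""
    if sex not in SEXES:
        raise SchemaError(f"sex must be 'male' or 'female', got {sex!r}")
    if spec.rule == "fixed_alcohol":
        rule = alcohol_rule or AlcoholRule()
        return rule.points(float(value), sex)
    if value < 0:
        raise SchemaError(f"{spec.name} value must be >= 0, got {value}")
    if spec.name == "bmi" and value == 0:
        raise SchemaError("bmi must be strictly positive")
    if cutpoints is None:
        cutpoints = load_default_cutpoints()
    t1, t2 = cutpoints.lookup(spec.name, sex)
    group = 0 if value < t1 else (1 if value < t2 else 2)
    return _POINTS_BY_GROUP[spec.polarity][group]


def _component_points_vector(
    values: np.ndarray,
    sex_mask_by_sex: dict[Sex, np.ndarray],
    spec: ComponentSpec,
    cutpoints: CutpointSet,
    alcohol_rule: AlcoholRule,
) -> np.ndarray:
    pts = np.full(values.shape, np.nan)
    for sex, mask in sex_mask_by_sex.items():
        v = values[mask]
        if spec.rule == "fixed_alcohol":
            thr = alcohol_rule.threshold(sex)
            p = np.where(v == 0, 2, np.where(v >= thr, 0, 1))
        else:
            t1, t2 = cutpoints.lookup(spec.name, sex)
            group = np.where(v < t1, 0, np.where(v < t2, 1, 2))
            lo, mid, hi = _POINTS_BY_GROUP[spec.polarity]
            p = np.choose(group, [lo, mid, hi])
        pts[mask] = np.where(np.isnan(v), np.nan, p)
    return pts


def compute_obs(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    cutpoints: CutpointSet | None = None,
) -> pd.DataFrame:
    """Per-participant component points and total/dietary/lifestyle scores.

    Returns a frame aligned with ``cohort`` holding one ``pts_<component>``
    column per schema component plus ``obs_total``, ``obs_dietary`` and
    ``obs_lifestyle``.  The dietary score excludes exactly the four
    lifestyle variables (physical activity, alcohol, BMI, cotinine); by
    construction ``obs_total = obs_dietary + obs_lifestyle``.
    """
    schema = schema or load_default_schema()
    cutpoints = cutpoints or load_default_cutpoints()
    missing = [c.name for c in schema if c.name not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing component columns: {missing}")
    sex_masks = {
        sex: (cohort["sex"] == sex).to_numpy() for sex in SEXES
    }
    unknown = ~(sex_masks["male"] | sex_masks["female"])
    if unknown.any():
        raise SchemaError("cohort contains sex values other than male/female")

    out = pd.DataFrame(index=cohort.index)
    for comp in schema:
        out[f"pts_{comp.name}"] = _component_points_vector(
            cohort[comp.name].to_numpy(dtype=float),
            sex_masks,
            comp,
            cutpoints,
            schema.alcohol_rule,
        )
    dietary_cols = [f"pts_{c.name}" for c in schema.dietary]
    lifestyle_cols = [f"pts_{c.name}" for c in schema.lifestyle]
    out["obs_dietary"] = out[dietary_cols].sum(axis=1, min_count=len(dietary_cols))
    if lifestyle_cols:
        out["obs_lifestyle"] = out[lifestyle_cols].sum(
            axis=1, min_count=len(lifestyle_cols)
        )
    else:
        out["obs_lifestyle"] = 0.0
    out["obs_total"] = out["obs_dietary"] + out["obs_lifestyle"]
    if not out.isna().any().any():
        out = out.astype(int)
    return out


def assign_quartiles(
    obs: Sequence[float],
    sex: Sequence[str],
    weights: Sequence[float] | None = None,
) -> pd.Series:
    """Sex-specific OBS quartile labels Q1..Q4 (Q1 = lowest OBS).

    Cuts use the package quantile convention at p = 0.25, 0.5, 0.75 within
    each sex; boundary ties go to the upper group.  Requires ≥ 4 distinct
    OBS values per sex.
    """
    obs = pd.Series(np.asarray(obs, dtype=float))
    sex = pd.Series(np.asarray(sex, dtype=object), index=obs.index)
    w = None if weights is None else np.asarray(weights, dtype=float)
    labels = pd.Series(index=obs.index, dtype=object)
    for s in pd.unique(sex):
        mask = (sex == s).to_numpy()
        vals = obs[mask].to_numpy()
        if np.unique(vals).size < 4:
            raise DegenerateDistributionError(
                f"need at least 4 distinct OBS values for sex {s!r}"
            )
        c1, c2, c3 = _cuts(vals, (0.25, 0.5, 0.75), None if w is None else w[mask])
        if not c1 < c2 < c3:
            raise DegenerateDistributionError(
                f"degenerate quartile boundaries for sex {s!r}: {(c1, c2, c3)}"
            )
        q = np.where(vals < c1, "Q1", np.where(vals < c2, "Q2",
                     np.where(vals < c3, "Q3", "Q4")))
        labels.loc[mask] = q
    return pd.Series(
        pd.Categorical(labels, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True),
        index=obs.index,
        name="obs_quartile",
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class OBSScorer(BaseEstimator, TransformerMixin):
    """Transformer that scores a cohort table into OBS results.

    Parameters
    ----------
    schema : OBSSchema, optional
        Component scheme; defaults to the packaged 20-component scheme.
    cutpoints : CutpointSet, optional
        Tertile boundaries; defaults to the packaged table unless
        ``recompute_cutpoints`` is set.
    recompute_cutpoints : bool
        If True, ``fit`` recomputes sex-specific tertiles from the training
        cohort (unweighted unless ``weighted``).
    weighted : bool
        Use the cohort's ``weight`` column when recomputing cutpoints.
    add_quartiles : bool
        If True, ``transform`` appends sex-specific OBS quartile labels.

    Attributes
    ----------
    schema_ : OBSSchema
    cutpoints_ : CutpointSet
    """

    def __init__(
        self,
        schema: OBSSchema | None = None,
        cutpoints: CutpointSet | None = None,
        recompute_cutpoints: bool = False,
        weighted: bool = False,
        add_quartiles: bool = False,
    ):
        self.schema = schema
        self.cutpoints = cutpoints
        self.recompute_cutpoints = recompute_cutpoints
        self.weighted = weighted
        self.add_quartiles = add_quartiles

    def fit(self, X: pd.DataFrame, y=None) -> "OBSScorer":
        self.schema_ = self.schema or load_default_schema()
        if self.recompute_cutpoints:
            w = X["weight"].to_numpy() if self.weighted else None
            self.cutpoints_ = compute_cutpoints(X, self.schema_, weights=w)
        else:
            self.cutpoints_ = self.cutpoints or load_default_cutpoints()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            raise RuntimeError("OBSScorer must be fitted before transform")
        scores = compute_obs(X, self.schema_, self.cutpoints_)
        if self.add_quartiles:
            scores["obs_quartile"] = assign_quartiles(
                scores["obs_total"].to_numpy(), X["sex"].to_numpy()
            ).to_numpy()
        return scores
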