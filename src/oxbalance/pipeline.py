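"""End-to-end OBS → telomere analysis orchestration.

Runs the full study on an analytic cohort table: exclusions, OBS scoring,
sex-stratified survey-weighted regression of log T/S on the OBS under four
nested covariate models, quartile contrasts with p-for-trend, dietary and
lifestyle sub-score models, leave-one-component-out sensitivity, and
publication-style report tables.

Covariate models (strictly nested):

1. crude (exposure only)
2. \\+ age, ethnicity, education, poverty-income ratio (PIR)
3. \\+ dietary energy intake
4. \\+ C-reactive protein (CRP)

Age, energy and CRP enter as continuous terms; ethnicity (5 levels,
reference non-Hispanic white), education (5 ordered levels) and PIR
(3 levels) as dummy-coded categories.  The outcome is the natural log of
the telomere T/S ratio.  Sexes are analysed by separate model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import AttritionLog, apply_exclusions
from .schema import (
    CutpointSet,
    OBSSchema,
    SchemaError,
    load_default_cutpoints,
    load_default_schema,
)
from .scoring import assign_quartiles, compute_cutpoints, compute_obs
from .survey import (
    RegressionResult,
    SurveyDesign,
    SurveyLinearRegression,
    trend_test,
    weighted_descriptives,
)

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "build_design_matrix",
    "run_primary_analysis",
    "run_subscore_analysis",
    "run_sensitivity",
    "make_reports",
    "run_full_study",
    "StudyResult",
    "ETHNICITY_LEVELS",
    "EDUCATION_LEVELS",
    "PIR_LEVELS",
]

ETHNICITY_LEVELS = (
    "non_hispanic_white",
    "non_hispanic_black",
    "mexican_american",
    "other_race",
    "other_hispanic",
)
EDUCATION_LEVELS = (
    "less_than_9th",
    "9_11th_grade",
    "high_school_or_ged",
    "some_college",
    "college_graduate",
)
PIR_LEVELS = ("le_1.3", "1.3_to_3.5", "gt_3.5")

_CATEGORY_LEVELS = {
    "ethnicity": ETHNICITY_LEVELS,
    "education": EDUCATION_LEVELS,
    "pir": PIR_LEVELS,
}
_CONTINUOUS = ("age", "energy", "crp")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four nested covariate models."""

    model_id: int
    covariates: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"model{self.model_id}"


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, ()),
    2: ModelSpec(2, ("age", "ethnicity", "education", "pir")),
    3: ModelSpec(3, ("age", "ethnicity", "education", "pir", "energy")),
    4: ModelSpec(4, ("age", "ethnicity", "education", "pir", "energy", "crp")),
}


def build_design_matrix(
    cohort: pd.DataFrame, covariates: tuple[str, ...]
) -> pd.DataFrame:
    """Covariate design-matrix columns (no intercept, no exposure).

    Continuous covariates pass through; categorical ones are dummy coded
    against their first (reference) level.  Unknown category values raise.
    """
    cols: dict[str, np.ndarray] = {}
    for name in covariates:
        if name in _CONTINUOUS:
            cols[name] = cohort[name].to_numpy(dtype=float)
        elif name in _CATEGORY_LEVELS:
            levels = _CATEGORY_LEVELS[name]
            cat = pd.Categorical(cohort[name], categories=levels)
            if (cat.codes < 0).any():
                bad = sorted(set(cohort[name]) - set(levels))
                raise SchemaError(f"unknown {name} categories: {bad}")
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (cat == lev).astype(float)
        else:
            raise SchemaError(f"unknown covariate {name!r}")
    return pd.DataFrame(cols, index=cohort.index)


def _fit_continuous(
    sub: pd.DataFrame,
    exposure: pd.Series,
    exposure_name: str,
    spec: ModelSpec,
    design: SurveyDesign,
) -> RegressionResult:
    X = pd.DataFrame({"const": np.ones(len(sub)), exposure_name: exposure.to_numpy()},
                     index=sub.index)
    X = pd.concat([X, build_design_matrix(sub, spec.covariates)], axis=1)
    est = SurveyLinearRegression().fit(X, np.log(sub["ltl"].to_numpy()), design=design)
    return est.result_for(exposure_name, model=spec.label)


def _result_rows(res: RegressionResult, sex: str, exposure: str, term: str) -> dict:
    d = res.to_dict()
    d.update({"sex": sex, "exposure": exposure, "term": term})
    return d


def run_primary_analysis(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    cutpoints: CutpointSet | None = None,
    models: tuple[int, ...] = (1, 2, 3, 4),
    trend_coding: str = "ordinal",
) -> pd.DataFrame:
    """Sex-stratified association of the total OBS with log T/S.

    For each sex and model: the continuous-OBS term, the Q2–Q4 contrasts
    against the lowest quartile, and the p-for-trend term.  Returns a tidy
    frame (sex, model, exposure, term, beta, se, ci_low, ci_high, t, p, df).
    """
    schema = schema or load_default_schema()
    scores = compute_obs(cohort, schema, cutpoints)
    rows: list[dict] = []
    for sex in ("male", "female"):
        mask = (cohort["sex"] == sex).to_numpy()
        if not mask.any():
            raise SchemaError(f"cohort has no {sex} participants")
        sub = cohort.loc[mask]
        obs = scores.loc[mask, "obs_total"].astype(float)
        quart = assign_quartiles(obs.to_numpy(), sub["sex"].to_numpy())
        design = SurveyDesign.from_frame(sub)
        y = np.log(sub["ltl"].to_numpy())
        for m in models:
            spec = MODEL_SPECS[m]
            res = _fit_continuous(sub, obs, "obs", spec, design)
            rows.append(_result_rows(res, sex, "obs_total", "continuous"))

            cov = build_design_matrix(sub, spec.covariates)
            X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
            qcat = pd.Categorical(
                quart.to_numpy(), categories=["Q1", "Q2", "Q3", "Q4"], ordered=True
            )
            for lev in ("Q2", "Q3", "Q4"):
                X[lev] = (qcat == lev).astype(float)
            X = pd.concat([X, cov], axis=1)
            est = SurveyLinearRegression().fit(X, y, design=design)
            for lev in ("Q2", "Q3", "Q4"):
                rows.append(
                    _result_rows(est.result_for(lev, model=spec.label),
                                 sex, "obs_total", lev)
                )
            tre = trend_test(
                y, quart.to_numpy(), cov, design,
                coding=trend_coding, exposure=obs.to_numpy(), model=spec.label,
            )
            rows.append(_result_rows(tre, sex, "obs_total", "trend"))
    return pd.DataFrame(rows)


def run_subscore_analysis(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    cutpoints: CutpointSet | None = None,
    models: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Continuous dietary-OBS and lifestyle-OBS models, by sex."""
    schema = schema or load_default_schema()
    scores = compute_obs(cohort, schema, cutpoints)
    rows: list[dict] = []
    for sex in ("male", "female"):
        mask = (cohort["sex"] == sex).to_numpy()
        sub = cohort.loc[mask]
        design = SurveyDesign.from_frame(sub)
        for score_col in ("obs_dietary", "obs_lifestyle"):
            exposure = scores.loc[mask, score_col].astype(float)
            for m in models:
                spec = MODEL_SPECS[m]
                res = _fit_continuous(sub, exposure, "obs", spec, design)
                rows.append(_result_rows(res, sex, score_col, "continuous"))
    return pd.DataFrame(rows)


def run_sensitivity(
    cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    cutpoints: CutpointSet | None = None,
    model: int = 4,
) -> pd.DataFrame:
    """Leave-one-component-out sensitivity of the continuous-OBS estimate.

    Each schema component is removed in turn, the reduced score is
    recomputed by summing the remaining 19 components (range 0–38; no
    renormalization), and the chosen model is refit per sex.
    """
    schema = schema or load_default_schema()
    spec = MODEL_SPECS[model]
    rows: list[dict] = []
    for name in schema.names:
        reduced = schema.drop(name)
        scores = compute_obs(cohort, reduced, cutpoints)
        for sex in ("male", "female"):
            mask = (cohort["sex"] == sex).to_numpy()
            sub = cohort.loc[mask]
            design = SurveyDesign.from_frame(sub)
            res = _fit_continuous(
                sub, scores.loc[mask, "obs_total"].astype(float), "obs", spec, design
            )
            d = res.to_dict()
            d.update({"sex": sex, "removed_component": name})
            rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def format_beta_ci(beta: float, lo: float, hi: float) -> str:
    """Four-decimal beta with its 95% CI, e.g. ``0.0701 (0.0205–0.1197)``."""
    return f"{beta:.4f} ({lo:.4f}–{hi:.4f})"


def _format_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def baseline_table(
    cohort: pd.DataFrame, quartiles: pd.Series
) -> pd.DataFrame:
    """Weighted baseline characteristics by OBS quartile for one sex.

    Continuous variables show weighted mean ± SD (or median (P25, P75) for
    the skewed CRP and T/S ratio); categorical variables show unweighted
    counts with weighted percentages.  No inferential p-values are
    computed.  Empty quartile cells render with explicit zero counts.
    """
    groups: dict[str, pd.DataFrame] = {"Total": cohort}
    for q in ("Q1", "Q2", "Q3", "Q4"):
        groups[q] = cohort.loc[(quartiles == q).to_numpy()]

    rows: dict[str, dict[str, str]] = {}

    def put(row: str, col: str, text: str) -> None:
        rows.setdefault(row, {})[col] = text

    for col, sub in groups.items():
        if len(sub) == 0:
            put("n", col, "0")
            continue
        design = SurveyDesign.from_frame(sub)
        put("n", col, str(len(sub)))
        d = weighted_descriptives(sub["age"], design, "mean_sd")
        put("Age (year)", col, f"{d['mean']:.1f} ± {d['sd']:.1f}")
        for var, levels, title in (
            ("ethnicity", ETHNICITY_LEVELS, "Race/ethnicity"),
            ("education", EDUCATION_LEVELS, "Education"),
            ("pir", PIR_LEVELS, "Family PIR"),
        ):
            cat = weighted_descriptives(sub[var], design, "category_pct")
            for lev in levels:
                stats = cat.get(lev, {"n": 0, "pct": 0.0})
                put(f"{title}: {lev}", col, f"{stats['n']} ({stats['pct']:.2f})")
        d = weighted_descriptives(sub["energy"], design, "mean_sd")
        put("Energy (kcal)", col, f"{d['mean']:.0f} ± {d['sd']:.0f}")
        d = weighted_descriptives(sub["crp"], design, "median_iqr")
        put("CRP (mg/dL)", col, f"{d['median']:.2f} ({d['p25']:.2f}, {d['p75']:.2f})")
        d = weighted_descriptives(sub["ltl"], design, "median_iqr")
        put("Telomere (T/S ratio)", col,
            f"{d['median']:.2f} ({d['p25']:.2f}, {d['p75']:.2f})")
        d = weighted_descriptives(np.log(sub["ltl"]), design, "mean_sd")
        put("Log-transformed telomere", col, f"{d['mean']:.2f} ± {d['sd']:.2f}")

    for row in rows.values():
        for col in groups:
            row.setdefault(col, "0" if row is rows.get("n") else "—")
    table = pd.DataFrame(rows).T
    table.index.name = "characteristic"
    return table[list(groups)]


def association_table(primary: pd.DataFrame) -> pd.DataFrame:
    """Quartile/trend/continuous beta table (one row per sex × model)."""
    rows = []
    for sex in ("male", "female"):
        for model in sorted(primary["model"].unique()):
            sel = primary[(primary["sex"] == sex) & (primary["model"] == model)]
            row: dict[str, str] = {"sex": sex, "model": model, "Q1": "Ref"}
            for lev in ("Q2", "Q3", "Q4"):
                r = sel[sel["term"] == lev].iloc[0]
                row[lev] = format_beta_ci(r["beta"], r["ci_low"], r["ci_high"])
            r = sel[sel["term"] == "trend"].iloc[0]
            row["p_trend"] = _format_p(r["p"])
            r = sel[sel["term"] == "continuous"].iloc[0]
            row["continuous"] = format_beta_ci(r["beta"], r["ci_low"], r["ci_high"])
            rows.append(row)
    return pd.DataFrame(rows)


def subscore_table(subscore: pd.DataFrame) -> pd.DataFrame:
    """Dietary/lifestyle sub-score beta table (male and female columns)."""
    rows = []
    for exposure in ("obs_dietary", "obs_lifestyle"):
        for model in sorted(subscore["model"].unique()):
            row = {"exposure": exposure, "model": model}
            for sex in ("male", "female"):
                sel = subscore[
                    (subscore["sex"] == sex)
                    & (subscore["model"] == model)
                    & (subscore["exposure"] == exposure)
                ].iloc[0]
                row[sex] = format_beta_ci(
                    sel["beta"], sel["ci_low"], sel["ci_high"]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_table(sensitivity: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name in sensitivity["removed_component"].unique():
        row = {"removed_component": name}
        for sex in ("male", "female"):
            sel = sensitivity[
                (sensitivity["sex"] == sex)
                & (sensitivity["removed_component"] == name)
            ].iloc[0]
            row[sex] = format_beta_ci(sel["beta"], sel["ci_low"], sel["ci_high"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Bundle of everything the full pipeline produces."""

    cohort: pd.DataFrame
    attrition: AttritionLog
    scores: pd.DataFrame
    quartiles: pd.Series
    cutpoints: CutpointSet
    primary: pd.DataFrame
    subscore: pd.DataFrame
    sensitivity: pd.DataFrame
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)


def make_reports(result: StudyResult) -> dict[str, pd.DataFrame]:
    """Publication-style tables from a completed study run."""
    reports: dict[str, pd.DataFrame] = {
        "attrition": result.attrition.to_frame(),
        "association": association_table(result.primary),
        "subscores": subscore_table(result.subscore),
        "sensitivity": sensitivity_table(result.sensitivity),
    }
    for sex in ("male", "female"):
        mask = (result.cohort["sex"] == sex).to_numpy()
        reports[f"baseline_{sex}"] = baseline_table(
            result.cohort.loc[mask], result.quartiles.loc[mask]
        )
    return reports


def write_reports(reports: dict[str, pd.DataFrame], outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in reports.items():
        table.to_csv(out / f"{name}.tsv", sep="\t",
                     index=table.index.name is not None)


def run_full_study(
    raw_cohort: pd.DataFrame,
    schema: OBSSchema | None = None,
    cutpoints: CutpointSet | None = None,
    recompute_cutpoints: bool = False,
    models: tuple[int, ...] = (1, 2, 3, 4),
    sensitivity_model: int = 4,
) -> StudyResult:
    """Exclusions → scoring → all analyses → report tables.

    ``recompute_cutpoints=True`` derives sex-specific tertiles from the
    filtered cohort (the right choice for synthetic or non-NHANES data);
    otherwise the packaged boundaries are used.
    """
    schema = schema or load_default_schema()
    cohort, attrition = apply_exclusions(raw_cohort, schema)
    if recompute_cutpoints:
        cutpoints = compute_cutpoints(cohort, schema)
    scores = compute_obs(cohort, schema, cutpoints)
    quartiles = assign_quartiles(
        scores["obs_total"].to_numpy(), cohort["sex"].to_numpy()
    )
    quartiles.index = cohort.index
    result = StudyResult(
        cohort=cohort,
        attrition=attrition,
        scores=scores,
        quartiles=quartiles,
        cutpoints=cutpoints or load_default_cutpoints(),
        primary=run_primary_analysis(cohort, schema, cutpoints, models),
        subscore=run_subscore_analysis(cohort, schema, cutpoints, models),
        sensitivity=run_sensitivity(cohort, schema, cutpoints, sensitivity_model),
    )
    result.reports = make_reports(result)
    return result
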