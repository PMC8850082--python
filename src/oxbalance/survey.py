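"""Design-based estimation for stratified multistage survey samples.

Point estimates are weighted least squares with the analysis weights;
variances come from Taylor (series) linearization over the between-PSU
variability of weighted score totals, the estimator implemented by SAS
``PROC SURVEYREG`` and the R ``survey`` package for "with replacement"
first-stage sampling.  For stratum ``h`` with ``n_h`` PSUs and per-PSU
score totals ``z_hj = Σ_{i∈PSU hj} w_i x_i e_i``,

    G = Σ_h n_h/(n_h − 1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)'
    V(β̂) = (X'WX)⁻¹ G (X'WX)⁻¹

with design degrees of freedom ``#PSUs − #strata`` driving t-based
confidence intervals and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .scoring import weighted_quantile_cut

__all__ = [
    "SurveyDesign",
    "RegressionResult",
    "LonelyPSUError",
    "CollinearityError",
    "weighted_descriptives",
    "survey_linear_regression",
    "trend_test",
    "SurveyLinearRegression",
]


class LonelyPSUError(ValueError):
    """A stratum contains a single PSU: between-PSU variance is undefined."""


class CollinearityError(ValueError):
    """The weighted cross-product matrix X'WX is singular."""


@dataclass
class SurveyDesign:
    """Per-observation survey design variables.

    ``psu`` ids are interpreted nested within ``strata`` (the same PSU label
    in two strata denotes two distinct PSUs).  Weights must be positive and
    finite.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray

    def __init__(self, strata, psu, weights):
        self.strata = np.asarray(strata)
        self.psu = np.asarray(psu)
        self.weights = np.asarray(weights, dtype=float)
        if not (len(self.strata) == len(self.psu) == len(self.weights)):
            raise ValueError("strata, psu and weights must have equal length")
        if (self.weights <= 0).any() or not np.isfinite(self.weights).all():
            raise ValueError("weights must be strictly positive and finite")

    def __len__(self) -> int:
        return len(self.weights)

    def subset(self, mask) -> "SurveyDesign":
        mask = np.asarray(mask)
        return SurveyDesign(self.strata[mask], self.psu[mask], self.weights[mask])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(
            df["stratum"].to_numpy(), df["psu"].to_numpy(), df["weight"].to_numpy()
        )

    def _groups(self):
        """Integer codes for strata and (stratum, psu) pairs.

        Returns (stratum codes per obs, PSU codes per obs, #strata, #PSUs,
        stratum code of each PSU, stratum labels).
        """
        s_codes, s_uniques = pd.factorize(self.strata)
        p_codes, _ = pd.factorize(self.psu)
        m = int(p_codes.max()) + 1
        key = s_codes.astype(np.int64) * m + p_codes
        uniq, pair_codes = np.unique(key, return_inverse=True)
        psu_stratum = (uniq // m).astype(int)
        return s_codes, pair_codes, len(s_uniques), len(uniq), psu_stratum, s_uniques

    @property
    def n_strata(self) -> int:
        return self._groups()[2]

    @property
    def n_psus(self) -> int:
        return self._groups()[3]

    @property
    def df(self) -> int:
        """Design degrees of freedom: #PSUs − #strata."""
        return self.n_psus - self.n_strata


@dataclass
class RegressionResult:
    """Design-based inference for one model term."""

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: int
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t": self.t,
            "p": self.p,
            "df": self.df,
            "model": self.model,
        }


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def weighted_descriptives(
    values: Sequence,
    design: SurveyDesign,
    kind: Literal["mean_sd", "median_iqr", "category_pct"] = "mean_sd",
) -> dict:
    """Survey-weighted summary of one variable.

    ``mean_sd`` returns the weighted mean and the weighted SD (population
    form, denominator Σw).  ``median_iqr`` returns the weighted median and
    quartiles using the package quantile convention.  ``category_pct``
    returns unweighted counts plus weighted percentages (summing to 100).
    """
    w = design.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    if kind == "category_pct":
        s = pd.Series(np.asarray(values, dtype=object))
        out = {}
        for level in pd.unique(s):
            mask = (s == level).to_numpy()
            out[level] = {
                "n": int(mask.sum()),
                "pct": float(100.0 * w[mask].sum() / total),
            }
        return out
    v = np.asarray(values, dtype=float)
    if kind == "mean_sd":
        mean = float(np.sum(w * v) / total)
        var = float(np.sum(w * (v - mean) ** 2) / total)
        return {"mean": mean, "sd": float(np.sqrt(var)), "n": int(v.size)}
    if kind == "median_iqr":
        return {
            "median": weighted_quantile_cut(v, 0.5, w),
            "p25": weighted_quantile_cut(v, 0.25, w),
            "p75": weighted_quantile_cut(v, 0.75, w),
            "n": int(v.size),
        }
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def _linearized_cov(
    X: np.ndarray, resid: np.ndarray, design: SurveyDesign, lonely_psu: str
) -> tuple[np.ndarray, int]:
    """Taylor-linearization covariance of the WLS estimator and design df."""
    w = design.weights
    A = X.T @ (w[:, None] * X)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise CollinearityError(
            f"weighted cross-product matrix is singular (condition {cond:.3g})"
        )
    z = (w * resid)[:, None] * X  # per-observation weighted score contributions

    s_codes, pair_codes, n_strata, n_psus, psu_stratum, s_labels = design._groups()
    p = X.shape[1]
    # per-PSU score totals
    z_psu = np.zeros((n_psus, p))
    np.add.at(z_psu, pair_codes, z)

    grand_mean = z_psu.mean(axis=0)
    G = np.zeros((p, p))
    for h in range(n_strata):
        members = np.flatnonzero(psu_stratum == h)
        n_h = members.size
        if n_h < 2:
            if lonely_psu == "error":
                raise LonelyPSUError(
                    f"stratum {s_labels[h]!r} has a single PSU; variance is undefined "
                    "(use lonely_psu='adjust' to centre at the grand mean)"
                )
            d = z_psu[members[0]] - grand_mean
            G += np.outer(d, d)
            continue
        zh = z_psu[members]
        d = zh - zh.mean(axis=0)
        G += (n_h / (n_h - 1)) * (d.T @ d)
    Ainv = np.linalg.inv(A)
    V = Ainv @ G @ Ainv
    return V, n_psus - n_strata


def survey_linear_regression(
    y: Sequence[float],
    X: pd.DataFrame,
    design: SurveyDesign,
    model: str = "",
    lonely_psu: Literal["error", "adjust"] = "error",
) -> list[RegressionResult]:
    """Fit a survey-weighted linear model; one result per column of X.

    ``X`` is the full design matrix including the intercept column.
    """
    est = SurveyLinearRegression(lonely_psu=lonely_psu).fit(X, y, design=design)
    return est.results_table(model=model)


class SurveyLinearRegression(BaseEstimator, RegressorMixin):
    """Survey-weighted linear regression with linearization variance.

    Point estimates come from weighted least squares
    (``statsmodels.api.WLS``); the covariance is the stratified
    between-PSU Taylor linearization described in the module docstring,
    with t-based intervals on ``#PSUs − #strata`` degrees of freedom.

    Parameters
    ----------
    lonely_psu : {"error", "adjust"}
        Single-PSU strata raise :class:`LonelyPSUError` by default;
        ``"adjust"`` centres their score total at the grand mean across all
        PSUs (a conservative fallback).

    Attributes
    ----------
    coef_ : pandas.Series           term → β̂
    cov_ : pandas.DataFrame         linearized covariance of β̂
    bse_ : pandas.Series            design-based standard errors
    tvalues_, pvalues_ : pandas.Series
    conf_int_ : pandas.DataFrame    t-based 95% limits (columns low, high)
    df_ : int                       design degrees of freedom
    """

    def __init__(self, lonely_psu: Literal["error", "adjust"] = "error"):
        self.lonely_psu = lonely_psu

    def fit(
        self,
        X: pd.DataFrame,
        y: Sequence[float],
        design: SurveyDesign | None = None,
    ) -> "SurveyLinearRegression":
        if design is None:
            raise ValueError("a SurveyDesign is required to fit")
        Xdf = pd.DataFrame(X)
        terms = [str(c) for c in Xdf.columns]
        Xa = Xdf.to_numpy(dtype=float)
        ya = np.asarray(y, dtype=float)
        if len(ya) != len(Xa) or len(ya) != len(design):
            raise ValueError("X, y and design must have equal length")

        wls = sm.WLS(ya, Xa, weights=design.weights).fit()
        beta = wls.params
        resid = ya - Xa @ beta
        V, df = _linearized_cov(Xa, resid, design, self.lonely_psu)

        se = np.sqrt(np.diag(V))
        tval = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        pval = 2 * stats.t.sf(np.abs(tval), df)
        tcrit = stats.t.ppf(0.975, df)

        self.terms_ = terms
        self.coef_ = pd.Series(beta, index=terms)
        self.cov_ = pd.DataFrame(V, index=terms, columns=terms)
        self.bse_ = pd.Series(se, index=terms)
        self.tvalues_ = pd.Series(tval, index=terms)
        self.pvalues_ = pd.Series(pval, index=terms)
        self.conf_int_ = pd.DataFrame(
            {"low": beta - tcrit * se, "high": beta + tcrit * se}, index=terms
        )
        self.df_ = int(df)
        self.n_strata_ = design.n_strata
        self.n_psus_ = design.n_psus
        return self

    def predict(self, X) -> np.ndarray:
        return pd.DataFrame(X).to_numpy(dtype=float) @ self.coef_.to_numpy()

    def result_for(self, term: str, model: str = "") -> RegressionResult:
        return RegressionResult(
            term=term,
            beta=float(self.coef_[term]),
            se=float(self.bse_[term]),
            ci_low=float(self.conf_int_.loc[term, "low"]),
            ci_high=float(self.conf_int_.loc[term, "high"]),
            t=float(self.tvalues_[term]),
            p=float(self.pvalues_[term]),
            df=self.df_,
            model=model,
        )

    def results_table(self, model: str = "") -> list[RegressionResult]:
        return [self.result_for(t, model=model) for t in self.terms_]


def trend_test(
    y: Sequence[float],
    quartiles: Sequence,
    covariates: pd.DataFrame | None,
    design: SurveyDesign,
    coding: Literal["ordinal", "median"] = "ordinal",
    exposure: Sequence[float] | None = None,
    model: str = "",
) -> RegressionResult:
    """P-for-trend across ordered exposure quartiles.

    The quartile label is entered as a single continuous term in the
    adjusted model: its ordinal index 1–4 by default, or the per-quartile
    median of ``exposure`` with ``coding="median"``.
    """
    q = pd.Categorical(quartiles, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True)
    if (q.codes < 0).any():
        raise ValueError("quartile labels must be Q1..Q4")
    if coding == "ordinal":
        score = q.codes.astype(float) + 1.0
    elif coding == "median":
        if exposure is None:
            raise ValueError("median coding requires the underlying exposure values")
        exposure = np.asarray(exposure, dtype=float)
        med = {
            lev: weighted_quantile_cut(
                exposure[q.codes == i], 0.5, design.weights[q.codes == i]
            )
            for i, lev in enumerate(q.categories)
        }
        score = np.array([med[lev] for lev in np.asarray(q)])
    else:
        raise ValueError(f"unknown coding {coding!r}")

    X = pd.DataFrame({"const": np.ones(len(score)), "trend": score})
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    est = SurveyLinearRegression().fit(X, y, design=design)
    return est.result_for("trend", model=model)
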