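import numpy as np
import pandas as pd
import pytest

import oxbalance as ox
from oxbalance.survey import (
    CollinearityError,
    LonelyPSUError,
    SurveyDesign,
    SurveyLinearRegression,
    trend_test,
    weighted_descriptives,
)


def oracle_linearized_cov(X, y, w, strata, psu):
    """Brute-force Taylor-linearization covariance, written as explicit
    loops, independently of the vectorized implementation."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n, p = X.shape

    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(n):
        A += w[i] * np.outer(X[i], X[i])
        b += w[i] * y[i] * X[i]
    beta = np.linalg.solve(A, b)

    z = {}
    for i in range(n):
        e = y[i] - X[i] @ beta
        key = (strata[i], psu[i])
        z[key] = z.get(key, np.zeros(p)) + w[i] * X[i] * e

    G = np.zeros((p, p))
    for h in sorted({s for s, _ in z}):
        zs = [z[k] for k in z if k[0] == h]
        n_h = len(zs)
        zbar = sum(zs) / n_h
        for zj in zs:
            G += (n_h / (n_h - 1)) * np.outer(zj - zbar, zj - zbar)
    Ainv = np.linalg.inv(A)
    return beta, Ainv @ G @ Ainv


@pytest.fixture
def tiny_dataset():
    """Fixed n=12: 2 strata x 2 PSUs x 3 observations, fixed weights."""
    rng = np.random.default_rng(42)
    strata = np.repeat([0, 0, 1, 1], 3)
    psu = np.repeat([1, 2, 1, 2], 3)
    w = np.array([1.5, 2.0, 1.0, 3.0, 2.5, 1.0, 2.0, 2.0, 1.5, 1.0, 3.5, 2.0])
    x = rng.normal(size=12)
    y = 0.5 + 0.8 * x + rng.normal(scale=0.3, size=12)
    X = pd.DataFrame({"const": np.ones(12), "x": x})
    return X, y, SurveyDesign(strata, psu, w)


class TestLinearization:
    def test_matches_loop_oracle_to_1e10(self, tiny_dataset):
        X, y, design = tiny_dataset
        est = SurveyLinearRegression().fit(X, y, design=design)
        beta, V = oracle_linearized_cov(
            X.to_numpy(), y, design.weights, design.strata, design.psu
        )
        np.testing.assert_allclose(est.coef_.to_numpy(), beta, rtol=1e-10)
        np.testing.assert_allclose(est.cov_.to_numpy(), V, rtol=1e-10)
        assert est.df_ == 4 - 2

    def test_degenerate_design_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        design = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        est = SurveyLinearRegression().fit(X, y, design=design)
        Xa = X.to_numpy()
        closed_form = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        np.testing.assert_allclose(est.coef_.to_numpy(), closed_form, rtol=1e-12)

    def test_iid_design_matches_hc0_sandwich_up_to_small_sample_factor(self):
        # one stratum, each observation its own PSU: the linearization equals
        # n/(n-1) times the classic HC0 sandwich (score totals sum to zero)
        rng = np.random.default_rng(2)
        n = 40
        x = rng.normal(size=n)
        y = 0.3 - 1.2 * x + rng.normal(size=n) * (1 + x**2) ** 0.5
        X = np.column_stack([np.ones(n), x])
        design = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        est = SurveyLinearRegression().fit(
            pd.DataFrame(X, columns=["const", "x"]), y, design=design
        )
        beta = est.coef_.to_numpy()
        e = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = (X * (e**2)[:, None]).T @ X
        hc0 = bread @ meat @ bread
        np.testing.assert_allclose(
            est.cov_.to_numpy(), n / (n - 1) * hc0, rtol=1e-10
        )

    def test_halving_weights_of_duplicated_rows_keeps_estimates(self, tiny_dataset):
        X, y, design = tiny_dataset
        est1 = SurveyLinearRegression().fit(X, y, design=design)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.r_[y, y]
        design2 = SurveyDesign(
            np.r_[design.strata, design.strata],
            np.r_[design.psu, design.psu],
            np.r_[design.weights, design.weights] / 2,
        )
        est2 = SurveyLinearRegression().fit(X2, y2, design=design2)
        np.testing.assert_allclose(
            est1.coef_.to_numpy(), est2.coef_.to_numpy(), rtol=1e-12
        )

    def test_invariant_to_relabeling(self, tiny_dataset):
        X, y, design = tiny_dataset
        est1 = SurveyLinearRegression().fit(X, y, design=design)
        relabeled = SurveyDesign(
            np.array([f"str-{s}" for s in design.strata]),
            np.array([f"psu-{p}" for p in design.psu]),
            design.weights,
        )
        est2 = SurveyLinearRegression().fit(X, y, design=relabeled)
        np.testing.assert_allclose(est1.cov_.to_numpy(), est2.cov_.to_numpy())
        assert est1.df_ == est2.df_

    def test_ci_geometry(self, tiny_dataset):
        from scipy import stats

        X, y, design = tiny_dataset
        est = SurveyLinearRegression().fit(X, y, design=design)
        res = est.result_for("x")
        tcrit = stats.t.ppf(0.975, res.df)
        assert res.ci_high - res.beta == pytest.approx(tcrit * res.se)
        assert res.ci_low <= res.beta <= res.ci_high

    def test_lonely_psu_raises_by_default(self, tiny_dataset):
        X, y, design = tiny_dataset
        lonely = SurveyDesign(design.strata, np.where(design.strata == 1, 9, design.psu),
                              design.weights)
        with pytest.raises(LonelyPSUError):
            SurveyLinearRegression().fit(X, y, design=lonely)
        est = SurveyLinearRegression(lonely_psu="adjust").fit(X, y, design=lonely)
        assert np.isfinite(est.bse_).all()

    def test_collinear_design_raises(self, tiny_dataset):
        X, y, design = tiny_dataset
        X = X.assign(x2=2 * X["x"])
        with pytest.raises(CollinearityError):
            SurveyLinearRegression().fit(X, y, design=design)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            SurveyDesign([0, 0], [1, 2], [1.0, 0.0])


class TestWeightedDescriptives:
    def equal_design(self, n):
        return SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))

    def test_equal_weights_match_plain_statistics(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=101)
        d = weighted_descriptives(v, self.equal_design(101), "mean_sd")
        assert d["mean"] == pytest.approx(v.mean())
        assert d["sd"] == pytest.approx(v.std())
        m = weighted_descriptives(v, self.equal_design(101), "median_iqr")
        assert m["median"] == pytest.approx(np.sort(v)[50])

    def test_hand_computed_weighted_mean(self):
        design = SurveyDesign([0, 0, 0], [1, 2, 3], [1.0, 1.0, 2.0])
        d = weighted_descriptives([0.0, 0.0, 3.0], design, "mean_sd")
        assert d["mean"] == pytest.approx(1.5)

    def test_category_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["a", "b", "c"], size=60)
        design = SurveyDesign(np.zeros(60), np.arange(60), rng.uniform(0.5, 3, 60))
        d = weighted_descriptives(labels, design, "category_pct")
        assert sum(x["pct"] for x in d.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(x["n"] for x in d.values()) == 60

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            SurveyDesign([0], [1], [0.0])


class TestTrend:
    def planted(self, n=200, slope=0.2, seed=5):
        rng = np.random.default_rng(seed)
        q = np.array(["Q1", "Q2", "Q3", "Q4"])[rng.integers(0, 4, size=n)]
        idx = np.array([int(lbl[1]) for lbl in q], float)
        y = slope * idx + rng.normal(scale=0.01, size=n)
        design = SurveyDesign(np.repeat(np.arange(4), n // 4),
                              rng.integers(0, 2, size=n), np.ones(n))
        return y, q, design

    def test_planted_monotone_signal_detected(self):
        y, q, design = self.planted()
        res = trend_test(y, q, None, design)
        assert res.beta > 0
        assert res.p < 0.05

    def test_permuted_labels_destroy_significance(self):
        y, q, design = self.planted()
        rng = np.random.default_rng(6)
        res = trend_test(y, rng.permutation(q), None, design)
        assert res.p > 0.05

    def test_median_coding_uses_exposure_scale(self):
        y, q, design = self.planted()
        exposure = np.array([int(lbl[1]) * 10.0 for lbl in q])
        ordinal = trend_test(y, q, None, design, coding="ordinal")
        median = trend_test(y, q, None, design, coding="median",
                            exposure=exposure)
        # slope shrinks by the exposure scale; t statistic is unchanged
        assert median.beta == pytest.approx(ordinal.beta / 10.0, rel=1e-6)
        assert median.t == pytest.approx(ordinal.t, rel=1e-6)
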