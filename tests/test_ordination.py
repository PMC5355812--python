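"""DCA screening, PCA with scaling, regression and trend statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silutil import (
    dca_gradient_length,
    pca_with_scaling,
    regress_adjusted_r2,
    trend_test,
)


def _env_matrix(rng, n=20):
    """Positive environment-style matrix sharing one linear gradient."""
    util = 34 + rng.normal(0, 5, n)
    return pd.DataFrame(
        {
            "utilization": util,
            "f_curta": 10 + 0.5 * (util - 34) + rng.normal(0, 3, n),
            "d18o": 42 + 0.1 * (util - 34) + rng.normal(0, 0.5, n),
            "tsi": 1365.5 + rng.normal(0, 0.4, n),
        }
    )


class TestDCAScreen:
    def test_identical_rows_have_zero_gradient(self):
        df = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (5, 1)))
        screen = dca_gradient_length(df)
        assert screen.gradient_length_sd == 0.0
        assert screen.is_linear

    def test_linear_response_is_short(self):
        rng = np.random.default_rng(0)
        screen = dca_gradient_length(_env_matrix(rng), downweight=False)
        assert screen.gradient_length_sd < 1.5
        assert screen.is_linear

    def test_unimodal_turnover_is_long(self):
        # Gaussian response curves spanning the gradient: classic strong
        # species turnover, gradient length well above 2 SD
        rng = np.random.default_rng(1)
        grad = np.linspace(0, 100, 50)
        optima = np.linspace(0, 100, 20)
        Y = np.exp(-((grad[:, None] - optima[None, :]) ** 2) / (2 * 10.0**2)) * 20
        screen = dca_gradient_length(pd.DataFrame(rng.poisson(Y).astype(float)))
        assert screen.gradient_length_sd > 2.0
        assert not screen.is_linear

    def test_constant_column_dropped_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(2)
        df = _env_matrix(rng)
        df["flat"] = 3.0
        with caplog.at_level(logging.WARNING, logger="silutil"):
            screen = dca_gradient_length(df)
        assert "flat" in caplog.text
        assert screen.gradient_length_sd < 1.5

    def test_negative_columns_shifted_and_logged(self):
        rng = np.random.default_rng(3)
        df = _env_matrix(rng)
        df["anomaly"] = rng.normal(0, 1, len(df))  # spans negative values
        screen = dca_gradient_length(df)
        assert "anomaly" in screen.column_shifts
        assert screen.column_shifts["anomaly"] > 0

    def test_row_duplication_invariance(self):
        rng = np.random.default_rng(4)
        df = _env_matrix(rng, n=12)
        doubled = pd.concat([df, df], ignore_index=True)
        a = dca_gradient_length(df, downweight=False).gradient_length_sd
        b = dca_gradient_length(doubled, downweight=False).gradient_length_sd
        assert b == pytest.approx(a, rel=1e-6)

    def test_too_few_rows_refused(self):
        with pytest.raises(ValueError, match="3 rows"):
            dca_gradient_length(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_axis(self):
        x = np.linspace(0, 1, 10)
        res = pca_with_scaling(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.axis_variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_trace_identity(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(0, 1, (15, 6)))
        res = pca_with_scaling(df)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)
        assert res.axis_variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_eigen_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (10, 4))
        res = pca_with_scaling(pd.DataFrame(X))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        s = np.linalg.svd(Z, compute_uv=False)
        assert res.eigenvalues == pytest.approx(s**2 / (len(X) - 1), abs=1e-9)

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (12, 4))
        res = pca_with_scaling(pd.DataFrame(X))
        L = res.variable_loadings.to_numpy()
        assert L.T @ L == pytest.approx(np.eye(4), abs=1e-9)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert res.sample_scores.to_numpy() @ L.T == pytest.approx(Z, abs=1e-9)

    def test_invariant_to_column_order_and_affine_rescaling(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(0, 1, (15, 3)), columns=list("abc"))
        base = pca_with_scaling(df)
        shuffled = pca_with_scaling(df[["c", "a", "b"]])
        rescaled = pca_with_scaling(df.assign(b=5 * df["b"] - 3))
        assert shuffled.eigenvalues == pytest.approx(base.eigenvalues, abs=1e-9)
        assert rescaled.eigenvalues == pytest.approx(base.eigenvalues, abs=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(0, 1, (10, 3)))
        res = pca_with_scaling(df)
        for ax in res.variable_loadings.columns:
            load = res.variable_loadings[ax].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_too_few_rows_refused(self):
        with pytest.raises(ValueError, match="3 rows"):
            pca_with_scaling(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestRegression:
    def test_exact_line(self):
        x = np.arange(8.0)
        res = regress_adjusted_r2(x, 3 * x - 1)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_orthogonal_residuals_give_negative_adjustment(self):
        # construct y with zero correlation to x at n = 5
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function of x
        res = regress_adjusted_r2(x, y)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)
        assert res.adjusted_r2 == pytest.approx(-1 / 3, abs=1e-9)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regress_adjusted_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTrend:
    def test_strict_linear_decline(self):
        ages = np.linspace(0.5, 12.0, 30)
        values = 0.4 + 0.04 * ages  # declines toward present
        slope, p = trend_test(values, ages)
        assert slope == pytest.approx(0.04)
        assert p < 1e-20

    def test_constant_series(self):
        assert trend_test(np.ones(10), np.arange(10.0)) == (0.0, 1.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        ages = np.linspace(0, 12, 30)
        pvals = [trend_test(rng.normal(0, 1, 30), ages)[1] for _ in range(500)]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_record_geometry_power(self):
        # a 0.5 permil decline over 9 kyr against 0.1 permil noise is
        # detected at p < 0.001 in nearly every replicate
        rng = np.random.default_rng(11)
        ages = np.linspace(0.2, 9.2, 57)
        hits = 0
        for _ in range(100):
            vals = 0.4 + (0.5 / 9.0) * ages + rng.normal(0, 0.1, ages.size)
            hits += trend_test(vals, ages)[1] < 0.001
        assert hits >= 95
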