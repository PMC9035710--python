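"""Statistical pipeline: correlation formulas against the published
triplets, OLS exactness, diagnostics against brute-force oracles, and the
staged-regression bookkeeping."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import pearsonr

import revlearn as rl
from revlearn.stats import (PAPER_STAGES, HierarchicalOLS, RankDeficientError,
                            cooks_distance, correlation_matrix, durbin_watson,
                            ols_fit, pearson_with_ci, t_from_r, vif)


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, -x)
        assert res.r == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "r,n,t_expected",
        [
            (-0.912, 13, -7.379),  # choline vs GPC+PC
            (-0.667, 13, -2.971),  # choline vs reversals
            (0.630, 13, 2.688),  # reversals vs correct
            (-0.632, 13, -2.701),  # perseverative vs alpha+
            (-0.709, 13, -3.333),  # perseverative vs regressive
        ],
    )
    def test_published_t_triplets(self, r, n, t_expected):
        """t-from-r reproduces the printed t(11) values up to last-digit
        rounding of the printed r."""
        assert t_from_r(r, n) == pytest.approx(t_expected, abs=0.01)

    def test_published_ci(self):
        """Fisher-z CI for r=-0.912, n=13 reproduces the printed interval
        [-0.974, -0.726] to print precision."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(13)
        e = rng.standard_normal(13)
        # construct y with sample correlation exactly -0.912
        xz = (x - x.mean()) / x.std()
        ez = e - e.mean()
        ez -= xz * np.dot(ez, xz) / np.dot(xz, xz)
        ez /= np.linalg.norm(ez)
        r = -0.912
        y = r * xz / np.sqrt(13) + np.sqrt(1 - r**2) * ez
        res = pearson_with_ci(x, y)
        assert res.r == pytest.approx(-0.912, abs=1e-9)
        assert res.df == 11
        assert res.t == pytest.approx(-7.379, abs=0.01)
        assert res.ci_low == pytest.approx(-0.974, abs=0.005)
        assert res.ci_high == pytest.approx(-0.726, abs=0.005)
        assert res.p < 0.001

    def test_matches_scipy(self, rng):
        x = rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        res = pearson_with_ci(x, y)
        ref = pearsonr(x, y)
        ci = ref.confidence_interval()
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)
        assert res.ci_low == pytest.approx(ci.low, abs=1e-9)
        assert res.ci_high == pytest.approx(ci.high, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            pearson_with_ci([1.0, 2.0], [1.0, 2.0])


class TestOLS:
    def test_exact_linear_recovery(self, rng):
        x1 = rng.standard_normal(30)
        x2 = rng.standard_normal(30)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": 2 * x1 - x2})
        fit = ols_fit(data, "y", ["x1", "x2"])
        assert fit.params["x1"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["x2"] == pytest.approx(-1.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_orthogonal_response(self):
        n = 16
        x = np.tile([1.0, -1.0], n // 2)
        y = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to x
        data = pd.DataFrame({"x": x, "y": y})
        fit = ols_fit(data, "y", ["x"])
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_predictor_is_error(self, rng):
        x = rng.standard_normal(20)
        data = pd.DataFrame({"a": x, "b": x, "y": rng.standard_normal(20)})
        with pytest.raises(RankDeficientError):
            ols_fit(data, "y", ["a", "b"])


class TestVIF:
    def test_orthogonal_predictors(self):
        x1 = np.tile([1.0, -1.0], 8)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        data = pd.DataFrame({"x1": x1, "x2": x2})
        assert vif(data, ["x1", "x2"]).max() == pytest.approx(1.0)

    def test_near_collinearity_blows_up(self, rng):
        x = rng.standard_normal(40)
        data = pd.DataFrame({"x1": x, "x2": x + 1e-4 * rng.standard_normal(40)})
        assert vif(data, ["x1", "x2"]).min() > 10  # past the usual threshold

    def test_matches_direct_formula(self, rng):
        data = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        data["c"] += data["a"]
        v = vif(data, ["a", "b", "c"])
        r2 = ols_fit(data, "a", ["b", "c"]).rsquared
        assert v["a"] == pytest.approx(1 / (1 - r2))


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert durbin_watson([1, -1, 1, -1, 1]) == pytest.approx(3.2)

    def test_uncorrelated_residuals_near_two(self, rng):
        dw = np.mean(
            [durbin_watson(rng.standard_normal(500)) for _ in range(20)]
        )
        assert dw == pytest.approx(2.0, abs=0.05)

    def test_constant_residuals(self):
        assert durbin_watson([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_zero_residuals_error(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])


def _loo_cooks(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force Cook's distance: refit without each observation and
    measure the shift of the fitted values, D_i = ||yhat - yhat_(i)||^2 /
    (p * s^2)."""
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    yhat = X @ beta
    s2 = np.sum((y - yhat) ** 2) / (n - p)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        beta_i = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
        out[i] = np.sum((yhat - X @ beta_i) ** 2) / (p * s2)
    return out


class TestCooksDistance:
    def test_matches_leave_one_out_oracle(self, rng):
        for _ in range(5):
            X = np.column_stack([np.ones(12), rng.standard_normal((12, 2))])
            y = X @ np.array([1.0, 0.5, -0.3]) + rng.standard_normal(12)
            fit = sm.OLS(y, X).fit()
            assert np.allclose(cooks_distance(fit), _loo_cooks(X, y), atol=1e-8)

    def test_gross_outlier_dominates(self, rng):
        x = np.linspace(0, 1, 10)
        y = 2 * x + 0.01 * rng.standard_normal(10)
        x_out = np.append(x, 3.0)
        y_out = np.append(y, -5.0)
        X = sm.add_constant(x_out)
        d = cooks_distance(sm.OLS(y_out, X).fit())
        assert d.argmax() == 10
        assert d[10] > 1.0

    def test_exact_fit_gives_zero(self):
        x = np.tile([0.0, 1.0, 2.0, 3.0], 2)
        y = 2 * x + 1
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose(cooks_distance(fit), 0.0, atol=1e-20)


@pytest.fixture(scope="module")
def planted():
    cfg = rl.CohortConfig(n_subjects=40, seed=9)
    _, table = rl.generate_cohort(cfg)
    return table


class TestHierarchicalRegression:
    def test_r2_monotone_and_delta_sums(self, planted):
        stages = rl.hierarchical_regression(planted, "choline_mM", PAPER_STAGES)
        r2 = [s.r2 for s in stages]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert sum(s.delta_r2 for s in stages) == pytest.approx(r2[-1])
        for s in stages:
            assert 0.0 <= s.r2 <= 1.0
            assert s.adj_r2 <= s.r2 + 1e-12

    def test_f_change_matches_statsmodels_nested_f_test(self, planted):
        """The incremental F test agrees with the statsmodels restricted-
        model comparison on every stage."""
        stages = rl.hierarchical_regression(planted, "choline_mM", PAPER_STAGES)
        for prev, cur in zip(PAPER_STAGES, PAPER_STAGES[1:]):
            small = ols_fit(planted, "choline_mM", prev)
            big = ols_fit(planted, "choline_mM", cur)
            f_ref, p_ref, df_ref = big.compare_f_test(small)
            st = stages[PAPER_STAGES.index(cur)]
            assert st.f_change == pytest.approx(f_ref, rel=1e-10)
            assert st.f_change_p == pytest.approx(p_ref, rel=1e-8)
            assert st.df_change[0] == int(df_ref)

    def test_non_nested_stages_rejected(self, planted):
        with pytest.raises(ValueError):
            HierarchicalOLS(planted, "choline_mM",
                            [("gpcpc_mM",), ("reversals",)])

    def test_redundant_stage_column_is_error(self, planted):
        data = planted.copy()
        data["dup"] = data["gpcpc_mM"]
        with pytest.raises(RankDeficientError):
            HierarchicalOLS(
                data, "choline_mM", [("gpcpc_mM",), ("gpcpc_mM", "dup")]
            ).fit()

    def test_standardised_betas_scale_relation(self, planted):
        stages = rl.hierarchical_regression(planted, "choline_mM", PAPER_STAGES)
        st = stages[-1]
        sy = planted["choline_mM"].std(ddof=1)
        for name in st.predictors:
            sx = planted[name].std(ddof=1)
            assert st.coefs.loc[name, "beta"] == pytest.approx(
                st.coefs.loc[name, "b"] * sx / sy, abs=1e-10
            )

    def test_missing_column_named(self, planted):
        with pytest.raises(KeyError, match="nonexistent"):
            HierarchicalOLS(planted, "choline_mM", [("nonexistent",)])


@pytest.fixture(scope="module")
def cohort13():
    cfg = rl.CohortConfig(seed=13)  # n_subjects defaults to 13
    _, table = rl.generate_cohort(cfg)
    return table


class TestPaperAnalysis:
    def test_choline_report_structure(self, cohort13):
        res = rl.run_paper_analysis(cohort13, response="choline_mM")
        assert res.n == 13
        assert [s.index for s in res.stages] == [1, 2, 3]
        assert res.stages[2].predictors == PAPER_STAGES[2]
        assert res.diagnostics.vif.min() >= 1.0
        assert 0.0 <= res.diagnostics.durbin_watson <= 4.0
        assert (res.diagnostics.cooks >= 0).all()
        assert res.correlations is not None
        text = res.summary()
        assert "Stage 3" in text and "Durbin-Watson" in text

    def test_naa_control_overfits_at_n13(self, cohort13):
        """With no planted NAA effects the 7-predictor stage-3 model at
        n=13 shows the overfitting signature: adjusted R^2 far below R^2."""
        res = rl.run_paper_analysis(cohort13, response="naa_mM")
        st3 = res.stages[-1]
        assert st3.adj_r2 < st3.r2 - 0.1

    def test_invalid_response(self, cohort13):
        with pytest.raises(ValueError):
            rl.run_paper_analysis(cohort13, response="creatine_mM")

    def test_correlation_matrix_layout(self, cohort13):
        corr = correlation_matrix(cohort13, ["choline_mM", "gpcpc_mM", "reversals"])
        assert len(corr) == 3
        assert set(corr.columns) >= {"r", "t", "ci_low", "ci_high", "p"}
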