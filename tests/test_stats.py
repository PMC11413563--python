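"""Statistics layer: closed-form tests, FDR, partial correlation, GLMs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from psychspeech.stats import (
    bh_fdr,
    brainlang_glm,
    chi2_2x2,
    cohens_d,
    fit_glm,
    mann_whitney,
    mass_univariate,
    partial_spearman,
    welch_t,
    welch_t_samples,
)


class TestWelch:
    def test_identical_summaries(self):
        r = welch_t(1.0, 0.5, 10, 1.0, 0.5, 10)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)
        assert r.effect_size == 0.0

    def test_tli_disorganization_row(self):
        # printed cohort summaries reproduce the published effect size 1.120
        r = welch_t(0.18, 0.26, 29, 1.09, 1.12, 29)
        assert abs(r.effect_size) == pytest.approx(1.120, abs=0.005)
        assert r.p < 0.001

    def test_doubling_n_decreases_p(self):
        p1 = welch_t(0.0, 1.0, 10, 0.5, 1.0, 10).p
        p2 = welch_t(0.0, 1.0, 20, 0.5, 1.0, 20).p
        assert p2 < p1

    def test_summary_equals_raw_sample_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([2.0, 3.0, 7.0])
        r1 = welch_t_samples(x, y)
        r2 = welch_t(x.mean(), x.std(ddof=1), 4, y.mean(), y.std(ddof=1), 3)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.standard_normal(rng.integers(3, 12))
            y = rng.standard_normal(rng.integers(3, 12)) + rng.normal()
            ours = welch_t_samples(x, y)
            ref = sps.ttest_ind(y, x, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestChi2:
    def test_sex_row_reproduces_printed_values(self):
        r = chi2_2x2(7, 22, 8, 21)
        assert round(r.p, 3) == 0.764
        assert round(r.effect_size, 3) == 0.039

    def test_balanced_table(self):
        r = chi2_2x2(10, 10, 10, 10)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)
        assert r.effect_size == 0.0

    def test_hand_computed_statistic(self):
        r = chi2_2x2(20, 8, 15, 14)
        assert r.statistic == pytest.approx(2.334, abs=0.001)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 5, 5)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            ours = chi2_2x2(a, b, c, d)
            chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert ours.statistic == pytest.approx(chi2, abs=1e-10)
            assert ours.p == pytest.approx(p, abs=1e-10)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.1)  # 2 of 20 arrangements

    def test_location_shift_invariance_of_u(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(12), rng.standard_normal(15)
        assert mann_whitney(x, y).statistic == \
            mann_whitney(x + 5, y + 5).statistic

    def test_degenerate_constant_samples(self):
        r = mann_whitney([2, 2], [2, 2, 2])
        assert r.p == 1.0


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_step_up_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = bh_fdr(p)
            assert np.all(q >= p - 1e-15)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, ref, atol=1e-12)


class TestPartialSpearman:
    def test_no_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        ours = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(rho, abs=1e-10)

    def test_confounder_fully_explains_association(self):
        g = np.repeat([0.0, 1.0], 20)
        rng = np.random.default_rng(5)
        x = g * 2 + rng.normal(0, 0.01, 40)
        y = g * 3 + rng.normal(0, 0.01, 40)
        r = partial_spearman(x, y, g)
        assert abs(r.statistic) < 0.35  # raw Spearman would be ~1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 2, 25)
        y = rng.uniform(0.1, 2, 25)
        z = rng.uniform(size=25)
        a = partial_spearman(x, y, z)
        b = partial_spearman(np.exp(x), y**3, z)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x, y, c = rng.standard_normal((3, 40))
        ours = partial_spearman(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=0.02)

    def test_constant_variable_raises(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), np.arange(10))


class TestGLM:
    def test_gaussian_identity_equals_ols(self):
        rng = np.random.default_rng(8)
        x = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = x @ [1.0, 2.0] + rng.standard_normal(50)
        res = fit_glm(y, x, "gaussian-identity")
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_positive_response_required_for_log_link(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.arange(10.0) - 3  # contains non-positives
        with pytest.raises(ValueError, match="positive"):
            fit_glm(y, x, "gamma-log")

    def test_rank_deficiency_reports_aliased(self):
        x = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(np.random.default_rng(9).uniform(1, 2, 20), x, "gamma-log")

    def test_gamma_log_recovers_known_coefficients(self):
        rng = np.random.default_rng(10)
        n = 500
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        mu = np.exp(x @ [0.5, 0.8])
        shape = 5.0
        y = rng.gamma(shape, mu / shape)
        res = fit_glm(y, x, "gamma-log")
        assert res.params == pytest.approx([0.5, 0.8], abs=0.15)
        assert res.gof_p > 0.001

    def test_tweedie_log_runs_and_q_monotone(self):
        rng = np.random.default_rng(11)
        n = 200
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = np.exp(x @ [0.2, 0.5]) * rng.gamma(4, 0.25, n)
        res = fit_glm(y, x, "tweedie-log")
        assert np.all(res.q_values >= res.p_values - 1e-15)


class TestMassUnivariate:
    @staticmethod
    def _subjects(n_per_group, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "group": ["HC"] * n_per_group + ["FEP"] * n_per_group,
            "age": rng.normal(21, 3, 2 * n_per_group),
            "sex": rng.integers(0, 2, 2 * n_per_group),
            "education": rng.integers(0, 2, 2 * n_per_group),
        })

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        subs = self._subjects(10)
        vals = rng.standard_normal((20, 5))
        res = mass_univariate(vals, subs)
        perm = rng.permutation(20)
        res_p = mass_univariate(vals[perm], subs.iloc[perm].reset_index(drop=True))
        assert np.allclose(res["t"], res_p["t"])

    def test_matches_statsmodels_ols_per_roi(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        subs = self._subjects(12, seed=1)
        vals = rng.standard_normal((24, 3))
        res = mass_univariate(vals, subs)
        gv = (subs["group"] == "HC").astype(float)  # sorted levels: FEP < HC
        x = sm.add_constant(np.column_stack([
            gv, subs["age"], subs["sex"], subs["education"]]))
        for j in range(3):
            fit = sm.OLS(vals[:, j], x).fit()
            assert res["t"].iloc[j] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(14)
        subs = self._subjects(20, seed=2)
        vals = rng.standard_normal((40, 50))
        vals[20:, :5] += 1.8  # strong effect in 5 of 50 ROIs
        res = mass_univariate(vals, subs)
        assert res["significant"][:5].all()
        assert res["significant"][5:].sum() <= 2


class TestBrainLang:
    def test_constant_language_measure_errors(self):
        rng = np.random.default_rng(15)
        n = 30
        disp = pd.DataFrame({"d1": rng.uniform(1, 2, n)})
        lang = pd.DataFrame({"m1": np.ones(n)})
        subs = pd.DataFrame({"age": rng.normal(21, 2, n),
                             "sex": rng.integers(0, 2, n),
                             "education": rng.integers(0, 2, n)})
        with pytest.raises(ValueError, match="rank deficient"):
            brainlang_glm(disp, lang, subs)

    def test_signed_dispersion_is_shifted_for_log_link(self):
        rng = np.random.default_rng(16)
        n = 40
        disp = pd.DataFrame({"d1": rng.normal(0, 1, n)})  # signed values
        lang = pd.DataFrame({"m1": rng.standard_normal(n)})
        subs = pd.DataFrame({"age": rng.normal(21, 2, n),
                             "sex": rng.integers(0, 2, n),
                             "education": rng.integers(0, 2, n)})
        out = brainlang_glm(disp, lang, subs)
        assert out["shifted"].all()

    def test_planted_association_detected(self):
        rng = np.random.default_rng(17)
        n = 58
        m1 = rng.standard_normal(n)
        disp = pd.DataFrame({"d1": np.exp(0.5 * m1 + rng.normal(0, 0.2, n))})
        lang = pd.DataFrame({"m1": m1, "null": rng.standard_normal(n)})
        subs = pd.DataFrame({"age": rng.normal(21, 2, n),
                             "sex": rng.integers(0, 2, n),
                             "education": rng.integers(0, 2, n)})
        out = brainlang_glm(disp, lang, subs).set_index("language")
        assert out.loc["m1", "q"] < 0.05
        assert out.loc["null", "q"] > 0.05
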