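"""Effect-size machinery: exact ratio formulas, classification rule,
variance-component recovery against a brute-force likelihood oracle,
family selection, estimated marginal means, and CV decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from skiemg.mixedfx import (
    FitError,
    ModelSpec,
    classify_effect,
    classify_terms,
    cv_decomposition,
    fit_model,
    icc_adjusted,
    icc_cond_from_r2,
    icc_conditional,
    r2_nakagawa,
)
from skiemg.synth import simulate_turn_table


class TestIccFormulas:
    def test_icc_adjusted(self):
        assert icc_adjusted(1.0, 0.0) == pytest.approx(1.0)
        assert icc_adjusted(0.0, 1.0) == pytest.approx(0.0)

    def test_icc_conditional(self):
        assert icc_conditional(1.0, 1.0, 2.0) == pytest.approx(0.25)
        assert icc_conditional(0.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(FitError):
            icc_adjusted(0.0, 0.0)

    def test_icc_cond_from_r2(self):
        assert icc_cond_from_r2(0.521, 1.000) == pytest.approx(0.479)
        assert icc_cond_from_r2(0.0, 1.0) == pytest.approx(1.0)
        assert icc_cond_from_r2(0.681, 1.000) == pytest.approx(0.319)
        with pytest.raises(FitError):
            icc_cond_from_r2(0.9, 0.5)


class TestR2Nakagawa:
    def test_direct_substitution(self):
        r2m, r2c = r2_nakagawa(2.0, 1.0, 1.0)
        assert r2m == pytest.approx(0.5) and r2c == pytest.approx(0.75)

    def test_no_fixed_variance_limit(self):
        r2m, r2c = r2_nakagawa(0.0, 3.0, 1.0)
        assert r2m == 0.0
        assert r2c == pytest.approx(icc_adjusted(3.0, 1.0))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.floats(0.0, 50.0), st.floats(0.0, 50.0), st.floats(1e-3, 50.0)))
    def test_identity_r2m_plus_icc_cond_equals_r2c(self, triple):
        vf, vr, ve = triple
        r2m, r2c = r2_nakagawa(vf, vr, ve)
        assert abs(r2m + icc_conditional(vr, ve, vf) - r2c) < 1e-6


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "p,adj,cond,label",
        [
            (0.0005, 1.000, 0.465, "very strong"),
            (0.035, 1.000, 0.859, "moderate"),
            (0.011, 0.528, 0.525, "negligible"),  # ICC_adj ~ ICC_cond
            (0.20, 1.000, 0.3, "negligible"),  # not significant
            (0.01, 1.000, 0.6, "strong"),
            (0.01, 1.000, 0.95, "small"),
        ],
    )
    def test_rule(self, p, adj, cond, label):
        assert classify_effect(p, adj, cond).label == label


def oracle_lmm(y, X, groups):
    """Brute-force ML for the random-intercept normal model.

    Profiles the GLS fixed effects on an explicit (vr, ve) grid built from
    the marginal covariance matrix, then polishes the best grid point with a
    local simplex. Shares no code with the fitting path under test.
    """
    n = len(y)
    Z = np.zeros((n, groups.max() + 1))
    Z[np.arange(n), groups] = 1.0

    def profiled_nll(params):
        vr, ve = np.exp(params)
        V = ve * np.eye(n) + vr * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        return 0.5 * (n * math.log(2 * math.pi) + logdet + r @ Vi @ r)

    grid = [(lv, le) for lv in np.linspace(-4, 4, 17) for le in np.linspace(-4, 4, 17)]
    best = min(grid, key=profiled_nll)
    res = optimize.minimize(profiled_nll, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


class TestFitModel:
    def test_variance_components_match_brute_force_oracle(self):
        """2 sessions x 6 observations: components agree with the grid oracle to 1e-3."""
        rng = np.random.default_rng(5)
        df = simulate_turn_table(2, 3, sigma_id=1.0, sigma_e=0.7, rng=rng, mean=10.0)
        fit = fit_model(df, ModelSpec("value", "run", "normal"))
        y = df["value"].to_numpy()
        X = np.column_stack([np.ones(len(df)), (df["run"] == "Last").to_numpy(float)])
        groups = (df["session_id"] == "S001").to_numpy(int)
        vr_o, ve_o = oracle_lmm(y, X, groups)
        assert fit.var_random == pytest.approx(vr_o, abs=1e-3)
        assert fit.var_residual == pytest.approx(ve_o, abs=1e-3)

    def test_parameter_recovery_single_replicate(self):
        rng = np.random.default_rng(12)
        df = simulate_turn_table(40, 15, sigma_id=2.0, sigma_e=1.0, rng=rng, mean=30.0, leg_effect=3.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        assert 2.5 <= fit.var_random <= 6.0
        assert 0.9 <= fit.var_residual <= 1.1
        assert abs(fit.r2m + fit.icc_cond - fit.r2c) < 1e-6
        assert fit.icc_cond <= fit.icc_adj + 1e-12

    def test_lognormal_data_selects_lognormal(self):
        wins = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            df = simulate_turn_table(15, 15, sigma_id=0.3, sigma_e=0.6, rng=rng, mean=3.0, family="lognormal")
            wins += fit_model(df, ModelSpec("value", "run*leg", "auto")).family == "lognormal"
        assert wins >= 20  # >= 80% of replicates

    def test_gamma_family_recovers_shape_and_variance(self):
        rng = np.random.default_rng(7)
        df = simulate_turn_table(25, 15, sigma_id=0.3, sigma_e=0.0, rng=rng, mean=3.0, family="gamma", gamma_shape=10.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "gamma"))
        assert fit.gamma_shape == pytest.approx(10.0, rel=0.25)
        assert fit.var_random == pytest.approx(0.09, rel=0.4)

    def test_nonpositive_response_excludes_log_families(self):
        rng = np.random.default_rng(3)
        df = simulate_turn_table(8, 8, sigma_id=1.0, sigma_e=1.0, rng=rng, mean=0.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "auto"))
        assert fit.family == "normal"
        assert set(fit.families_aic) == {"normal"}

    def test_singular_fit_flagged_not_raised(self):
        rng = np.random.default_rng(4)
        df = simulate_turn_table(10, 10, sigma_id=0.0, sigma_e=1.0, rng=rng, mean=20.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        assert fit.singular in (True, False)  # must not raise
        assert fit.var_random < 0.05

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(2)
        df = simulate_turn_table(4, 4, 1.0, 1.0, rng=rng)
        with pytest.raises(FitError):
            fit_model(df[df.run == "First"], ModelSpec("value", "run", "normal"))


class TestEmmeans:
    def test_balanced_normal_emmeans_equal_cell_means(self):
        rng = np.random.default_rng(8)
        df = simulate_turn_table(10, 12, sigma_id=1.5, sigma_e=0.8, rng=rng, mean=25.0, run_effect=2.0, leg_effect=4.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        for cell in fit.emmeans:
            raw = df[(df.run == cell["run"]) & (df.leg == cell["leg"])]["value"].mean()
            assert cell["emmean"] == pytest.approx(raw, abs=1e-8)

    def test_injected_difference_recovered(self):
        rng = np.random.default_rng(9)
        df = simulate_turn_table(20, 15, sigma_id=2.0, sigma_e=1.0, rng=rng, mean=30.0, run_effect=5.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        for d in fit.emmean_diffs:
            assert d["ci_low"] <= 5.0 <= d["ci_high"]


class TestClassifyTerms:
    def test_null_run_effect_classified_negligible(self):
        rng = np.random.default_rng(10)
        df = simulate_turn_table(20, 15, sigma_id=2.0, sigma_e=1.0, rng=rng, mean=30.0, leg_effect=5.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        classes = classify_terms(fit)
        assert classes["run"].label == "negligible"
        assert classes["leg"].label != "negligible"


class TestCvDecomposition:
    def test_direct_substitution(self):
        rng = np.random.default_rng(11)
        df = simulate_turn_table(30, 20, sigma_id=2.0, sigma_e=1.0, rng=rng, mean=20.0)
        fit = fit_model(df, ModelSpec("value", "run*leg", "normal"))
        cv = cv_decomposition(fit)
        assert cv.cv_random == pytest.approx(100 * math.sqrt(fit.var_random) / fit.grand_mean)
        assert cv.cv_intra == pytest.approx(100 * math.sqrt(fit.var_residual) / fit.grand_mean)
        assert cv.cv_syst >= 0

    def test_recovery_against_closed_form(self):
        """Each CV within 20% relative of its generating value over replicates."""
        cvr, cvi = [], []
        for seed in range(25):
            rng = np.random.default_rng(2000 + seed)
            df = simulate_turn_table(30, 15, sigma_id=2.0, sigma_e=1.0, rng=rng, mean=20.0)
            cv = cv_decomposition(fit_model(df, ModelSpec("value", "run*leg", "normal")))
            cvr.append(cv.cv_random)
            cvi.append(cv.cv_intra)
        assert np.mean(cvr) == pytest.approx(100 * 2.0 / 20.0, rel=0.20)
        assert np.mean(cvi) == pytest.approx(100 * 1.0 / 20.0, rel=0.20)
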