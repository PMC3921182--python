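"""Mixed-model fitting and information-theoretic machinery."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from soarsel.models import (
    ModelSpec,
    aicc,
    akaike_weights,
    build_design,
    compare_covariance,
    ecoregion_model_average,
    effect_multiplier,
    fit_mixed_ar1,
    marginal_means,
    met_candidate_set,
    model_average,
    screen_effects,
)
from soarsel.synthetic import simulate_ar1_panels


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(20 + 6, rel=1e-6)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError, match="AICc"):
            aicc(0.0, 5, 6)

    def test_random_tuples_match_independent_formula(self, rng):
        for _ in range(20):
            ll = rng.normal(0, 50)
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 500))
            expected = -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)


class TestAkaikeWeights:
    def test_equal_models(self):
        assert np.allclose(akaike_weights([10.0] * 4), 0.25)

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=5e-4)
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_normalization_and_shift_invariance(self, rng):
        a = rng.normal(500, 10, 7)
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()
        assert np.allclose(w, akaike_weights(a + 123.4))


class FakeFit:
    """Minimal stand-in carrying hand-set coefficients for averaging tests."""

    def __init__(self, coefficients):
        self._c = coefficients

    @property
    def coefficients(self):
        return self._c


class TestModelAverage:
    def test_identical_beta_everywhere(self):
        fits = [FakeFit({"x": (2.0, 0.5)}), FakeFit({"x": (2.0, 0.5)})]
        res = model_average(fits, np.array([0.6, 0.4]), "x")
        assert res.estimate == pytest.approx(2.0)
        assert res.unconditional_se == pytest.approx(0.5)
        assert res.importance == pytest.approx(1.0)

    def test_absent_everywhere_shrinks_to_zero(self):
        fits = [FakeFit({"y": (1.0, 0.1)})]
        res = model_average(fits, np.array([1.0]), "x")
        assert (res.estimate, res.unconditional_se, res.importance) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic_two_models(self):
        fits = [FakeFit({"x": (1.0, 0.2)}), FakeFit({})]
        w = np.array([0.7, 0.3])
        res = model_average(fits, w, "x")
        est = 0.7 * 1.0
        var = 0.7 * (0.04 + (1.0 - est) ** 2) + 0.3 * (0.0 + est**2)
        assert res.estimate == pytest.approx(est)
        assert res.unconditional_se == pytest.approx(np.sqrt(var))
        assert res.importance == pytest.approx(0.7)
        assert res.ci_low == pytest.approx(est - 1.96 * res.unconditional_se)

    def test_single_model_reduces_exactly(self):
        fits = [FakeFit({"x": (1.5, 0.3)})]
        res = model_average(fits, akaike_weights([42.0]), "x")
        assert res.estimate == pytest.approx(1.5)
        assert res.unconditional_se == pytest.approx(0.3)


class TestEffectMultiplierAndScreen:
    def test_worked_example(self):
        # a ln(rf) slope of 1.080 per km of thermal height scales rf ~2.95x
        assert effect_multiplier(1.080, 1.0, ndigits=None) == pytest.approx(
            np.exp(1.080), rel=1e-12
        )
        assert effect_multiplier(1.080, 1.0, ndigits=None) == pytest.approx(
            2.95, abs=0.01
        )

    def test_null_and_negative(self):
        assert effect_multiplier(0.0) == pytest.approx(1.0)
        assert effect_multiplier(-0.218, 1.0, ndigits=None) == pytest.approx(
            np.exp(-0.218)
        )

    def test_strict_inequality_screen(self):
        table = pd.DataFrame({"p": [0.01, 0.0099, 0.5]})
        out = screen_effects(table, alpha=0.01)
        assert list(out["significant"]) == [False, True, False]

    def test_invalid_p_values(self):
        with pytest.raises(ValueError, match="p-values"):
            screen_effects(pd.DataFrame({"p": [1.2]}))


class TestDesign:
    def test_treatment_coding_and_term_columns(self):
        data = pd.DataFrame({
            "sex": ["M", "F", "M", "F"],
            "month": [1, 1, 2, 2],
            "thermal_height": [0.5, 0.9, 1.0, 1.2],
        })
        X, info = build_design(data, ["sex", "month", "thermal_height"])
        assert X.shape == (4, 4)  # intercept + sex + month + slope
        assert info.term_columns["thermal_height"] == [3]
        assert info.levels["month"] == [1, 2]

    def test_interaction_columns(self):
        data = pd.DataFrame({
            "sex": ["M", "F", "M", "F"] * 3,
            "month": [1, 1, 2, 2, 3, 3] * 2,
        })
        X, info = build_design(data, ["sex", "month", "sex:month"])
        assert len(info.term_columns["sex:month"]) == 2  # (2-1)*(3-1)

    def test_rank_deficiency_detected(self):
        data = pd.DataFrame({"a": ["x", "y"] * 4, "b": ["u", "v"] * 4})
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(data, ["a", "b"])


class TestMixedModelFit:
    def test_rho_recovered_near_zero(self):
        data = simulate_ar1_panels(seed=21, n_birds=120, n_months=12, rho=0.0)
        fit = fit_mixed_ar1(data, ModelSpec([]))
        assert abs(fit.rho) < 0.05

    def test_constant_response_gives_zero_slopes(self):
        data = simulate_ar1_panels(seed=2, n_birds=10, n_months=6,
                                   beta={"thermal_height": 0.0})
        data["ln_rf"] = 1.0
        fit = fit_mixed_ar1(data, ModelSpec(["thermal_height"]))
        assert fit.beta["thermal_height"] == pytest.approx(0.0, abs=1e-6)
        assert fit.beta["intercept"] == pytest.approx(1.0, abs=1e-6)

    def test_slope_recovery_with_ci(self):
        data = simulate_ar1_panels(seed=31, n_birds=40, n_months=12,
                                   beta={"thermal_height": 1.0}, rho=0.6)
        fit = fit_mixed_ar1(data, ModelSpec(["thermal_height"]))
        b, se = fit.coefficients["thermal_height"]
        assert b - 3 * se < 1.0 < b + 3 * se
        assert 0.3 < fit.rho < 0.8

    def test_ar1_loglik_dominates_cs_on_ar1_data(self):
        data = simulate_ar1_panels(seed=41, n_birds=30, n_months=12, rho=0.6)
        spec = ModelSpec([])
        ar1 = fit_mixed_ar1(data, spec)
        cs = fit_mixed_ar1(data, ModelSpec([], covariance="compound_symmetry"))
        assert ar1.loglik >= cs.loglik - 1e-6  # CS is nested in AR(1) at rho=0

    def test_determinism(self):
        data = simulate_ar1_panels(seed=5, n_birds=20, n_months=8,
                                   beta={"thermal_height": 0.5})
        spec = ModelSpec(["thermal_height"])
        a = fit_mixed_ar1(data, spec)
        b = fit_mixed_ar1(data, spec)
        assert a.loglik == b.loglik
        assert np.array_equal(a.beta.to_numpy(), b.beta.to_numpy())

    def test_needs_two_birds(self):
        data = simulate_ar1_panels(seed=6, n_birds=1, n_months=12)
        with pytest.raises(ValueError, match="2 birds"):
            fit_mixed_ar1(data, ModelSpec([]))


class TestCompareCovariance:
    def test_ar1_data_selects_ar1(self):
        data = simulate_ar1_panels(seed=51, n_birds=40, n_months=12, rho=0.6)
        result = compare_covariance(data, ModelSpec([]))
        assert result["winner"] == "ar1"
        assert result["aicc"]["ar1"] < result["aicc"]["compound_symmetry"]

    def test_uncorrelated_data_prefers_simpler_structure(self):
        data = simulate_ar1_panels(seed=52, n_birds=60, n_months=12, rho=0.0)
        result = compare_covariance(data, ModelSpec([]))
        # identical likelihood surface at rho=0 => fewer parameters win
        assert result["winner"] == "compound_symmetry"


class TestMarginalMeans:
    def test_balanced_one_factor_equals_group_means(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({
            "bird_id": np.repeat([f"b{i}" for i in range(8)], 6),
            "month": np.tile(np.arange(1, 7), 8),
            "sex": np.repeat(["M", "F"] * 4, 6),
            "ln_rf": rng.normal(0, 1, 48),
        })
        data.loc[data["sex"] == "M", "ln_rf"] += 1.0
        fit = fit_mixed_ar1(data, ModelSpec(["sex"]))
        mm = marginal_means(fit, "sex").set_index("level")
        # balanced design: marginal means equal model intercept +/- sex effect,
        # which equal the GLS-weighted group means; compare to raw means loosely
        raw = data.groupby("sex")["ln_rf"].mean()
        assert mm.loc["M", "mean"] == pytest.approx(raw["M"], abs=0.15)
        assert mm.loc["F", "mean"] == pytest.approx(raw["F"], abs=0.15)

    def test_unbalanced_two_factor_matches_balanced_grid_oracle(self):
        rng = np.random.default_rng(8)
        n = 120
        data = pd.DataFrame({
            "bird_id": rng.choice([f"b{i}" for i in range(10)], n),
            "month": rng.integers(1, 7, n),
            "sex": rng.choice(["M", "F"], n, p=[0.8, 0.2]),
            "site": rng.choice(["A", "B", "C"], n, p=[0.6, 0.3, 0.1]),
            "ln_rf": rng.normal(0, 1, n),
        })
        fit = fit_mixed_ar1(data, ModelSpec(["sex", "site"]))
        mm = marginal_means(fit, "sex").set_index("level")
        b = fit.beta
        # hand-built balanced-grid prediction for sex=M averaged over sites
        pred_m = b["intercept"] + b["sex[M]"] + (b["site[B]"] + b["site[C]"]) / 3
        assert mm.loc["M", "mean"] == pytest.approx(pred_m, rel=1e-9)

    def test_absent_factor_errors(self):
        data = simulate_ar1_panels(seed=9, n_birds=10, n_months=6)
        fit = fit_mixed_ar1(data, ModelSpec([]))
        with pytest.raises(ValueError, match="categorical"):
            marginal_means(fit, "sex")


class TestCandidateSetAveraging:
    def test_candidate_set_is_all_met_subsets(self):
        sets = met_candidate_set(["sex"])
        assert len(sets) == 8
        assert ["sex"] in sets
        assert ["sex", "thermal_height", "thermal_velocity", "wind_speed"] in sets

    def test_ecoregion_model_average_recovers_strong_effect(self):
        data = simulate_ar1_panels(
            seed=61, n_birds=30, n_months=12,
            beta={"thermal_height": 1.0, "thermal_velocity": 0.0, "wind_speed": 0.0},
            rho=0.4,
        )
        out = ecoregion_model_average(data, base_terms=[])
        avg = out["averages"]["thermal_height"]
        assert avg.importance > 0.9
        assert avg.ci_low < 1.0 < avg.ci_high
        assert out["weights"].sum() == pytest.approx(1.0, abs=1e-12)
        null_avg = out["averages"]["thermal_velocity"]
        assert abs(null_avg.estimate) < 0.2


@pytest.mark.parametrize("method", ["ml", "reml"])
def test_ar1_fit_matches_r_nlme_oracle(tmp_path, method):
    """Independent cross-check of the AR(1) fit against nlme::lme."""
    data = simulate_ar1_panels(seed=71, n_birds=12, n_months=10,
                               beta={"thermal_height": 0.8}, rho=0.5)
    csv = tmp_path / "panel.csv"
    data.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        library(nlme)
        d <- read.csv("{csv}")
        m <- lme(ln_rf ~ thermal_height, random = ~1 | bird_id,
                 correlation = corAR1(form = ~ month | bird_id),
                 data = d, method = "{method.upper()}")
        cat(sprintf("%.10f %.10f %.10f\\n", logLik(m),
            fixef(m)[1], fixef(m)[2]))
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    r_ll, r_int, r_slope = map(float, proc.stdout.split()[-3:])
    fit = fit_mixed_ar1(data, ModelSpec(["thermal_height"]), method=method)
    assert fit.loglik == pytest.approx(r_ll, abs=1e-3)
    assert fit.beta["intercept"] == pytest.approx(r_int, abs=1e-4)
    assert fit.beta["thermal_height"] == pytest.approx(r_slope, abs=1e-4)
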