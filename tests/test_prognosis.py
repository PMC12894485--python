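"""Conversion models and the prognosis chain: exact algebra, round trips,
monotonicity, and regression recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mscsf import prognosis as prog
from mscsf.simulate import SimConfig, generate_training_cohort


def fitted_models(a=0.2, b=0.5, coef=(0.0, 0.06, 0.0004)):
    m = prog.ConversionModels(
        a=a, b=b, c0=coef[0], c1=coef[1], c2=coef[2], cw_min=0.0, cw_max=100.0
    )
    return m


class TestSlopeModel:
    def test_noise_free_line_exact(self):
        x = np.linspace(0, 3, 40)
        y = 0.2 + 0.5 * x
        m = prog.fit_msdss_slope_model(x, y)
        assert m.a == pytest.approx(0.2, abs=1e-10)
        assert m.b == pytest.approx(0.5, abs=1e-10)
        assert m.linear_r2 == pytest.approx(1.0)

    def test_recovery_from_training_cohort(self):
        cfg = SimConfig(
            n_rrms=200, n_progms=100, n_oind=0, n_nind=0,
            nonprogressor_frac=0.0, slope_noise_sd=0.08,
        )
        cohort = generate_training_cohort(cfg, seed=12)
        parts = cohort.participants
        m = prog.fit_msdss_slope_model(
            parts["msdss_true"], parts["combiwise_slope_true"]
        )
        assert m.a == pytest.approx(cohort.provenance["a_true"], rel=0.10)
        assert m.b == pytest.approx(cohort.provenance["b_true"], rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            prog.fit_msdss_slope_model([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prog.fit_msdss_slope_model(np.ones(20), np.arange(20.0))


class TestQuadraticModel:
    def test_noise_free_exact_recovery(self, rng):
        cw = rng.uniform(0, 100, 200)
        edss = 0.1 + 0.05 * cw + 0.0004 * cw**2
        m = prog.fit_combiwise_edss_model(cw, edss)
        assert (m.c0, m.c1, m.c2) == pytest.approx((0.1, 0.05, 0.0004), abs=1e-8)
        assert m.cw_min == 0.0 and m.cw_max == 100.0

    def test_pure_linear_generator_c2_near_zero(self, rng):
        cw = rng.uniform(0, 100, 500)
        edss = 0.08 * cw + rng.normal(0, 0.2, 500)
        m = prog.fit_combiwise_edss_model(cw, edss)
        # c2 SE for this design is ~1e-5; 3 SE bound
        assert abs(m.c2) < 3e-5

    def test_forward_rmse_tracks_noise(self, rng):
        noise = 0.3
        cw = rng.uniform(0, 100, 3000)
        edss = 0.06 * cw + 0.0004 * cw**2 + rng.normal(0, noise, 3000)
        m = prog.fit_combiwise_edss_model(cw, edss)
        rmse = np.sqrt(np.mean((m.q(cw) - edss) ** 2))
        assert rmse <= 2 * noise

    def test_insufficient_span_rejected(self, rng):
        cw = rng.uniform(40, 60, 100)
        with pytest.raises(ValueError, match="span"):
            prog.fit_combiwise_edss_model(cw, 0.1 * cw)

    def test_nonmonotone_curve_warns_and_restricts_domain(self, rng):
        cw = np.linspace(0, 100, 200)
        edss = 5.0 + 0.1 * cw - 0.001 * cw**2  # turns at cw = 50
        with pytest.warns(UserWarning, match="non-monotone"):
            m = prog.fit_combiwise_edss_model(cw, edss)
        assert m.cw_max == pytest.approx(50.0, abs=1e-6)


class TestInverse:
    def test_linear_special_case(self):
        m = fitted_models(coef=(0.0, 0.1, 0.0))
        assert prog.edss_to_combiwise(2.0, m) == pytest.approx(20.0)

    def test_round_trip_on_random_monotone_quadratics(self, rng):
        worst = 0.0
        for _ in range(100):
            c1 = rng.uniform(0.02, 0.12)
            c2 = rng.uniform(0.0, (0.1 - c1) / 200 + 5e-4)
            m = fitted_models(coef=(rng.uniform(-0.5, 0.5), c1, c2))
            edss = rng.uniform(m.q(0.0), m.q(100.0), 100)
            for e in edss:
                cw = prog.edss_to_combiwise(float(e), m)
                worst = max(worst, abs(m.q(cw) - e))
        assert worst < 1e-9

    def test_out_of_range_clamps_with_warning(self):
        m = fitted_models()
        with pytest.warns(UserWarning, match="clamped"):
            assert prog.edss_to_combiwise(-1.0, m) == 0.0
        with pytest.warns(UserWarning, match="clamped"):
            assert prog.edss_to_combiwise(99.0, m) == 100.0


class TestChain:
    def test_zero_interval_returns_baseline_exactly(self, rng):
        m = fitted_models()
        base = rng.uniform(0.5, 7.5, 50)
        out = prog.predict_followup_edss(rng.normal(1, 0.5, 50), base, np.zeros(50), m)
        assert out["predicted_followup_edss"].to_numpy() == pytest.approx(base, abs=1e-9)

    def test_zero_b_gives_uniform_delta_cw(self, rng):
        m = fitted_models(a=0.4, b=0.0)
        out = prog.predict_followup_edss(
            rng.normal(1, 1, 30), np.full(30, 3.0), np.full(30, 5.0), m
        )
        assert np.allclose(out["delta_cw"], 0.4 * 5.0)

    def test_monotone_in_msdss(self):
        m = fitted_models()
        msdss = np.linspace(0, 3, 20)
        out = prog.predict_followup_edss(msdss, np.full(20, 3.0), np.full(20, 8.0), m)
        assert (np.diff(out["predicted_followup_edss"]) >= -1e-12).all()

    def test_monotone_in_interval(self):
        m = fitted_models()
        ivl = np.linspace(0, 15, 20)
        out = prog.predict_followup_edss(np.full(20, 1.5), np.full(20, 2.0), ivl, m)
        assert (np.diff(out["predicted_followup_edss"]) >= -1e-12).all()

    def test_missing_inputs_skipped_with_reason(self):
        m = fitted_models()
        out = prog.predict_followup_edss(
            [1.0, np.nan, 1.0], [2.0, 2.0, np.nan], [5.0, 5.0, 5.0], m,
            participant_id=["a", "b", "c"],
        )
        assert len(out) == 1
        reasons = {s["participant_id"]: s["reason"] for s in out.attrs["skipped"]}
        assert reasons == {"b": "missing msdss_pred", "c": "missing baseline_edss"}

    def test_prediction_not_grid_snapped(self):
        m = fitted_models()
        out = prog.predict_followup_edss([2.0], [2.0], [3.0], m)
        val = out["predicted_followup_edss"].iloc[0]
        assert abs(val * 2 - round(val * 2)) > 1e-6  # off the half-point grid


class TestEvaluatePrognosis:
    def _preds(self, rng, n=40):
        base = rng.uniform(1, 6, n)
        delta = rng.normal(0.5, 0.3, n)
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "baseline_edss": base,
                "delta_edss": delta,
                "predicted_followup_edss": np.clip(base + delta, 0, 10),
            }
        )

    def test_perfect_prediction(self, rng):
        preds = self._preds(rng)
        rep = prog.evaluate_prognosis(preds, preds["predicted_followup_edss"].to_numpy())
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.r2_augmented == pytest.approx(1.0)

    def test_constant_delta_collapses_to_base_model(self, rng):
        preds = self._preds(rng)
        preds["delta_edss"] = 0.0
        y = preds["baseline_edss"] + rng.normal(0, 0.5, len(preds))
        rep = prog.evaluate_prognosis(preds, y.to_numpy())
        assert rep.r2_augmented == rep.r2_base
        assert rep.p_gain is None

    def test_nested_r2_never_decreases(self, rng):
        for _ in range(100):
            preds = self._preds(rng, n=30)
            y = rng.normal(3, 1.5, 30)
            rep = prog.evaluate_prognosis(preds, y)
            assert rep.r2_augmented >= rep.r2_base - 1e-12

    def test_too_few_cases_rejected(self, rng):
        preds = self._preds(rng, n=5)
        with pytest.raises(ValueError, match=">= 10"):
            prog.evaluate_prognosis(preds, np.ones(5))


class TestMultivariate:
    def test_recovers_planted_coefficients_at_cohort_scale(self, rng):
        n = 96
        base = rng.uniform(0, 7, n)
        age = rng.normal(45, 11, n)
        prob = rng.random(n)
        y = 0.33 * base + 2.9 * prob + 0.04 * age + rng.normal(0, 1.0, n)
        rep = prog.multivariate_followup_model(base, age, prob, y)
        t = rep.terms
        assert abs(t.loc["baseline_edss", "estimate"] - 0.33) < 2 * t.loc["baseline_edss", "se"]
        assert abs(t.loc["progms_probability", "estimate"] - 2.9) < 2 * t.loc["progms_probability", "se"]

    def test_zero_noise_exact(self, rng):
        n = 50
        base = rng.uniform(0, 7, n)
        age = rng.normal(45, 11, n)
        prob = rng.random(n)
        y = 1.0 + 0.33 * base + 2.9 * prob + 0.04 * age
        rep = prog.multivariate_followup_model(base, age, prob, y)
        assert rep.terms.loc["progms_probability", "estimate"] == pytest.approx(2.9, abs=1e-8)
        assert rep.r_squared == pytest.approx(1.0)

    def test_irrelevant_age_not_significant_on_average(self):
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 80
            base, age, prob = r.uniform(0, 7, n), r.normal(45, 11, n), r.random(n)
            y = 0.4 * base + r.normal(0, 1, n)
            ps.append(
                prog.multivariate_followup_model(base, age, prob, y)
                .terms.loc["age", "p"]
            )
        # under the null, p-values are uniform: mean near 0.5
        assert 0.25 < np.mean(ps) < 0.75


class TestMriBaseline:
    def test_intercept_only(self):
        scores = pd.DataFrame({"lesion_load": [1.0, 2.0, 3.0]})
        out = prog.mri_baseline_edss(scores, {"intercept": 2.0})
        assert (out == 2.0).all()

    def test_clamped_to_scale(self):
        scores = pd.DataFrame({"lesion_load": [50.0]})
        out = prog.mri_baseline_edss(scores, {"intercept": 0.0, "lesion_load": 1.0})
        assert out.iloc[0] == 10.0

    def test_missing_component_rejected(self):
        scores = pd.DataFrame({"lesion_load": [1.0]})
        with pytest.raises(KeyError, match="atrophy"):
            prog.mri_baseline_edss(scores, {"atrophy": 0.5})

    def test_recovers_generator_estimate(self, rng):
        true = rng.uniform(0, 8, 200)
        noisy = np.clip(true + rng.normal(0, 0.3, 200), 0, 10)
        scores = pd.DataFrame({"score": noisy})
        out = prog.mri_baseline_edss(scores, {"intercept": 0.0, "score": 1.0})
        assert np.sqrt(np.mean((out - true) ** 2)) < 0.45
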