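"""Closed-form predictions, matching law, observer-model fitting and comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from depthcue import (
    ConditionSpec,
    CueStrengths,
    MLEParams,
    ObserverKind,
    ScenarioSpec,
    VecSumParams,
    compare_models,
    crossed_design_table,
    default_parameters,
    fit_observer_model,
    generate_scenario,
    predict_combined_line,
    predict_condition,
    predict_match_from_jnds,
    strength_ratio_from_jnds,
)


def _cond(ks, kc, z_s=10.0):
    return ConditionSpec(
        "S", "C", z_s, CueStrengths({"s": ks}), CueStrengths({"c": kc})
    )


class TestPredictCondition:
    def test_vecsum_symmetric_strengths_veridical_pse(self):
        pse, _ = predict_condition(ObserverKind.VECSUM, _cond(0.7, 0.7), VecSumParams(2.0))
        assert pse == pytest.approx(10.0)

    def test_vecsum_closed_form(self):
        pse, jnd = predict_condition(ObserverKind.VECSUM, _cond(0.5, 1.0), VecSumParams(1.0))
        assert pse == pytest.approx(5.0)
        assert jnd == pytest.approx(1.0)

    def test_mle_veridical_pse_pooled_jnd(self):
        cond = _cond(1.0, 1.0)
        params = MLEParams({"s": 1.0, "c": 1.0})
        pse, jnd = predict_condition(ObserverKind.MLE, cond, params)
        assert pse == pytest.approx(10.0)
        assert jnd == pytest.approx(math.sqrt(2))

    def test_zero_comparison_strength_error(self):
        with pytest.raises(ValueError, match="zero"):
            predict_condition(ObserverKind.VECSUM, _cond(1.0, 0.0), VecSumParams(1.0))


class TestCrossedDesignTable:
    classes = {
        "single": CueStrengths({"disparity": 0.8}),
        "combined": CueStrengths({"texture": 0.6, "disparity": 0.8}),
    }

    def test_vecsum_jnd_depends_only_on_comparison(self):
        t = crossed_design_table(ObserverKind.VECSUM, self.classes, VecSumParams(1.0), 10.0)
        assert len(t) == 4
        by_cmp = t.groupby("comparison")["jnd"].nunique()
        assert (by_cmp == 1).all()
        assert t[t["comparison"] == "combined"]["jnd"].iloc[0] == pytest.approx(1.0)
        assert t[t["comparison"] == "single"]["jnd"].iloc[0] == pytest.approx(1.25)

    def test_vecsum_combined_comparison_pse_below_z_s(self):
        t = crossed_design_table(ObserverKind.VECSUM, self.classes, VecSumParams(1.0), 10.0)
        row = t[(t["standard"] == "single") & (t["comparison"] == "combined")]
        assert row["pse"].iloc[0] < 10.0

    def test_mle_all_pses_veridical(self):
        params = MLEParams({"texture": 1.0, "disparity": 1.0})
        t = crossed_design_table(ObserverKind.MLE, self.classes, params, 10.0)
        assert np.allclose(t["pse"], 10.0)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError, match="2 stimulus classes"):
            crossed_design_table(
                ObserverKind.VECSUM, {"only": CueStrengths({"t": 1.0})}, VecSumParams(), 10.0
            )

    def test_crossed_combined_jnd_consistent_with_inverse_square_rule(self):
        """The combined-comparison JND in the table equals the inverse-squares
        combination of the single-cue JNDs (the two routes are one identity)."""
        from depthcue import combined_jnd_from_single

        t = crossed_design_table(ObserverKind.VECSUM, self.classes, VecSumParams(1.0), 10.0)
        jnd_combined = t[t["comparison"] == "combined"]["jnd"].iloc[0]
        singles = [1.0 / 0.6, 1.0 / 0.8]  # sigma_M / k per cue
        assert jnd_combined == pytest.approx(combined_jnd_from_single(singles), rel=1e-12)


class TestMatchingLaw:
    def test_equal_jnds_identity(self):
        assert predict_match_from_jnds(12.0, 1.5, 1.5) == pytest.approx(12.0)

    def test_direct_ratio(self):
        assert predict_match_from_jnds(30.0, 2.0, 1.0) == pytest.approx(15.0)

    def test_invariant_to_common_rescaling(self):
        assert predict_match_from_jnds(10.0, 2.0, 3.0) == pytest.approx(
            predict_match_from_jnds(10.0, 0.2, 0.3)
        )

    def test_chain_reproduces_strength_ratio(self):
        """With JND_i = sigma_M/k_i, the JND-based match prediction equals
        (k1/k2) z1 exactly, for any sigma_M."""
        k1, k2, z1, sigma_M = 0.9, 0.45, 10.0, 3.7
        z2 = predict_match_from_jnds(z1, sigma_M / k1, sigma_M / k2)
        assert z2 == pytest.approx((k1 / k2) * z1, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_match_from_jnds(10.0, 0.0, 1.0)

    def test_strength_ratio_examples(self):
        assert strength_ratio_from_jnds(1.0, 2.0) == pytest.approx(2.0)
        assert strength_ratio_from_jnds(1.5, 1.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            strength_ratio_from_jnds(-1.0, 1.0)


class TestPredictCombinedLine:
    def test_point_prediction_is_norm(self, rng):
        out = predict_combined_line([0.6, 0.8], None, 0, rng)
        assert out["combined_slope"] == pytest.approx(1.0)

    def test_absent_cue_contributes_nothing(self, rng):
        out = predict_combined_line([1.0, 0.0], None, 0, rng)
        assert out["combined_slope"] == pytest.approx(1.0)

    def test_band_and_clipping_warning(self, rng):
        out = predict_combined_line([0.2, 0.3], [0.5, 0.5], 2000, rng)
        assert out["low"] <= out["combined_slope"] <= out["high"]
        assert out["clip_warning"]  # draws frequently negative at these SEs

    def test_needs_two_slopes(self, rng):
        with pytest.raises(ValueError):
            predict_combined_line([1.0], None, 0, rng)


@pytest.fixture(scope="module")
def crossed_trials():
    spec = ScenarioSpec("crossed-single-cue", default_parameters("crossed-single-cue"), seed=42)
    out = {}
    for kind in ObserverKind:
        bundle = generate_scenario(spec, kind)
        out[kind] = pd.concat(bundle.tables.values(), ignore_index=True)
    return out


class TestObserverModelFit:
    def test_vecsum_strength_ratio_recovery(self, crossed_trials):
        fit = fit_observer_model(crossed_trials[ObserverKind.VECSUM], ObserverKind.VECSUM)
        ratio = fit.params["T1"] / fit.params["T2"]
        assert ratio == pytest.approx(2.0, rel=0.10)
        assert fit.loglik < 0

    def test_mle_sigma_ratio_recovery(self, crossed_trials):
        fit = fit_observer_model(crossed_trials[ObserverKind.MLE], ObserverKind.MLE)
        ratio = fit.params["T2"] / fit.params["T1"]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_observer_model(pd.DataFrame(columns=["std_cues"]), ObserverKind.VECSUM)

    def test_single_condition_unidentifiable(self, crossed_trials):
        t = crossed_trials[ObserverKind.VECSUM]
        one = t[t["condition_id"] == t["condition_id"].iloc[0]]
        with pytest.raises(ValueError, match="condition"):
            fit_observer_model(one, ObserverKind.VECSUM)

    def test_generating_model_selected(self, crossed_trials):
        assert compare_models(crossed_trials[ObserverKind.VECSUM]).selected == "vecsum"
        assert compare_models(crossed_trials[ObserverKind.MLE]).selected == "mle"

    def test_tiny_table_reports_low_power_without_crash(self, crossed_trials):
        t = crossed_trials[ObserverKind.VECSUM].groupby("condition_id").head(3)
        result = compare_models(t)
        assert result.low_power
        assert result.selected in ("vecsum", "mle")
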