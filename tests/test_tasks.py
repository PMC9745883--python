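"""Task simulators: constant stimuli, staircase, matching, magnitude estimation."""

import numpy as np
import pytest
from scipy.stats import norm

from depthcue import (
    ConstantStimuliDesign,
    CueStrengths,
    MLEParams,
    ObserverKind,
    Stimulus,
    VecSumParams,
    derive_rng,
    run_constant_stimuli,
    run_magnitude_estimation,
    run_matching,
    run_staircase,
)


def _design(**kw):
    defaults = dict(
        condition_id="c0",
        standard=Stimulus(10.0, CueStrengths({"t": 1.0})),
        comparison_strengths=CueStrengths({"t": 1.0}),
        levels=(8.5, 9.0, 9.5, 10.0, 10.5, 11.0, 11.5),
        trials_per_level=40,
        seed=11,
    )
    defaults.update(kw)
    return ConstantStimuliDesign(**defaults)


class TestConstantStimuli:
    def test_row_count(self, vs_params):
        t = run_constant_stimuli(_design(), ObserverKind.VECSUM, vs_params)
        assert len(t) == 7 * 40
        assert set(t["resp_cmp_deeper"].unique()) <= {0, 1}

    def test_same_seed_identical_bytes(self, vs_params):
        a = run_constant_stimuli(_design(), ObserverKind.VECSUM, vs_params)
        b = run_constant_stimuli(_design(), ObserverKind.VECSUM, vs_params)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_center_level_rate_is_half_at_predicted_pse(self, vs_params):
        """With levels symmetric around (K_s/K_c) z_s, the central level sits
        at the closed-form PSE and draws ~50% comparison-deeper responses."""
        # K_s = 1, K_c = 2 -> PSE = 5
        d = _design(
            comparison_strengths=CueStrengths({"t": 2.0}),
            levels=(4.0, 4.5, 5.0, 5.5, 6.0),
            trials_per_level=4000,
        )
        t = run_constant_stimuli(d, ObserverKind.VECSUM, vs_params)
        center = t[t["z_cmp"] == 5.0]["resp_cmp_deeper"].mean()
        se = 0.5 / np.sqrt(4000)
        assert center == pytest.approx(0.5, abs=3 * se)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            _design(levels=(10.0, 10.0))
        with pytest.raises(ValueError, match="ascending"):
            _design(levels=(11.0, 10.0))
        with pytest.raises(ValueError):
            _design(trials_per_level=0)


class TestStaircase:
    def test_converges_to_70_7_percent_point(self, vs_params):
        """Mean of the last 8 reversal depths tracks PSE + Phi^-1(0.707)*JND
        (the 1-up-2-down convergence point) over replicate staircases."""
        standard = Stimulus(10.0, CueStrengths({"t": 1.0}))
        target = 10.0 + norm.ppf(np.sqrt(0.5)) * 1.0  # ~10.545
        means = []
        for rep in range(200):
            rng = derive_rng(99, "staircase", str(rep))
            res = run_staircase(
                standard, standard.strengths, ObserverKind.VECSUM, vs_params, rng
            )
            assert res.converged
            means.append(np.mean(res.reversal_depths[-8:]))
        assert np.mean(means) == pytest.approx(target, abs=0.2)

    def test_step_halving_sequence(self, vs_params):
        standard = Stimulus(10.0, CueStrengths({"t": 1.0}))
        res = run_staircase(
            standard,
            standard.strengths,
            ObserverKind.VECSUM,
            vs_params,
            derive_rng(1, "halving"),
            initial_step=1.6,
        )
        s = res.step_sizes
        assert s[0] == 1.6 and s[1] == 0.8 and s[2] == 0.4
        assert all(v == 0.2 for v in s[3:])

    def test_no_reversal_flagged_incomplete(self, vs_params):
        standard = Stimulus(10.0, CueStrengths({"t": 1.0}))
        res = run_staircase(
            standard,
            standard.strengths,
            ObserverKind.VECSUM,
            vs_params,
            derive_rng(2, "incomplete"),
            start=200.0,  # huge offset: always "deeper", track only descends
            initial_step=0.01,
            max_trials=20,
        )
        assert not res.converged
        assert len(res.trials) == 20

    def test_unknown_rule_rejected(self, vs_params):
        standard = Stimulus(10.0, CueStrengths({"t": 1.0}))
        with pytest.raises(ValueError, match="rule"):
            run_staircase(
                standard, standard.strengths, ObserverKind.VECSUM, vs_params,
                derive_rng(0, "x"), rule="3down1up",
            )


class TestMatching:
    def test_equal_strengths_noise_free_is_identity(self, vs_params, rng):
        standard = Stimulus(10.0, CueStrengths({"m": 0.7}))
        res = run_matching(
            standard, CueStrengths({"d": 0.7}), ObserverKind.VECSUM, vs_params,
            5, rng, adjustment_noise_sd=0.0,
        )
        assert res.z2 == pytest.approx(10.0)

    def test_strength_ratio_sets_match_point(self, vs_params, rng):
        standard = Stimulus(10.0, CueStrengths({"m": 0.8}))
        res = run_matching(
            standard, CueStrengths({"d": 0.4}), ObserverKind.VECSUM, vs_params,
            1, rng, adjustment_noise_sd=0.0,
        )
        assert res.z2 == pytest.approx(20.0)

    def test_mle_matching_is_unbiased(self, rng):
        standard = Stimulus(10.0, CueStrengths({"m": 1.0}))
        params = MLEParams({"m": 1.0, "d": 1.5})
        res = run_matching(
            standard, CueStrengths({"d": 1.0}), ObserverKind.MLE, params, 1000, rng
        )
        sd = np.sqrt(1.0 + 1.5**2 + 0.5**2)  # estimation + adjustment noise
        assert res.z2 == pytest.approx(10.0, abs=3 * sd / np.sqrt(1000))

    def test_zero_comparison_strength_error(self, vs_params, rng):
        standard = Stimulus(10.0, CueStrengths({"m": 1.0}))
        with pytest.raises(ValueError, match="zero"):
            run_matching(
                standard, CueStrengths({"d": 0.0}), ObserverKind.VECSUM, vs_params, 5, rng
            )


class TestMagnitudeEstimation:
    def test_noiseless_judgments_on_the_line(self, vs_params, rng):
        stimuli = [Stimulus(z, CueStrengths({"t": 1.3})) for z in (1, 2, 3, 4, 5)]
        t = run_magnitude_estimation(stimuli, ObserverKind.VECSUM, vs_params, 0.0, rng)
        assert np.allclose(t["judged_depth"], 1.3 * t["z"])

    def test_regression_recovers_strength(self, vs_params, rng):
        stimuli = [Stimulus(z, CueStrengths({"t": 0.7})) for z in (1, 2, 3, 4, 5)]
        t = run_magnitude_estimation(
            stimuli, ObserverKind.VECSUM, vs_params, 0.3, rng, trials_per_stimulus=200
        )
        slope, _ = np.polyfit(t["z"], t["judged_depth"], 1)
        se = 0.3 / np.sqrt(((t["z"] - t["z"].mean()) ** 2).sum())
        assert slope == pytest.approx(0.7, abs=3 * se)

    def test_combined_slope_exceeds_singles(self, vs_params, rng):
        zs = (1.0, 2.0, 3.0)
        combined = CueStrengths({"t": 0.6, "d": 0.8})
        slopes = {}
        for label, cs in [("t", CueStrengths({"t": 0.6})), ("d", CueStrengths({"d": 0.8})), ("c", combined)]:
            t = run_magnitude_estimation(
                [Stimulus(z, cs) for z in zs], ObserverKind.VECSUM, vs_params, 0.0, rng
            )
            slopes[label], _ = np.polyfit(t["z"], t["judged_depth"], 1)
        assert slopes["c"] == pytest.approx(1.0)
        assert slopes["c"] > slopes["t"] and slopes["c"] > slopes["d"]

    def test_negative_noise_rejected(self, vs_params, rng):
        with pytest.raises(ValueError):
            run_magnitude_estimation(
                [Stimulus(1.0, CueStrengths({"t": 1.0}))],
                ObserverKind.VECSUM, vs_params, -0.1, rng,
            )
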