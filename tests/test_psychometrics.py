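"""Psychometric fitting and simulated behavioural designs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from timefuse import (
    ExperimentConfig,
    fit_psychometric,
    make_change_estimator,
    run_classification,
    run_staircase,
    simulate_2afc_trial,
)


def synth_trials(mu, width, lapse, levels, n_per_level, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for x in levels:
        p = lapse / 2 + (1 - lapse) * norm.cdf((x - mu) / width)
        rows += [(x, int(rng.random() < p)) for _ in range(n_per_level)]
    return pd.DataFrame(rows, columns=["level", "response"])


def noisy_clock(noise_cv=0.15, bias=0.0):
    """Cheap surrogate observer: relative-noise estimates, optional bias."""

    def estimator(tau, speed, rng):
        return tau * speed * np.exp(rng.normal(bias, noise_cv))

    return estimator


class TestFitPsychometric:
    def test_parameter_recovery_on_self_generated_data(self):
        trials = synth_trials(1.0, 0.2, 0.02, np.linspace(0.4, 1.6, 9), 400, 1)
        fit = fit_psychometric(trials)
        assert fit.location == pytest.approx(1.0, abs=0.05)
        assert fit.width == pytest.approx(0.2, abs=0.04)
        assert fit.lapse < 0.06
        assert fit.identified

    def test_probability_half_at_location_without_lapse(self):
        trials = synth_trials(0.0, 0.3, 0.0, np.linspace(-1, 1, 7), 500, 2)
        fit = fit_psychometric(trials)
        assert fit.predict(fit.location) == pytest.approx(0.5, abs=0.02)

    def test_variability_is_width_times_sqrt_two_pi(self):
        trials = synth_trials(1.0, 0.25, 0.0, np.linspace(0.5, 1.5, 5), 100, 3)
        fit = fit_psychometric(trials)
        assert fit.variability == pytest.approx(
            fit.width * np.sqrt(2 * np.pi), rel=1e-12
        )

    def test_invariant_to_order_and_duplication(self):
        trials = synth_trials(1.0, 0.2, 0.02, np.linspace(0.4, 1.6, 7), 150, 4)
        shuffled = trials.sample(frac=1.0, random_state=0)
        doubled = pd.concat([trials, trials], ignore_index=True)
        base = fit_psychometric(trials)
        for other in (fit_psychometric(shuffled), fit_psychometric(doubled)):
            assert other.location == pytest.approx(base.location, abs=1e-5)
            assert other.width == pytest.approx(base.width, rel=1e-4)

    def test_complete_separation_flagged(self):
        rows = [(0.0, 0)] * 50 + [(1.0, 1)] * 50
        fit = fit_psychometric(pd.DataFrame(rows, columns=["level", "response"]))
        assert not fit.identified
        assert np.isfinite(fit.width)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric(pd.DataFrame({"level": [1.0], "response": [1]}))
        with pytest.raises(ValueError):
            fit_psychometric(
                pd.DataFrame({"level": [0.0, 1.0], "response": [0, 2]})
            )


class TestSimulate2afc:
    def test_symmetric_observer_chooses_second_half_the_time(self):
        est = noisy_clock()
        picks = [
            simulate_2afc_trial(est, 0.6, 0.6, (1, 1), np.random.default_rng([5, i]))
            for i in range(2000)
        ]
        assert np.mean(picks) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))

    def test_much_longer_second_always_chosen(self):
        est = noisy_clock()
        picks = [
            simulate_2afc_trial(est, 0.3, 3.0, (1, 1), np.random.default_rng([6, i]))
            for i in range(200)
        ]
        assert np.mean(picks) == 1.0

    def test_playback_speed_biases_choice_direction(self):
        # rapid playback inflates apparent duration: same physical length,
        # rapid-second is called longer more often than slow-second
        cfg = ExperimentConfig()
        est = make_change_estimator(cfg, fused=True)
        rapid2 = [
            simulate_2afc_trial(est, 0.6, 0.6, (0.5, 2.0), np.random.default_rng([7, i]))
            for i in range(120)
        ]
        slow2 = [
            simulate_2afc_trial(est, 0.6, 0.6, (2.0, 0.5), np.random.default_rng([8, i]))
            for i in range(120)
        ]
        assert np.mean(rapid2) > np.mean(slow2)


class TestStaircase:
    def test_recovers_injected_bias_with_paired_starts(self):
        est = noisy_clock()
        def paired_pse(bias, tag):
            pses = []
            for r in range(10):
                pair = []
                for sign, s in ((1, 0), (-1, 1)):
                    st = run_staircase(
                        est,
                        ordering="equal",
                        start_delta=sign * 0.2,
                        seed=np.random.default_rng([tag, r, s]),
                        bias_second_s=bias,
                    )
                    pair.append(st.pse)
                pses.append(np.mean(pair))
            return np.array(pses)

        unbiased = paired_pse(0.0, 21)
        biased = paired_pse(0.05, 22)
        diff = biased.mean() - unbiased.mean()
        assert -0.095 < diff < -0.015  # compensates the +50 ms injection
        assert abs(unbiased.mean()) < 0.04

    def test_interleaving_equivalent_to_separate_runs(self):
        # memoryless observer: two staircases interleave without interacting,
        # so independent runs estimate the same PSE within scatter
        est = noisy_clock()
        pses = [
            run_staircase(
                est, "equal", seed=np.random.default_rng([23, r])
            ).pse
            for r in range(12)
        ]
        first, second = np.array(pses[:6]), np.array(pses[6:])
        pooled_sd = np.std(pses)
        assert abs(first.mean() - second.mean()) < 3 * pooled_sd

    def test_unknown_ordering_rejected(self):
        with pytest.raises(ValueError):
            run_staircase(noisy_clock(), ordering="sideways")


class TestClassification:
    def test_weber_flat_for_scale_invariant_observer(self):
        est = noisy_clock()
        mults = np.array([0.55, 0.7, 0.85, 1.0, 1.15, 1.3, 1.45])
        _, _, rv1 = run_classification(est, 0.575 * mults, 400, seed=9)
        _, _, rv2 = run_classification(est, 1.15 * mults, 400, seed=9)
        assert rv1 == pytest.approx(rv2, rel=0.25)

    def test_single_duration_block_rejected(self):
        with pytest.raises(ValueError):
            run_classification(noisy_clock(), [1.0], 50, seed=0)

    def test_linear_axis_divides_by_block_mean(self):
        est = noisy_clock()
        mults = np.array([0.6, 0.8, 1.0, 1.2, 1.4])
        _, fit_r, rv_r = run_classification(
            est, 2.0 * mults, 300, seed=3, axis="ratio"
        )
        _, fit_l, rv_l = run_classification(
            est, 2.0 * mults, 300, seed=3, axis="linear"
        )
        assert rv_l == pytest.approx(fit_l.variability / 2.0, rel=1e-12)
        assert rv_r == pytest.approx(rv_l, rel=0.05)
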