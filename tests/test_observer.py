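"""Snapshot schedules, likelihood curves and the duration estimator."""

import numpy as np
import pytest

from timefuse import (
    KernelSpec,
    LikelihoodCurve,
    combine_streams,
    draw_schedule,
    gp_log_density,
    make_tau_grid,
    ml_estimate,
    observe,
    stream_likelihood,
    trial_likelihood,
)
from timefuse.observer import SnapshotSchedule


class TestLikelihoodCurve:
    def test_from_weights_normalizes(self):
        c = LikelihoodCurve.from_weights(np.array([1.0, 2.0]), [3.0, 1.0])
        assert c.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodCurve(np.array([2.0, 1.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            LikelihoodCurve(np.array([1.0, 2.0]), np.array([0.9, 0.9]))
        with pytest.raises(ValueError):
            LikelihoodCurve.from_weights(np.array([1.0, 2.0]), [0.0, 0.0])

    def test_log_weights_handle_large_negatives(self):
        # normalization must subtract the max before exponentiating
        c = LikelihoodCurve.from_log_weights(
            np.array([1.0, 2.0, 3.0]), np.array([-5000.0, -5001.0, -5100.0])
        )
        assert np.isfinite(c.density).all()
        assert c.density[0] > c.density[1] > c.density[2]


class TestDrawSchedule:
    def test_anchors_always_present(self):
        for s in range(50):
            sched = draw_schedule(3.0, seed=s)
            times = sched.retained_times
            assert times[0] == 0.0 and times[-1] == 3.0
            assert np.all(np.diff(times) > 0)

    def test_cap_limits_retained_snapshots(self):
        for s in range(200):
            assert draw_schedule(50.0, cap=4, seed=s).n_snapshots <= 4

    def test_zero_intermediate_probability_matches_poisson(self):
        # short interval: P(no arrivals) = exp(-rate * tau)
        tau, n = 0.1, 10_000
        zero = sum(
            draw_schedule(tau, seed=s).n_intermediates == 0 for s in range(n)
        )
        p = np.exp(-tau)
        se = np.sqrt(p * (1 - p) / n)
        assert zero / n == pytest.approx(p, abs=3 * se)

    def test_cap_below_two_rejected(self):
        with pytest.raises(ValueError):
            draw_schedule(1.0, cap=1)

    def test_schedule_invariants_enforced(self):
        with pytest.raises(ValueError):
            SnapshotSchedule(5.0, np.array([6.0]))  # outside (0, tau)
        with pytest.raises(ValueError):
            SnapshotSchedule(5.0, np.array([1.0, 2.0, 3.0]), cap=4)  # over cap


class TestObserve:
    def test_anchor_only_schedule_gives_two_values_per_stream(self, kernel):
        sched = SnapshotSchedule(5.0, np.array([]), cap=2)
        snaps = observe(sched, kernel, n_streams=7, seed=0)
        assert snaps.values.shape == (7, 2)

    def test_anchor_pair_correlation_matches_kernel(self, kernel):
        # corr(y(0), y(100)) = exp(-1) / (1 + sigma^2)
        sched = SnapshotSchedule(100.0, np.array([]), cap=2)
        snaps = observe(sched, kernel, n_streams=10_000, seed=1)
        r = np.corrcoef(snaps.values[:, 0], snaps.values[:, 1])[0, 1]
        expect = np.exp(-1.0) / 1.01
        assert r == pytest.approx(expect, abs=3.0 / np.sqrt(10_000))


class TestStreamLikelihood:
    def test_normalization_contract(self, kernel, rng):
        curve = stream_likelihood(
            rng.standard_normal(2), 0, make_tau_grid(5.0), kernel
        )
        assert curve.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_anchors_favor_short_durations(self, kernel):
        # zero change between anchors: closed-form bivariate densities say
        # tau = 1 s is far more probable than tau = 1000 s
        curve = stream_likelihood(
            np.zeros(2), 0, np.array([1.0, 1000.0]), kernel
        )
        assert curve.density[0] > curve.density[1]
        # cross-check the ratio against the closed form
        def biv(tau):
            return gp_log_density(np.zeros(2), np.array([0.0, tau]), kernel)

        expect = np.exp(biv(1.0) - biv(1000.0))
        got = curve.density[0] / curve.density[1]
        assert got == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_anchors_only_matches_dense_oracle(self, kernel, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal(2)
        grid = np.geomspace(0.2, 150.0, 60)
        curve = stream_likelihood(vals, 0, grid, kernel)
        logd = np.array(
            [gp_log_density(vals, np.array([0.0, t]), kernel) for t in grid]
        )
        expect = np.exp(logd - logd.max())
        expect /= expect.sum()
        assert np.max(np.abs(curve.density - expect)) < 1e-10

    def test_wrong_value_count_rejected(self, kernel):
        with pytest.raises(ValueError):
            stream_likelihood(np.zeros(3), 0, make_tau_grid(1.0), kernel)

    def test_empty_grid_rejected(self, kernel):
        with pytest.raises(ValueError):
            stream_likelihood(np.zeros(2), 0, np.array([]), kernel)

    def test_monte_carlo_marginalization_converges(self, kernel):
        # doubling the draw count at 2000 barely moves the curve
        sched = draw_schedule(5.0, seed=3)
        assert sched.n_intermediates == 2
        snaps = observe(sched, kernel, 12, seed=3)
        grid = make_tau_grid(5.0)
        a = trial_likelihood(snaps, grid, kernel, mc_draws=2000, seed=10)
        b = trial_likelihood(snaps, grid, kernel, mc_draws=4000, seed=11)
        assert np.max(np.abs(a.density - b.density)) < 0.01 * a.density.max()

    def test_joint_trial_equals_product_of_streams(self, kernel):
        sched = draw_schedule(5.0, seed=4)
        snaps = observe(sched, kernel, 5, seed=4)
        grid = make_tau_grid(5.0)
        joint = trial_likelihood(snaps, grid, kernel, mc_draws=64, seed=9)
        per_stream = [
            stream_likelihood(
                snaps.values[i],
                snaps.n_intermediates,
                grid,
                kernel,
                mc_draws=64,
                seed=9,
                capacity=sched.cap - 2,
            )
            for i in range(5)
        ]
        assert np.allclose(
            joint.density, combine_streams(per_stream).density, atol=1e-12
        )

    def test_uniform_prior_option_differs_when_saturated(self, kernel):
        sched = draw_schedule(10.0, seed=5)
        assert sched.n_intermediates == 2
        snaps = observe(sched, kernel, 12, seed=5)
        grid = make_tau_grid(10.0)
        forgetting = trial_likelihood(snaps, grid, kernel, seed=2)
        uniform = trial_likelihood(
            snaps, grid, kernel, seed=2, intermediate_prior="uniform"
        )
        assert not np.allclose(forgetting.density, uniform.density)


class TestCombineStreams:
    def test_single_curve_unchanged(self):
        c = LikelihoodCurve.from_weights(np.array([1.0, 2.0]), [0.3, 0.7])
        assert np.allclose(combine_streams([c]).density, c.density)

    def test_uniform_curve_is_multiplicative_identity(self):
        grid = np.geomspace(0.1, 10, 50)
        c = LikelihoodCurve.from_weights(grid, np.exp(-((np.log(grid)) ** 2)))
        u = LikelihoodCurve.uniform(grid)
        assert np.allclose(
            combine_streams([c, u]).density, c.density, atol=1e-12
        )

    def test_order_invariance(self, kernel, rng):
        grid = make_tau_grid(2.0, n=40)
        curves = [
            stream_likelihood(rng.standard_normal(2), 0, grid, kernel)
            for _ in range(4)
        ]
        a = combine_streams(curves)
        b = combine_streams(curves[::-1])
        assert np.allclose(a.density, b.density, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = LikelihoodCurve.uniform(np.array([1.0, 2.0]))
        b = LikelihoodCurve.uniform(np.array([1.0, 3.0]))
        with pytest.raises(ValueError):
            combine_streams([a, b])

    def test_combination_is_sharper_than_components(self, kernel):
        # 12 streams together constrain elapsed time more than any one alone
        sched = draw_schedule(5.0, seed=6)
        snaps = observe(sched, kernel, 12, seed=6)
        grid = make_tau_grid(5.0)
        singles = [
            stream_likelihood(
                snaps.values[i], snaps.n_intermediates, grid, kernel, seed=1
            )
            for i in range(12)
        ]
        combined = combine_streams(singles)
        assert all(combined.entropy() <= s.entropy() for s in singles)


class TestMlEstimate:
    def test_single_spike(self):
        grid = np.array([1.0, 7.0, 9.0])
        c = LikelihoodCurve(grid, np.array([0.0, 1.0, 0.0]))
        assert ml_estimate(c) == 7.0

    def test_uniform_ties_break_to_smallest(self):
        c = LikelihoodCurve.uniform(np.array([2.0, 5.0, 11.0]))
        assert ml_estimate(c) == 2.0
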