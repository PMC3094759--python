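"""Power-law noise movies and pixel-stream extraction."""

import numpy as np
import pytest

from timefuse import (
    ExperimentConfig,
    KernelSpec,
    MovieSpec,
    belief_curve,
    draw_peak,
    fuse,
    generate_movie,
    make_tau_grid,
    map_estimate,
    pixel_streams,
    rescale_kernel,
    save_frames_pgm,
    trial_likelihood,
)
from timefuse.observer import SnapshotSchedule, SnapshotSet
from timefuse.experiments import substream


class TestGenerateMovie:
    def test_static_mode_repeats_one_frame(self):
        mov = generate_movie(MovieSpec(size=16, n_frames=6, mode="static", seed=1))
        assert mov.shape == (6, 16, 16)
        assert all(np.array_equal(mov[0], f) for f in mov)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MovieSpec(n_frames=0)
        with pytest.raises(ValueError):
            MovieSpec(mode="frozen")
        with pytest.raises(ValueError):
            MovieSpec(playback_speed=0.0)

    def test_reproducible_and_seed_sensitive(self):
        a = generate_movie(MovieSpec(size=16, n_frames=3, seed=4))
        b = generate_movie(MovieSpec(size=16, n_frames=3, seed=4))
        c = generate_movie(MovieSpec(size=16, n_frames=3, seed=5))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_pixel_marginals_standard_gaussian(self):
        # average over independent movies: zero mean, unit variance
        samples = np.concatenate(
            [
                generate_movie(MovieSpec(size=24, n_frames=2, seed=s)).ravel()
                for s in range(40)
            ]
        )
        assert abs(samples.mean()) < 0.05
        assert samples.var() == pytest.approx(1.0, abs=0.1)

    def test_pixel_trace_autocorrelation_matches_temporal_kernel(self):
        k = KernelSpec(decay_rate=1.0)
        spec = MovieSpec(
            size=32, n_frames=600, frame_interval=0.1, temporal_kernel=k, seed=2
        )
        vals, _ = pixel_streams(generate_movie(spec), 6, 10.0, seed=3)
        for lag_s in (0.1, 1.0):
            lag = int(round(lag_s / spec.frame_interval))
            r = np.mean(
                [np.corrcoef(v[:-lag], v[lag:])[0, 1] for v in vals]
            )
            assert r == pytest.approx(np.exp(-lag_s), abs=0.08)

    def test_playback_speed_shifts_autocorrelation(self):
        # speed-2 autocorrelation at lag L = natural autocorrelation at 2L
        k = KernelSpec(decay_rate=1.0)
        def mean_ac(speed, lag, seed):
            spec = MovieSpec(
                size=24,
                n_frames=500,
                frame_interval=0.1,
                temporal_kernel=k,
                playback_speed=speed,
                seed=seed,
            )
            vals, _ = pixel_streams(generate_movie(spec), 5, 8.0, seed=seed)
            return np.mean(
                [np.corrcoef(v[:-lag], v[lag:])[0, 1] for v in vals]
            )

        fast = np.mean([mean_ac(2.0, 3, s) for s in range(4)])
        slow = np.mean([mean_ac(1.0, 6, s + 10) for s in range(4)])
        assert fast == pytest.approx(slow, abs=0.08)
        assert fast == pytest.approx(np.exp(-0.6), abs=0.08)

    def test_spatial_amplitude_spectrum_slope(self):
        mov = generate_movie(MovieSpec(size=64, n_frames=30, seed=6))
        amps = np.abs(np.fft.fft2(mov, axes=(1, 2))).mean(axis=0)
        f = np.fft.fftfreq(64)
        fmag = np.hypot(f[:, None], f[None, :]).ravel()
        band = (fmag > 0.05) & (fmag < 0.4)
        slope = np.polyfit(np.log(fmag[band]), np.log(amps.ravel()[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)


class TestPixelStreams:
    def test_respects_minimum_separation(self):
        mov = generate_movie(MovieSpec(size=32, n_frames=2, seed=0))
        _, pos = pixel_streams(mov, 8, min_separation=8.0, seed=1)
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.hypot(*(pos[i] - pos[j])) >= 8.0

    def test_default_stream_count_matches_observer(self):
        mov = generate_movie(MovieSpec(size=64, n_frames=2, seed=0))
        vals, _ = pixel_streams(mov, seed=1)
        assert vals.shape[0] == 12

    def test_static_movie_gives_constant_streams(self):
        mov = generate_movie(MovieSpec(size=16, n_frames=5, mode="static", seed=2))
        vals, _ = pixel_streams(mov, 3, 4.0, seed=0)
        assert np.all(vals.std(axis=1) < 1e-12)

    def test_infeasible_separation_rejected(self):
        mov = generate_movie(MovieSpec(size=8, n_frames=2, seed=0))
        with pytest.raises(ValueError):
            pixel_streams(mov, 20, min_separation=6.0, seed=0)

    def test_separated_streams_weakly_correlated(self):
        # 1/f^2 spatial power retains some long-range correlation; check the
        # sample cross-correlations stay modest at half-frame separation
        mov = generate_movie(
            MovieSpec(size=64, n_frames=300, frame_interval=0.1,
                      temporal_kernel=KernelSpec(decay_rate=1.0), seed=7)
        )
        vals, _ = pixel_streams(mov, 6, min_separation=24.0, seed=8)
        cc = [
            np.corrcoef(vals[i], vals[j])[0, 1]
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert np.mean(np.abs(cc)) < 0.25


class TestSaveFrames:
    def test_writes_ascii_pgm(self, tmp_path):
        mov = generate_movie(MovieSpec(size=8, n_frames=2, seed=1))
        paths = save_frames_pgm(mov, str(tmp_path))
        assert len(paths) == 2
        head = open(paths[0]).read().splitlines()
        assert head[0] == "P2" and head[1] == "8 8"


class TestEndToEndObserverDemo:
    def test_playback_speed_bias_direction_from_pixel_streams(self):
        # feed the snapshot observer movie pixel streams: rapid playback
        # must inflate apparent duration relative to slow playback
        cfg = ExperimentConfig()
        dt = 0.05
        tau = 1.0
        n_frames = int(tau / dt) + 1

        def fused_estimate(speed, trial):
            rng = substream(99, "demo", int(speed * 10), trial)
            spec = MovieSpec(
                size=32,
                n_frames=n_frames,
                frame_interval=dt,
                temporal_kernel=cfg.kernel,
                playback_speed=speed,
                seed=int(rng.integers(2**31)),
            )
            vals, _ = pixel_streams(generate_movie(spec), 12, 8.0, rng)
            # snapshots at frames 0, 7, 14 and 20: anchors plus two
            # intermediates whose times the estimator marginalizes
            frames = [0, 7, 14, n_frames - 1]
            sched = SnapshotSchedule(
                tau, np.array([frames[1] * dt, frames[2] * dt]), cap=4
            )
            snaps = SnapshotSet(vals[:, frames], sched)
            grid = make_tau_grid(tau)
            sensory = trial_likelihood(snaps, grid, cfg.kernel, seed=rng)
            internal = belief_curve(
                draw_peak(tau, cfg.internal, rng), cfg.internal, grid
            )
            return map_estimate(fuse(sensory, internal))

        slow = np.mean([fused_estimate(0.5, t) for t in range(150)])
        fast = np.mean([fused_estimate(2.0, t) for t in range(150)])
        assert fast > slow
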