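"""Rival event-counting model of stimulus-derived timing.

Instead of decoding the amount of *change* between snapshots, an observer
might count discrete "events" in the stimulus — here, each time a 1/f^2
Gaussian-process stream crosses a threshold level upward — and judge
duration from the count.  Because the variance of the event count grows
linearly with time while its mean does too, the relative variability of a
count-based duration estimate shrinks as 1/sqrt(tau): a *sub-Weberian*
signature that distinguishes this scheme behaviourally from the change-based
observer, whose estimates scale with the interval.

The counting observer is assumed to know the true statistics of event
occurrence.  This is realised empirically: Gaussian processes are simulated
over a range of durations under the same generative settings used at test
time, and the joint frequency table of (duration bin, event count) is
tallied.  Normalizing a constant-count slice of the table gives the sensory
belief P(tau | N_e), which fuses with the internal estimate exactly as in
the change model.

Threshold crossings of an exponential-kernel process are sensitive to the
simulation step (the continuous-time process is non-differentiable, so the
discrete step acts as the event detector's temporal resolution); the step is
therefore an explicit, recorded model parameter.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .observer import LikelihoodCurve

__all__ = [
    "CountTable",
    "detect_events",
    "simulate_ou_paths",
    "count_events_for_duration",
    "build_count_table",
    "count_likelihood",
    "DEFAULT_THRESHOLD",
    "DEFAULT_FINE_DT",
]

logger = logging.getLogger("timefuse")

#: Default event-detection threshold, in units of the process sd.
DEFAULT_THRESHOLD = 1.0
#: Default simulation step for event detection, seconds.
DEFAULT_FINE_DT = 0.05


def detect_events(values: np.ndarray, threshold: float) -> int | np.ndarray:
    """Number of upward threshold crossings in a uniformly sampled sequence.

    Counts indices i with value[i-1] < threshold <= value[i], along the last
    axis.  Returns an int for 1-D input, an integer array otherwise.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detect crossings")
    up = (values[..., :-1] < threshold) & (values[..., 1:] >= threshold)
    counts = np.count_nonzero(up, axis=-1)
    return int(counts) if values.ndim == 1 else counts


def simulate_ou_paths(
    kernel: KernelSpec,
    duration: float,
    fine_dt: float,
    n_paths: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent stationary OU sample paths on a uniform fine grid.

    Exact transition sampling: x_{i+1} = rho x_i + sqrt(1 - rho^2) w with
    rho = exp(-lambda dt) and stationary unit variance.  Measurement noise is
    *not* added: discrete crossing counts of white noise would reflect the
    noise, not the stream.  Shape (n_paths, n_steps + 1).
    """
    if not duration > 0 or not fine_dt > 0:
        raise ValueError("duration and fine_dt must be > 0")
    n_steps = max(int(round(duration / fine_dt)), 1)
    rho = float(np.exp(-kernel.decay_rate * fine_dt))
    innov_sd = float(np.sqrt(1.0 - rho**2))
    x = np.empty((n_paths, n_steps + 1))
    x[:, 0] = rng.standard_normal(n_paths)
    shocks = rng.standard_normal((n_paths, n_steps))
    for i in range(n_steps):
        x[:, i + 1] = rho * x[:, i] + innov_sd * shocks[:, i]
    return x


def count_events_for_duration(
    kernel: KernelSpec,
    duration: float,
    n_streams: int,
    threshold: float,
    fine_dt: float,
    rng: np.random.Generator,
    n_trials: int = 1,
) -> np.ndarray:
    """Total upward crossings over ``n_streams`` streams, per trial.

    Streams the OU recursion step by step, so memory stays O(paths) however
    long the interval (a table build can involve tens of thousands of paths
    over hundreds of steps).
    """
    if not duration > 0 or not fine_dt > 0:
        raise ValueError("duration and fine_dt must be > 0")
    n_paths = n_trials * n_streams
    n_steps = max(int(round(duration / fine_dt)), 1)
    rho = float(np.exp(-kernel.decay_rate * fine_dt))
    innov_sd = float(np.sqrt(1.0 - rho**2))
    x = rng.standard_normal(n_paths)
    crossings = np.zeros(n_paths, dtype=np.int64)
    for _ in range(n_steps):
        x_new = rho * x + innov_sd * rng.standard_normal(n_paths)
        crossings += (x < threshold) & (x_new >= threshold)
        x = x_new
    return crossings.reshape(n_trials, n_streams).sum(axis=1)


@dataclass(frozen=True)
class CountTable:
    """Empirical joint frequency table over (duration bin, event count).

    ``frequencies[b, c]`` is the number of simulated trials whose duration
    fell in bin b and produced c events (summed over streams).  Reproducible
    from the recorded (seed, bins, reps, threshold, fine_dt, streams, kernel).
    """

    duration_bins: np.ndarray  # bin edges, seconds, length n_bins + 1
    frequencies: np.ndarray  # (n_bins, max_count + 1) non-negative ints
    threshold: float
    fine_dt: float
    reps_per_bin: int
    n_streams: int
    seed: int
    kernel: KernelSpec = field(repr=False, default=KernelSpec())

    def __post_init__(self) -> None:
        edges = np.asarray(self.duration_bins, dtype=float)
        freq = np.asarray(self.frequencies)
        if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("duration_bins must be increasing edges")
        if freq.ndim != 2 or freq.shape[0] != edges.size - 1:
            raise ValueError("frequencies must be (n_bins, n_counts)")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        object.__setattr__(self, "duration_bins", edges)
        object.__setattr__(self, "frequencies", freq.astype(np.int64))

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric bin midpoints (bins are laid out logarithmically)."""
        e = self.duration_bins
        return np.sqrt(e[:-1] * e[1:])

    @property
    def max_count(self) -> int:
        return self.frequencies.shape[1] - 1

    def to_csv(self) -> str:
        """Delimited export with a header recording the build settings."""
        buf = io.StringIO()
        buf.write(
            f"# seed={self.seed} threshold={self.threshold} "
            f"fine_dt={self.fine_dt} reps_per_bin={self.reps_per_bin} "
            f"n_streams={self.n_streams} "
            f"lambda={self.kernel.decay_rate} sigma={self.kernel.noise_sd}\n"
        )
        buf.write("# bin_edges=" + ",".join(map(str, self.duration_bins)) + "\n")
        df = pd.DataFrame(
            self.frequencies,
            index=pd.Index(self.midpoints, name="duration_mid_s"),
            columns=[f"count_{c}" for c in range(self.max_count + 1)],
        )
        df.to_csv(buf)
        return buf.getvalue()


def build_count_table(
    kernel: KernelSpec,
    duration_bins: np.ndarray,
    reps_per_bin: int = 200,
    threshold: float = DEFAULT_THRESHOLD,
    fine_dt: float = DEFAULT_FINE_DT,
    seed: int = 0,
    n_streams: int = 12,
) -> CountTable:
    """Tally event counts from simulated streams across duration bins.

    For each bin midpoint, ``reps_per_bin`` independent sets of ``n_streams``
    streams are simulated and their summed crossing counts histogrammed.  The
    count axis auto-extends to the largest observed count.  Deterministic
    given ``seed``.
    """
    edges = np.asarray(duration_bins, dtype=float)
    if reps_per_bin < 1:
        raise ValueError("reps_per_bin must be >= 1")
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("duration_bins must be increasing edges")
    rng = np.random.default_rng(seed)
    mids = np.sqrt(edges[:-1] * edges[1:])
    per_bin_counts = []
    max_count = 0
    for mid in mids:
        counts = count_events_for_duration(
            kernel, mid, n_streams, threshold, fine_dt, rng, n_trials=reps_per_bin
        )
        max_count = max(max_count, int(counts.max()))
        per_bin_counts.append(counts)
    freq = np.zeros((mids.size, max_count + 1), dtype=np.int64)
    for b, counts in enumerate(per_bin_counts):
        np.add.at(freq[b], counts, 1)
    return CountTable(
        duration_bins=edges,
        frequencies=freq,
        threshold=threshold,
        fine_dt=fine_dt,
        reps_per_bin=reps_per_bin,
        n_streams=n_streams,
        seed=seed,
        kernel=kernel,
    )


def count_likelihood(
    observed_count: int, table: CountTable, tau_grid: np.ndarray
) -> LikelihoodCurve:
    """P(tau | N_e): a normalized constant-count slice of the table.

    The observed count's column is converted to a density per second over
    the duration bins and Laplace-smoothed with one pseudo-trial spread
    uniformly over the table's span (a constant density floor, so empty
    cells carry no zero-density pathologies and narrow bins gain no spurious
    mass), then linearly interpolated onto ``tau_grid`` (zero outside the
    table's span) and normalized.
    """
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    if observed_count > table.max_count:
        raise ValueError(
            f"count {observed_count} exceeds the table's maximum "
            f"{table.max_count} with zero total frequency"
        )
    tau_grid = np.asarray(tau_grid, dtype=float)
    column = table.frequencies[:, observed_count].astype(float)
    widths = np.diff(table.duration_bins)
    span = table.duration_bins[-1] - table.duration_bins[0]
    density_mid = column / widths + 1.0 / span  # per-second, smoothed
    density = np.interp(
        tau_grid, table.midpoints, density_mid, left=0.0, right=0.0
    )
    if not density.sum() > 0:
        raise ValueError(
            "degenerate curve: tau grid does not overlap the table's span"
        )
    return LikelihoodCurve.from_weights(tau_grid, density)
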