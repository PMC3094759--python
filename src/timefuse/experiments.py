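"""Trial-level simulation harnesses for the timing models.

Four harnesses exercise the observers under the conditions of the behavioural
designs and export tidy trial records plus grouped summaries:

``bias``
    1-second noise stimuli whose generative correlation timescale is scaled
    by a playback-speed factor while the observer keeps natural expectations.
    Faster playback means more change per unit time, hence overestimation.
``precision``
    Matched internal-only vs. fused trials (shared internal-belief draws):
    fusing the sensory likelihood with the internal belief narrows the
    across-trial spread of estimates.
``weber``
    Relative variability (sd of estimates / mean) versus true duration for
    the change-based and count-based observers, fused and purely sensory:
    the change model is Weberian (flat), the counting model sub-Weberian
    (falling as 1/sqrt(tau)).
``scalar``
    Distributions of purely sensory ML estimates, normalized by the true
    duration, superimpose across durations (scale invariance), for variant
    kernels and snapshot caps.

Every harness is exactly reproducible from (config, master seed): each trial
consumes an independent substream derived from the master seed and the trial
coordinates, so results do not depend on execution order and matched
conditions can share draws where the design demands it.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import scipy.stats

from .kernels import KernelSpec, rescale_kernel
from .observer import (
    LikelihoodCurve,
    draw_schedule,
    observe,
    trial_likelihood,
    ml_estimate,
    make_tau_grid,
)
from .internal_clock import (
    InternalBeliefSpec,
    draw_peak,
    belief_curve,
    fuse,
    map_estimate,
)
from .counting import (
    CountTable,
    build_count_table,
    count_events_for_duration,
    count_likelihood,
    detect_events,
    simulate_ou_paths,
)

__all__ = [
    "ExperimentConfig",
    "substream",
    "run_change_trial",
    "run_bias_experiment",
    "run_precision_experiment",
    "run_weber_experiment",
    "run_scalar_experiment",
    "summarize",
    "max_abs_bias",
    "ks_distance",
    "ks_critical_value",
    "WEBER_MODELS",
]

logger = logging.getLogger("timefuse")

#: Models known to the weber harness.
WEBER_MODELS = (
    "change_fused",
    "change_sensory",
    "internal_only",
    "count_fused",
    "count_sensory",
)

#: Default playback-speed grid, log-symmetric around natural speed.
DEFAULT_SPEEDS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of the model observers and harness defaults."""

    kernel: KernelSpec = field(default_factory=KernelSpec)
    n_streams: int = 12
    cap: int = 4
    poisson_rate: float = 1.0
    mc_draws: int = 128
    internal: InternalBeliefSpec = field(default_factory=InternalBeliefSpec)
    estimator: str = "fused"  # bias-harness estimate: 'fused' or 'sensory'
    intermediate_prior: str = "forgetting"
    grid_points: int = 200
    grid_span: float = 20.0
    # counting-model settings; count_streams is the number of independent
    # event sources (a spatial event detector scans the whole stimulus field,
    # far more regions than the handful of tracked snapshot locations)
    threshold: float = 1.0
    fine_dt: float = 0.05
    count_streams: int = 200
    reps_per_bin: int = 400
    table_lo: float = 0.5
    table_hi: float = 40.0
    table_bins: int = 24

    def __post_init__(self) -> None:
        if self.n_streams < 0:
            raise ValueError("n_streams must be >= 0")
        if self.estimator not in ("fused", "sensory"):
            raise ValueError("estimator must be 'fused' or 'sensory'")

    def tau_grid(self, tau_true: float) -> np.ndarray:
        return make_tau_grid(tau_true, self.grid_points, self.grid_span)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        """Build from a nested mapping (e.g. parsed YAML).

        Recognised keys mirror the dataclass; ``kernel`` takes
        {family, lambda_per_s, sigma}, ``internal`` takes
        {family, weber_fraction, peak_cv}.
        """
        d = dict(d)
        kernel = d.pop("kernel", {})
        if isinstance(kernel, dict):
            kernel = KernelSpec(
                decay_rate=kernel.get("lambda_per_s", 0.01),
                noise_sd=kernel.get("sigma", 0.1),
                family=kernel.get("family", "exponential"),
            )
        internal = d.pop("internal", {})
        if isinstance(internal, dict):
            internal = InternalBeliefSpec(
                weber_fraction=internal.get("weber_fraction", 0.15),
                peak_scatter_cv=internal.get("peak_cv", 0.15),
                family=internal.get("family", "gamma"),
            )
        return cls(kernel=kernel, internal=internal, **d)

    def to_dict(self) -> dict:
        """Flat mapping for run manifests."""
        d = asdict(self)
        d["kernel"] = {
            "family": self.kernel.family,
            "lambda_per_s": self.kernel.decay_rate,
            "sigma": self.kernel.noise_sd,
        }
        d["internal"] = {
            "family": self.internal.family,
            "weber_fraction": self.internal.weber_fraction,
            "peak_cv": self.internal.peak_scatter_cv,
        }
        return d


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Independent RNG substream derived from the master seed and a key path.

    String keys are hashed with CRC-32, so substreams are stable across runs
    and platforms and independent of execution order.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(entropy)


# --------------------------------------------------------------------------
# Single trials
# --------------------------------------------------------------------------

def run_change_trial(
    cfg: ExperimentConfig,
    tau_true: float,
    playback_speed: float,
    rng: np.random.Generator,
    internal: LikelihoodCurve | None = None,
    tau_grid: np.ndarray | None = None,
) -> dict:
    """One stochastic-change-model trial.

    Draws a snapshot schedule and stream values under the (possibly
    playback-rescaled) generative kernel, evaluates the combined sensory
    likelihood under the observer's natural-statistics kernel, and returns
    the sensory ML estimate plus, when an internal belief curve is supplied,
    the fused MAP estimate.  With ``n_streams`` 0 the sensory curve is
    uniform, so the fused estimate degenerates to the internal one.
    """
    grid = cfg.tau_grid(tau_true) if tau_grid is None else tau_grid
    schedule = draw_schedule(tau_true, cfg.cap, cfg.poisson_rate, rng)
    if cfg.n_streams == 0:
        sensory = LikelihoodCurve.uniform(grid)
    else:
        kernel_gen = rescale_kernel(cfg.kernel, playback_speed)
        snaps = observe(schedule, kernel_gen, cfg.n_streams, rng)
        sensory = trial_likelihood(
            snaps, grid, cfg.kernel, cfg.mc_draws, rng, cfg.intermediate_prior
        )
    out = {
        "ml": ml_estimate(sensory),
        "n_snapshots": schedule.n_snapshots,
    }
    if internal is not None:
        out["map"] = map_estimate(fuse(sensory, internal))
    return out


def _count_trial_estimates(
    cfg: ExperimentConfig,
    tau_true: float,
    table: CountTable,
    rng: np.random.Generator,
    internal: LikelihoodCurve,
    tau_grid: np.ndarray,
    n_events: int | None = None,
) -> dict:
    """One counting-model trial: sensory MAP and fused MAP from the count."""
    if n_events is None:
        n_events = int(
            count_events_for_duration(
                cfg.kernel,
                tau_true,
                cfg.count_streams,
                cfg.threshold,
                cfg.fine_dt,
                rng,
            )[0]
        )
    if n_events > table.max_count:
        logger.warning(
            "observed count %d beyond table maximum %d; clipping",
            n_events,
            table.max_count,
        )
        n_events = table.max_count
    sensory = count_likelihood(n_events, table, tau_grid)
    return {
        "ml": ml_estimate(sensory),
        "map": map_estimate(fuse(sensory, internal)),
        "n_events": n_events,
    }


# --------------------------------------------------------------------------
# Harnesses
# --------------------------------------------------------------------------

def run_bias_experiment(
    speeds=DEFAULT_SPEEDS,
    stim_duration: float = 1.0,
    n_trials: int = 1000,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Playback-speed bias of simulated duration judgments.

    For each speed the generative kernel's decay rate is multiplied by the
    speed while the observer's kernel stays natural.  Per-trial internal
    belief draws are shared across speeds (matched noise).  Both the fused
    and the pure-sensory estimates are recorded; the summary reports per-speed
    mean estimates normalized by the grand average over all speeds, per model.
    """
    cfg = config or ExperimentConfig()
    speeds = tuple(float(s) for s in speeds)
    if len(speeds) < 2:
        logger.warning(
            "bias experiment with a single speed: normalized means are "
            "trivially 1"
        )
    grid = cfg.tau_grid(stim_duration)
    rows = []
    for t in range(n_trials):
        peak = draw_peak(
            stim_duration, cfg.internal, substream(seed, "bias-internal", t)
        )
        internal = belief_curve(peak, cfg.internal, grid)
        for si, speed in enumerate(speeds):
            rng = substream(seed, "bias-sensory", si, t)
            res = run_change_trial(
                cfg, stim_duration, speed, rng, internal, grid
            )
            base = {
                "trial": t,
                "tau_true": stim_duration,
                "playback_speed": speed,
                "n_snapshots": res["n_snapshots"],
                "seed": seed,
            }
            rows.append({**base, "model": "change_fused", "estimate": res["map"]})
            rows.append({**base, "model": "change_sensory", "estimate": res["ml"]})
    records = pd.DataFrame(rows)
    summary = summarize(records, by=["model", "playback_speed"])
    summary["normalized_mean"] = summary.groupby("model")[
        "mean_estimate"
    ].transform(lambda m: m / m.mean())
    return records, summary


def run_precision_experiment(
    tau_set=(5.0,),
    n_trials: int = 5000,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variance reduction by sensory fusion, with matched internal draws.

    For every trial one internal belief is drawn and used both alone
    (``internal_only``: its own peak) and fused with a fresh sensory
    likelihood (``change_fused``), so the comparison of relative
    variabilities is paired.
    """
    cfg = config or ExperimentConfig()
    rows = []
    for ti, tau in enumerate(tau_set):
        grid = cfg.tau_grid(tau)
        for t in range(n_trials):
            peak = draw_peak(
                tau, cfg.internal, substream(seed, "prec-internal", ti, t)
            )
            internal = belief_curve(peak, cfg.internal, grid)
            res = run_change_trial(
                cfg,
                tau,
                1.0,
                substream(seed, "prec-sensory", ti, t),
                internal,
                grid,
            )
            base = {
                "trial": t,
                "tau_true": tau,
                "playback_speed": 1.0,
                "seed": seed,
            }
            rows.append(
                {
                    **base,
                    "model": "internal_only",
                    "n_snapshots": 0,
                    "estimate": map_estimate(internal),
                }
            )
            rows.append(
                {
                    **base,
                    "model": "change_fused",
                    "n_snapshots": res["n_snapshots"],
                    "estimate": res["map"],
                }
            )
    records = pd.DataFrame(rows)
    return records, summarize(records, by=["model", "tau_true"])


def default_count_table(
    cfg: ExperimentConfig, seed: int = 0
) -> CountTable:
    """Event-count table under the config's generative settings.

    Realises the assumption that the counting observer knows the true
    statistics of event occurrence: the table is built with the same kernel,
    threshold, step and stream count used at test time.
    """
    bins = np.geomspace(cfg.table_lo, cfg.table_hi, cfg.table_bins + 1)
    return build_count_table(
        cfg.kernel,
        bins,
        reps_per_bin=cfg.reps_per_bin,
        threshold=cfg.threshold,
        fine_dt=cfg.fine_dt,
        seed=seed,
        n_streams=cfg.count_streams,
    )


def run_weber_experiment(
    models=WEBER_MODELS,
    tau_set=(2.5, 5.0, 10.0),
    n_trials: int = 1000,
    config: ExperimentConfig | None = None,
    seed: int = 0,
    count_table: CountTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative variability versus true duration, per model.

    Internal belief draws are shared across models at each (duration, trial)
    coordinate, so model contrasts are paired.  Count-based models use an
    empirical count table built under the generative settings (supplied or
    built on the fly).
    """
    cfg = config or ExperimentConfig()
    models = tuple(models)
    unknown = set(models) - set(WEBER_MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    span = max(tau_set) / min(tau_set)
    if span < 4.0:
        logger.warning("tau_set spans only %.2fx (< 4x)", span)
    need_count = bool({"count_fused", "count_sensory"} & set(models))
    if need_count and count_table is None:
        count_table = default_count_table(
            cfg, seed=int(substream(seed, "count-table").integers(2**31))
        )
    need_change = bool({"change_fused", "change_sensory"} & set(models))
    count_grid = None
    trial_counts = None
    if need_count:
        count_grid = np.geomspace(cfg.table_lo, cfg.table_hi, cfg.grid_points)
        # one long event simulation per trial, counted in nested duration
        # windows: common random numbers across durations
        tau_max = float(max(tau_set))
        n_max = max(int(round(tau_max / cfg.fine_dt)), 1)
        trial_counts = np.zeros((n_trials, len(tau_set)), dtype=int)
        for t in range(n_trials):
            rng = substream(seed, "weber-count", t)
            paths = simulate_ou_paths(
                cfg.kernel, tau_max, cfg.fine_dt, cfg.count_streams, rng
            )
            for ti, tau in enumerate(tau_set):
                n_steps = min(max(int(round(tau / cfg.fine_dt)), 1), n_max)
                trial_counts[t, ti] = int(
                    detect_events(paths[:, : n_steps + 1], cfg.threshold).sum()
                )
    rows = []
    for ti, tau in enumerate(tau_set):
        grid = cfg.tau_grid(tau)
        for t in range(n_trials):
            # internal peak = tau * multiplier, multiplier shared across
            # durations (matched Weber scatter: paired model contrasts)
            peak = tau * draw_peak(
                1.0, cfg.internal, substream(seed, "weber-internal", t)
            )
            internal = belief_curve(peak, cfg.internal, grid)
            base = {
                "trial": t,
                "tau_true": tau,
                "playback_speed": 1.0,
                "n_snapshots": 0,
                "seed": seed,
            }
            if "internal_only" in models:
                rows.append(
                    {
                        **base,
                        "model": "internal_only",
                        "estimate": map_estimate(internal),
                    }
                )
            if need_change:
                res = run_change_trial(
                    cfg,
                    tau,
                    1.0,
                    substream(seed, "weber-change", ti, t),
                    internal,
                    grid,
                )
                if "change_sensory" in models:
                    rows.append(
                        {
                            **base,
                            "model": "change_sensory",
                            "n_snapshots": res["n_snapshots"],
                            "estimate": res["ml"],
                        }
                    )
                if "change_fused" in models:
                    rows.append(
                        {
                            **base,
                            "model": "change_fused",
                            "n_snapshots": res["n_snapshots"],
                            "estimate": res["map"],
                        }
                    )
            if need_count:
                # counting observer lives on a fixed grid spanning the
                # count table: its support cannot depend on the hidden tau
                res = _count_trial_estimates(
                    cfg,
                    tau,
                    count_table,
                    substream(seed, "weber-count-est", ti, t),
                    belief_curve(peak, cfg.internal, count_grid),
                    count_grid,
                    n_events=int(trial_counts[t, ti]),
                )
                if "count_sensory" in models:
                    rows.append(
                        {**base, "model": "count_sensory", "estimate": res["ml"]}
                    )
                if "count_fused" in models:
                    rows.append(
                        {**base, "model": "count_fused", "estimate": res["map"]}
                    )
    records = pd.DataFrame(rows)
    return records, summarize(records, by=["model", "tau_true"])


def run_scalar_experiment(
    tau_set=(2.5, 5.0, 10.0),
    n_trials: int = 800,
    variants=None,
    seed: int = 0,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Scale invariance of purely sensory estimate distributions.

    Runs sensory-only trials for each variant (default model, an alternate
    correlation timescale, and alternate snapshot caps), dividing each ML
    estimate by the true duration.  Returns trial records with a
    ``normalized`` column for histogramming and KS comparisons.
    """
    cfg = config or ExperimentConfig()
    if variants is None:
        variants = [
            {"name": "default"},
            {"name": "alt_kernel", "kernel": replace(cfg.kernel, decay_rate=2 * cfg.kernel.decay_rate)},
            {"name": "cap_2", "cap": 2},
            {"name": "cap_6", "cap": 6},
        ]
    rows = []
    for vi, variant in enumerate(variants):
        name = variant.get("name", f"variant_{vi}")
        vcfg = replace(
            cfg,
            kernel=variant.get("kernel", cfg.kernel),
            cap=variant.get("cap", cfg.cap),
        )
        for ti, tau in enumerate(tau_set):
            grid = vcfg.tau_grid(tau)
            for t in range(n_trials):
                res = run_change_trial(
                    vcfg,
                    tau,
                    1.0,
                    substream(seed, "scalar", vi, ti, t),
                    None,
                    grid,
                )
                rows.append(
                    {
                        "trial": t,
                        "model": "change_sensory",
                        "variant": name,
                        "tau_true": tau,
                        "playback_speed": 1.0,
                        "n_snapshots": res["n_snapshots"],
                        "estimate": res["ml"],
                        "normalized": res["ml"] / tau,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Summaries and statistics
# --------------------------------------------------------------------------

def summarize(records: pd.DataFrame, by) -> pd.DataFrame:
    """Grouped estimate statistics: n, mean, sd, relative variability.

    Relative variability (sd of point estimates divided by their mean) is the
    behavioural quantity: the spread of responses across trials, not the
    width of any single-trial posterior.
    """
    grouped = records.groupby(list(by))["estimate"]
    out = grouped.agg(
        n_trials="count", mean_estimate="mean", sd_estimate="std"
    ).reset_index()
    out["relative_variability"] = out["sd_estimate"] / out["mean_estimate"]
    return out


def max_abs_bias(summary: pd.DataFrame, model: str = "change_fused") -> float:
    """Largest |normalized mean - 1| across playback speeds, as a fraction."""
    sub = summary[summary["model"] == model]
    if "normalized_mean" not in sub or sub.empty:
        raise ValueError("summary lacks normalized means for this model")
    return float(np.abs(sub["normalized_mean"] - 1.0).max())


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov distance."""
    return float(scipy.stats.ks_2samp(np.asarray(a), np.asarray(b)).statistic)


def ks_critical_value(
    a, b, alpha: float = 0.05, n_perm: int = 400, seed: int = 0
) -> float:
    """Monte-Carlo (permutation) critical value of the two-sample KS distance.

    Pools the samples, re-splits them at random ``n_perm`` times, and returns
    the (1 - alpha) quantile of the null KS distances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = ks_distance(perm[: a.size], perm[a.size:])
    return float(np.quantile(null, 1.0 - alpha))
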