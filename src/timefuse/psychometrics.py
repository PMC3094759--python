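"""Psychometric fitting and simulated behavioural designs.

Links the model observers to the readouts used with human subjects: a
cumulative-Gaussian psychometric fit with a lapse rate, adaptive staircases
converging on points of subjective equality (PSE), a two-alternative
forced-choice (2AFC) duration comparison, and a long/short classification
block.

The fitted response curve is

    p(x) = lapse / 2 + (1 - lapse) * Phi((x - mu) / sigma_w),

and the variability of judgment is defined as the reciprocal of the maximal
slope of the lapse-independent curve, i.e. sigma_w * sqrt(2 pi) — the width
of the underlying Gaussian up to a constant.

Simulated observers are supplied as estimator callables
``estimator(tau_true, playback_speed, rng) -> seconds`` so any model (change
based, count based, internal only) can drive the same designs; factories for
the standard observers live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .counting import CountTable
from .experiments import ExperimentConfig, run_change_trial, _count_trial_estimates
from .internal_clock import belief_curve, draw_peak

__all__ = [
    "PsychometricFit",
    "StaircaseState",
    "fit_psychometric",
    "make_change_estimator",
    "make_count_estimator",
    "simulate_2afc_trial",
    "run_staircase",
    "run_classification",
]

logger = logging.getLogger("timefuse")

#: Default upper bound on the fitted lapse rate.
DEFAULT_LAPSE_MAX = 0.1


# --------------------------------------------------------------------------
# Psychometric curve fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit with lapse rate.

    ``variability`` is sigma_w * sqrt(2 pi): the reciprocal of the maximal
    slope of the lapse-independent curve.  ``identified`` is False when the
    data are completely separated (the width collapses onto its lower
    bound), in which case the bounded width is reported.
    """

    location: float
    width: float
    lapse: float
    log_likelihood: float
    n_trials: int
    identified: bool = True

    @property
    def variability(self) -> float:
        return float(self.width * np.sqrt(2.0 * np.pi))

    def predict(self, x) -> np.ndarray:
        """Fitted response probability at stimulus level(s) x."""
        x = np.asarray(x, dtype=float)
        base = norm.cdf((x - self.location) / self.width)
        return self.lapse / 2.0 + (1.0 - self.lapse) * base


def _aggregate_trials(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a (level, response) table to per-level counts."""
    if isinstance(trials, pd.DataFrame):
        levels = trials["level"].to_numpy(dtype=float)
        responses = trials["response"].to_numpy()
    else:
        arr = np.asarray(trials, dtype=float)
        levels, responses = arr[:, 0], arr[:, 1]
    responses = np.asarray(responses)
    if not np.isin(responses, (0, 1)).all():
        raise ValueError("responses must be binary 0/1")
    responses = responses.astype(float)
    uniq = np.unique(levels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct stimulus levels")
    n = np.array([(levels == u).sum() for u in uniq], dtype=float)
    k = np.array([responses[levels == u].sum() for u in uniq], dtype=float)
    return uniq, n, k


def fit_psychometric(
    trials, lapse_max: float = DEFAULT_LAPSE_MAX
) -> PsychometricFit:
    """Fit (mu, sigma_w, lapse) to binary responses by maximum likelihood.

    ``trials`` is a DataFrame with columns ``level`` and ``response`` (or an
    (n, 2) array).  The fit is deterministic: a fixed multi-start grid of
    initial conditions feeds L-BFGS-B and the best optimum is returned.
    Invariant to trial order and to duplication of the table.
    """
    levels, n, k = _aggregate_trials(trials)
    span = float(levels[-1] - levels[0])
    width_lo = 1e-3 * span
    width_hi = 20.0 * span
    tiny = 1e-12

    def nll(theta):
        mu, log_w, lapse = theta
        p = lapse / 2.0 + (1.0 - lapse) * norm.cdf(
            (levels - mu) / np.exp(log_w)
        )
        p = np.clip(p, tiny, 1.0 - tiny)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))

    bounds = [
        (levels[0] - span, levels[-1] + span),
        (np.log(width_lo), np.log(width_hi)),
        (0.0, lapse_max),
    ]
    mu_starts = [
        float(np.interp(0.5, k / n, levels))
        if np.all(np.diff(k / n) >= 0)
        else float(np.median(levels)),
        float(np.average(levels, weights=n)),
    ]
    best = None
    for mu0 in mu_starts:
        for w0 in (0.1 * span, 0.3 * span, span):
            for l0 in (0.0, 0.02):
                res = minimize(
                    nll,
                    x0=np.array([mu0, np.log(w0), l0]),
                    method="L-BFGS-B",
                    bounds=bounds,
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
    mu, log_w, lapse = best.x
    width = float(np.exp(log_w))
    # complete separation: responses jump 0 -> 1 and the width hits its floor
    identified = width > 2.0 * width_lo
    if not identified:
        logger.warning(
            "psychometric fit not identified (separated data); reporting "
            "bounded width %g",
            width,
        )
    return PsychometricFit(
        location=float(mu),
        width=width,
        lapse=float(lapse),
        log_likelihood=float(-best.fun),
        n_trials=int(n.sum()),
        identified=identified,
    )


# --------------------------------------------------------------------------
# Model observers as estimator callables
# --------------------------------------------------------------------------

def make_change_estimator(
    cfg: ExperimentConfig, fused: bool = True, bias_s: float = 0.0
):
    """Estimator callable backed by the stochastic change observer.

    ``bias_s`` adds a constant to every estimate — used to validate that the
    staircase recovers a known injected bias.
    """

    def estimator(tau_true: float, playback_speed: float, rng) -> float:
        grid = cfg.tau_grid(tau_true)
        internal = None
        if fused:
            internal = belief_curve(
                draw_peak(tau_true, cfg.internal, rng), cfg.internal, grid
            )
        res = run_change_trial(cfg, tau_true, playback_speed, rng, internal, grid)
        return (res["map"] if fused else res["ml"]) + bias_s

    return estimator


def make_count_estimator(
    cfg: ExperimentConfig, table: CountTable, fused: bool = True
):
    """Estimator callable backed by the event-counting observer."""

    count_grid = np.geomspace(cfg.table_lo, cfg.table_hi, cfg.grid_points)

    def estimator(tau_true: float, playback_speed: float, rng) -> float:
        if playback_speed != 1.0:
            raise ValueError("count estimator supports natural playback only")
        grid = count_grid
        internal = belief_curve(
            draw_peak(tau_true, cfg.internal, rng), cfg.internal, grid
        )
        res = _count_trial_estimates(cfg, tau_true, table, rng, internal, grid)
        return res["map"] if fused else res["ml"]

    return estimator


# --------------------------------------------------------------------------
# Behavioural designs
# --------------------------------------------------------------------------

def simulate_2afc_trial(
    estimator,
    dur1: float,
    dur2: float,
    speeds=(1.0, 1.0),
    seed: int | np.random.Generator = 0,
    bias_second_s: float = 0.0,
) -> int:
    """Which of two sequential stimuli is judged longer (1 = second).

    Each interval yields an independent estimate under its own generative
    playback speed; ties are broken by a fair coin.
    """
    if not (dur1 > 0 and dur2 > 0):
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    est1 = estimator(dur1, speeds[0], rng)
    est2 = estimator(dur2, speeds[1], rng) + bias_second_s
    if est2 == est1:
        return int(rng.integers(2))
    return int(est2 > est1)


@dataclass
class StaircaseState:
    """History and outcome of one adaptive staircase on Delta (seconds)."""

    history: list = field(default_factory=list)  # (delta, response) pairs
    reversal_deltas: list = field(default_factory=list)
    pse: float | None = None
    converged: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=["delta", "response"])


def run_staircase(
    estimator,
    ordering: str = "slow_rapid",
    start_delta: float = 0.2,
    step: float = 0.05,
    min_step: float = 0.00625,
    n_reversals: int = 12,
    pse_reversals: int = 6,
    max_trials: int = 200,
    base_range=(0.5, 0.65),
    speeds=(0.5, 2.0),
    seed: int | np.random.Generator = 0,
    bias_second_s: float = 0.0,
) -> StaircaseState:
    """1-up/1-down staircase on the duration difference of a 2AFC pair.

    The first stimulus lasts a pseudorandom base duration; the second lasts
    base + Delta.  A "second longer" response decreases Delta, otherwise it
    increases, so Delta converges on the 50% point (the PSE).  The step
    halves at every reversal down to ``min_step``; the PSE is the mean Delta
    at the final ``pse_reversals`` reversals.  ``ordering`` assigns the
    playback speeds: ``slow_rapid`` (first slow), ``rapid_slow``, or
    ``equal`` (both natural).
    """
    orderings = {
        "slow_rapid": (min(speeds), max(speeds)),
        "rapid_slow": (max(speeds), min(speeds)),
        "equal": (1.0, 1.0),
    }
    if ordering not in orderings:
        raise ValueError(f"ordering must be one of {sorted(orderings)}")
    pair_speeds = orderings[ordering]
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    state = StaircaseState()
    delta = float(start_delta)
    cur_step = float(step)
    prev_resp: int | None = None
    for _ in range(max_trials):
        base = float(rng.uniform(*base_range))
        dur2 = max(base + delta, 1e-3)
        resp = simulate_2afc_trial(
            estimator,
            base,
            dur2,
            pair_speeds,
            rng,
            bias_second_s=bias_second_s,
        )
        state.history.append((delta, resp))
        if prev_resp is not None and resp != prev_resp:
            state.reversal_deltas.append(delta)
            cur_step = max(cur_step / 2.0, min_step)
            if len(state.reversal_deltas) >= n_reversals:
                break
        prev_resp = resp
        delta += -cur_step if resp == 1 else cur_step
    state.converged = len(state.reversal_deltas) >= n_reversals
    if not state.converged:
        logger.warning(
            "staircase reached max_trials with %d reversals",
            len(state.reversal_deltas),
        )
    if len(state.reversal_deltas) >= pse_reversals:
        state.pse = float(np.mean(state.reversal_deltas[-pse_reversals:]))
    return state


def run_classification(
    estimator,
    tau_set,
    n_trials: int = 400,
    seed: int = 0,
    reference: str = "running_mean",
    axis: str = "ratio",
) -> tuple[pd.DataFrame, PsychometricFit, float]:
    """Long/short classification of single intervals within a block.

    The observer estimates each interval and calls it "long" when the
    estimate exceeds its reference: the running mean of all previous
    estimates in the block (``running_mean``, warmed up on the true block
    mean) or the true block mean (``true_block_mean``).  Proportions of
    "long" per duration are fit with a cumulative Gaussian on the configured
    axis — default ``ratio`` (duration / block mean), where the fitted
    variability is already relative; ``linear`` fits in seconds and divides
    by the block mean.

    Returns (per-trial records, fit, relative variability).
    """
    if reference not in ("running_mean", "true_block_mean"):
        raise ValueError("reference must be running_mean or true_block_mean")
    if axis not in ("ratio", "linear"):
        raise ValueError("axis must be 'ratio' or 'linear'")
    tau_set = np.asarray(tau_set, dtype=float)
    if tau_set.size < 2:
        raise ValueError("tau_set must contain at least 2 durations")
    block_mean = float(tau_set.mean())
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(tau_set, n_trials // tau_set.size + 1))[
        :n_trials
    ]
    rows = []
    running_sum, running_n = 0.0, 0
    for t, tau in enumerate(order):
        est = estimator(float(tau), 1.0, np.random.default_rng([seed, 1000 + t]))
        if reference == "true_block_mean" or running_n < 5:
            ref = block_mean
        else:
            ref = running_sum / running_n
        resp = int(est > ref)
        rows.append(
            {"trial": t, "tau_true": float(tau), "estimate": est, "response": resp}
        )
        running_sum += est
        running_n += 1
    records = pd.DataFrame(rows)
    if axis == "ratio":
        records["level"] = records["tau_true"] / block_mean
    else:
        records["level"] = records["tau_true"]
    fit = fit_psychometric(records[["level", "response"]])
    rel_var = fit.variability if axis == "ratio" else fit.variability / block_mean
    return records, fit, rel_var
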