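"""Stimulus-independent internal duration belief and Bayesian fusion.

Observers sense the passage of time even without informative stimuli.  That
internal sense is modelled as a probabilistic belief over elapsed time,
P_internal(tau): on each trial a belief curve is centred on a peak drawn with
multiplicative (Weber-law) scatter around the true duration, so the
across-trial standard deviation of the peak divided by the true duration is
constant.  The default belief family is a gamma density parameterized by its
mode, with the shape fixed so the belief's own width also scales with its
mode (scalar-consistent); a log-normal family and a flat (uninformative)
option are provided because downstream results should not depend on the
distributional details.

The sensory likelihood and the internal belief combine by Bayes' rule on the
grid — a pointwise product, renormalized — and the posterior peak (MAP) is
the model's duration estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .observer import LikelihoodCurve, ml_estimate

__all__ = [
    "InternalBeliefSpec",
    "draw_peak",
    "belief_curve",
    "internal_belief",
    "fuse",
    "map_estimate",
]

logger = logging.getLogger("timefuse")

_FAMILIES = ("gamma", "lognormal", "flat")


@dataclass(frozen=True)
class InternalBeliefSpec:
    """Shape of the internal duration belief.

    Parameters
    ----------
    weber_fraction : float
        Relative width of a single trial's belief curve (its sd divided by
        its mean scale); sets the gamma shape a = 1/weber_fraction**2 or the
        log-normal log-sd.  Default 0.15, within the classic human range.
    peak_scatter_cv : float
        Coefficient of variation of the trial-to-trial multiplicative scatter
        of the belief's peak around the true duration (the Weber scatter of
        the internal clock).  Default 0.15.
    family : str
        ``"gamma"`` (default), ``"lognormal"``, or ``"flat"``.
    """

    weber_fraction: float = 0.15
    peak_scatter_cv: float = 0.15
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown belief family {self.family!r}; available: {_FAMILIES}"
            )
        if self.family != "flat" and not self.weber_fraction > 0:
            raise ValueError("weber_fraction must be > 0")
        if self.peak_scatter_cv < 0:
            raise ValueError("peak_scatter_cv must be >= 0")

    @property
    def gamma_shape(self) -> float:
        """Gamma shape implied by the weber fraction (CV = 1/sqrt(shape))."""
        return 1.0 / self.weber_fraction**2


def draw_peak(
    tau_true: float,
    spec: InternalBeliefSpec,
    rng: np.random.Generator,
) -> float:
    """Trial-specific belief peak: log-normal scatter, E[peak] = tau_true.

    The log-normal guarantees positivity and makes the scatter multiplicative
    (Weber-like); its mean is fixed at the true duration so the internal
    estimate is unbiased on average.
    """
    if not tau_true > 0:
        raise ValueError("tau_true must be > 0")
    cv = spec.peak_scatter_cv
    if cv == 0:
        return float(tau_true)
    s2 = np.log1p(cv**2)
    mu = np.log(tau_true) - 0.5 * s2
    return float(np.exp(rng.normal(mu, np.sqrt(s2))))


def belief_curve(
    peak: float, spec: InternalBeliefSpec, tau_grid: np.ndarray
) -> LikelihoodCurve:
    """Internal belief with a given peak, evaluated and normalized on a grid."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if spec.family == "flat":
        return LikelihoodCurve.uniform(tau_grid)
    if not peak > 0:
        raise ValueError("belief peak must be > 0")
    if spec.family == "gamma":
        a = spec.gamma_shape
        if a <= 1:
            raise ValueError("gamma shape must exceed 1 for a modal belief")
        scale = peak / (a - 1.0)  # gamma mode = (a - 1) * scale
        dist = stats.gamma(a, scale=scale)
    else:  # lognormal, mode = exp(mu - s^2)
        s = spec.weber_fraction
        dist = stats.lognorm(s, scale=float(np.exp(np.log(peak) + s**2)))
    covered = dist.cdf(tau_grid[-1]) - dist.cdf(tau_grid[0])
    if covered < 0.999:
        logger.warning(
            "tau grid [%g, %g] covers only %.4f of the internal belief mass",
            tau_grid[0],
            tau_grid[-1],
            covered,
        )
    return LikelihoodCurve.from_weights(tau_grid, dist.pdf(tau_grid))


def internal_belief(
    tau_true: float,
    spec: InternalBeliefSpec,
    tau_grid: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> LikelihoodCurve:
    """Draw a trial's internal belief curve around the true duration."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    return belief_curve(draw_peak(tau_true, spec, rng), spec, tau_grid)


def fuse(sensory: LikelihoodCurve, internal: LikelihoodCurve) -> LikelihoodCurve:
    """Bayes' rule on the grid: renormalized pointwise product.

    Symmetric and associative; fusing with a uniform curve is the identity.
    """
    if sensory.tau_grid.shape != internal.tau_grid.shape or not np.array_equal(
        sensory.tau_grid, internal.tau_grid
    ):
        raise ValueError("curves must share one tau grid")
    product = sensory.density * internal.density
    if not product.sum() > 0:
        raise ValueError(
            "degenerate posterior: sensory and internal curves have disjoint "
            "support (check the tau grid configuration)"
        )
    return LikelihoodCurve.from_weights(sensory.tau_grid, product)


def map_estimate(curve: LikelihoodCurve) -> float:
    """Posterior peak; identical contract to the sensory ML estimate."""
    return ml_estimate(curve)
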