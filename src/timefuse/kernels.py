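"""Stationary Gaussian-process models of sensory streams.

Sensory input (e.g. luminance at well-separated retinal locations) is modelled
as a set of independent, stationary, zero-mean Gaussian processes whose
second-order statistics follow the 1/f^2 power law of natural image sequences.
The exponential (Ornstein-Uhlenbeck) covariance

    k(t, t') = exp(-lambda |t - t'|) + sigma^2 [t == t', same sample]

realises that spectrum (a Lorentzian, ~1/f^2 above the knee at lambda), with
independent measurement noise of standard deviation ``sigma`` on each sampled
value.  The process variance is normalised to 1, so all signal values are
dimensionless.

This module defines the kernel, builds covariance matrices on sampled time
grids, simulates stream ensembles, and provides an exact dense-covariance
log-density used as the numerical oracle for the observer's likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "KernelSpec",
    "StreamEnsemble",
    "build_covariance",
    "simulate_streams",
    "rescale_kernel",
    "gp_log_density",
    "DEFAULT_LAMBDA",
    "DEFAULT_SIGMA",
    "DEFAULT_N_STREAMS",
]

logger = logging.getLogger("timefuse")

#: Default decay rate of the exponential kernel, 1/seconds.
DEFAULT_LAMBDA = 0.01
#: Default measurement-noise standard deviation (signal units).
DEFAULT_SIGMA = 0.1
#: Default number of independent sensory streams.
DEFAULT_N_STREAMS = 12

#: Diagonal jitter added once on Cholesky failure before giving up.
_CHOL_JITTER = 1e-10

_KERNEL_FAMILIES = ("exponential",)


@dataclass(frozen=True)
class KernelSpec:
    """Second-order statistics of a sensory stream.

    Parameters
    ----------
    decay_rate : float
        Inverse correlation time lambda, 1/seconds.  Must be positive.
    noise_sd : float
        Standard deviation sigma of the independent measurement noise added
        to every sampled value (dimensionless signal units).  Non-negative.
    family : str
        Kernel family; only ``"exponential"`` is implemented.  The slot exists
        so variant spectra can be registered without touching callers.
    """

    decay_rate: float = DEFAULT_LAMBDA
    noise_sd: float = DEFAULT_SIGMA
    family: str = "exponential"

    #: Stationary variance of the underlying process (fixed at 1).
    process_variance: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.family not in _KERNEL_FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; "
                f"available: {_KERNEL_FAMILIES}"
            )
        if not self.decay_rate > 0:
            raise ValueError(f"decay_rate must be > 0, got {self.decay_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def correlation(self, lag: np.ndarray | float) -> np.ndarray | float:
        """Noise-free kernel value at a time lag: exp(-lambda |lag|)."""
        return np.exp(-self.decay_rate * np.abs(lag))


@dataclass(frozen=True)
class StreamEnsemble:
    """A set of mutually independent stream draws on a shared time grid.

    ``values`` has shape (n_streams, n_times), row i holding stream i sampled
    at ``times`` (measurement noise included).
    """

    times: np.ndarray
    values: np.ndarray
    kernel: KernelSpec
    seed: int

    @property
    def n_streams(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: a time column plus one column per stream."""
        data = {"time_s": self.times}
        for i, row in enumerate(self.values):
            data[f"stream_{i}"] = row
        return pd.DataFrame(data)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def build_covariance(times: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Covariance matrix of stream values sampled at ``times``.

    Entry (m, n) is exp(-lambda |t_n - t_m|) + sigma^2 [m == n]: measurement
    noise sits on the diagonal only, so coincident *distinct* samples would
    still decorrelate by sigma^2.

    Parameters
    ----------
    times : array of float
        Strictly increasing sample times, seconds.
    kernel : KernelSpec

    Returns
    -------
    (n, n) symmetric positive-semidefinite array.
    """
    times = _check_times(times)
    lags = np.abs(times[:, None] - times[None, :])
    cov = np.asarray(kernel.correlation(lags), dtype=float)
    cov[np.diag_indices_from(cov)] += kernel.noise_sd**2
    return cov


def rescale_kernel(kernel: KernelSpec, playback_speed: float) -> KernelSpec:
    """Kernel of a stream played back ``playback_speed`` times faster.

    Time-compressing a stationary process by a factor s multiplies its decay
    rate by s (the spectrum shifts to frequencies s times higher); the
    measurement noise, injected at sampling, is unchanged.
    """
    if not playback_speed > 0:
        raise ValueError(f"playback_speed must be > 0, got {playback_speed}")
    return replace(kernel, decay_rate=kernel.decay_rate * playback_speed)


def _chol_with_jitter(cov: np.ndarray):
    """Cholesky factor of ``cov``, retrying once with tiny diagonal jitter."""
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        logger.warning(
            "covariance factorization failed; retrying with %g jitter",
            _CHOL_JITTER,
        )
        try:
            return cho_factor(cov + _CHOL_JITTER * np.eye(len(cov)), lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance is numerically singular even after jitter; "
                "use a kernel with noise_sd > 0"
            ) from err


def simulate_streams(
    times: np.ndarray,
    kernel: KernelSpec,
    n_streams: int = DEFAULT_N_STREAMS,
    seed: int = 0,
) -> StreamEnsemble:
    """Draw ``n_streams`` independent stream sample paths at ``times``.

    Each stream is a zero-mean multivariate Gaussian draw with covariance
    ``build_covariance(times, kernel)``.  Identical seeds reproduce identical
    ensembles bit-for-bit.
    """
    times = _check_times(times)
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    cov = build_covariance(times, kernel)
    c, lower = _chol_with_jitter(cov)
    chol = np.tril(c)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_streams, times.size))
    values = white @ chol.T
    return StreamEnsemble(times=times, values=values, kernel=kernel, seed=seed)


def gp_log_density(
    values: np.ndarray, times: np.ndarray, kernel: KernelSpec
) -> float:
    """Exact log density of one stream's values under the kernel.

    Log of the zero-mean multivariate normal with covariance
    ``build_covariance(times, kernel)``, evaluated via a Cholesky
    factorization.  Serves as the dense oracle against which the observer's
    fast recursive likelihood is validated.
    """
    values = np.asarray(values, dtype=float)
    times = _check_times(times)
    if values.shape != times.shape:
        raise ValueError("values and times must have the same length")
    cov = build_covariance(times, kernel)
    c_and_lower = _chol_with_jitter(cov)
    chol = np.tril(c_and_lower[0])
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    quad = values @ cho_solve(c_and_lower, values)
    n = times.size
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))
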