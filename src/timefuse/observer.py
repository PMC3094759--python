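"""Snapshot-based Bayesian observer of elapsed time.

An observer times a hidden interval of length tau by remembering a small,
capped number of "snapshots" of each sensory stream: one at the start of the
interval, one at the end, and up to ``cap - 2`` intermediates sampled by a
rate-1 Poisson process with random forgetting.  The snapshots are shorn of
their temporal labels — the observer keeps only the values and their order.

Because the streams are stationary Gaussian processes with known second-order
statistics, the amount of change between snapshots is informative about the
time that separates them: little change suggests samples close together,
large change samples far apart.  For each candidate duration tau the observer
evaluates the probability of the observed values under the kernel, treating
the unknown intermediate snapshot times as sorted uniform order statistics on
(0, tau) and marginalizing them by Monte Carlo (common random numbers across
the tau grid).  The product over independent streams, normalized on the grid,
is the sensory likelihood P(observations | tau); its peak is the sensory
maximum-likelihood (ML) duration estimate.

The per-candidate Gaussian density is computed with an exact scalar Kalman
filter (the state-space form of the exponential kernel plus white measurement
noise), which is algebraically identical to the dense multivariate-normal
density but vectorizes across the candidate grid, the Monte-Carlo draws and
the streams.  Equivalence with :func:`timefuse.kernels.gp_log_density` is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .kernels import KernelSpec, build_covariance, _chol_with_jitter

__all__ = [
    "SnapshotSchedule",
    "SnapshotSet",
    "LikelihoodCurve",
    "draw_schedule",
    "observe",
    "stream_likelihood",
    "trial_likelihood",
    "combine_streams",
    "ml_estimate",
    "make_tau_grid",
    "absolute_tau_grid",
    "DEFAULT_CAP",
    "DEFAULT_POISSON_RATE",
    "DEFAULT_MC_DRAWS",
]

#: Default snapshot cap (anchors + up to two intermediates).
DEFAULT_CAP = 4
#: Default rate of the intermediate-snapshot Poisson process, 1/seconds.
DEFAULT_POISSON_RATE = 1.0
#: Default Monte-Carlo draws for hidden-intermediate-time marginalization.
DEFAULT_MC_DRAWS = 128

#: Grid size and half-decade span of the per-trial candidate-duration grid.
GRID_POINTS = 200
GRID_SPAN = 20.0


# --------------------------------------------------------------------------
# Candidate-duration grids and normalized curves
# --------------------------------------------------------------------------

def make_tau_grid(
    tau_true: float, n: int = GRID_POINTS, span: float = GRID_SPAN
) -> np.ndarray:
    """Log-spaced candidate durations [tau/span, tau*span] around a trial."""
    if not tau_true > 0:
        raise ValueError("tau_true must be > 0")
    return np.geomspace(tau_true / span, tau_true * span, n)


def absolute_tau_grid(
    lo: float = 0.05, hi: float = 200.0, n: int = 400
) -> np.ndarray:
    """Fixed log-spaced grid for cross-trial analyses."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class LikelihoodCurve:
    """A normalized function over a fixed candidate-duration grid.

    Used interchangeably for sensory likelihoods, internal beliefs and fused
    posteriors: ``density`` holds non-negative weights summing to 1 over the
    strictly increasing ``tau_grid``.
    """

    tau_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.tau_grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.shape != dens.shape:
            raise ValueError("tau_grid and density must be matching 1-D arrays")
        if grid.size < 2 or not np.all(np.diff(grid) > 0) or not np.all(
            np.isfinite(grid)
        ):
            raise ValueError("tau_grid must be finite and strictly increasing")
        if np.any(dens < 0) or not np.all(np.isfinite(dens)):
            raise ValueError("density must be finite and non-negative")
        if abs(dens.sum() - 1.0) > 1e-9:
            raise ValueError("density must sum to 1; use from_weights()")
        object.__setattr__(self, "tau_grid", grid)
        object.__setattr__(self, "density", dens)

    @classmethod
    def from_weights(
        cls, tau_grid: np.ndarray, weights: np.ndarray
    ) -> "LikelihoodCurve":
        """Normalize non-negative weights into a curve."""
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if not total > 0 or not np.isfinite(total):
            raise ValueError("weights must have positive finite sum")
        return cls(np.asarray(tau_grid, dtype=float), weights / total)

    @classmethod
    def from_log_weights(
        cls, tau_grid: np.ndarray, log_weights: np.ndarray
    ) -> "LikelihoodCurve":
        """Normalize log-weights (max subtracted before exponentiation)."""
        lw = np.asarray(log_weights, dtype=float)
        m = np.max(lw)
        if not np.isfinite(m):
            raise ValueError("log-weights are all -inf or non-finite")
        return cls.from_weights(tau_grid, np.exp(lw - m))

    @classmethod
    def uniform(cls, tau_grid: np.ndarray) -> "LikelihoodCurve":
        grid = np.asarray(tau_grid, dtype=float)
        return cls(grid, np.full(grid.size, 1.0 / grid.size))

    def entropy(self) -> float:
        """Shannon entropy (nats) of the grid weights."""
        p = self.density[self.density > 0]
        return float(-(p * np.log(p)).sum())


def combine_streams(curves) -> LikelihoodCurve:
    """Pointwise product of normalized curves on a shared grid, renormalized.

    Order-invariant; combining with a uniform curve is the identity.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].tau_grid
    for c in curves[1:]:
        if c.tau_grid.shape != grid.shape or not np.array_equal(c.tau_grid, grid):
            raise ValueError("curves must share one tau grid")
    with np.errstate(divide="ignore"):
        log_total = np.sum([np.log(c.density) for c in curves], axis=0)
    return LikelihoodCurve.from_log_weights(grid, log_total)


def ml_estimate(curve: LikelihoodCurve) -> float:
    """Grid point of maximal weight; ties broken toward the smallest tau."""
    dens = curve.density
    if not np.any(dens > 0):
        raise ValueError("degenerate curve: all weights zero")
    return float(curve.tau_grid[int(np.argmax(dens))])


# --------------------------------------------------------------------------
# Snapshot schedules and observation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnapshotSchedule:
    """Times at which snapshots of the streams were retained on one trial.

    Anchors at 0 and ``tau_true`` are always present and never forgotten;
    ``intermediate_times`` are the surviving Poisson-process samples, strictly
    inside (0, tau_true) and strictly increasing.  The intermediate times are
    generative bookkeeping only — the estimator never sees them, just their
    count and order.
    """

    tau_true: float
    intermediate_times: np.ndarray
    cap: int = DEFAULT_CAP
    poisson_rate: float = DEFAULT_POISSON_RATE

    def __post_init__(self) -> None:
        t = np.asarray(self.intermediate_times, dtype=float)
        if not self.tau_true > 0:
            raise ValueError("tau_true must be > 0")
        if self.cap < 2:
            raise ValueError("cap must be >= 2 (the two anchors)")
        if t.size:
            if not (np.all(t > 0) and np.all(t < self.tau_true)):
                raise ValueError("intermediates must lie strictly in (0, tau)")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("intermediates must be strictly increasing")
        if t.size + 2 > self.cap:
            raise ValueError("retained snapshots exceed cap")
        object.__setattr__(self, "intermediate_times", t)

    @property
    def n_intermediates(self) -> int:
        return int(self.intermediate_times.size)

    @property
    def n_snapshots(self) -> int:
        return self.n_intermediates + 2

    @property
    def retained_times(self) -> np.ndarray:
        """All retained times in order: 0, intermediates, tau_true."""
        return np.concatenate(
            ([0.0], self.intermediate_times, [self.tau_true])
        )


@dataclass(frozen=True)
class SnapshotSet:
    """Per-stream snapshot values in retained-time order.

    ``values`` has shape (n_streams, n_snapshots); column 0 is the start
    anchor, the last column the end anchor.  Only the count and order of the
    intermediate columns are estimator-visible, never their times.
    """

    values: np.ndarray
    schedule: SnapshotSchedule = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.schedule.n_snapshots:
            raise ValueError("values must be (n_streams, n_snapshots)")
        object.__setattr__(self, "values", v)

    @property
    def n_streams(self) -> int:
        return self.values.shape[0]

    @property
    def n_intermediates(self) -> int:
        return self.schedule.n_intermediates


def draw_schedule(
    tau_true: float,
    cap: int = DEFAULT_CAP,
    poisson_rate: float = DEFAULT_POISSON_RATE,
    seed: int | np.random.Generator = 0,
) -> SnapshotSchedule:
    """Sample a snapshot schedule: anchors plus Poisson intermediates.

    Candidate intermediate times arrive as a Poisson process of rate
    ``poisson_rate`` on (0, tau_true) and are processed in time order.  At
    most ``cap - 2`` intermediates are retained: each arrival beyond capacity
    forgets one of the *previously* retained intermediates uniformly at
    random (new snapshots displace old ones; anchors are never forgotten).
    """
    if not tau_true > 0:
        raise ValueError("tau_true must be > 0")
    if cap < 2:
        raise ValueError("cap must be >= 2 (the two anchors)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    capacity = cap - 2
    n_cand = int(rng.poisson(poisson_rate * tau_true))
    candidates = np.sort(rng.uniform(0.0, tau_true, size=n_cand))
    retained: list[float] = []
    if capacity > 0:
        for t in candidates:
            retained.append(float(t))
            if len(retained) > capacity:
                # forget an older snapshot, uniformly at random
                retained.pop(int(rng.integers(len(retained) - 1)))
    return SnapshotSchedule(
        tau_true=tau_true,
        intermediate_times=np.array(retained),
        cap=cap,
        poisson_rate=poisson_rate,
    )


def observe(
    schedule: SnapshotSchedule,
    kernel_true: KernelSpec,
    n_streams: int = 12,
    seed: int | np.random.Generator = 0,
) -> SnapshotSet:
    """Draw stream values at the schedule's retained times.

    Values are jointly Gaussian under ``kernel_true`` (the generative kernel,
    possibly playback-rescaled), independently per stream.
    """
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    times = schedule.retained_times
    cov = build_covariance(times, kernel_true)
    chol = np.tril(_chol_with_jitter(cov)[0])
    white = rng.standard_normal((n_streams, times.size))
    return SnapshotSet(values=white @ chol.T, schedule=schedule)


# --------------------------------------------------------------------------
# Likelihood over candidate durations
# --------------------------------------------------------------------------

def _ou_kalman_loglik(
    rho: np.ndarray, values: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Gaussian log density of snapshot values under the exponential kernel.

    Exact scalar Kalman filter for the model x_{i+1} = rho_i x_i + w_i,
    y_i = x_i + noise, with stationary unit process variance.  ``rho`` has
    shape (..., m-1) — per-gap correlations exp(-lambda * dt) — and
    ``values`` shape (S, m); the result has shape (..., S), the log density
    of each stream's value vector for every leading batch index.
    """
    values = np.asarray(values, dtype=float)
    n_streams, m = values.shape
    batch = rho.shape[:-1]
    var = noise_sd**2
    pred_var = np.ones(batch)  # predictive variance of x_i, data-independent
    pred_mean = np.zeros(batch + (n_streams,))
    quad = np.zeros(batch + (n_streams,))  # sum of resid^2 / innov_var
    log_terms = np.zeros(batch)  # sum of log innov_var, stream-independent
    for i in range(m):
        innov_var = pred_var + var
        log_terms += np.log(innov_var)
        resid = values[:, i] - pred_mean
        sq = resid * resid
        sq /= innov_var[..., None]
        quad += sq
        if i < m - 1:
            gain = pred_var / innov_var
            r = rho[..., i]
            # pred_mean <- r * (pred_mean + gain * resid), buffers reused
            resid *= gain[..., None]
            pred_mean += resid
            pred_mean *= r[..., None]
            pred_var = r**2 * (pred_var * (1.0 - gain)) + (1.0 - r**2)
    ll = quad
    ll += log_terms[..., None] + m * np.log(2.0 * np.pi)
    ll *= -0.5
    return ll


def _stratified_uniform(
    rng: np.random.Generator, mc_draws: int
) -> np.ndarray:
    """One uniform per draw, stratified over [0, 1] (Latin-hypercube column).

    Marginally uniform with one point per stratum of width 1/D, shuffled so
    that joint use of several stratified dimensions stays unbiased; cuts the
    Monte-Carlo variance of smooth layout functionals substantially.
    """
    return (rng.permutation(mc_draws) + rng.uniform(size=mc_draws)) / mc_draws


def _uniform_gap_patterns(
    n_intermediates: int, mc_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-interval gaps with intermediates as sorted uniform order stats.

    Returns consecutive gaps, shape (mc_draws, k + 1); for k = 0 a single
    exact pattern.  This is the *exact* conditional law whenever the observed
    intermediate count is below capacity (then exactly k Poisson arrivals
    occurred, and Poisson arrival times are iid uniform given their count).
    """
    if n_intermediates == 0:
        return np.ones((1, 1))
    u = np.sort(
        np.column_stack(
            [
                _stratified_uniform(rng, mc_draws)
                for _ in range(n_intermediates)
            ]
        ),
        axis=1,
    )
    pts = np.concatenate(
        [
            np.zeros((mc_draws, 1)),
            u,
            np.ones((mc_draws, 1)),
        ],
        axis=1,
    )
    return np.diff(pts, axis=1)


#: Exact truncated-Poisson inversion below this mean; normal approx above.
_POISSON_EXACT_LAM = 12.0
#: Partner depths beyond this are lumped together (mass 2^-8 < 0.4%).
_MAX_PARTNER_DEPTH = 8


def _truncated_poisson_counts(
    lam: np.ndarray, u: np.ndarray, min_n: int = 2
) -> np.ndarray:
    """Quantile-coupled draws of N ~ Poisson(lam) conditioned on N >= min_n.

    ``lam`` has shape (G,), ``u`` shape (D,) — the same uniform quantile is
    inverted at every grid point, so N varies smoothly with the candidate
    duration (common random numbers).  Exact CDF inversion for small means;
    a rounded normal approximation above ``_POISSON_EXACT_LAM``, where the
    discrete correction is immaterial to the snapshot layout.
    """
    out = np.empty((lam.size, u.size))
    small = lam <= _POISSON_EXACT_LAM
    if np.any(small):
        lam_s = lam[small]
        kmax = int(np.ceil(_POISSON_EXACT_LAM + 10 * np.sqrt(_POISSON_EXACT_LAM)))
        ks = np.arange(kmax + 1)
        log_pmf = (
            ks[None, :] * np.log(lam_s[:, None])
            - lam_s[:, None]
            - np.cumsum(np.concatenate([[0.0], np.log(np.maximum(ks[1:], 1))]))[
                None, :
            ]
        )
        cdf = np.cumsum(np.exp(log_pmf), axis=1)
        rows = np.empty((lam_s.size, u.size))
        for i in range(lam_s.size):
            p_below = cdf[i, min_n - 1]
            q = p_below + u * (1.0 - p_below)
            rows[i] = np.searchsorted(cdf[i], q)
        out[small] = np.maximum(rows, float(min_n))
    if np.any(~small):
        lam_b = lam[~small][:, None]
        from scipy.special import ndtri

        z = ndtri(np.clip(u, 1e-12, 1 - 1e-12))[None, :]
        out[~small] = np.maximum(
            np.rint(lam_b + np.sqrt(lam_b) * z), float(min_n)
        )
    return out


def _forgetting_gap_patterns_cap2(
    tau_grid: np.ndarray,
    poisson_rate: float,
    mc_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact retention law for two retained intermediates (capacity 2).

    Random forgetting displaces old snapshots, so the survivors cluster late:
    with N >= 2 Poisson arrivals the retained pair occupies ranks (N - m, N),
    where the partner depth m is Geometric(1/2) truncated at N - 1 (each new
    arrival evicts one of the two older survivors uniformly at random).
    Conditional on N the arrival times are uniform order statistics, so on
    the unit interval u_(N) = V^(1/N), and u_(N-m) follows by m successive
    conditional-maximum steps u_(r-1) = u_(r) * W^(1/(r-1)).

    N depends on the candidate duration (N ~ Poisson(rate * tau) given
    N >= 2), so the gaps are per-grid-point, shape (G, mc_draws, 3).  All
    underlying uniforms are shared across the grid: layouts vary smoothly
    with the candidate duration (common random numbers).
    """
    lam = np.asarray(poisson_rate, dtype=float) * np.asarray(tau_grid)
    n = _truncated_poisson_counts(
        lam, _stratified_uniform(rng, mc_draws)
    )  # (G, D)
    m_geo = np.minimum(rng.geometric(0.5, size=mc_draws), _MAX_PARTNER_DEPTH)
    m = np.minimum(m_geo[None, :], n - 1.0)
    log_v = np.log(_stratified_uniform(rng, mc_draws))
    u_last = np.exp(log_v[None, :] / n)
    log_w = np.log(rng.uniform(size=(_MAX_PARTNER_DEPTH, mc_draws)))
    u_partner = u_last.copy()
    for j in range(1, _MAX_PARTNER_DEPTH + 1):
        step = np.where(
            j <= m, log_w[j - 1][None, :] / np.maximum(n - j, 1.0), 0.0
        )
        u_partner = u_partner * np.exp(step)
    gaps = np.stack(
        [u_partner, u_last - u_partner, 1.0 - u_last], axis=-1
    )  # (G, D, 3)
    return np.clip(gaps, 0.0, None)


#: Depth-chain steps simulated for general-capacity retention layouts;
#: survival beyond this depth has probability ((c-1)/c)^steps, negligible.
_CHAIN_STEPS = 30


def _forgetting_gap_patterns_general(
    capacity: int,
    tau_grid: np.ndarray,
    poisson_rate: float,
    mc_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Retention-law layouts for a saturated snapshot set of any capacity.

    Direct generalization of the capacity-2 law: the survivor set always
    contains the newest arrival, and each new arrival evicts one of the
    ``capacity`` previously retained intermediates uniformly at random.  The
    joint law of the survivors' depths (arrivals counted back from the last)
    is simulated once per Monte-Carlo draw as an explicit eviction chain,
    truncated at ``_CHAIN_STEPS`` arrivals (the depth distribution mixes
    geometrically, so deeper survivors are negligible).  Conditional on the
    arrival count N the normalized times are uniform order statistics at the
    survivors' ranks, generated by successive conditional-maximum steps
    u_(r-1) = u_(r) * W^(1/(r-1)) with all uniforms shared across the grid
    (common random numbers).

    Returns unit-interval gaps, shape (G, mc_draws, capacity + 1).
    """
    n_older = capacity - 1  # survivors other than the newest arrival
    sentinel = _CHAIN_STEPS + 10**6
    # eviction-chain history: depths of the non-newest survivors after j
    # arrivals, for j = 0.._CHAIN_STEPS
    hist = np.full((_CHAIN_STEPS + 1, mc_draws, n_older), sentinel, dtype=np.int64)
    depths = np.full((mc_draws, n_older), sentinel, dtype=np.int64)
    for j in range(2, _CHAIN_STEPS + 1):
        aged = np.where(depths < sentinel, depths + 1, sentinel)
        if j <= capacity:
            # below capacity every arrival survives: previous newest joins
            # the older set at depth 1
            aged[:, j - 2] = 1
            depths = aged
        else:
            evict = rng.integers(0, capacity, size=mc_draws)
            # evict == 0 drops the previous newest (aged stays as is);
            # evict == i drops older slot i-1, freeing it for the newest
            for i in range(1, capacity):
                hit = evict == i
                aged[hit, i - 1] = 1
            depths = aged
        hist[j] = depths
    lam = np.asarray(poisson_rate, dtype=float) * np.asarray(tau_grid)
    n = _truncated_poisson_counts(
        lam, _stratified_uniform(rng, mc_draws), min_n=capacity
    )  # (G, D)
    j_eff = np.minimum(n, _CHAIN_STEPS).astype(np.int64)
    d_sel = hist[j_eff, np.arange(mc_draws)[None, :], :]  # (G, D, n_older)
    log_v = np.log(_stratified_uniform(rng, mc_draws))
    u_cur = np.exp(log_v[None, :] / n)  # u_(N)
    times = np.empty(tuple(n.shape) + (capacity,))
    times[..., -1] = u_cur
    log_w = np.log(rng.uniform(size=(_CHAIN_STEPS, mc_draws)))
    for s in range(1, _CHAIN_STEPS + 1):
        step = np.where(
            s <= n - 1, log_w[s - 1][None, :] / np.maximum(n - s, 1.0), 0.0
        )
        u_cur = u_cur * np.exp(step)
        for i in range(n_older):
            hit = d_sel[..., i] == s
            if hit.any():
                times[..., i] = np.where(hit, u_cur, times[..., i])
    times.sort(axis=-1)
    pts = np.concatenate(
        [
            np.zeros(times.shape[:-1] + (1,)),
            times,
            np.ones(times.shape[:-1] + (1,)),
        ],
        axis=-1,
    )
    return np.clip(np.diff(pts, axis=-1), 0.0, None)


def _per_stream_log_marginals(
    values: np.ndarray,
    n_intermediates: int,
    tau_grid: np.ndarray,
    kernel_obs: KernelSpec,
    mc_draws: int,
    rng: np.random.Generator,
    intermediate_prior: str = "forgetting",
    poisson_rate: float = DEFAULT_POISSON_RATE,
    capacity: int = DEFAULT_CAP - 2,
) -> np.ndarray:
    """log E_u[ p(values | tau, u) ] per stream, shape (G, S).

    Common random numbers: one set of unit-interval layout draws is scaled to
    every candidate tau, so the Monte-Carlo error is smooth across the grid.
    Under the default ``forgetting`` prior, a saturated capacity-2 snapshot
    set marginalizes the hidden times under the exact Poisson-plus-random-
    forgetting retention law; every other case (count below capacity) uses
    sorted uniform order statistics, which there *is* the exact law.  The
    ``uniform`` prior forces order statistics everywhere (a simpler, slightly
    late-biased approximation; also used for saturated capacities above 2,
    where the retention law is not implemented in closed form).
    """
    if intermediate_prior not in ("forgetting", "uniform"):
        raise ValueError("intermediate_prior must be 'forgetting' or 'uniform'")
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid must be non-empty")
    if intermediate_prior == "forgetting" and n_intermediates == capacity == 2:
        gaps = _forgetting_gap_patterns_cap2(
            tau_grid, poisson_rate, mc_draws, rng
        )  # (G, D, 3)
        lags = tau_grid[:, None, None] * gaps
    elif (
        intermediate_prior == "forgetting"
        and n_intermediates == capacity
        and 3 <= capacity <= 8
    ):
        gaps = _forgetting_gap_patterns_general(
            capacity, tau_grid, poisson_rate, mc_draws, rng
        )  # (G, D, capacity + 1)
        lags = tau_grid[:, None, None] * gaps
    else:
        gaps = _uniform_gap_patterns(n_intermediates, mc_draws, rng)  # (D, m-1)
        lags = tau_grid[:, None, None] * gaps[None, :, :]  # (G, D, m-1)
    rho = np.exp(-kernel_obs.decay_rate * lags)
    ll = _ou_kalman_loglik(rho, values, kernel_obs.noise_sd)  # (G, D, S)
    if ll.shape[1] == 1:
        return ll[:, 0, :]
    peak = ll.max(axis=1)
    np.exp(ll - peak[:, None, :], out=ll)
    return peak + np.log(ll.mean(axis=1))


def stream_likelihood(
    values: np.ndarray,
    n_intermediates: int,
    tau_grid: np.ndarray,
    kernel_obs: KernelSpec,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed: int | np.random.Generator = 0,
    intermediate_prior: str = "forgetting",
    poisson_rate: float = DEFAULT_POISSON_RATE,
    capacity: int = DEFAULT_CAP - 2,
) -> LikelihoodCurve:
    """Normalized likelihood of elapsed time from one stream's snapshots.

    ``values`` are the retained snapshot values in order (start anchor,
    intermediates, end anchor).  For each candidate tau the hidden
    intermediate times are marginalized under their conditional law given the
    observed count — the Poisson-plus-forgetting retention law (default) or
    plain sorted uniform order statistics — by Monte-Carlo average over
    ``mc_draws`` layouts with common random numbers (exact when
    ``n_intermediates`` is 0).  The returned curve sums to 1 on the grid.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != 1:
        values = values.reshape(1, -1)
    if values.shape[1] != n_intermediates + 2:
        raise ValueError("values length must equal n_intermediates + 2")
    if mc_draws < 1:
        raise ValueError("mc_draws must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    logm = _per_stream_log_marginals(
        values,
        n_intermediates,
        tau_grid,
        kernel_obs,
        mc_draws,
        rng,
        intermediate_prior,
        poisson_rate,
        capacity,
    )
    return LikelihoodCurve.from_log_weights(tau_grid, logm[:, 0])


def trial_likelihood(
    snapshots: SnapshotSet,
    tau_grid: np.ndarray,
    kernel_obs: KernelSpec,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed: int | np.random.Generator = 0,
    intermediate_prior: str = "forgetting",
) -> LikelihoodCurve:
    """Combined normalized likelihood from all streams of one trial.

    Equals ``combine_streams`` over the per-stream curves computed with
    shared Monte-Carlo layouts, evaluated jointly for speed (one Kalman sweep
    covers every stream).  The snapshot schedule supplies the retention
    parameters (cap, Poisson rate) for the hidden-time marginalization.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    sched = snapshots.schedule
    logm = _per_stream_log_marginals(
        snapshots.values,
        snapshots.n_intermediates,
        tau_grid,
        kernel_obs,
        mc_draws,
        rng,
        intermediate_prior,
        sched.poisson_rate,
        sched.cap - 2,
    )  # (G, S)
    return LikelihoodCurve.from_log_weights(tau_grid, logm.sum(axis=1))
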