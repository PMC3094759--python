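# Methods

## Sensory streams

Each sensory stream is a stationary, zero-mean, unit-variance Gaussian
process with exponential (Ornstein–Uhlenbeck) covariance
`exp(-λ|Δt|) + σ²δ`, the Lorentzian-spectrum realisation of the ~1/f²
temporal statistics of natural image sequences. Defaults: decay rate
λ = 0.01 s⁻¹ (correlation time 100 s) and measurement-noise sd σ = 0.1,
with the noise on the diagonal only (independent per sample). Streams are
mutually independent; 12 are tracked by default, standing in for luminance
at well-separated retinal points. Playback at speed *s* is modelled by
multiplying λ by *s* (time compression shifts the spectrum by *s*); the
measurement noise, injected at sampling, is unchanged.

The kernel family is a registered extension point; only the exponential
form is implemented, and "variant spectrum" analyses use the exponential
with an altered decay rate.

## Snapshot observer

A trial of true duration τ yields per-stream snapshots at the interval's
start and end (anchors, never forgotten) plus intermediates from a Poisson
process of rate 1 s⁻¹ on (0, τ), subject to random forgetting: each arrival
beyond the capacity (cap − 2, default 2) evicts one previously retained
intermediate uniformly at random. The estimator sees snapshot values and
their order, never the intermediate times.

For each candidate duration on a log-spaced grid of 200 points spanning
[τ/20, 20τ], the likelihood of one stream's values marginalizes the hidden
intermediate times under their conditional law given the retained count k:

* **k below capacity.** Exactly k Poisson arrivals occurred, so the times
  are sorted uniform order statistics on (0, τ) — exact, no approximation.
* **k equal to capacity (saturated).** Forgetting biases survivors toward
  the end of the interval. For the eviction rule above the law is closed
  enough to sample exactly: with N ≥ k arrivals (N ~ Poisson(rate·τ)
  conditioned ≥ k), the newest arrival always survives and the remaining
  survivor depths follow an explicit eviction chain — for capacity 2 the
  partner depth is Geometric(1/2) truncated at N − 1. Conditional on N the
  times are uniform order statistics at the survivors' ranks. The chain is
  simulated exactly (truncated at 30 arrivals, beyond which survival
  probability is ((c−1)/c)³⁰ ≈ 10⁻⁴ for capacity 2); order statistics are
  generated by successive conditional-maximum steps. An alternative
  `uniform` prior (plain order statistics everywhere) is kept as an option;
  it under-weights late layouts and biases estimates at long intervals by a
  few percent.

The marginalization is a Monte-Carlo average over 128 layout draws by
default, with every underlying uniform shared across the candidate grid
(common random numbers), so the likelihood curve is smooth in τ; the
truncated-Poisson count is inverted through the shared quantile (exact CDF
inversion below mean 12, rounded normal approximation above). The principal
layout quantiles (arrival count, last-arrival position, order-statistic
dimensions) are stratified over [0, 1] (Latin-hypercube columns), which
keeps the estimator unbiased while cutting its variance severalfold.
Doubling the draw count at 2000 moves normalized weights by well under 1%
(tested).

The per-candidate Gaussian density is computed by an exact scalar Kalman
filter — the state-space form of the OU process with white measurement
noise — which is algebraically identical to the dense multivariate-normal
density (asserted against a Cholesky-based oracle to 1e-10 in the tests)
and vectorizes across grid, draws and streams. Likelihood curves are
accumulated in log space and normalized after subtracting the maximum.
Streams multiply; the grid argmax (first index on ties, i.e. smallest τ) is
the sensory ML estimate. The estimator deliberately does **not** use the
probability of the retained count itself, P(k | τ): the snapshot count is
bookkeeping of the sampling process, and using it would inject the
snapshot-rate timescale directly into the estimate.

## Internal belief and fusion

The internal (stimulus-independent) belief is a gamma density parameterized
by mode and shape. The trial's mode is τ times a log-normal multiplier with
mean 1 and coefficient of variation 0.15 (Weber scatter of the internal
clock; log-normal is the minimal positive multiplicative choice). The shape
is fixed at 1/w² with w = 0.15, so each trial's belief width also scales
with its mode (scalar-consistent). Both 0.15 defaults sit in the classic
human timing range; neither is derived from data here. A log-normal belief
family and a flat (uninformative) option are provided — downstream
qualitative results do not depend on the family, and the tests exercise the
log-normal variant.

Fusion is Bayes' rule on the shared grid: pointwise product, renormalized.
A zero product raises a degenerate-posterior error (grid misconfiguration).
The posterior argmax (MAP) is the reported duration.

## Counting observer

Events are upward crossings (value[i−1] < θ ≤ value[i]) of the latent
stream by the threshold θ = +1 process-sd, detected on an exact-transition
OU simulation with step 0.05 s. Measurement noise is excluded from event
detection: white noise would make the discrete crossing count a property of
the noise amplitude and step, not of the stream. Crossing counts of an OU
process are discretization-sensitive (the continuous-time process is
non-differentiable), so the step is an explicit, recorded model parameter.

The event detector abstracts a spatial feature detector scanning the whole
stimulus field, so it draws on many more independent event sources than the
12 tracked snapshot streams: `count_streams` defaults to 200. With only 12
sources the summed count carries negligible precision next to the internal
belief and no count-based signature survives fusion.

The observer "knows the true statistics of event occurrence" via an
empirical table: counts tallied from simulated streams across 24
logarithmic duration bins on [0.5, 40] s, 400 repetitions per bin, built
under the same kernel, threshold, step and stream count used at test time.
P(τ | N) is the observed-count column as a per-second density over bin
midpoints, smoothed by one pseudo-trial spread uniformly over the table
span (a constant density floor — adding a whole pseudo-count per *cell*
would hand narrow bins a spurious density advantage), interpolated onto the
candidate grid and normalized. The counting observer's grid is fixed to the
table span, independent of the hidden true duration.

At the natural λ = 0.01 s⁻¹, behavioural durations (seconds) lie far inside
the 100 s correlation time, where the count variance grows *faster* than
linearly with duration (the stream's level is nearly frozen within a trial,
so the trial-to-trial rate variation contributes a quadratic term). This
makes the counting observer even more sub-Weberian there. The classical
linear-variance law holds once durations exceed the correlation time; the
test suite verifies the log-log slope of count variance versus duration in
that mixing regime (λ = 1 s⁻¹, step 0.01 s ≪ 1/λ).

## Harnesses

All harnesses derive one RNG substream per trial coordinate from the master
seed (CRC-mixed key paths), so results are independent of execution order
and exactly reproducible from (config, seed); summaries are pure functions
of the emitted trial records. Matched designs share draws: the bias harness
reuses each trial's internal belief across playback speeds; the precision
harness pairs internal-only and fused conditions on the same belief; the
Weber harness shares the internal peak multiplier across durations and
counts events in nested windows of one long simulation per trial, so
cross-duration contrasts are paired.

* **Bias.** Speeds {¼, ½, 1, 2, 4} (log-symmetric around natural), 1-second
  stimuli: generative kernel rescaled, observer kernel natural. Mean
  estimates are normalized by the grand average over speeds. Both fused and
  pure-sensory estimates are recorded; the fused estimator is the default
  readout — sensory-only biases approach the playback factor itself, while
  fusion with the internal belief produces the order-10% biases of interest.
* **Precision.** Default duration 5 s (sensory information appreciable),
  5000 trials; relative variability (sd of point estimates across trials ÷
  their mean — the behavioural spread, not single-trial posterior width) of
  fused versus internal-only estimates.
* **Weber.** Relative variability versus τ ∈ {2.5, 5, 10} s for
  change-fused, change-sensory, internal-only, count-fused, count-sensory.
* **Scalar.** Pure-sensory ML estimates divided by τ, per variant (default;
  doubled decay rate; caps 2 and 6), compared across durations by
  two-sample KS distance against a permutation-calibrated 5% critical value.

## Psychophysical readouts

The psychometric curve is lapse/2 + (1 − lapse)·Φ((x − μ)/σ_w), fit by
maximum likelihood over a fixed multi-start grid (deterministic); lapse is
bounded by 0.1 (standard practice). Variability is the reciprocal of the
maximal slope of the lapse-independent curve, σ_w·√(2π). Complete
separation is flagged (`identified=False`) with the bounded width reported.

Staircases are 1-up/1-down on the duration difference Δ with step halving
at reversals (floor step/8) and PSE the mean of the last 6 of 12 reversals;
the base duration varies pseudorandomly on [0.5, 0.65] s. A single
staircase started from one side carries a start-side offset (step halving
freezes the walk near its first reversal), so PSEs are read from pairs of
staircases approaching from above and below, mirroring the interleaved
two-staircase design; their offsets cancel.

Long/short classification compares each fused estimate to a reference —
the running mean of previous estimates in the block (warmed up on the true
block mean for the first 5 trials) or, optionally, the true block mean.
Proportions of "long" are fit on a ratio axis (duration ÷ block mean), on
which the fitted variability is already the relative variability; a linear
axis (seconds, divided by the block mean afterwards) is available. The two
axes agree to first order and the choice is a convention.

Model observers enter all three designs as estimator callables
`(tau, playback_speed, rng) -> seconds`, so change-based, count-based and
surrogate observers are interchangeable.

## Noise movies

Movies are synthesized spectrally: complex Gaussian Fourier coefficients
with amplitude ∝ |f|⁻¹ (1/f² spatial power; exponent configurable), DC
zeroed, each coefficient evolving frame-to-frame by the exact stationary OU
update with rate λ·playback_speed. Pixels are Gaussian, zero-mean,
unit-variance by construction (amplitudes scaled via Parseval), with
temporal autocorrelation equal to the temporal kernel. Static mode freezes
one frame. Because the spatial power law concentrates energy at low
frequencies, pixel streams retain some long-range spatial correlation even
at large separations — extracted streams are "weakly correlated" rather
than exactly independent, and the extraction enforces a configurable
minimum separation. 8-bit export clips at ±3 sd (display only).

## What the synthetic data do and do not show

Every input is generated by the package itself under the model's own
assumptions: Gaussian streams with exactly known second-order statistics,
an observer that knows those statistics, and an internal belief with clean
Weber scatter. Passing tests therefore demonstrate the *internal
consistency* of the framework and the direction and rough size of its
behavioural predictions — not that human observers implement it. Real
sensory streams are non-Gaussian and spatially correlated, real observers'
expectations adapt, and visual temporal filtering reshapes the effective
stimulus spectrum; none of that is modelled.

## Known limitations

* Scale invariance is approximate. The fixed observation noise σ and the
  absolute rate-1 snapshot timescale both break exact scaling: normalized
  estimate distributions are slightly wider at 5 s than at 10 s (the noise
  floor matters more when the signal change is smaller), a difference of
  order ten percent in width that density histograms would not resolve but
  that a two-sample KS test at 500 trials per group detects roughly half
  the time — the corresponding acceptance test documents this boundary
  case. Far shorter intervals are noise-dominated and visibly non-scalar;
  far longer ones saturate the kernel.
* The saturated-retention layout law is implemented exactly for capacities
  up to 8 via the eviction chain, with the chain truncated at 30 arrivals.
* Count-table quality degrades for counts far outside the simulated range;
  counts beyond the table maximum are clipped (logged) at test time.
* The counting observer's event-source count and detector resolution are
  not identified by anything in the data — they set the strength, not the
  direction, of the sub-Weberian signature.
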