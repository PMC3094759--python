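"""Spatiotemporally smooth power-law Gaussian noise movies.

The behavioural stimuli are "rolling cloud" movies: Gaussian random fields
whose spatial amplitude spectrum follows a power law (default exponent 1 on
amplitude, i.e. 1/f^2 power, the natural-scene family) and whose temporal
evolution follows the exponential kernel per spatial-frequency component.

Synthesis is spectral: each Fourier coefficient is an independent complex
Gaussian with amplitude A(f) proportional to |f|^-a, evolved frame-to-frame
by the exact stationary OU update c' = rho c + sqrt(1 - rho^2) eps with
rho = exp(-lambda_eff * dt), where lambda_eff is the kernel's decay rate
multiplied by the playback speed.  Every pixel trace is therefore Gaussian,
zero mean, unit variance, with temporal autocorrelation exp(-lambda_eff lag).
A static mode repeats a single frozen frame (zero temporal change), matching
the no-temporal-cue control condition.

Pixel streams extracted at well-separated locations serve as direct inputs
to the snapshot observer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, rescale_kernel

__all__ = ["MovieSpec", "generate_movie", "pixel_streams", "save_frames_pgm"]


@dataclass(frozen=True)
class MovieSpec:
    """Parameters of a noise movie.

    ``spatial_exponent`` applies to the amplitude spectrum (power falls as
    twice the exponent); ``frame_interval`` is the sample interval in
    seconds; ``playback_speed`` scales the temporal decay rate (displaying
    sampled frames faster shifts the spectrum to higher frequencies).
    """

    size: int = 64
    n_frames: int = 25
    frame_interval: float = 0.04
    spatial_exponent: float = 1.0
    temporal_kernel: KernelSpec = field(default_factory=KernelSpec)
    playback_speed: float = 1.0
    mode: str = "dynamic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("size must be >= 2")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.playback_speed > 0:
            raise ValueError("playback_speed must be > 0")
        if self.mode not in ("dynamic", "static"):
            raise ValueError("mode must be 'dynamic' or 'static'")


def _amplitude_spectrum(size: int, exponent: float) -> np.ndarray:
    """Power-law amplitude array on the FFT grid, scaled for unit pixel var.

    For a field y = Re(ifft2(Z)) with independent complex-Gaussian
    coefficients Z_k of amplitude A_k (ifft2 divides by the pixel count
    N = size^2), the pixel variance is sum(A_k^2) / (2 N^2); A is scaled so
    that this equals 1.  The DC component is zeroed (zero-mean frames).
    """
    f = np.fft.fftfreq(size)
    fmag = np.hypot(f[:, None], f[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(fmag > 0, fmag**-exponent, 0.0)
    amp *= size**2 * np.sqrt(2.0 / np.sum(amp**2))
    return amp


def generate_movie(spec: MovieSpec) -> np.ndarray:
    """Synthesize a (n_frames, size, size) Gaussian noise movie.

    Reproducible from ``spec.seed``; distinct seeds give independent draws
    (one fresh draw per presentation).  Pixel values are zero mean and unit
    variance by construction.
    """
    rng = np.random.default_rng(spec.seed)
    amp = _amplitude_spectrum(spec.size, spec.spatial_exponent)

    def draw_coeffs() -> np.ndarray:
        z = rng.standard_normal((spec.size, spec.size)) + 1j * rng.standard_normal(
            (spec.size, spec.size)
        )
        return amp * z / np.sqrt(2.0)

    coeffs = draw_coeffs()
    first = np.real(np.fft.ifft2(coeffs))
    if spec.mode == "static":
        return np.broadcast_to(first, (spec.n_frames, spec.size, spec.size)).copy()
    kern = rescale_kernel(spec.temporal_kernel, spec.playback_speed)
    rho = float(np.exp(-kern.decay_rate * spec.frame_interval))
    innov = float(np.sqrt(1.0 - rho**2))
    frames = np.empty((spec.n_frames, spec.size, spec.size))
    frames[0] = first
    for i in range(1, spec.n_frames):
        coeffs = rho * coeffs + innov * draw_coeffs()
        frames[i] = np.real(np.fft.ifft2(coeffs))
    return frames


def pixel_streams(
    movie: np.ndarray,
    n_pixels: int = 12,
    min_separation: float = 16.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract stream values at random, minimum-separated pixel locations.

    Separation is Euclidean in pixels.  Returns (values, positions) with
    ``values`` of shape (n_pixels, n_frames) — already standardized (zero
    mean, unit variance by movie construction) and directly usable as
    observer stream inputs — and ``positions`` of shape (n_pixels, 2)
    (row, col).
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be (n_frames, height, width)")
    _, h, w = movie.shape
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    # rejection sampling with restarts: a greedy prefix can wedge near the
    # packing limit, so a stalled attempt is abandoned and retried fresh
    positions: list[tuple[int, int]] = []
    attempts = 0
    stall = 0
    stall_limit = max(max_attempts // 20, 50)
    while len(positions) < n_pixels:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_pixels} pixels with separation "
                f">= {min_separation} in a {h}x{w} frame"
            )
        attempts += 1
        cand = (int(rng.integers(h)), int(rng.integers(w)))
        if all(
            np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation
            for p in positions
        ):
            positions.append(cand)
            stall = 0
        else:
            stall += 1
            if stall >= stall_limit:
                positions.clear()
                stall = 0
    pos = np.array(positions)
    values = movie[:, pos[:, 0], pos[:, 1]].T.copy()
    return values, pos


def save_frames_pgm(
    movie: np.ndarray, out_dir: str, clip_sd: float = 3.0
) -> list[str]:
    """Export frames as 8-bit grayscale ASCII PGM images.

    Values are clipped at +/- ``clip_sd`` standard deviations and mapped
    linearly onto 0..255 (display-only transformation).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    scaled = np.clip(movie, -clip_sd, clip_sd)
    scaled = ((scaled + clip_sd) / (2 * clip_sd) * 255).astype(np.uint8)
    for i, frame in enumerate(scaled):
        path = os.path.join(out_dir, f"frame_{i:04d}.pgm")
        with open(path, "w") as fh:
            fh.write(f"P2\n{frame.shape[1]} {frame.shape[0]}\n255\n")
            for row in frame:
                fh.write(" ".join(map(str, row)) + "\n")
        paths.append(path)
    return paths
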