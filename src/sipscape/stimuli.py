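"""Random-phase stimulus synthesis and Fourier spectral-slope estimation.

Random-phase images have a prescribed radial power spectrum, power(f) ∝ f^α
with α the *set slope* of the log-log plot of Fourier power versus spatial
frequency, and uniformly random phases, so they carry no recognisable
content.  Natural scenes and visual artworks cluster near α ≈ −2; the study
design spans α ∈ {−5, …, 0}.  Colored stimuli are obtained by placing three
independent same-slope grayscale syntheses in the R, G and B channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandomPhaseSpec",
    "SlopeEstimate",
    "synthesize_gray_random_phase",
    "synthesize_colored_random_phase",
    "measure_fourier_slope",
    "compute_visual_angle",
    "default_fit_range",
]

#: Rec. 709 luma weights used wherever an RGB image must be reduced to
#: a single luminance channel.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


class InvalidSpecError(ValueError):
    """Raised for a malformed random-phase specification."""


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot support a log-log slope fit."""


@dataclass(frozen=True)
class RandomPhaseSpec:
    """Specification of one random-phase synthesis.

    Parameters
    ----------
    size_px:
        Square side length in pixels.  Must be even and at least 16.
    set_slope:
        Target slope α of log power vs log spatial frequency.  The study
        used α ∈ {−5, −4, −3, −2, −1, 0}; any real value is accepted.
    seed:
        Master seed.  All randomness of the synthesis derives from it.
    """

    size_px: int = 1024
    set_slope: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 16 or self.size_px % 2 != 0:
            raise InvalidSpecError(
                f"size_px must be an even integer >= 16, got {self.size_px}"
            )
        if not np.isfinite(self.set_slope):
            raise InvalidSpecError("set_slope must be finite")


@dataclass(frozen=True)
class SlopeEstimate:
    """Least-squares slope of log radial power vs log spatial frequency."""

    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple[float, float]


def _radial_frequency(size: int) -> np.ndarray:
    """Radial frequency grid in cycles/image for an FFT-ordered spectrum."""
    f1 = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(f1, f1, indexing="xy")
    return np.hypot(fx, fy)


def _synthesize_gray(size: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Core synthesis: amplitude ∝ f^(slope/2), i.i.d. uniform phases.

    The inverse transform's real part is taken, which is equivalent to
    Hermitian-symmetrising the spectrum; the symmetrisation rescales
    expected power uniformly across frequencies and therefore leaves the
    spectral slope untouched.  The DC term is zeroed (the f=0 power law is
    undefined) and the result is linearly rescaled to [0, 1].
    """
    f = _radial_frequency(size)
    with np.errstate(divide="ignore"):
        amplitude = np.where(f > 0, f, 1.0) ** (slope / 2.0)
    amplitude[0, 0] = 0.0
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(size, size))
    spectrum = amplitude * np.exp(1j * phase)
    img = np.fft.ifft2(spectrum).real
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        # slope 0 with pathological phases could in principle collapse;
        # return a flat mid-gray field rather than divide by zero.
        return np.full((size, size), 0.5)
    return (img - lo) / (hi - lo)


def synthesize_gray_random_phase(
    spec: RandomPhaseSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Synthesize one grayscale random-phase image in [0, 1].

    Deterministic given ``spec`` (the generator defaults to
    ``np.random.default_rng(spec.seed)``); pass ``rng`` explicitly to use a
    sub-stream, e.g. for color channels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _synthesize_gray(spec.size_px, spec.set_slope, rng)


def synthesize_colored_random_phase(
    spec: RandomPhaseSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Synthesize a colored random-phase image (H×W×3 in [0, 1]).

    Three independent grayscale syntheses with the same set slope are merged
    into the R, G and B channels.  Channel sub-streams are the three children
    of ``SeedSequence(spec.seed)``, so the output is reproducible from the
    master seed alone and the channels are statistically independent
    (pairwise correlation ≈ 0 in expectation).  A caller-supplied ``rng`` is
    used sequentially for the three channels instead.
    """
    if rng is None:
        children = np.random.SeedSequence(spec.seed).spawn(3)
        streams = [np.random.default_rng(c) for c in children]
    else:
        streams = [rng, rng, rng]
    channels = [
        _synthesize_gray(spec.size_px, spec.set_slope, streams[i]) for i in range(3)
    ]
    return np.stack(channels, axis=-1)


def default_fit_range(size_px: int) -> tuple[float, float]:
    """Default radial fit range (10, size/4) cycles/image.

    The lower bound avoids DC leakage and poorly populated low-frequency
    annuli; the upper bound stays clear of the anisotropic spectrum corners
    beyond the Nyquist circle.
    """
    return (10.0, size_px / 4.0)


def _to_luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[2] == 3:
        return np.asarray(img, dtype=float) @ LUMA_WEIGHTS
    raise ValueError(f"expected H×W or H×W×3 image, got shape {img.shape}")


def radial_power_profile(
    img: np.ndarray,
    fit_range: tuple[float, float] | None = None,
    n_bins: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged power spectrum in log-spaced radial bins.

    Returns ``(freq, power)``: the geometric-mean frequency and the mean
    power of each non-empty bin.  Frequencies are in cycles/image.
    """
    lum = _to_luminance(img)
    size = min(lum.shape)
    if fit_range is None:
        fit_range = default_fit_range(size)
    f_min, f_max = fit_range
    nyquist = size / 2.0
    if not (1.0 <= f_min < f_max <= nyquist):
        raise ValueError(
            f"fit_range {fit_range} outside [1, Nyquist={nyquist}] or inverted"
        )
    power = np.abs(np.fft.fft2(lum)) ** 2
    f = _radial_frequency(lum.shape[0]) if lum.shape[0] == lum.shape[1] else None
    if f is None:
        f1 = np.fft.fftfreq(lum.shape[0]) * lum.shape[0]
        f2 = np.fft.fftfreq(lum.shape[1]) * lum.shape[1]
        fx, fy = np.meshgrid(f2, f1, indexing="xy")
        f = np.hypot(fx, fy)
    edges = np.logspace(math.log10(f_min), math.log10(f_max), n_bins + 1)
    which = np.digitize(f.ravel(), edges) - 1
    mask = (which >= 0) & (which < n_bins) & (f.ravel() >= f_min) & (f.ravel() <= f_max)
    which = which[mask]
    pw = power.ravel()[mask]
    fr = f.ravel()[mask]
    freqs, powers = [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        freqs.append(np.exp(np.mean(np.log(fr[sel]))))
        powers.append(pw[sel].mean())
    return np.asarray(freqs), np.asarray(powers)


def measure_fourier_slope(
    img: np.ndarray,
    fit_range: tuple[float, float] | None = None,
    n_bins: int = 30,
) -> SlopeEstimate:
    """Estimate the Fourier spectral slope of an image.

    RGB input is converted to luminance (Rec. 709); the 2-D power spectrum
    is rotationally averaged into log-spaced radial bins and a least-squares
    line is fit to log10(power) vs log10(frequency) over ``fit_range``
    (default (10, size/4) cycles/image).
    """
    lum = _to_luminance(img)
    if np.ptp(lum) == 0:
        raise DegenerateSpectrumError("constant image has no spectral slope")
    freq, power = radial_power_profile(img, fit_range=fit_range, n_bins=n_bins)
    if len(freq) < 3:
        raise DegenerateSpectrumError("fewer than 3 populated radial bins")
    if np.any(power <= 0):
        raise DegenerateSpectrumError("empty power in fit range")
    x = np.log10(freq)
    y = np.log10(power)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    size = min(lum.shape)
    fr = fit_range if fit_range is not None else default_fit_range(size)
    return SlopeEstimate(float(slope), float(intercept), float(r2), tuple(fr))


def compute_visual_angle(stimulus_width_cm: float, viewing_distance_cm: float) -> float:
    """Visual angle in degrees subtended by a stimulus: 2·atan(w / 2d)."""
    if stimulus_width_cm <= 0 or viewing_distance_cm <= 0:
        raise ValueError("stimulus width and viewing distance must be positive")
    return math.degrees(2.0 * math.atan(stimulus_width_cm / (2.0 * viewing_distance_cm)))
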