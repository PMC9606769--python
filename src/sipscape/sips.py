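"""Statistical image properties (SIPs).

A SIP is a scalar, objective descriptor of an image's formal structure.
This module computes the eight model SIPs used throughout the analysis —
complexity, PHOG self-similarity, second-order edge-orientation entropy,
the filter-bank variance measures P_a(2) and P_f(30), mean CIELab b, mean
HSV saturation, and hue entropy — together with the auxiliary SIPs they are
conventionally reported against (Fourier slope, first-order entropy, PHOG
anisotropy, mirror symmetry, the remaining P_a/P_f pooling grids, and the
remaining colour statistics).

All measures are computed after resampling the image to a fixed square
resolution (default 800×800), so they are invariant to the stored size of
the input.  Gradient fields use central differences with periodic (wrap)
boundary handling; filter responses are circular cross-correlations.  These
conventions make an image tiled in register with the spatial-pyramid grid
exactly self-similar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv, rgb2lab
from skimage.filters import gabor_kernel
from skimage.transform import resize

from .stimuli import LUMA_WEIGHTS, default_fit_range, measure_fourier_slope

__all__ = [
    "SIPConfig",
    "FilterBank",
    "default_filter_bank",
    "compute_sip_vector",
    "compute_sip_table",
    "gradient_complexity",
    "phog_features",
    "edge_orientation_entropies",
    "filter_variance_features",
    "color_statistics",
    "mirror_symmetry_lrud",
    "SIP_NAMES",
    "EIGHT_MODEL_SIPS",
    "POOL_GRIDS",
]

POOL_GRIDS = (2, 4, 8, 16, 30)

#: Canonical column order of a SIP table.
SIP_NAMES = (
    "complexity",
    "self_similarity",
    "phog_anisotropy",
    "entropy_first_order",
    "entropy_second_order",
    *[f"variance_Pa_{k}" for k in POOL_GRIDS],
    *[f"variance_Pf_{k}" for k in POOL_GRIDS],
    "lab_L_mean",
    "lab_a_mean",
    "lab_b_mean",
    "hsv_H_mean",
    "hsv_S_mean",
    "hsv_V_mean",
    "entropy_hsv_H",
    "entropy_hsv_S",
    "entropy_hsv_V",
    "symmetry_lrud",
    "fourier_slope",
)

#: The eight largely independent model SIPs the regression analyses use.
EIGHT_MODEL_SIPS = (
    "complexity",
    "self_similarity",
    "entropy_second_order",
    "variance_Pa_2",
    "variance_Pf_30",
    "lab_b_mean",
    "hsv_S_mean",
    "entropy_hsv_H",
)

IMAGE_CATEGORIES = ("original", "random_phase", "style_transferred", "reference")


class FormatError(ValueError):
    """Input is not a decodable RGB raster."""


class DegenerateImageError(ValueError):
    """The image lacks the structure a measure needs (e.g. zero gradient)."""


class InsufficientEdgesError(DegenerateImageError):
    """Fewer edge pixels than orientation bins."""


class GridError(ValueError):
    """Pooling grid larger than the pooled response map."""


@dataclass(frozen=True)
class SIPConfig:
    """Tunable parameters of the SIP computation.

    resolution:
        Square side every image is resampled to before measurement.
        The study convention is 800; tests use smaller sizes.
    phog_levels / phog_bins:
        Spatial-pyramid depth and orientation bins of the PHOG measures.
    n_orientations / n_edges / edge_sigma:
        Oriented-edge extraction: number of first-derivative-of-Gaussian
        orientations, number of strongest non-overlapping edge pixels kept,
        and the Gaussian scale (pixels).
    n_distance_bins / max_pairs / pair_seed:
        Second-order entropy pair handling: log-spaced edge-pair distance
        bins, cap on enumerated pairs, and the seed of the subsampling RNG.
    conv_stride:
        Subsampling stride applied to filter-bank response maps before
        pooling (1 = dense).
    allow_grayscale:
        Promote single-channel input to RGB instead of raising.
    """

    resolution: int = 800
    phog_levels: int = 3
    phog_bins: int = 16
    n_orientations: int = 24
    n_edges: int = 10_000
    edge_sigma: float = 1.0
    nms_radius: int = 3
    n_distance_bins: int = 20
    max_pairs: int = 1_000_000
    pair_seed: int = 0
    conv_stride: int = 1
    slope_bins: int = 30
    allow_grayscale: bool = False


DEFAULT_CONFIG = SIPConfig()


# ---------------------------------------------------------------------------
# shared low-level pieces
# ---------------------------------------------------------------------------

def _as_rgb(img: np.ndarray, allow_grayscale: bool = False) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        if not allow_grayscale:
            raise FormatError("single-channel image; enable allow_grayscale to promote")
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected H×W×3 image, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise FormatError("image contains non-finite values")
    return np.clip(img, 0.0, 1.0)


def _wrap_gradient(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences with periodic boundary; returns (gx, gy)."""
    gx = (np.roll(channel, -1, axis=1) - np.roll(channel, 1, axis=1)) / 2.0
    gy = (np.roll(channel, -1, axis=0) - np.roll(channel, 1, axis=0)) / 2.0
    return gx, gy


def _lab_255(img: np.ndarray) -> np.ndarray:
    """CIELab channels rescaled to a common 0–255 span (L×2.55; a, b as-is)."""
    lab = rgb2lab(img)
    lab = lab.copy()
    lab[..., 0] *= 2.55
    return lab


def lab_gradient_field(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HOG-style colour gradient field.

    Per pixel: gradient magnitude of each (0–255 scaled) Lab channel; the
    channel with the largest magnitude wins and supplies both the reported
    magnitude and the (unsigned, mod 180°) orientation.
    Returns ``(magnitude, orientation_deg)``.
    """
    lab = _lab_255(img)
    mags = np.empty(lab.shape)
    oris = np.empty(lab.shape)
    for c in range(3):
        gx, gy = _wrap_gradient(lab[..., c])
        mags[..., c] = np.hypot(gx, gy)
        oris[..., c] = np.degrees(np.arctan2(gy, gx)) % 180.0
    best = np.argmax(mags, axis=-1)
    take = np.take_along_axis
    magnitude = take(mags, best[..., None], axis=-1)[..., 0]
    orientation = take(oris, best[..., None], axis=-1)[..., 0]
    return magnitude, orientation


def _weighted_orientation_hist(
    orientation: np.ndarray, magnitude: np.ndarray, bins: int
) -> np.ndarray:
    idx = np.floor(orientation / 180.0 * bins).astype(int)
    idx = np.clip(idx, 0, bins - 1)
    return np.bincount(idx.ravel(), weights=magnitude.ravel(), minlength=bins)


def _normalize_hist(h: np.ndarray) -> np.ndarray:
    s = h.sum()
    return h / s if s > 0 else np.zeros_like(h)


def histogram_intersection(h: np.ndarray, g: np.ndarray) -> float:
    """HIK similarity Σ min(hᵢ, gᵢ) of two L1-normalized histograms."""
    return float(np.minimum(h, g).sum())


def _cell_slices(n: int, cells: int) -> list[slice]:
    bounds = np.linspace(0, n, cells + 1).astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(cells)]


def _shannon_entropy(p: np.ndarray, base: float = math.e) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum() / math.log(base))


# ---------------------------------------------------------------------------
# complexity (HOG gradient strength)
# ---------------------------------------------------------------------------

def gradient_complexity(img: np.ndarray) -> float:
    """Mean gradient strength of the colour gradient image.

    First-derivative magnitudes are taken per Lab channel (scaled to a
    0–255 span), the pixelwise maximum over channels is the gradient image,
    and its mean is the complexity.  0 exactly for constant images.
    """
    magnitude, _ = lab_gradient_field(_as_rgb(img))
    return float(magnitude.mean())


# ---------------------------------------------------------------------------
# PHOG: self-similarity, anisotropy
# ---------------------------------------------------------------------------

def _pyramid_histograms(
    magnitude: np.ndarray, orientation: np.ndarray, level: int, bins: int
) -> np.ndarray:
    """L1-normalized orientation histograms of the 2^L × 2^L cell grid."""
    cells = 2 ** level
    rows = _cell_slices(magnitude.shape[0], cells)
    cols = _cell_slices(magnitude.shape[1], cells)
    out = np.empty((cells * cells, bins))
    i = 0
    for r in rows:
        for c in cols:
            h = _weighted_orientation_hist(orientation[r, c], magnitude[r, c], bins)
            out[i] = _normalize_hist(h)
            i += 1
    return out


def phog_features(
    img: np.ndarray, levels: int = 3, bins: int = 16
) -> dict[str, float]:
    """PHOG self-similarity, anisotropy and complexity.

    self_similarity:
        Median over the level-``levels`` cells of the histogram-intersection
        kernel between each cell's orientation histogram and the whole-image
        (ground) histogram; 1 for images tiled in register with the grid.
    anisotropy:
        Standard deviation of the bin strengths of the level-``levels``
        normalized histograms, rescaled by the one-hot maximum
        √(B−1)/B so a single-orientation image scores 1.
    phog_complexity:
        Mean gradient strength on the 0–255 scale, divided by 255.
    """
    magnitude, orientation = lab_gradient_field(_as_rgb(img))
    if magnitude.sum() <= 0:
        raise DegenerateImageError("zero-gradient image: PHOG undefined")
    ground = _normalize_hist(_weighted_orientation_hist(orientation, magnitude, bins))
    cell_hists = _pyramid_histograms(magnitude, orientation, levels, bins)
    sims = [histogram_intersection(h, ground) for h in cell_hists]
    self_similarity = float(np.median(sims))
    max_std = math.sqrt(bins - 1) / bins
    anisotropy = float(np.std(cell_hists) / max_std)
    return {
        "self_similarity": self_similarity,
        "anisotropy": min(anisotropy, 1.0),
        "phog_complexity": min(float(magnitude.mean()) / 255.0, 1.0),
    }


# ---------------------------------------------------------------------------
# edge-orientation entropies (1st / 2nd order)
# ---------------------------------------------------------------------------

def _oriented_edges(
    img: np.ndarray, config: SIPConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Strongest non-overlapping oriented edge pixels.

    Luminance is filtered with first-derivative-of-Gaussian kernels at
    ``n_orientations`` angles (realised as projections of the Gaussian
    gradient, to which the oriented filters are equivalent by linearity);
    per pixel the strongest |response| wins.  Non-maximum suppression
    within a square radius keeps one edge per neighbourhood, then the
    ``n_edges`` strongest survive.

    Returns ``(ys, xs, orientation_idx, strength)``.
    """
    rgb = _as_rgb(img, allow_grayscale=True)
    lum = rgb @ LUMA_WEIGHTS
    gx = ndimage.gaussian_filter(lum, config.edge_sigma, order=(0, 1), mode="wrap")
    gy = ndimage.gaussian_filter(lum, config.edge_sigma, order=(1, 0), mode="wrap")
    n = config.n_orientations
    thetas = np.arange(n) * math.pi / n
    resp = (
        gx[None] * np.cos(thetas)[:, None, None]
        + gy[None] * np.sin(thetas)[:, None, None]
    )
    strength = np.abs(resp).max(axis=0)
    ori_idx = np.abs(resp).argmax(axis=0)
    size = 2 * config.nms_radius + 1
    local_max = ndimage.maximum_filter(strength, size=size, mode="wrap")
    # floor at 1e-12 of the peak: filter-response round-off in flat regions
    # must not masquerade as edges
    floor = 1e-12 * float(strength.max())
    keep = (strength >= local_max) & (strength > floor)
    ys, xs = np.nonzero(keep)
    s = strength[ys, xs]
    if len(s) < n:
        # very smooth images (steep spectral slopes) have only a handful of
        # distinct local maxima; fall back to the classical strongest-pixel
        # rule over the whole gradient field
        ys, xs = np.nonzero(strength > floor)
        s = strength[ys, xs]
    if len(s) < n:
        raise InsufficientEdgesError(
            f"only {len(s)} edge pixels found (< {n} orientations)"
        )
    order = np.argsort(s)[::-1][: config.n_edges]
    ys, xs, s = ys[order], xs[order], s[order]
    return ys, xs, ori_idx[ys, xs], s


def edge_orientation_entropies(
    img: np.ndarray, config: SIPConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """First- and second-order edge-orientation entropies, in [0, 1].

    First order: Shannon entropy of the strength-weighted orientation
    histogram, normalized by log(n_orientations).

    Second order: edge pairs are binned by their Euclidean distance into
    log-spaced bins; within each bin the entropy of the (strength-product
    weighted) histogram of orientation differences is computed, normalized
    by log(n_orientations), and the mean over populated bins is returned.
    Pairs are enumerated exhaustively when their number is at most
    ``max_pairs`` and subsampled with a seeded RNG otherwise.
    """
    ys, xs, ori, s = _oriented_edges(img, config)
    n = config.n_orientations
    hist1 = np.bincount(ori, weights=s, minlength=n)
    first = _shannon_entropy(_normalize_hist(hist1)) / math.log(n)

    m = len(s)
    n_pairs = m * (m - 1) // 2
    if n_pairs <= config.max_pairs:
        ii, jj = np.triu_indices(m, k=1)
    else:
        rng = np.random.default_rng(config.pair_seed)
        ii = rng.integers(0, m, size=int(config.max_pairs * 1.1))
        jj = rng.integers(0, m, size=int(config.max_pairs * 1.1))
        ok = ii != jj
        ii, jj = ii[ok][: config.max_pairs], jj[ok][: config.max_pairs]
    d = np.hypot(ys[ii] - ys[jj], xs[ii] - xs[jj]).astype(float)
    diag = math.hypot(*img.shape[:2])
    edges = np.logspace(0.0, math.log10(diag), config.n_distance_bins + 1)
    dbin = np.clip(np.digitize(d, edges) - 1, 0, config.n_distance_bins - 1)
    # unsigned circular orientation distance (0 … n/2 bins ≙ 0° … 90°);
    # symmetric in the pair, so independent of enumeration order
    raw = (ori[ii] - ori[jj]) % n
    dori = np.minimum(raw, n - raw)
    w = s[ii] * s[jj]
    ent = []
    for b in range(config.n_distance_bins):
        sel = dbin == b
        if not sel.any():
            continue
        h = np.bincount(dori[sel], weights=w[sel], minlength=n)
        ent.append(_shannon_entropy(_normalize_hist(h)) / math.log(n))
    second = float(np.mean(ent)) if ent else 0.0
    return {"entropy_first_order": float(first), "entropy_second_order": second}


# ---------------------------------------------------------------------------
# filter-bank variance measures P_a(k), P_f(k)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterBank:
    """A bank of zero-mean, L2-normalized linear filters.

    Each kernel carries metadata: ``channel`` ∈ {lum, rg, by} selects the
    input plane (luminance or a colour-opponent difference), plus free-form
    orientation/scale tags.
    """

    kernels: tuple[np.ndarray, ...]
    meta: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for k in self.kernels:
            if abs(k.sum()) > 1e-8 * max(1.0, np.abs(k).sum()):
                raise ValueError("filter kernels must be zero-mean")
            if not math.isclose(float((k**2).sum()), 1.0, rel_tol=1e-6):
                raise ValueError("filter kernels must be L2-normalized")

    def __len__(self) -> int:
        return len(self.kernels)


def _prep_kernel(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    k = k - k.mean()
    norm = math.sqrt(float((k**2).sum()))
    if norm == 0:
        raise ValueError("degenerate all-zero kernel")
    return k / norm


def _dog_kernel(size: int, sigma1: float, sigma2: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g1 = np.exp(-r2 / (2 * sigma1**2)) / (2 * math.pi * sigma1**2)
    g2 = np.exp(-r2 / (2 * sigma2**2)) / (2 * math.pi * sigma2**2)
    return g1 - g2


def default_filter_bank(
    n_orientations: int = 8, frequencies: tuple[float, ...] = (0.1, 0.2, 0.3)
) -> FilterBank:
    """Built-in deterministic bank: 48 Gabor + 2 colour-opponent kernels.

    Even (cosine) and odd (sine) Gabor phases at ``n_orientations``
    orientations × ``frequencies`` scales act on luminance; two
    difference-of-Gaussian kernels act on the R−G and B−(R+G)/2 opponent
    planes.  All kernels are zero-mean and unit-norm, so the response to a
    constant image is exactly 0.
    """
    kernels: list[np.ndarray] = []
    meta: list[dict] = []
    for f in frequencies:
        for i in range(n_orientations):
            theta = i * math.pi / n_orientations
            g = gabor_kernel(frequency=f, theta=theta)
            for phase, part in (("even", g.real), ("odd", g.imag)):
                kernels.append(_prep_kernel(part))
                meta.append(
                    {"channel": "lum", "frequency": f, "theta": theta, "phase": phase}
                )
    for tag, (s1, s2) in (("rg", (1.0, 2.0)), ("by", (1.5, 3.0))):
        kernels.append(_prep_kernel(_dog_kernel(13, s1, s2)))
        meta.append({"channel": tag, "sigma": (s1, s2), "phase": "dog"})
    return FilterBank(tuple(kernels), tuple(meta))


_DEFAULT_BANK: FilterBank | None = None


def _get_default_bank() -> FilterBank:
    global _DEFAULT_BANK
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = default_filter_bank()
    return _DEFAULT_BANK


def circular_cross_correlation(img2d: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT circular cross-correlation, kernel centred at its middle pixel."""
    H, W = img2d.shape
    kh, kw = kernel.shape
    cy, cx = kh // 2, kw // 2
    P = np.zeros((H, W))
    ys = (np.arange(kh) - cy) % H
    xs = (np.arange(kw) - cx) % W
    np.add.at(P, (ys[:, None], xs[None, :]), kernel)
    return np.fft.ifft2(np.fft.fft2(img2d) * np.conj(np.fft.fft2(P))).real


def filter_response_maps(
    img: np.ndarray, bank: FilterBank | None = None, stride: int = 1
) -> list[np.ndarray]:
    """Rectified (absolute) response maps of every filter in the bank."""
    rgb = _as_rgb(img, allow_grayscale=True)
    planes = {
        "lum": rgb @ LUMA_WEIGHTS,
        "rg": rgb[..., 0] - rgb[..., 1],
        "by": rgb[..., 2] - (rgb[..., 0] + rgb[..., 1]) / 2.0,
    }
    if bank is None:
        bank = _get_default_bank()
    ffts = {}
    maps = []
    for kernel, info in zip(bank.kernels, bank.meta):
        chan = info.get("channel", "lum")
        if chan not in ffts:
            ffts[chan] = np.fft.fft2(planes[chan])
        H, W = planes[chan].shape
        kh, kw = kernel.shape
        cy, cx = kh // 2, kw // 2
        P = np.zeros((H, W))
        ys = (np.arange(kh) - cy) % H
        xs = (np.arange(kw) - cx) % W
        np.add.at(P, (ys[:, None], xs[None, :]), kernel)
        resp = np.fft.ifft2(ffts[chan] * np.conj(np.fft.fft2(P))).real
        maps.append(np.abs(resp[::stride, ::stride]))
    return maps


def _max_pool(resp: np.ndarray, k: int) -> np.ndarray:
    if min(resp.shape) < k:
        raise GridError(f"pooling grid {k}×{k} larger than map {resp.shape}")
    rows = _cell_slices(resp.shape[0], k)
    cols = _cell_slices(resp.shape[1], k)
    out = np.empty((k, k))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            out[i, j] = resp[r, c].max()
    return out


def _variances_from_maps(maps: list[np.ndarray], k: int) -> dict[str, float]:
    pooled = np.stack([_max_pool(m, k).ravel() for m in maps])  # F × k²
    pa = float(np.var(pooled))
    pf = float(np.median(np.var(pooled, axis=1)))
    return {"variance_Pa": pa, "variance_Pf": pf}


def filter_variance_features(
    img: np.ndarray, bank: FilterBank | None = None, k: int = 2, stride: int = 1
) -> dict[str, float]:
    """Variance measures over max-pooled filter-bank responses.

    Responses of all F filters are rectified and max-pooled onto a k×k
    grid, giving k²·F entries.  ``variance_Pa`` is the variance over all
    entries (an inverse measure of richness); ``variance_Pf`` is the median
    over filters of the per-filter variance of its k² entries (a measure of
    variability).  Variances are population (ddof 0).
    """
    if k not in POOL_GRIDS:
        raise GridError(f"k must be one of {POOL_GRIDS}, got {k}")
    maps = filter_response_maps(img, bank, stride=stride)
    return _variances_from_maps(maps, k)


# ---------------------------------------------------------------------------
# colour statistics
# ---------------------------------------------------------------------------

def _channel_entropy_bits(values: np.ndarray, bins: int = 256) -> float:
    h, _ = np.histogram(values.ravel(), bins=bins, range=(0.0, 1.0))
    return _shannon_entropy(_normalize_hist(h.astype(float)), base=2.0)


def color_statistics(img: np.ndarray) -> dict[str, float]:
    """CIELab / HSV channel means and HSV channel entropies.

    Lab on the standard scales (L ∈ [0,100], a,b ∈ ≈[−128,127]); HSV in
    [0,1] except the hue mean, which is circular and reported as an angle
    in degrees [0°, 360°).  Entropies come from 256-bin histograms (hue
    bins wrap) and are in bits.
    """
    rgb = _as_rgb(img)
    lab = rgb2lab(rgb)
    hsv = rgb2hsv(rgb)
    hue = hsv[..., 0]
    ang = hue * 2.0 * math.pi
    mean_vec = complex(np.cos(ang).mean(), np.sin(ang).mean())
    hue_mean = math.degrees(math.atan2(mean_vec.imag, mean_vec.real)) % 360.0
    # hue histogram: 256 bins over the circle [0,1); 1.0 wraps to bin 0
    idx = np.floor((hue.ravel() % 1.0) * 256).astype(int) % 256
    hue_hist = np.bincount(idx, minlength=256).astype(float)
    return {
        "lab_L_mean": float(lab[..., 0].mean()),
        "lab_a_mean": float(lab[..., 1].mean()),
        "lab_b_mean": float(lab[..., 2].mean()),
        "hsv_H_mean": hue_mean,
        "hsv_S_mean": float(hsv[..., 1].mean()),
        "hsv_V_mean": float(hsv[..., 2].mean()),
        "entropy_hsv_H": _shannon_entropy(_normalize_hist(hue_hist), base=2.0),
        "entropy_hsv_S": _channel_entropy_bits(hsv[..., 1]),
        "entropy_hsv_V": _channel_entropy_bits(hsv[..., 2]),
    }


# ---------------------------------------------------------------------------
# mirror symmetry
# ---------------------------------------------------------------------------

def _half_cell_hists(half: np.ndarray, cells: int, bins: int) -> np.ndarray:
    magnitude, orientation = lab_gradient_field(half)
    return _pyramid_histograms(magnitude, orientation, int(math.log2(cells)), bins)


def mirror_symmetry_lrud(
    img: np.ndarray, cells: int = 4, bins: int = 16
) -> dict[str, float]:
    """Combined left/right and up/down mirror symmetry in [0, 1].

    Each component compares PHOG cell histograms (4×4 grid of cells, i.e.
    pyramid level 2) of one half against the mirror-reflected opposite
    half; reflecting the half in pixel space reflects gradient
    orientations automatically.  The combined value is the mean of the two
    components, each a mean of per-cell histogram intersections.
    """
    rgb = _as_rgb(img)
    magnitude, _ = lab_gradient_field(rgb)
    if magnitude.sum() <= 0:
        raise DegenerateImageError("zero-gradient image: symmetry undefined")
    H, W = rgb.shape[:2]
    w, h = W // 2, H // 2
    pairs = {
        "left_right": (rgb[:, :w], rgb[:, W - w :][:, ::-1]),
        "up_down": (rgb[:h, :], rgb[H - h :, :][::-1, :]),
    }
    out: dict[str, float] = {}
    for name, (a, b) in pairs.items():
        ha = _half_cell_hists(a, cells, bins)
        hb = _half_cell_hists(b, cells, bins)
        sims = [histogram_intersection(x, y) for x, y in zip(ha, hb)]
        out[name] = float(np.mean(sims))
    out["symmetry_lrud"] = (out["left_right"] + out["up_down"]) / 2.0
    return out


# ---------------------------------------------------------------------------
# the full SIP vector
# ---------------------------------------------------------------------------

def compute_sip_vector(
    img: np.ndarray,
    config: SIPConfig = DEFAULT_CONFIG,
    bank: FilterBank | None = None,
) -> dict[str, float]:
    """Compute the full SIP vector of an RGB image.

    The image is resampled (bilinear) to ``config.resolution`` square
    before all measures, so results do not depend on the stored size.
    Returns a dict keyed by :data:`SIP_NAMES`.  Deterministic.
    """
    rgb = _as_rgb(img, allow_grayscale=config.allow_grayscale)
    if min(rgb.shape[:2]) < 64:
        raise FormatError(f"image side {min(rgb.shape[:2])} < 64")
    res = config.resolution
    if rgb.shape[:2] != (res, res):
        rgb = np.clip(
            resize(rgb, (res, res), order=1, anti_aliasing=False, preserve_range=True),
            0.0,
            1.0,
        )
    out: dict[str, float] = {}
    out["complexity"] = float(lab_gradient_field(rgb)[0].mean())
    if out["complexity"] > 0:
        ph = phog_features(rgb, config.phog_levels, config.phog_bins)
        out["self_similarity"] = ph["self_similarity"]
        out["phog_anisotropy"] = ph["anisotropy"]
        ent = edge_orientation_entropies(rgb, config)
        out.update(ent)
        sym = mirror_symmetry_lrud(rgb, bins=config.phog_bins)
        out["symmetry_lrud"] = sym["symmetry_lrud"]
    else:
        # constant image: no gradients anywhere
        out["self_similarity"] = 1.0
        out["phog_anisotropy"] = 0.0
        out["entropy_first_order"] = 0.0
        out["entropy_second_order"] = 0.0
        out["symmetry_lrud"] = 1.0
    maps = filter_response_maps(rgb, bank, stride=config.conv_stride)
    for k in POOL_GRIDS:
        v = _variances_from_maps(maps, k)
        out[f"variance_Pa_{k}"] = v["variance_Pa"]
        out[f"variance_Pf_{k}"] = v["variance_Pf"]
    out.update(color_statistics(rgb))
    lum = rgb @ LUMA_WEIGHTS
    if np.ptp(lum) > 0:
        est = measure_fourier_slope(rgb, default_fit_range(res), n_bins=config.slope_bins)
        out["fourier_slope"] = est.slope
    else:
        out["fourier_slope"] = float("nan")
    return {name: out[name] for name in SIP_NAMES}


def compute_sip_table(
    images: dict[str, np.ndarray],
    config: SIPConfig = DEFAULT_CONFIG,
    category: str | dict[str, str] = "original",
    bank: FilterBank | None = None,
):
    """Compute a SIP table (pandas DataFrame) for a set of images.

    ``images`` maps image_id → RGB array; ``category`` is a single label or
    a per-id mapping from :data:`IMAGE_CATEGORIES`.  The returned frame is
    indexed by image_id with one column per SIP plus ``category``.
    """
    import pandas as pd

    if bank is None:
        bank = _get_default_bank()
    rows = {}
    for image_id in sorted(images):
        rows[image_id] = compute_sip_vector(images[image_id], config, bank)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image_id"
    cats = category if isinstance(category, dict) else {i: category for i in rows}
    bad = set(cats.values()) - set(IMAGE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    df["category"] = [cats[i] for i in df.index]
    return df
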