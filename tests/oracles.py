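"""Independent brute-force re-implementations of the SIP definitions.

Every function here recomputes a measure by straightforward enumeration —
explicit pixel loops, explicit rotated kernels, explicit pair loops,
explicit subset enumeration — sharing no code path with the package
implementation.  They define the expected values the oracle-equivalence
tests freeze against.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from scipy import ndimage

# classic sRGB/CIE constants (Pascale's tabulation, D65 2° observer)
_XYZ_FROM_RGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])


def _srgb_to_lab_pixel(rgb):
    lin = [
        c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4 for c in rgb
    ]
    xyz = _XYZ_FROM_RGB @ np.asarray(lin)
    t = xyz / _WHITE_D65

    def f(v):
        return v ** (1.0 / 3.0) if v > 0.008856 else 7.787 * v + 16.0 / 116.0

    fx, fy, fz = f(t[0]), f(t[1]), f(t[2])
    return np.array([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)])


def lab_scaled(img):
    """Per-pixel sRGB→CIELab by the textbook formulas, L scaled ×2.55."""
    H, W, _ = img.shape
    out = np.empty((H, W, 3))
    for y in range(H):
        for x in range(W):
            out[y, x] = _srgb_to_lab_pixel(img[y, x])
    out[..., 0] *= 2.55
    return out


def gradient_field(img):
    """Wrap central-difference max-channel gradient (magnitude, orientation)."""
    lab = lab_scaled(img)
    H, W, _ = lab.shape
    mag = np.zeros((H, W))
    ori = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            best = -1.0
            for c in range(3):
                gx = (lab[y, (x + 1) % W, c] - lab[y, (x - 1) % W, c]) / 2.0
                gy = (lab[(y + 1) % H, x, c] - lab[(y - 1) % H, x, c]) / 2.0
                m = math.hypot(gx, gy)
                if m > best:
                    best = m
                    ori[y, x] = math.degrees(math.atan2(gy, gx)) % 180.0
            mag[y, x] = best
    return mag, ori


def complexity(img):
    mag, _ = gradient_field(img)
    return float(np.mean(mag))


def _cell_bounds(n, cells):
    return np.linspace(0, n, cells + 1).astype(int)


def _hist(mag, ori, ys, xs, bins):
    h = np.zeros(bins)
    for y in ys:
        for x in xs:
            b = min(int(ori[y, x] / 180.0 * bins), bins - 1)
            h[b] += mag[y, x]
    s = h.sum()
    return h / s if s > 0 else h


def phog(img, levels=3, bins=16):
    mag, ori = gradient_field(img)
    H, W = mag.shape
    ground = _hist(mag, ori, range(H), range(W), bins)
    cells = 2 ** levels
    rb, cb = _cell_bounds(H, cells), _cell_bounds(W, cells)
    cell_hists = []
    for i in range(cells):
        for j in range(cells):
            cell_hists.append(
                _hist(mag, ori, range(rb[i], rb[i + 1]), range(cb[j], cb[j + 1]), bins)
            )
    sims = sorted(float(np.minimum(h, ground).sum()) for h in cell_hists)
    n = len(sims)
    median = (sims[n // 2] if n % 2 else (sims[n // 2 - 1] + sims[n // 2]) / 2.0)
    flat = np.concatenate(cell_hists)
    aniso = float(np.std(flat)) / (math.sqrt(bins - 1) / bins)
    return {"self_similarity": median, "anisotropy": min(aniso, 1.0)}


def symmetry_lrud(img, cells=4, bins=16):
    H, W, _ = img.shape
    w, h = W // 2, H // 2

    def half_hists(half):
        mag, ori = gradient_field(half)
        hh, ww = mag.shape
        rb, cb = _cell_bounds(hh, cells), _cell_bounds(ww, cells)
        out = []
        for i in range(cells):
            for j in range(cells):
                out.append(
                    _hist(mag, ori, range(rb[i], rb[i + 1]), range(cb[j], cb[j + 1]), bins)
                )
        return out

    comps = {}
    for name, (a, b) in {
        "left_right": (img[:, :w], img[:, W - w :][:, ::-1]),
        "up_down": (img[:h, :], img[H - h :, :][::-1, :]),
    }.items():
        ha, hb = half_hists(a), half_hists(b)
        comps[name] = float(
            np.mean([np.minimum(x, y).sum() for x, y in zip(ha, hb)])
        )
    comps["symmetry_lrud"] = (comps["left_right"] + comps["up_down"]) / 2.0
    return comps


# ---------------------------------------------------------------------------
# edge-orientation entropies via explicit rotated kernels + pair loops
# ---------------------------------------------------------------------------

def _deriv_gauss_kernel(theta, sigma=1.0, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    phi = np.exp(-(ax**2) / (2 * sigma**2))
    phi /= phi.sum()
    k = np.empty((2 * r + 1, 2 * r + 1))
    for i, dy in enumerate(ax):
        for j, dx in enumerate(ax):
            k[i, j] = -(dx * math.cos(theta) + dy * math.sin(theta)) / sigma**2 * phi[i] * phi[j]
    return k


def edge_entropies(img, config):
    """Exhaustive-pair oracle for the two edge-orientation entropies."""
    lum = img @ np.array([0.2126, 0.7152, 0.0722])
    n = config.n_orientations
    resp = np.stack(
        [
            ndimage.convolve(lum, _deriv_gauss_kernel(i * math.pi / n, config.edge_sigma), mode="wrap")
            for i in range(n)
        ]
    )
    strength = np.abs(resp).max(axis=0)
    ori = np.abs(resp).argmax(axis=0)
    H, W = strength.shape
    rad = config.nms_radius
    floor = 1e-12 * float(strength.max())
    keep = []
    for y in range(H):
        for x in range(W):
            s = strength[y, x]
            if s <= floor:
                continue
            is_max = True
            for dy in range(-rad, rad + 1):
                for dx in range(-rad, rad + 1):
                    if strength[(y + dy) % H, (x + dx) % W] > s:
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                keep.append((s, y, x))
    if len(keep) < n:
        keep = [
            (strength[y, x], y, x)
            for y in range(H)
            for x in range(W)
            if strength[y, x] > floor
        ]
    keep.sort(key=lambda t: -t[0])
    keep = keep[: config.n_edges]
    s = np.array([k[0] for k in keep])
    ys = np.array([k[1] for k in keep])
    xs = np.array([k[2] for k in keep])
    o = np.array([ori[k[1], k[2]] for k in keep])

    h1 = np.zeros(n)
    for si, oi in zip(s, o):
        h1[oi] += si
    p = h1 / h1.sum()
    first = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(n)

    diag = math.hypot(H, W)
    edges = np.logspace(0.0, math.log10(diag), config.n_distance_bins + 1)
    bins = [np.zeros(n) for _ in range(config.n_distance_bins)]
    m = len(s)
    for i in range(m):
        for j in range(i + 1, m):
            d = math.hypot(float(ys[i] - ys[j]), float(xs[i] - xs[j]))
            b = min(max(np.searchsorted(edges, d, side="right") - 1, 0),
                    config.n_distance_bins - 1)
            raw = (o[i] - o[j]) % n
            bins[b][min(raw, n - raw)] += s[i] * s[j]
    ents = []
    for h in bins:
        tot = h.sum()
        if tot <= 0:
            continue
        p = h / tot
        ents.append(-sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(n))
    return {
        "entropy_first_order": first,
        "entropy_second_order": float(np.mean(ents)) if ents else 0.0,
    }


# ---------------------------------------------------------------------------
# filter-bank variances via explicit wrap-indexed sliding windows
# ---------------------------------------------------------------------------

def filter_variances(img, bank, k):
    lum = img @ np.array([0.2126, 0.7152, 0.0722])
    planes = {
        "lum": lum,
        "rg": img[..., 0] - img[..., 1],
        "by": img[..., 2] - (img[..., 0] + img[..., 1]) / 2.0,
    }
    H, W = lum.shape
    per_filter = []
    for kernel, info in zip(bank.kernels, bank.meta):
        plane = planes[info.get("channel", "lum")]
        kh, kw = kernel.shape
        cy, cx = kh // 2, kw // 2
        # spatial-domain route: wrap-pad then explicit sliding windows
        pad = np.pad(plane, ((cy, kh - 1 - cy), (cx, kw - 1 - cx)), mode="wrap")
        windows = np.lib.stride_tricks.sliding_window_view(pad, (kh, kw))
        resp = np.abs(np.einsum("ijkl,kl->ij", windows, kernel))
        rb, cb = _cell_bounds(H, k), _cell_bounds(W, k)
        pooled = []
        for i in range(k):
            for j in range(k):
                pooled.append(resp[rb[i] : rb[i + 1], cb[j] : cb[j + 1]].max())
        per_filter.append(pooled)
    allv = np.array(per_filter).ravel()
    pa = float(np.mean((allv - allv.mean()) ** 2))
    per_var = [float(np.mean((np.array(p) - np.mean(p)) ** 2)) for p in per_filter]
    pf = float(np.median(per_var))
    return {"variance_Pa": pa, "variance_Pf": pf}


# ---------------------------------------------------------------------------
# colour statistics via colorsys-style per-pixel loops
# ---------------------------------------------------------------------------

def color_statistics(img):
    import colorsys

    H, W, _ = img.shape
    lab_sum = np.zeros(3)
    hs, ss, vs = [], [], []
    for y in range(H):
        for x in range(W):
            lab = _srgb_to_lab_pixel(img[y, x])
            lab_sum += lab
            h, s, v = colorsys.rgb_to_hsv(*img[y, x])
            hs.append(h)
            ss.append(s)
            vs.append(v)
    npix = H * W
    sin_sum = sum(math.sin(2 * math.pi * h) for h in hs)
    cos_sum = sum(math.cos(2 * math.pi * h) for h in hs)
    hue_mean = math.degrees(math.atan2(sin_sum, cos_sum)) % 360.0

    def entropy_bits(values, circular=False):
        counts = Counter()
        for v in values:
            if circular:
                counts[int((v % 1.0) * 256) % 256] += 1
            else:
                counts[min(int(v * 256), 255)] += 1
        return -sum(
            (c / npix) * math.log2(c / npix) for c in counts.values() if c > 0
        )

    return {
        "lab_L_mean": lab_sum[0] / npix,
        "lab_a_mean": lab_sum[1] / npix,
        "lab_b_mean": lab_sum[2] / npix,
        "hsv_H_mean": hue_mean,
        "hsv_S_mean": float(np.mean(ss)),
        "hsv_V_mean": float(np.mean(vs)),
        "entropy_hsv_H": entropy_bits(hs, circular=True),
        "entropy_hsv_S": entropy_bits(ss),
        "entropy_hsv_V": entropy_bits(vs),
    }


# ---------------------------------------------------------------------------
# regression subset enumeration oracle
# ---------------------------------------------------------------------------

def best_subsets(X, y, n_best=10):
    """Exhaustive top-n lists per size via raw lstsq with intercept."""
    names = list(X.columns)
    Xv = np.asarray(X, float)
    yv = np.asarray(y, float)
    n, p = Xv.shape
    tss = float(np.sum((yv - yv.mean()) ** 2))
    out = {}
    for s in range(1, p + 1):
        scored = []
        for combo in itertools.combinations(range(p), s):
            A = np.column_stack([np.ones(n), Xv[:, combo]])
            beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
            rss = float(np.sum((yv - A @ beta) ** 2))
            r2 = min(1.0 - rss / tss, 1.0)
            r2a = 1.0 - (1.0 - r2) * (n - 1) / (n - s - 1)
            scored.append((r2a, tuple(names[i] for i in combo)))
        scored.sort(key=lambda t: (-t[0], t[1]))
        out[s] = scored[:n_best]
    return out


def kruskal_h(groups):
    """Tie-corrected Kruskal–Wallis H by rank-sum arithmetic."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for q in range(i, j + 1):
            ranks[order[q]] = avg
        i = j + 1
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    counts = Counter(pooled)
    tie = sum(c**3 - c for c in counts.values())
    correction = 1.0 - tie / (N**3 - N)
    return h / correction if correction > 0 else float("nan")
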