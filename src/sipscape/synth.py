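"""Synthetic study generator with known ground truth.

Every analysis stage of the pipeline can be exercised without any external
data by simulating the whole study: image sets (random-phase stimuli plus
"pseudo-painting" texture collages standing in for painted/style-transferred
material), a balanced incomplete rating design, and ratings generated from
a linear model on standardized SIPs with planted rater clusters, participant
offsets and trial noise.

Study-emulating defaults: 40 participants; six set slopes −5…0 with 25
random-phase images each (every participant rates 30 of the 150, balanced in
slope, so each image collects exactly 8 ratings); 150 pseudo-paintings rated
by everyone; three rating dimensions (Pleasing, Harmonious, Interesting);
rater archetypes u-shaped (half the sample), increasing, decreasing, and an
anticorrelated Harmonious/Interesting group.

The collage generator is designed only to spread the eight model SIPs over
a wide range (larger patches → steeper Fourier slope; wider hue spread →
higher hue entropy); it makes no claim of artistic validity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sips import EIGHT_MODEL_SIPS
from .stimuli import RandomPhaseSpec, synthesize_colored_random_phase

__all__ = [
    "SyntheticStudyConfig",
    "GroundTruth",
    "ARCHETYPES",
    "generate_pseudo_painting",
    "generate_image_sets",
    "generate_design",
    "generate_ratings",
    "sample_sip_table",
    "sample_inter_rating_vectors",
    "INTER_RATING_ARCHETYPES",
]

ARCHETYPES = ("u_shaped", "increasing", "decreasing", "anticorrelated_HI")

#: Default raw loadings (dimension × eight model SIPs) of the rating model,
#: qualitatively emulating the published effect pattern: self-similarity and
#: hue entropy pull Harmonious and Interesting in opposite directions;
#: complexity and P_a(2) depress, P_f(30) raises, Pleasing.  Row sums of
#: squares ≈ 0.55–0.65, matching explained variances of 50–69%.
DEFAULT_BETA = pd.DataFrame(
    {
        "complexity": [-0.35, -0.30, 0.15],
        "self_similarity": [0.15, 0.40, -0.30],
        "entropy_second_order": [0.05, 0.05, 0.05],
        "variance_Pa_2": [-0.30, -0.25, -0.15],
        "variance_Pf_30": [0.35, 0.10, 0.35],
        "lab_b_mean": [-0.25, -0.15, -0.20],
        "hsv_S_mean": [-0.30, -0.10, -0.35],
        "entropy_hsv_H": [0.15, -0.30, 0.35],
    },
    index=["Pleasing", "Harmonious", "Interesting"],
)

#: Per-cluster mean inter-rating correlation vectors (ρ_PH, ρ_PI, ρ_HI)
#: emulating the published five-cluster pattern, including one group with
#: anticorrelated Harmonious/Interesting ratings.
INTER_RATING_ARCHETYPES = {
    1: (0.55, 0.64, 0.47),
    2: (0.44, 0.39, 0.31),
    3: (0.64, 0.29, 0.01),
    4: (0.21, 0.56, 0.04),
    5: (0.04, 0.32, -0.34),
}
INTER_RATING_SIZES = {1: 14, 2: 13, 3: 4, 4: 5, 5: 4}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions of the simulation (defaults = the emulated design)."""

    n_participants: int = 40
    slopes: tuple[float, ...] = (-5.0, -4.0, -3.0, -2.0, -1.0, 0.0)
    images_per_slope: int = 25
    rated_per_slope: int = 5
    n_pseudo_paintings: int = 150
    image_size: int = 256
    cluster_proportions: dict = field(
        default_factory=lambda: {
            "u_shaped": 0.5,
            "increasing": 0.2,
            "decreasing": 0.2,
            "anticorrelated_HI": 0.1,
        }
    )
    beta: pd.DataFrame = field(default_factory=lambda: DEFAULT_BETA.copy())
    noise_sd: float = 0.3
    participant_offset_sd: float = 0.2
    rating_scale: float = 0.12
    slope_peak: float = -2.5
    slope_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cluster_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"cluster proportions sum to {total}, expected 1")
        unknown = set(self.cluster_proportions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not np.isfinite(np.asarray(self.beta, float)).all():
            raise ValueError("beta matrix must be finite")


@dataclass
class GroundTruth:
    """Planted quantities the analyses are expected to recover."""

    beta_star: pd.DataFrame  # implied standardized coefficients, dim × SIP
    beta_raw: pd.DataFrame
    cluster_labels: pd.Series  # participant -> archetype
    slope_curves: dict  # archetype -> dict(dim -> (kind, params))
    slope_peak: float
    sweetspot_center: pd.Series | None = None


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _power_law_radius(rng, r_min, r_max, tau):
    """Inverse-CDF draw from p(r) ∝ r^(−tau) on [r_min, r_max]."""
    u = rng.uniform()
    if abs(tau - 1.0) < 1e-9:
        return r_min * (r_max / r_min) ** u
    a = 1.0 - tau
    return (r_min**a + u * (r_max**a - r_min**a)) ** (1.0 / a)


def generate_pseudo_painting(
    size: int,
    rng: np.random.Generator,
    patch_scale: float = 0.1,
    hue_spread: float = 0.2,
    saturation: float = 0.7,
    orientation_bias: float = 0.0,
    orientation_concentration: float = 0.0,
    n_patches: int = 1500,
    value_range: tuple[float, float] = (0.35, 0.95),
    coverage: float = 2.5,
) -> np.ndarray:
    """One dead-leaves-style collage of overlapping colored patches.

    Patches are sharp-rimmed elliptical discs painted over one another
    until their cumulative area reaches ``coverage`` image areas (capped at
    ``n_patches``).  Patch radii follow a power-law size distribution whose
    exponent is steered by ``patch_scale``: a larger characteristic scale
    weights the mixture toward coarse discs, tilting the image's power
    spectrum toward steeper (more negative) Fourier slopes — the classic
    occlusion model of natural-image spectra.  ``hue_spread`` is the s.d.
    of patch hues around a random base hue (wider spread → higher hue
    entropy); ``orientation_concentration`` elongates patches along
    ``orientation_bias`` (radians).
    """
    from skimage.color import hsv2rgb

    base_hue = rng.uniform()
    canvas = np.full((size, size, 3), 0.5)
    # size-distribution exponent: patch_scale 0.03 → ≈4.7 (fine-grained),
    # 0.35 → ≈2.2 (dominated by coarse discs)
    tau = float(np.clip(5.0 - 8.0 * patch_scale, 2.0, 5.0))
    r_min, r_max = 2.0, 0.4 * size
    area = 0.0
    target = coverage * size * size
    for _ in range(n_patches):
        if area >= target:
            break
        cy, cx = rng.uniform(0, size, 2)
        hue = (base_hue + rng.normal(0.0, hue_spread)) % 1.0
        sat = np.clip(saturation * rng.uniform(0.6, 1.2), 0.0, 1.0)
        val = rng.uniform(*value_range)
        color = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]
        theta = (
            orientation_bias + rng.normal(0.0, 0.3)
            if orientation_concentration > 0
            else rng.uniform(0.0, math.pi)
        )
        elong = 1.0 + orientation_concentration * 2.0
        base_r = _power_law_radius(rng, r_min, r_max, tau)
        s_major = base_r * rng.uniform(0.8, 1.25) * elong
        s_minor = base_r * rng.uniform(0.8, 1.25) / elong
        area += math.pi * s_major * s_minor
        # render only the patch's bounding window
        ext = 1.6 * s_major
        y0, y1 = max(0, int(cy - ext)), min(size, int(cy + ext) + 1)
        x0, x1 = max(0, int(cx - ext)), min(size, int(cx + ext) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        r = np.sqrt((u / s_major) ** 2 + (v / s_minor) ** 2)
        # ~1-pixel rim at every size so edges stay sharp across scales
        rim = max(2.0, math.sqrt(s_major * s_minor) / 1.2)
        alpha = 0.5 * (1.0 + np.tanh(rim * (1.0 - r)))
        alpha = alpha[..., None] * rng.uniform(0.7, 1.0)
        canvas[y0:y1, x0:x1] = (
            canvas[y0:y1, x0:x1] * (1.0 - alpha) + color[None, None, :] * alpha
        )
    return np.clip(canvas, 0.0, 1.0)


def generate_image_sets(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> dict:
    """Synthesize the study image sets.

    Returns ``{"random_phase": {id: img}, "pseudo_paintings": {id: img},
    "set_slopes": Series}``.  Random-phase ids encode slope and index
    (``rp_s-3_07``); pseudo-painting collage parameters are drawn over wide
    ranges so the eight model SIPs vary broadly across the set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    random_phase: dict[str, np.ndarray] = {}
    set_slopes: dict[str, float] = {}
    for slope in config.slopes:
        for i in range(config.images_per_slope):
            seed = int(rng.integers(0, 2**31 - 1))
            img_id = f"rp_s{slope:g}_{i:02d}"
            spec = RandomPhaseSpec(config.image_size, slope, seed)
            random_phase[img_id] = synthesize_colored_random_phase(spec)
            set_slopes[img_id] = slope
    pseudo: dict[str, np.ndarray] = {}
    for i in range(config.n_pseudo_paintings):
        pseudo[f"pp_{i:03d}"] = generate_pseudo_painting(
            config.image_size,
            rng,
            patch_scale=float(np.exp(rng.uniform(math.log(0.03), math.log(0.35)))),
            hue_spread=rng.uniform(0.02, 0.45),
            saturation=rng.uniform(0.15, 1.0),
            orientation_bias=rng.uniform(0.0, math.pi),
            orientation_concentration=rng.uniform(0.0, 1.5),
            n_patches=int(rng.integers(30, 160)),
        )
    return {
        "random_phase": random_phase,
        "pseudo_paintings": pseudo,
        "set_slopes": pd.Series(set_slopes),
    }


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Balanced incomplete assignment of images to participants.

    Every participant rates ``rated_per_slope`` random-phase images per
    slope (30 in the default six-slope design) and every pseudo-painting.
    The assignment is globally balanced: each random-phase image is rated
    by exactly n_participants·rated_per_slope/images_per_slope raters
    (8 in the default design).  Per participant, the two image blocks come
    in random order with the original-painting block conventionally last.

    Returns a frame (participant_id, image_id, category, set_slope, block).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    P = config.n_participants
    m = config.images_per_slope
    r = config.rated_per_slope
    windows = m // r
    if m % r != 0 or P % windows != 0:
        raise ValueError(
            "infeasible balance: images_per_slope must be divisible by "
            f"rated_per_slope ({m} % {r} = {m % r}) and n_participants by "
            f"images_per_slope/rated_per_slope ({P} % {windows} = {P % windows}); "
            f"raters per image would be {P * r}/{m} = {P * r / m:g}"
        )
    rows = []
    participants = [f"P{p:02d}" for p in range(P)]
    for slope in config.slopes:
        ids = [f"rp_s{slope:g}_{i:02d}" for i in range(m)]
        perm = rng.permutation(m)
        porder = rng.permutation(P)
        for q, p_idx in enumerate(porder):
            start = (q * r) % m
            for j in range(r):
                rows.append(
                    {
                        "participant_id": participants[p_idx],
                        "image_id": ids[perm[(start + j) % m]],
                        "category": "random_phase",
                        "set_slope": slope,
                    }
                )
    for p in participants:
        for i in range(config.n_pseudo_paintings):
            rows.append(
                {
                    "participant_id": p,
                    "image_id": f"pp_{i:03d}",
                    "category": "style_transferred",
                    "set_slope": np.nan,
                }
            )
    df = pd.DataFrame(rows)
    block_order = {
        p: rng.permutation(["random_phase", "style_transferred"]).tolist() + ["original"]
        for p in participants
    }
    df["block"] = [
        block_order[p].index(c) + 1 for p, c in zip(df["participant_id"], df["category"])
    ]
    return df


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def _slope_term(kind: str, x: np.ndarray, config: SyntheticStudyConfig) -> np.ndarray:
    amp = config.slope_amplitude
    span = (max(config.slopes) - min(config.slopes)) / 2.0
    mid = (max(config.slopes) + min(config.slopes)) / 2.0
    if kind == "u_shaped":
        return amp * (1.0 - ((x - config.slope_peak) / span) ** 2)
    if kind == "increasing":
        return amp * (x - mid) / span
    if kind == "decreasing":
        return -amp * (x - mid) / span
    raise ValueError(f"unknown slope-term kind {kind!r}")


def _assign_clusters(config: SyntheticStudyConfig, participants: list[str]) -> pd.Series:
    P = len(participants)
    counts = {a: int(round(prop * P)) for a, prop in config.cluster_proportions.items()}
    # fix rounding drift on the largest group
    drift = P - sum(counts.values())
    if drift:
        largest = max(counts, key=counts.get)
        counts[largest] += drift
    labels = []
    for a in config.cluster_proportions:
        labels.extend([a] * counts[a])
    return pd.Series(labels[:P], index=participants, name="archetype")


def generate_ratings(
    sip_table: pd.DataFrame,
    design: pd.DataFrame,
    config: SyntheticStudyConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long-format rating table and its ground truth.

    Per trial:  rating = clip₀₁[ 0.5 + s·(Σⱼ β_dj z(SIPⱼ) + slope-term +
    offset_p + ε) ], with z-scoring over the images in ``sip_table``, the
    cluster-specific slope term applied to random-phase images, offsets
    N(0, participant_offset_sd²), trial noise N(0, noise_sd²), and s the
    rating_scale compressing the standardized latent into the click scale.
    The anticorrelated archetype rates Interesting with the sign of its
    Harmonious loadings (and slope term) flipped.

    Ground truth records the *implied standardized coefficients* for the
    fully rated (style-transferred) set: β/sd(per-image mean latent), which
    is what a standardized regression on per-image mean ratings estimates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    beta = config.beta
    sips = list(beta.columns)
    missing = [s for s in sips if s not in sip_table.columns]
    if missing:
        raise ValueError(f"SIP table lacks model columns {missing}")
    X = np.asarray(sip_table[sips], dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant SIP column; cannot z-score")
    Z = (X - X.mean(axis=0)) / sd
    latent = pd.DataFrame(
        Z @ np.asarray(beta, float).T, index=sip_table.index, columns=beta.index
    )

    participants = sorted(design["participant_id"].unique())
    clusters = _assign_clusters(config, participants)
    offsets = pd.Series(
        rng.normal(0.0, config.participant_offset_sd, len(participants)),
        index=participants,
    )

    rows = []
    dims = list(beta.index)
    for p in participants:
        d_p = design[design["participant_id"] == p]
        arch = clusters[p]
        img_ids = d_p["image_id"].to_numpy()
        cats = d_p["category"].to_numpy()
        slopes = d_p["set_slope"].to_numpy(dtype=float)
        base = latent.loc[img_ids]
        for dim in dims:
            u = base[dim].to_numpy().copy()
            sterm = np.zeros(len(u))
            rp = cats == "random_phase"
            if arch == "anticorrelated_HI" and dim == "Interesting":
                u = -base["Harmonious"].to_numpy()
                if rp.any():
                    sterm[rp] = -_slope_term("u_shaped", slopes[rp], config)
            else:
                kind = "u_shaped" if arch == "anticorrelated_HI" else arch
                if rp.any():
                    sterm[rp] = _slope_term(kind, slopes[rp], config)
            eps = rng.normal(0.0, config.noise_sd, len(u))
            val = 0.5 + config.rating_scale * (u + sterm + offsets[p] + eps)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": p,
                        "image_id": img_ids,
                        "category": cats,
                        "dimension": dim,
                        "rating": np.clip(val, 0.0, 1.0),
                    }
                )
            )
    ratings = pd.concat(rows, ignore_index=True)

    # implied standardized coefficients for the fully rated set
    st_ids = design.loc[design["category"] == "style_transferred", "image_id"].unique()
    raters = (
        design[design["category"] == "style_transferred"]
        .groupby("image_id")["participant_id"]
        .nunique()
        .mean()
        if len(st_ids)
        else float(len(participants))
    )
    props = pd.Series(0.0, index=list(ARCHETYPES))
    props.update(clusters.value_counts(normalize=True))
    eff = beta.copy().astype(float)
    if props["anticorrelated_HI"] > 0 and "Interesting" in eff.index:
        w = props["anticorrelated_HI"]
        eff.loc["Interesting"] = (1 - w) * beta.loc["Interesting"] - w * beta.loc[
            "Harmonious"
        ]
    implied = eff.copy()
    if len(st_ids):
        Zs = Z[sip_table.index.get_indexer(pd.Index(st_ids))]
    else:
        Zs = Z
    mean_noise_var = (
        config.noise_sd**2 + config.participant_offset_sd**2
    ) / max(float(raters), 1.0)
    for dim in eff.index:
        lat = Zs @ eff.loc[dim].to_numpy()
        total_sd = math.sqrt(float(np.var(lat)) + mean_noise_var)
        implied.loc[dim] = eff.loc[dim] / total_sd

    curves = {}
    for arch in config.cluster_proportions:
        curves[arch] = {}
        for dim in dims:
            if arch == "anticorrelated_HI":
                kind = "u_shaped" if dim != "Interesting" else "inverted_u_flipped"
            else:
                kind = arch
            curves[arch][dim] = kind
    truth = GroundTruth(
        beta_star=implied,
        beta_raw=beta.copy(),
        cluster_labels=clusters,
        slope_curves=curves,
        slope_peak=config.slope_peak,
    )
    return ratings, truth


# ---------------------------------------------------------------------------
# fast statistical surrogates
# ---------------------------------------------------------------------------

def sample_sip_table(
    n_images: int,
    rng: np.random.Generator,
    base_correlation: float = 0.3,
    category: str = "style_transferred",
) -> pd.DataFrame:
    """Draw a SIP-like table directly from a correlated Gaussian.

    A fast surrogate for calibration experiments (regression recovery,
    subset-search batteries) that do not need actual images: the eight
    model SIP columns follow a multivariate normal with an AR(1)-style
    correlation ``base_correlation^|i−j|``.  Only the z-scores matter to
    downstream analyses.
    """
    p = len(EIGHT_MODEL_SIPS)
    idx = np.arange(p)
    corr = base_correlation ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(corr)
    X = rng.standard_normal((n_images, p)) @ L.T
    df = pd.DataFrame(
        X,
        columns=list(EIGHT_MODEL_SIPS),
        index=[f"img_{i:03d}" for i in range(n_images)],
    )
    df.index.name = "image_id"
    df["category"] = category
    return df


def sample_inter_rating_vectors(
    rng: np.random.Generator,
    sizes: dict[int, int] | None = None,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Participant (ρ_PH, ρ_PI, ρ_HI) vectors around the five archetypes.

    Emulates the five published inter-rating clusters (one of them with a
    negative Harmonious/Interesting correlation) by jittering each archetype
    center with isotropic Gaussian noise.  Returns (features, true labels).
    """
    sizes = sizes or INTER_RATING_SIZES
    rows, labels = [], []
    pid = 0
    for c, n in sizes.items():
        center = np.array(INTER_RATING_ARCHETYPES[c])
        for _ in range(n):
            rows.append(np.clip(center + rng.normal(0.0, noise_sd, 3), -1.0, 1.0))
            labels.append(c)
            pid += 1
    feats = pd.DataFrame(
        rows,
        columns=["rho_PH", "rho_PI", "rho_HI"],
        index=[f"P{i:02d}" for i in range(pid)],
    )
    return feats, pd.Series(labels, index=feats.index, name="true_cluster")
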