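"""Relating aesthetic ratings to image statistics and design factors.

Ratings live in a long-format table: one row per (participant, image,
dimension) with the rating on a continuous [0, 1] scale and the dimension
one of Pleasing / Harmonious / Interesting.  The analyses here are the
study's statistical toolbox: per-image aggregation, standardized-β multiple
regression with effect-size bands, Kruskal–Wallis tests with Dunn's
post-test, quadratic preference curves over the set Fourier slope, and
inter-rating-dimension correlations (pooled or within participant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RATING_DIMENSIONS",
    "RegressionResult",
    "GroupTestResult",
    "QuadraticFit",
    "validate_rating_table",
    "aggregate_ratings",
    "standardized_regression",
    "effect_band",
    "kruskal_dunn",
    "slope_preference_curves",
    "inter_rating_correlations",
    "significance_stars",
]

RATING_DIMENSIONS = ("Pleasing", "Harmonious", "Interesting")
RATING_CATEGORIES = ("original", "random_phase", "style_transferred")

#: |β*| (and Spearman ρ) effect-size bands.
EFFECT_BANDS = {"weak": (0.0, 0.2), "moderate": (0.2, 0.5), "strong": (0.5, np.inf)}

STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


def effect_band(beta_star: float) -> str:
    """Classify |β*|: weak < 0.2 ≤ moderate < 0.5 ≤ strong."""
    b = abs(beta_star)
    if b < 0.2:
        return "weak"
    if b < 0.5:
        return "moderate"
    return "strong"


def significance_stars(p: float) -> str:
    """Four-level star convention: * … **** at 0.05/0.01/0.001/0.0001."""
    stars = sum(p < level for level in STAR_LEVELS)
    return "*" * stars if stars else "n.s."


def validate_rating_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format schema and closed value sets."""
    required = {"participant_id", "image_id", "category", "dimension", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    bad_dim = set(ratings["dimension"]) - set(RATING_DIMENSIONS)
    if bad_dim:
        raise ValueError(f"unknown rating dimensions {sorted(bad_dim)}")
    bad_cat = set(ratings["category"]) - set(RATING_CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories {sorted(bad_cat)}")
    r = ratings["rating"].astype(float)
    if r.isna().any() or (r < 0).any() or (r > 1).any():
        raise ValueError("ratings must lie in [0, 1]")
    dup = ratings.duplicated(["participant_id", "image_id", "dimension"])
    if dup.any():
        raise ValueError("duplicate (participant, image, dimension) rows")
    return ratings


def aggregate_ratings(ratings: pd.DataFrame, by: str = "image") -> pd.DataFrame:
    """Mean ratings with counts, grouped per image / artist / participant×slope.

    ``by='image'`` returns one row per (image, dimension); ``by='artist'``
    expects an ``artist`` column; ``by='participant_slope'`` expects a
    ``set_slope`` column and averages within participant × slope ×
    dimension.  The ``n`` column reports the number of ratings entering
    each mean (a coverage audit: 8 per random-phase image in the study
    design).
    """
    keys = {
        "image": ["image_id", "dimension"],
        "artist": ["artist", "dimension"],
        "participant_slope": ["participant_id", "set_slope", "dimension"],
    }
    if by not in keys:
        raise ValueError(f"unknown grouping {by!r}; expected one of {list(keys)}")
    cols = keys[by]
    missing = set(cols) - set(ratings.columns)
    if missing:
        raise ValueError(f"grouping needs columns {sorted(missing)}")
    if ratings.empty:
        raise ValueError("empty rating table")
    g = ratings.groupby(cols, observed=True)["rating"].agg(["mean", "count"])
    return g.rename(columns={"mean": "rating", "count": "n"}).reset_index()


@dataclass
class RegressionResult:
    """Standardized OLS summary: β*, partial p-values, effect bands, fit."""

    predictors: tuple[str, ...]
    beta_star: np.ndarray
    p_values: np.ndarray
    r2: float
    r2_adj: float
    n: int
    p: int
    f_pvalue: float
    conf_int: np.ndarray  # per predictor (low, high) for β*
    condition_number: float

    @property
    def effect_bands(self) -> tuple[str, ...]:
        return tuple(effect_band(b) for b in self.beta_star)

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_star": self.beta_star,
                "p": self.p_values,
                "stars": [significance_stars(p) for p in self.p_values],
                "band": self.effect_bands,
            },
            index=list(self.predictors),
        )


def standardized_regression(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    condition_bound: float = 1e4,
) -> RegressionResult:
    """OLS on z-scored predictors and response.

    Coefficients are the standardized β*; each p-value is the partial
    two-sided t-test in the full model ("controlled for" the other
    predictors).  β* are invariant to affine rescaling of any predictor or
    of the response.  A condition number beyond ``condition_bound`` emits a
    collinearity warning with variance-inflation factors.
    """
    names = tuple(X.columns)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    sd = Xv.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [names[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant predictors: {const}")
    Z = (Xv - Xv.mean(axis=0)) / sd
    ysd = yv.std(ddof=1)
    if ysd == 0:
        raise ValueError("constant response")
    zy = (yv - yv.mean()) / ysd
    model = sm.OLS(zy, sm.add_constant(Z)).fit()
    cond = float(np.linalg.cond(Z))
    if cond > condition_bound:
        vifs = {}
        for i in range(p):
            r2i = sm.OLS(Z[:, i], sm.add_constant(np.delete(Z, i, axis=1))).fit().rsquared
            vifs[names[i]] = float("inf") if r2i >= 1 else 1.0 / (1.0 - r2i)
        warnings.warn(f"ill-conditioned design (cond={cond:.3g}); VIF={vifs}")
    ci = np.asarray(model.conf_int())[1:]
    return RegressionResult(
        predictors=names,
        beta_star=np.asarray(model.params[1:]),
        p_values=np.asarray(model.pvalues[1:]),
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        n=n,
        p=p,
        f_pvalue=float(model.f_pvalue),
        conf_int=ci,
        condition_number=cond,
    )


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


@dataclass
class GroupTestResult:
    """Kruskal–Wallis H with Dunn pairwise post-tests."""

    h_statistic: float
    p_value: float
    groups: tuple[str, ...]
    group_sizes: dict[str, int]
    comparisons: list[PairwiseComparison] = field(default_factory=list)
    adjustment: str = "holm"


def kruskal_dunn(
    values, groups, adjustment: str = "holm"
) -> GroupTestResult:
    """Kruskal–Wallis test followed by Dunn's pairwise post-test.

    H is tie-corrected with a chi-square p-value.  Dunn's z for groups i, j
    uses mean ranks over the pooled sample,

        z = (R̄ᵢ − R̄ⱼ) / sqrt([N(N+1)/12 − T] (1/nᵢ + 1/nⱼ)),

    with tie correction T = Σ(t³ − t) / (12(N − 1)).  Raw two-sided normal
    p-values are multiplicity-adjusted over all pairs (Holm by default,
    ``adjustment='bonferroni'`` available).  Groups with fewer than 2
    values are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [str(g) for g in pd.unique(groups)]
    samples: dict[str, np.ndarray] = {}
    for g in labels:
        v = values[groups.astype(str) == g]
        if len(v) < 2:
            warnings.warn(f"group {g!r} has < 2 values; dropped")
            continue
        samples[g] = v
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 values")
    labs = tuple(samples)
    h, p_global = stats.kruskal(*samples.values())

    pooled = np.concatenate([samples[g] for g in labs])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labs:
        n_g = len(samples[g])
        mean_ranks[g] = ranks[start : start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_corr

    comps = []
    raw_ps = []
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            a, b = labs[i], labs[j]
            se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            comps.append([a, b, z, p_raw])
            raw_ps.append(p_raw)
    if adjustment not in ("holm", "bonferroni"):
        raise ValueError("adjustment must be 'holm' or 'bonferroni'")
    adj = multipletests(raw_ps, method=adjustment)[1] if raw_ps else []
    comparisons = [
        PairwiseComparison(a, b, z, p_raw, float(p_adj))
        for (a, b, z, p_raw), p_adj in zip(comps, adj)
    ]
    return GroupTestResult(
        float(h), float(p_global), labs, sizes, comparisons, adjustment
    )


@dataclass
class QuadraticFit:
    """Least-squares fit of a + b·x + c·x² to mean rating vs set slope."""

    a: float
    b: float
    c: float
    r2: float

    @property
    def vertex(self) -> float:
        if self.c == 0:
            return float("nan")
        return -self.b / (2.0 * self.c)

    @property
    def curvature_sign(self) -> int:
        return int(np.sign(self.c))

    @property
    def inverted_u(self) -> bool:
        return self.c < 0


def fit_quadratic(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values for a quadratic fit")
    c, b, a = np.polyfit(x, y, 2)
    yhat = a + b * x + c * x**2
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(float(a), float(b), float(c), r2)


def slope_preference_curves(
    ratings: pd.DataFrame, set_slopes: pd.Series | dict
) -> dict[str, dict]:
    """Per-dimension preference profile over the set Fourier slope.

    For each rating dimension: a Kruskal–Wallis test (with Dunn pairs)
    across the slope levels on per-participant mean ratings, and a
    quadratic least-squares fit of per-image mean rating vs set slope.
    A negative quadratic coefficient is the inverted-U signature.
    """
    if isinstance(set_slopes, dict):
        set_slopes = pd.Series(set_slopes)
    df = ratings.copy()
    df["set_slope"] = df["image_id"].map(set_slopes)
    if df["set_slope"].isna().any():
        raise ValueError("set_slope missing for some rated images")
    if df["set_slope"].nunique() < 3:
        raise ValueError("need >= 3 distinct slope levels")
    out: dict[str, dict] = {}
    for dim in RATING_DIMENSIONS:
        d = df[df["dimension"] == dim]
        if d.empty:
            continue
        per_part = (
            d.groupby(["participant_id", "set_slope"], observed=True)["rating"]
            .mean()
            .reset_index()
        )
        test = kruskal_dunn(per_part["rating"], per_part["set_slope"])
        per_image = d.groupby("image_id", observed=True).agg(
            rating=("rating", "mean"), set_slope=("set_slope", "first")
        )
        fit = fit_quadratic(per_image["set_slope"], per_image["rating"])
        out[dim] = {"group_test": test, "quadratic": fit}
    return out


def inter_rating_correlations(
    ratings: pd.DataFrame, scope: str = "pooled", min_common: int = 5
):
    """Spearman ρ between the three rating-dimension pairs.

    ``scope='pooled'``: ρ on per-image mean ratings, one value per pair.
    ``scope='per_participant'``: each participant's own ratings over the
    images they rated in both dimensions; participants with fewer than
    ``min_common`` common images are excluded with a warning.  Returns a
    DataFrame with columns rho_PH, rho_PI, rho_HI (single row ``pooled``
    for pooled scope, one row per participant otherwise).
    """
    pairs = {
        "rho_PH": ("Pleasing", "Harmonious"),
        "rho_PI": ("Pleasing", "Interesting"),
        "rho_HI": ("Harmonious", "Interesting"),
    }
    if scope == "pooled":
        wide = (
            ratings.groupby(["image_id", "dimension"], observed=True)["rating"]
            .mean()
            .unstack("dimension")
        )
        row = {}
        for name, (a, b) in pairs.items():
            common = wide[[a, b]].dropna()
            row[name] = float(stats.spearmanr(common[a], common[b]).statistic)
        return pd.DataFrame([row], index=["pooled"])
    if scope != "per_participant":
        raise ValueError("scope must be 'pooled' or 'per_participant'")
    rows = {}
    for pid, d in ratings.groupby("participant_id", observed=True):
        wide = d.pivot_table(
            index="image_id", columns="dimension", values="rating", observed=True
        )
        row = {}
        ok = True
        for name, (a, b) in pairs.items():
            if a not in wide or b not in wide:
                ok = False
                break
            common = wide[[a, b]].dropna()
            if len(common) < min_common:
                ok = False
                break
            row[name] = float(stats.spearmanr(common[a], common[b]).statistic)
        if ok:
            rows[pid] = row
        else:
            warnings.warn(f"participant {pid!r} excluded (insufficient common images)")
    return pd.DataFrame.from_dict(rows, orient="index")
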