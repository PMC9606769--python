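"""Distance to a reference "sweet spot" corpus in SIP space.

Traditional paintings concentrate in a restricted region of SIP space.
An image's dissimilarity to that region is measured by the squared
Mahalanobis distance D² = (x − c)ᵀ Σ⁻¹ (x − c), where c is the per-SIP
median of a reference SIP table and Σ its sample covariance — the
multivariate analogue of the Euclidean distance that accounts for scale
and correlation.  Per-SIP (one-dimensional, absolute) distances to the
reference medians are kept alongside for univariate profiles, and both are
related to aesthetic ratings via Spearman correlations: a negative ρ means
images closer to the reference are rated higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import RATING_DIMENSIONS, kruskal_dunn

__all__ = [
    "ReferenceDistribution",
    "build_reference",
    "select_differing_variables",
    "mahalanobis_sq",
    "distance_table",
    "distance_rating_correlation",
]


@dataclass(frozen=True)
class ReferenceDistribution:
    """Reference corpus summary: per-SIP medians + full covariance."""

    variables: tuple[str, ...]
    center: np.ndarray
    covariance: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        p = len(self.variables)
        if self.center.shape != (p,) or self.covariance.shape != (p, p):
            raise ValueError("center/covariance shapes inconsistent with variables")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


def build_reference(
    reference_sips: pd.DataFrame,
    variables: list[str],
    ridge_eps: float = 1e-8,
) -> ReferenceDistribution:
    """Summarise a reference SIP table on the chosen variable subspace.

    The center is the columnwise median (the study convention correlates
    distances to the reference *median*); the covariance is the ordinary
    sample covariance about the mean.  A near-singular covariance is
    ridge-regularised by ``ridge_eps``·mean(diag); if it remains singular
    the offending variables are named in the error.
    """
    missing = [v for v in variables if v not in reference_sips.columns]
    if missing:
        raise ValueError(f"variables not in reference table: {missing}")
    X = np.asarray(reference_sips[variables], dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need more than p + 2 = {p + 2} reference rows, got {n}")
    center = np.median(X, axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < p or np.linalg.cond(cov) > 1e12:
        cov = cov + np.eye(p) * ridge_eps * float(np.trace(cov)) / p
    if np.linalg.matrix_rank(cov) < p:
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "singular covariance after regularisation; most collinear pair: "
            f"{variables[i]!r} / {variables[j]!r}"
        )
    return ReferenceDistribution(tuple(variables), center, cov, n)


def select_differing_variables(
    test_sips: pd.DataFrame,
    reference_sips: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
) -> list[str]:
    """SIPs whose distributions differ between test set and reference.

    For each candidate a Kruskal–Wallis comparison between the two sets is
    run; candidates significant at ``alpha`` are returned.  This automates
    the study's rule of spanning the distance space with the variables that
    separate the test images from the reference corpus.
    """
    chosen = []
    for v in candidates:
        vals = np.concatenate(
            [np.asarray(test_sips[v], float), np.asarray(reference_sips[v], float)]
        )
        labels = ["test"] * len(test_sips) + ["reference"] * len(reference_sips)
        res = kruskal_dunn(vals, np.asarray(labels))
        if res.p_value < alpha:
            chosen.append(v)
    return chosen


def mahalanobis_sq(x: np.ndarray | pd.Series, ref: ReferenceDistribution) -> float:
    """Squared Mahalanobis distance (x − c)ᵀ Σ⁻¹ (x − c) to the reference."""
    xv = np.asarray(x, dtype=float).ravel()
    if xv.shape != ref.center.shape:
        raise ValueError(
            f"dimension mismatch: x has {xv.shape[0]}, reference {len(ref.variables)}"
        )
    d = xv - ref.center
    return float(d @ np.linalg.solve(ref.covariance, d))


def distance_table(test_sips: pd.DataFrame, ref: ReferenceDistribution) -> pd.DataFrame:
    """Per-image D² and per-SIP absolute distances to the reference median."""
    X = np.asarray(test_sips[list(ref.variables)], dtype=float)
    prec = ref.precision
    diffs = X - ref.center
    d2 = np.einsum("ij,jk,ik->i", diffs, prec, diffs)
    out = pd.DataFrame(index=test_sips.index)
    out["mahalanobis_sq"] = d2
    for j, v in enumerate(ref.variables):
        out[f"dist_{v}"] = np.abs(diffs[:, j])
    return out


def distance_rating_correlation(
    distances: pd.DataFrame,
    ratings_per_image: pd.DataFrame,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Spearman ρ of each rating dimension with every distance column.

    ``ratings_per_image`` is the per-(image, dimension) mean table from
    :func:`sipscape.ratings.aggregate_ratings`.  Rows of the result are the
    distance columns (D² plus each per-SIP distance), columns the rating
    dimensions, each cell holding (rho, p).  Negative ρ ⇔ images closer to
    the reference are rated higher.
    """
    wide = ratings_per_image.pivot_table(
        index="image_id", columns="dimension", values="rating", observed=True
    )
    shared = distances.index.intersection(wide.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared images (< {min_shared})")
    rows = {}
    for col in distances.columns:
        row = {}
        for dim in RATING_DIMENSIONS:
            if dim not in wide.columns:
                continue
            sub = pd.concat([distances.loc[shared, col], wide.loc[shared, dim]], axis=1)
            sub = sub.dropna()
            r = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            row[(dim, "rho")] = float(r.statistic)
            row[(dim, "p")] = float(r.pvalue)
        rows[col] = row
    return pd.DataFrame.from_dict(rows, orient="index")
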