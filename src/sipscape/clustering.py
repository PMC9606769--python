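"""Participant clustering with cluster-count diagnostics.

Participants are summarised either by their inter-rating correlation
vector (ρ_PH, ρ_PI, ρ_HI) or by their slope-preference profile (mean
rating per set Fourier slope × rating dimension, z-scored per feature),
and partitioned with k-means.  Three diagnostics are always reported —
elbow (largest second difference of the within-cluster sum of squares),
mean silhouette width, and the gap statistic against a uniform
bounding-box reference — and the chosen k follows the elbow subject to a
minimum cluster size (every cluster must exceed three participants, the
study's constraint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ratings import inter_rating_correlations

__all__ = [
    "ClusterResult",
    "participant_feature_vectors",
    "kmeans_with_diagnostics",
]


@dataclass
class ClusterResult:
    """K-means partition plus the diagnostics used to choose k."""

    assignments: pd.Series  # participant -> cluster id, for the chosen k
    centers: np.ndarray
    chosen_k: int
    elbow_k: int
    wss: dict[int, float]
    silhouette: dict[int, float]
    gap: dict[int, float]
    min_cluster_size: int
    constraint_violations: dict[int, int] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.assignments.value_counts().sort_index().to_dict()


def participant_feature_vectors(
    ratings: pd.DataFrame,
    mode: str = "inter_rating",
    set_slopes: pd.Series | dict | None = None,
    min_common: int = 5,
) -> pd.DataFrame:
    """One feature vector per participant.

    ``mode='inter_rating'``: the 3-vector of within-participant Spearman
    correlations (ρ_PH, ρ_PI, ρ_HI).  ``mode='slope_profile'``: mean rating
    per (set slope × dimension) — 18 features for the six-slope design —
    z-scored per feature so no slope/dimension dominates the metric.
    Participants with insufficient data are excluded with a warning.
    """
    if mode == "inter_rating":
        return inter_rating_correlations(
            ratings, scope="per_participant", min_common=min_common
        )
    if mode != "slope_profile":
        raise ValueError("mode must be 'inter_rating' or 'slope_profile'")
    if set_slopes is None:
        if "set_slope" not in ratings.columns:
            raise ValueError("slope_profile mode needs set_slopes or a set_slope column")
        df = ratings
    else:
        if isinstance(set_slopes, dict):
            set_slopes = pd.Series(set_slopes)
        df = ratings.copy()
        df["set_slope"] = df["image_id"].map(set_slopes)
        df = df.dropna(subset=["set_slope"])
    prof = df.pivot_table(
        index="participant_id",
        columns=["set_slope", "dimension"],
        values="rating",
        aggfunc="mean",
        observed=True,
    )
    incomplete = prof.index[prof.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"excluding participants with incomplete profiles: {list(incomplete)}")
        prof = prof.drop(index=incomplete)
    z = (prof - prof.mean()) / prof.std(ddof=0).replace(0.0, 1.0)
    z.columns = [f"s{s:g}_{d}" for s, d in z.columns]
    return z


def _gap_statistic(
    X: np.ndarray, k: int, wss_k: float, rng: np.random.Generator,
    n_refs: int = 50, n_init: int = 5
) -> float:
    """Gap(k) = E*[log WSS_ref(k)] − log WSS(k), uniform-box reference."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    logs = []
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        km = KMeans(
            n_clusters=k, n_init=n_init,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(ref)
        logs.append(np.log(max(km.inertia_, 1e-300)))
    return float(np.mean(logs) - np.log(max(wss_k, 1e-300)))


def kmeans_with_diagnostics(
    X: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(1, 9),
    n_init: int = 25,
    seed: int = 0,
    min_cluster_size: int = 4,
    gap_refs: int = 50,
) -> ClusterResult:
    """K-means over a range of k with elbow / silhouette / gap diagnostics.

    Lloyd's algorithm with k-means++ seeding and ``n_init`` restarts, best
    WSS kept per k.  The elbow suggestion is the k with the largest second
    difference of log-WSS (the kink of the scree curve on a scale-free
    axis, so an early large drop cannot mask a later sharp elbow); the
    chosen k is demoted to the largest k ≤ elbow
    whose best partition has every cluster of at least
    ``min_cluster_size`` members (the study kept clusters of more than
    three participants).
    """
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    Xv = np.asarray(X, dtype=float)
    n = len(Xv)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 for k in ks):
        raise ValueError("k must be >= 1")
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds {n} rows")
    rng = np.random.default_rng(seed)

    fits: dict[int, KMeans] = {}
    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    gap: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xv)
        fits[k] = km
        wss[k] = float(km.inertia_)
        if 2 <= k <= n - 1:
            sil[k] = float(silhouette_score(Xv, km.labels_))
        gap[k] = _gap_statistic(Xv, k, wss[k], rng, n_refs=gap_refs)

    # elbow: largest second difference of log-WSS over interior k values
    elbow_k = ks[0]
    if len(ks) >= 3:
        lw = {k: math.log(max(wss[k], 1e-300)) for k in ks}
        second_diff = {
            ks[i]: (lw[ks[i - 1]] - lw[ks[i]]) - (lw[ks[i]] - lw[ks[i + 1]])
            for i in range(1, len(ks) - 1)
        }
        elbow_k = max(second_diff, key=second_diff.get)

    violations = {
        k: int((np.bincount(fits[k].labels_) < min_cluster_size).sum()) for k in ks
    }
    chosen = elbow_k
    while chosen > min(ks) and violations[chosen] > 0:
        chosen = max(k for k in ks if k < chosen)
    if violations[chosen] > 0:
        warnings.warn(
            f"no k in range satisfies min cluster size {min_cluster_size}; "
            f"reporting k={chosen} with violations"
        )
    km = fits[chosen]
    return ClusterResult(
        assignments=pd.Series(km.labels_, index=index, name="cluster"),
        centers=km.cluster_centers_,
        chosen_k=chosen,
        elbow_k=elbow_k,
        wss=wss,
        silhouette=sil,
        gap=gap,
        min_cluster_size=min_cluster_size,
        constraint_violations=violations,
    )
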