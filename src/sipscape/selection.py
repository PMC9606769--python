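"""Predictor subset reduction in three steps.

The analysis reduces a large candidate SIP set to a small, low-collinearity
subset: (1) exhaustive best-subset regression retaining the ``n_best``
models by adjusted R² for every model size, with per-variable robustness
counts; (2) a cut to the most robust variables; (3) iterative elimination of
variables whose pairwise Spearman |ρ| exceeds a threshold (0.6 in the study
convention).  A principal-component regression on the full candidate set
serves as the reference model the reduced set is compared against.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "SubsetSearchResult",
    "spearman_matrix",
    "best_subset_search",
    "select_robust_variables",
    "prune_collinear",
    "pca_reference_model",
]

ENUMERATION_CAP = 2_000_000


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rank-correlation matrix with paired two-sided p-values.

    Constant columns have undefined correlations; those entries are NaN and
    the offending variables are listed in ``undefined``.
    """

    variables: tuple[str, ...]
    rho: np.ndarray
    p_values: np.ndarray
    undefined: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)

    def pair(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.rho[i, j])


@dataclass
class SubsetModel:
    members: tuple[str, ...]
    r2: float
    r2_adj: float


@dataclass
class SubsetSearchResult:
    """Best-subset search output: retained models per size + robustness.

    ``models[s]`` holds up to ``n_best`` models of size ``s`` sorted by
    adjusted R² (descending); ``robustness`` counts the appearances of each
    variable across every retained model (summed over merged results when
    the search ran once per response dimension).
    """

    models: dict[int, list[SubsetModel]] = field(default_factory=dict)
    robustness: dict[str, int] = field(default_factory=dict)
    method: str = "exhaustive"

    def merge(self, other: "SubsetSearchResult") -> "SubsetSearchResult":
        merged = SubsetSearchResult(
            models={**self.models}, robustness=dict(self.robustness)
        )
        for s, mods in other.models.items():
            merged.models.setdefault(s, []).extend(mods)
        for v, c in other.robustness.items():
            merged.robustness[v] = merged.robustness.get(v, 0) + c
        return merged


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Spearman ρ (average ranks on ties) with two-sided p-values.

    Constant columns get NaN rows/columns and are flagged, not reported
    as 0.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 complete rows")
    names = tuple(num.columns)
    p = len(names)
    constant = [c for c in names if num[c].nunique() <= 1]
    rho = np.full((p, p), np.nan)
    pval = np.full((p, p), np.nan)
    for i in range(p):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            if a in constant or b in constant:
                continue
            r = stats.spearmanr(num[a], num[b])
            rho[i, j] = rho[j, i] = r.statistic
            pval[i, j] = pval[j, i] = r.pvalue
    for c in constant:
        i = names.index(c)
        rho[i, i] = np.nan
        pval[i, i] = np.nan
    return CorrelationMatrix(names, rho, pval, tuple(constant))


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _subset_r2(gram: np.ndarray, xty: np.ndarray, tss: float, idx: tuple[int, ...]):
    """R² of the OLS fit on centred predictors ``idx`` (intercept implicit)."""
    sub = np.ix_(idx, idx)
    try:
        beta = np.linalg.solve(gram[sub], xty[list(idx)])
    except np.linalg.LinAlgError:
        return None
    ess = float(xty[list(idx)] @ beta)
    return min(ess / tss, 1.0) if tss > 0 else 0.0


def best_subset_search(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_best: int = 10,
    size_cap: int | None = None,
    enumeration_cap: int = ENUMERATION_CAP,
) -> SubsetSearchResult:
    """Retain the ``n_best`` regression subsets by adjusted R² per size.

    For each model size s up to ``size_cap``, all C(p, s) subsets are
    enumerated when that count is within ``enumeration_cap``; otherwise a
    branch-and-bound on residual sum of squares (prune when even using the
    whole remaining pool cannot beat the current n-th best) finds the same
    lists.  Rank-deficient candidate subsets are skipped with a warning.
    Ties in adjusted R² break lexicographically on the member names, so the
    output is deterministic and route-independent.
    """
    names = list(X.columns)
    p = len(names)
    size_cap = p if size_cap is None else min(size_cap, p)
    Xc = np.asarray(X, dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n <= size_cap + 2:
        raise ValueError(f"need n > size_cap + 2 rows (n={n}, size_cap={size_cap})")
    yc = yv - yv.mean()
    gram = Xc.T @ Xc
    xty = Xc.T @ yc
    tss = float(yc @ yc)

    result = SubsetSearchResult(robustness={v: 0 for v in names})
    skipped = 0

    def record(size: int, kept: list[tuple[float, tuple[int, ...], float]]):
        kept.sort(key=lambda t: (-t[0], tuple(names[i] for i in t[1])))
        mods = [
            SubsetModel(tuple(names[i] for i in idx), r2, r2a)
            for (r2a, idx, r2) in kept[:n_best]
        ]
        result.models[size] = mods
        for m in mods:
            for v in m.members:
                result.robustness[v] += 1

    for s in range(1, size_cap + 1):
        if math.comb(p, s) <= enumeration_cap:
            kept: list[tuple[float, tuple[int, ...], float]] = []
            for idx in itertools.combinations(range(p), s):
                r2 = _subset_r2(gram, xty, tss, idx)
                if r2 is None:
                    skipped += 1
                    continue
                kept.append((adjusted_r2(r2, n, s), idx, r2))
            record(s, kept)
        else:
            result.method = "branch_and_bound"
            kept = _branch_and_bound(gram, xty, tss, p, s, n, n_best)
            record(s, kept)
    if skipped:
        warnings.warn(f"skipped {skipped} rank-deficient candidate subsets")
    return result


def _branch_and_bound(
    gram: np.ndarray, xty: np.ndarray, tss: float, p: int, s: int, n: int, n_best: int
) -> list[tuple[float, tuple[int, ...], float]]:
    """Top-``n_best`` size-``s`` subsets by R² via RSS branch-and-bound.

    At a node (chosen, pool) the R² of chosen ∪ pool bounds every size-s
    completion from above (adding predictors never increases RSS), so the
    node is pruned when that bound cannot enter the current best list.
    """
    best: list[tuple[float, tuple[int, ...]]] = []  # (r2, idx), sorted desc

    def bound_ok(r2_bound: float) -> bool:
        return len(best) < n_best or r2_bound > best[-1][0] - 1e-15

    def visit(chosen: tuple[int, ...], start: int) -> None:
        remaining = s - len(chosen)
        pool = tuple(range(start, p))
        if len(pool) < remaining:
            return
        full = _subset_r2(gram, xty, tss, chosen + pool)
        if full is None or not bound_ok(full):
            return
        if remaining == 0:
            r2 = _subset_r2(gram, xty, tss, chosen)
            if r2 is not None:
                best.append((r2, chosen))
                best.sort(key=lambda t: -t[0])
                del best[n_best:]
            return
        for i in range(start, p - remaining + 1):
            visit(chosen + (i,), i + 1)

    visit((), 0)
    return [(adjusted_r2(r2, n, s), idx, r2) for r2, idx in best]


def select_robust_variables(
    result: SubsetSearchResult, n_select: int = 12
) -> list[str]:
    """The ``n_select`` variables appearing most often across retained models.

    Ties in the appearance count break by the best single-model adjusted R²
    a variable participates in, then lexicographically.
    """
    best_r2a: dict[str, float] = {}
    for mods in result.models.values():
        for m in mods:
            for v in m.members:
                best_r2a[v] = max(best_r2a.get(v, -np.inf), m.r2_adj)
    ranked = sorted(
        result.robustness,
        key=lambda v: (-result.robustness[v], -best_r2a.get(v, -np.inf), v),
    )
    return ranked[:n_select]


def prune_collinear(
    table: pd.DataFrame,
    candidates: list[str],
    threshold: float = 0.6,
    robustness: dict[str, int] | None = None,
    response: np.ndarray | pd.Series | None = None,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop one of each |ρ| > threshold pair until none remain.

    From the worst-offending pair the variable with the lower robustness
    count is dropped; ties break toward the lower max |ρ| with the response
    (when a response is supplied), then lexicographically *reversed* so the
    alphabetically later name goes first.  Returns the survivors (input
    order preserved) and an audit log of drops.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidates not in table: {missing}")
    robustness = robustness or {}
    resp_rho: dict[str, float] = {}
    if response is not None:
        for c in candidates:
            r = stats.spearmanr(table[c], response)
            resp_rho[c] = abs(float(r.statistic))
    surviving = list(candidates)
    log: list[dict] = []
    while True:
        cm = spearman_matrix(table[surviving]) if len(surviving) > 1 else None
        if cm is None:
            break
        rho = np.abs(cm.rho.copy())
        np.fill_diagonal(rho, 0.0)
        rho = np.nan_to_num(rho)
        i, j = np.unravel_index(np.argmax(rho), rho.shape)
        if rho[i, j] <= threshold:
            break
        a, b = cm.variables[i], cm.variables[j]

        def key(v: str) -> tuple:
            return (robustness.get(v, 0), resp_rho.get(v, 0.0), [-ord(ch) for ch in v])

        drop = min((a, b), key=key)
        surviving.remove(drop)
        log.append(
            {
                "dropped": drop,
                "against": b if drop == a else a,
                "abs_rho": float(rho[i, j]),
            }
        )
    return surviving, log


def pca_reference_model(
    table: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_components: int = 8,
):
    """Adjusted R² of a regression on leading principal-component scores.

    Columns are standardized, projected onto the first ``n_components``
    principal components, and an OLS model of ``y`` on the scores is fit.
    ``n_components`` is reduced automatically (with a warning) when it
    exceeds the rank of the standardized matrix.  Returns a
    :class:`sipscape.ratings.RegressionResult`.
    """
    from sklearn.decomposition import PCA

    from .ratings import standardized_regression

    num = table.select_dtypes(include=[np.number])
    X = np.asarray(num, dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping constant columns {list(num.columns[~keep])}")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rank = np.linalg.matrix_rank(Z)
    if n_components > rank:
        warnings.warn(f"n_components reduced from {n_components} to rank {rank}")
        n_components = rank
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
    cols = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(n_components)])
    return standardized_regression(cols, np.asarray(y, dtype=float))
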