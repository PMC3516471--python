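"""Temporal-profile clustering: fuzzy c-means with data-driven parameter
selection, plus hierarchical ordering for heatmaps.

Soft clustering follows the standard fuzzy c-means (FCM) scheme on
standardized log2 fold-change profiles.  Standardization (row mean 0, sd 1)
makes Euclidean distance between profiles equivalent to a correlation-type
dissimilarity, so clusters capture temporal *shape* rather than amplitude.
Genes with near-constant profiles (sd below ``min_sd``, default 0.25 on
logged fold changes) are removed first — they carry no shape information
and standardizing them amplifies noise.

Parameter selection, when not fixed by the caller:

* the fuzzifier m is the smallest grid value at which FCM run on a
  within-row shuffled copy of the data finds no structure (max membership
  within 0.05 of the uniform 1/c for >= 95% of rows) — larger m values only
  blur real structure further;
* the cluster number c is chosen by a minimum-centroid-separation elbow:
  the first c at which the closest pair of centroids collapses to under a
  fraction (default 0.5) of its separation at c = 2 signals one cluster too
  many, and c - 1 is returned.  (A superfluous centroid does not duplicate
  an existing one exactly — at moderate fuzzifiers it settles a small but
  nonzero distance away — so the collapse shows up as a drop to well under
  half the baseline separation rather than to near zero.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class ClusterFilter:
    """Profile-variability filter and membership display cutoff."""

    min_sd: float = 0.25
    membership_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.min_sd < 0:
            raise ValueError("min_sd must be >= 0")
        if not 0 < self.membership_cutoff < 1:
            raise ValueError("membership_cutoff must be in (0, 1)")


@dataclass
class SoftClusteringResult:
    c: int
    m: float
    centroids: np.ndarray  # c x T
    memberships: pd.DataFrame  # gene x c, rows sum to 1
    objective: float
    seed: int
    n_iter: int
    objective_trace: list[float] | None = None  # per-iteration J of the kept restart

    def labels(self, cutoff: float = 0.5) -> pd.Series:
        return assign_clusters(self, cutoff)


def filter_and_standardize(
    fc_table: pd.DataFrame,
    cluster_filter: ClusterFilter | None = None,
    include_reference: bool = True,
) -> pd.DataFrame:
    """Drop low-variability profiles and standardize the rest to mean 0, sd 1.

    ``fc_table`` needs ``log2fc_<t>`` columns; the 0 h reference point
    (log2FC identically 0) is prepended by default so profiles display the
    full time course.  Row sd uses ddof=1, matching the filter convention
    of soft-clustering toolkits for expression data.
    """
    cf = cluster_filter or ClusterFilter()
    cols = [c for c in fc_table.columns if c.startswith("log2fc_")]
    if len(cols) < 3:
        raise ValueError("need at least 3 time points for profile clustering")
    mat = fc_table[cols].astype(float).copy()
    if include_reference:
        mat.insert(0, "log2fc_0h", 0.0)
    sd = mat.std(axis=1, ddof=1)
    kept = mat.loc[sd >= cf.min_sd]
    centered = kept.sub(kept.mean(axis=1), axis=0)
    return centered.div(kept.std(axis=1, ddof=1), axis=0)


def _init_centroids(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(len(X), size=c, replace=False)
    return X[idx].copy()


def _memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    # u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)); exact zero distance -> hard 1
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 0
    rows_zero = zero.any(axis=1)
    safe = np.where(zero, 1.0, d2)
    inv = safe ** (-1.0 / (m - 1.0))
    u = inv / inv.sum(axis=1, keepdims=True)
    if rows_zero.any():
        u[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
    return u


def _objective(X: np.ndarray, centroids: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(((u**m) * d2).sum())


def fuzzy_cmeans(
    matrix: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
) -> SoftClusteringResult:
    """Fuzzy c-means by alternating membership/centroid updates.

    Runs ``n_restarts`` restarts (centroids initialized from distinct data
    rows) and keeps the solution with the lowest objective
    J = sum_ij u_ij^m ||x_j - c_i||^2, which is non-increasing across
    iterations of each run.  Iteration stops when the largest membership
    change falls below ``tol``.
    """
    X = np.asarray(matrix, dtype=float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(X))
    if not np.isfinite(X).all():
        raise ValueError("input matrix contains non-finite values")
    if c < 2 or m <= 1 or len(X) <= c:
        raise ValueError("need c >= 2, m > 1 and more rows than clusters")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centroids = _init_centroids(X, c, rng)
        u = _memberships(X, centroids, m)
        trace = [_objective(X, centroids, u, m)]
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            w = u**m
            centroids = (w.T @ X) / w.sum(axis=0)[:, None]
            u_new = _memberships(X, centroids, m)
            delta = np.abs(u_new - u).max()
            u = u_new
            trace.append(_objective(X, centroids, u, m))
            if delta < tol:
                break
        obj = trace[-1]
        if best is None or obj < best[0]:
            best = (obj, centroids, u, n_iter, trace)
    obj, centroids, u, n_iter, trace = best
    memberships = pd.DataFrame(u, index=index, columns=[f"cluster_{i + 1}" for i in range(c)])
    return SoftClusteringResult(
        c=c, m=m, centroids=centroids, memberships=memberships,
        objective=obj, seed=seed, n_iter=n_iter, objective_trace=trace,
    )


def assign_clusters(result: SoftClusteringResult, cutoff: float = 0.5) -> pd.Series:
    """Hard labels at a membership cutoff: argmax cluster (1-based) when the
    top membership exceeds ``cutoff``, else 0 (unassigned)."""
    u = result.memberships.to_numpy()
    top = u.max(axis=1)
    labels = np.where(top > cutoff, u.argmax(axis=1) + 1, 0)
    return pd.Series(labels, index=result.memberships.index, name="cluster")


def _shuffle_within_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = X.copy()
    for row in out:
        rng.shuffle(row)
    return out


def select_parameters(
    matrix: pd.DataFrame | np.ndarray,
    c_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    m_range: tuple[float, ...] = (1.1, 1.25, 1.5, 2.0, 2.5, 3.0),
    seed: int = 0,
    collapse_fraction: float = 0.5,
    n_restarts: int = 3,
) -> tuple[int, float, pd.DataFrame]:
    """Data-driven choice of (c, m); see the module docstring for the
    criteria.  Deterministic given ``seed``.  Returns the chosen values and
    a diagnostics table of the grid evaluations."""
    if not c_range or not m_range:
        raise ValueError("c_range and m_range must be nonempty")
    X = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    shuffled = _shuffle_within_rows(X, rng)
    c_probe = min(c_range)
    diag_rows = []

    chosen_m = None
    for m in sorted(m_range):
        res = fuzzy_cmeans(shuffled, c=c_probe, m=m, seed=seed, n_restarts=n_restarts)
        top = res.memberships.to_numpy().max(axis=1)
        frac_uniform = float((top < 1.0 / c_probe + 0.05).mean())
        diag_rows.append(("m", m, frac_uniform))
        if frac_uniform >= 0.95:
            chosen_m = m
            break
    if chosen_m is None:
        chosen_m = max(m_range)
        import warnings

        warnings.warn("no fuzzifier in range removed spurious structure; using largest")

    min_sep = {}
    for c in sorted(c_range):
        res = fuzzy_cmeans(X, c=c, m=chosen_m, seed=seed, n_restarts=n_restarts)
        sep = float(pdist(res.centroids).min())
        min_sep[c] = sep
        diag_rows.append(("c", c, sep))
    base = min_sep[min(c_range)]
    chosen_c = max(c_range)
    for c in sorted(c_range)[1:]:
        if min_sep[c] < collapse_fraction * base:
            chosen_c = c - 1
            break
    diagnostics = pd.DataFrame(diag_rows, columns=["parameter", "value", "criterion"])
    return chosen_c, chosen_m, diagnostics


def hierarchical_order(
    matrix: pd.DataFrame | np.ndarray, method: str = "complete"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering on 1 - centered Pearson correlation.

    Returns ``(leaf_order, linkage_matrix)``; the linkage is scipy's, with
    its deterministic tie handling.  Rows of zero variance have no defined
    correlation and raise with the offending row named.
    """
    X = np.asarray(matrix, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    sd = X.std(axis=1)
    if (sd == 0).any():
        idx = int(np.flatnonzero(sd == 0)[0])
        name = matrix.index[idx] if isinstance(matrix, pd.DataFrame) else idx
        raise ValueError(f"row {name!r} has zero variance; correlation undefined")
    dist = pdist(X, metric="correlation")
    linkage = hierarchy.linkage(dist, method=method)
    order = hierarchy.leaves_list(linkage)
    return order, linkage
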