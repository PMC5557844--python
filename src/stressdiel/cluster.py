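"""K-means clustering of expression profiles and drought-response labeling.

The clustering engine is a from-scratch Lloyd's algorithm with
k-means++ seeding, restarted ``n_init`` times from a seeded generator
and keeping the lowest within-cluster sum of squares (WCSS).  On tiny
problems (``k**n_rows`` below a fixed bound) the engine instead
enumerates every assignment and returns the exact global optimum —
Lloyd restarts cannot guarantee that, because the optimal partition's
basin of attraction can exclude every data-point initialization.

Genes are then labeled drought up / down / unresponsive from the
*cluster* mean of the drought-pair log2 fold changes: a gene inherits
"up" when its cluster mean is at or above +up_threshold, "down" at or
below -down_threshold, and "none" otherwise.  This mirrors grouping
fold-change heatmap profiles and marking whole responsive clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import FoldChangeProfile


@dataclass
class KmeansResult:
    """Outcome of one clustering run.

    ``assignments`` maps each row (gene) to a cluster id in [0, k);
    ``wcss_history`` records the objective after every Lloyd update and
    is non-increasing.
    """

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    wcss: float
    n_iter: int
    seed: int
    wcss_history: np.ndarray
    row_ids: pd.Index | None = None

    def assignments_series(self) -> pd.Series:
        index = self.row_ids if self.row_ids is not None else pd.RangeIndex(len(self.assignments))
        return pd.Series(self.assignments, index=index, name="cluster")


# exact enumeration bound: n=8, k=3 gives 6561 assignments; anything at
# or below this cost is solved to the global optimum directly
_EXACT_ENUMERATION_LIMIT = 20_000


def _exact_small(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Global optimum by vectorized enumeration of all k^n assignments."""
    import itertools

    n, d = X.shape
    assignments = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int8)
    sq_norms = (X * X).sum(axis=1)
    wcss = np.zeros(len(assignments))
    for j in range(k):
        mask = assignments == j  # (n_assignments, n)
        counts = mask.sum(axis=1)
        sums = mask @ X  # (n_assignments, d)
        q = mask @ sq_norms
        occupied = counts > 0
        wcss[occupied] += (
            q[occupied] - (sums[occupied] ** 2).sum(axis=1) / counts[occupied]
        )
    best = int(wcss.argmin())
    labels = assignments[best].astype(int)
    centroids = np.empty((k, d))
    for j in range(k):
        members = X[labels == j]
        centroids[j] = members.mean(axis=0) if len(members) else X[0]
    return labels, centroids, float(wcss[best])


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared Euclidean distances via the expansion trick
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    labels = d2.argmin(axis=1)
    return labels, np.maximum(d2[np.arange(len(X)), labels], 0.0)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centroids = _kmeanspp_init(X, k, rng)
    labels, dists = _assign(X, centroids)
    wcss = float(dists.sum())
    history = [wcss]
    for it in range(1, max_iter + 1):
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # repair: reseed the empty cluster with the point farthest
                # from its current centroid
                far = dists.argmax()
                centroids[j] = X[far]
                dists[far] = 0.0
        labels, dists = _assign(X, centroids)
        new_wcss = float(dists.sum())
        history.append(new_wcss)
        if wcss > 0 and (wcss - new_wcss) / wcss < tol:
            wcss = new_wcss
            break
        wcss = new_wcss
    return labels, centroids, wcss, len(history) - 1, history


def kmeans(
    profiles: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
) -> KmeansResult:
    """Cluster rows of ``profiles`` by squared-Euclidean K-means.

    Deterministic given ``seed``.  Rows must be complete (pre-filter
    absent values with :func:`stressdiel.expression.filter_missing`).
    Tiny problems are solved to the exact global optimum by
    enumeration; larger ones by ``n_init`` restarted Lloyd runs.
    """
    if isinstance(profiles, pd.DataFrame):
        row_ids = profiles.index
        X = profiles.to_numpy(dtype=float)
    else:
        row_ids = None
        X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValidationError("profiles must be 2-D (rows x features)")
    if np.isnan(X).any():
        raise ValidationError("profiles contain absent values; filter first")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n_rows ({n}), got {k}")

    if k**n <= _EXACT_ENUMERATION_LIMIT:
        labels, centroids, wcss = _exact_small(X, k)
        n_iter, history = 0, [wcss]
    else:
        rng = np.random.default_rng(seed)
        best: tuple | None = None
        for _ in range(max(1, n_init)):
            labels, centroids, wcss, n_iter, history = _lloyd(
                X, k, rng, max_iter, tol
            )
            if best is None or wcss < best[2] - 1e-12:
                best = (labels, centroids, wcss, n_iter, history)
        labels, centroids, wcss, n_iter, history = best

    # final centroids are exact member means (repair may have left stale rows)
    for j in range(k):
        members = labels == j
        if members.any():
            centroids[j] = X[members].mean(axis=0)
    return KmeansResult(
        k=k,
        assignments=labels,
        centroids=centroids,
        wcss=wcss,
        n_iter=n_iter,
        seed=seed,
        wcss_history=np.asarray(history),
        row_ids=row_ids,
    )


def pearson_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between gene profiles; optional K-means input space.

    Standardizing each row and clustering with squared Euclidean distance
    is equivalent (up to a factor) to clustering by Pearson distance, so
    this helper returns the standardized rows rather than an n x n matrix.
    """
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValidationError("constant profiles have no Pearson distance")
    return pd.DataFrame((X - mu) / sd, index=profiles.index, columns=profiles.columns)


def label_clusters(
    kmeans_result: KmeansResult,
    fold_changes: FoldChangeProfile,
    up_threshold: float = 1.0,
    down_threshold: float = 1.0,
    stress_type: str = "drought",
) -> pd.DataFrame:
    """Label every gene by its cluster's mean log2FC over drought pairs.

    Returns a table with gene_id, drought_class, source_cluster and the
    cluster mean drought log2FC the label derives from.
    """
    if up_threshold <= 0 or down_threshold <= 0:
        raise ValueError("thresholds must be positive")
    pair_cols = fold_changes.pair_meta.loc[
        fold_changes.pair_meta["stress_type"] == stress_type, "pair_id"
    ]
    if pair_cols.empty:
        raise ValueError(f"fold-change profile has no {stress_type!r} pairs")
    if kmeans_result.row_ids is None:
        raise ValidationError("kmeans_result lacks gene ids; cluster a DataFrame")

    drought_fc = fold_changes.log2fc.loc[kmeans_result.row_ids, pair_cols]
    assignments = kmeans_result.assignments_series()
    cluster_means = drought_fc.mean(axis=1).groupby(assignments).mean()

    def classify(mean_fc: float) -> str:
        if mean_fc >= up_threshold:
            return "up"
        if mean_fc <= -down_threshold:
            return "down"
        return "none"

    cluster_class = cluster_means.map(classify)
    return pd.DataFrame(
        {
            "gene_id": kmeans_result.row_ids,
            "drought_class": assignments.map(cluster_class).to_numpy(),
            "source_cluster": assignments.to_numpy(),
            "cluster_mean_drought_log2fc": assignments.map(cluster_means).to_numpy(),
        }
    )


def response_counts(labels: pd.DataFrame) -> dict[str, int]:
    """Exact counts of up / down / unresponsive genes."""
    counts = labels["drought_class"].value_counts() if len(labels) else pd.Series(dtype=int)
    return {
        "n_up": int(counts.get("up", 0)),
        "n_down": int(counts.get("down", 0)),
        "n_none": int(counts.get("none", 0)),
    }
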