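"""Sub-group (sub-species) structure detection.

Genomes are clustered hierarchically on a numeric feature matrix —
gene-cluster frequencies, or the rows of a symmetrized ANI similarity
matrix — with Euclidean distance and Ward's minimum-variance linkage.
The number of sub-groups is chosen with the gap statistic of
Tibshirani, Walther & Hastie: Gap(k) compares the log pooled
within-cluster dispersion of the data with its expectation under a
uniform reference distribution over the observed per-feature range, and
the optimal k is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.
The elbow-style within-cluster sum-of-squares curve is provided as a
complementary diagnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


def _as_features(features) -> tuple[np.ndarray, list]:
    if isinstance(features, pd.DataFrame):
        mat = features.to_numpy(dtype=float)
        index = list(features.index)
    else:
        mat = np.asarray(features, dtype=float)
        index = list(range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("feature matrix must be 2-D with at least 2 rows")
    if np.any(np.isnan(mat)):
        raise ValueError("feature matrix must not contain missing values")
    return mat, index


def ward_cluster(features, k: int) -> pd.Series:
    """Agglomerative Ward clustering into ``k`` groups.

    Returns integer cluster labels (1..k) indexed like the input rows.
    Deterministic for a given row order; scipy resolves equal merge
    costs by observation index.
    """
    mat, index = _as_features(features)
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    tree = linkage(mat, method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=index, name="cluster")


def within_cluster_ss(mat: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to cluster centroids."""
    total = 0.0
    for lab in np.unique(labels):
        block = mat[labels == lab]
        total += float(np.sum((block - block.mean(axis=0)) ** 2))
    return total


def wss_curve(features, k_max: int) -> pd.DataFrame:
    """Within-cluster sum of squares for k = 1..k_max (Ward labels).

    W_k is non-increasing in k and reaches 0 at k = #rows.
    """
    mat, _ = _as_features(features)
    n = mat.shape[0]
    if not 1 <= k_max <= n:
        raise ValueError(f"k_max must be in [1, {n}]")
    rows = []
    for k in range(1, k_max + 1):
        labels = ward_cluster(mat, k).to_numpy()
        rows.append({"k": k, "wss": within_cluster_ss(mat, labels)})
    return pd.DataFrame(rows)


def gap_statistic_k(
    features,
    k_max: int,
    n_reference: int = 100,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Optimal cluster count by the gap statistic.

    Gap(k) = mean_B[log W*_kb] - log W_k over ``n_reference`` uniform
    reference datasets drawn over the observed per-feature range, with
    s_k the reference standard deviation scaled by sqrt(1 + 1/B).
    Returns (optimal k, curve) where the curve has one row per k with
    columns ``k, gap, sk, log_wk``.  Optimal k is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}, falling back to k_max when no k
    satisfies the rule.
    """
    mat, _ = _as_features(features)
    n = mat.shape[0]
    if not 1 <= k_max < n:
        raise ValueError(f"k_max must be in [1, {n - 1}]")
    if n_reference < 10:
        raise ValueError("need at least 10 reference datasets")
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    if np.all(hi - lo == 0):
        raise ValueError("degenerate features: zero range in every dimension")
    rng = np.random.default_rng(seed)
    log_wk = np.empty(k_max)
    for k in range(1, k_max + 1):
        labels = ward_cluster(mat, k).to_numpy()
        log_wk[k - 1] = np.log(max(within_cluster_ss(mat, labels), 1e-300))
    log_wk_ref = np.empty((n_reference, k_max))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=mat.shape)
        for k in range(1, k_max + 1):
            labels = ward_cluster(ref, k).to_numpy()
            log_wk_ref[b, k - 1] = np.log(max(within_cluster_ss(ref, labels), 1e-300))
    gap = log_wk_ref.mean(axis=0) - log_wk
    sk = log_wk_ref.std(axis=0, ddof=0) * np.sqrt(1 + 1 / n_reference)
    optimal = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - sk[k]:
            optimal = k
            break
    curve = pd.DataFrame({"k": np.arange(1, k_max + 1), "gap": gap, "sk": sk, "log_wk": log_wk})
    return optimal, curve
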