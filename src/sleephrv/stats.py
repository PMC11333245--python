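"""Feature assembly, PCA and group separability.

The per-record feature vector stacks the nine quarter-wise HRV indices
over the four sleep quarters (36 features). Columns are centred and
variance-normalized (PCA on the correlation matrix), the covariance
eigenproblem is solved, and the leading scores are used to assess how
well the pregnancy groups separate. Simple nonparametric two-group
comparisons (rank-sum for location, Brown-Forsythe for spread) round
out the statistical surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "build_feature_matrix",
    "pca",
    "separability_report",
    "group_compare",
    "flag_outliers",
]


@dataclass
class FeatureMatrix:
    """Records x features table with group labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    record_ids: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue order
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str] | None = None


def build_feature_matrix(indices_df: pd.DataFrame, features: list[str] | None = None) -> FeatureMatrix:
    """Pivot a tidy per-(record, quarter) index table into records x features.

    Expects columns ``record_id``, ``group``, ``quarter`` plus index
    columns; produces one feature per (index, quarter) pair. Records
    with any missing value are dropped.
    """
    index_cols = [c for c in indices_df.columns if c not in ("record_id", "group", "quarter")]
    if features is not None:
        index_cols = [c for c in index_cols if c in features]
    wide = indices_df.pivot_table(
        index="record_id", columns="quarter", values=index_cols, aggfunc="first"
    )
    wide.columns = [f"{idx}_{q}" for idx, q in wide.columns]
    wide = wide.dropna(axis=0)
    groups = indices_df.drop_duplicates("record_id").set_index("record_id")["group"]
    labels = groups.loc[wide.index].to_numpy()
    return FeatureMatrix(
        X=wide.to_numpy(),
        labels=labels,
        feature_names=list(wide.columns),
        record_ids=list(wide.index),
    )


def pca(X, k: int | None = None, scale: bool = True, feature_names=None) -> PCAResult:
    """Principal component analysis via the covariance eigenproblem.

    Columns are mean-centred and (by default) variance-normalized; the
    sample covariance ``S = Xc^T Xc / (n - 1)`` is eigendecomposed,
    eigenpairs are sorted by descending eigenvalue, and scores are the
    projections of the centred data on the leading ``k`` eigenvectors.
    Sign convention: each eigenvector's largest-magnitude element is
    positive. ``k`` beyond the matrix rank is rejected.
    """
    if isinstance(X, FeatureMatrix):
        feature_names = X.feature_names
        X = X.X
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k is None:
        k = p
    if not (n > k >= 1):
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = Xc.std(axis=0, ddof=1)
    if scale:
        if np.any(sd == 0):
            raise ValueError("constant feature column cannot be variance-normalized")
        Xc = Xc / sd
    else:
        sd = np.ones(p)
    cov = Xc.T @ Xc / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    rank = int(np.sum(eigval > max(eigval[0], 1e-300) * 1e-10))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the centred data")
    for j in range(p):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = Xc @ eigvec[:, :k]
    evr = eigval / eigval.sum() if eigval.sum() > 0 else eigval
    return PCAResult(
        eigenvalues=eigval,
        eigenvectors=eigvec,
        scores=scores,
        explained_variance_ratio=evr,
        mean=mean,
        scale=sd,
        feature_names=feature_names,
    )


def _silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (hand-rolled, Euclidean)."""
    D = cdist(coords, coords)
    vals = []
    for i in range(coords.shape[0]):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            vals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == g].mean() for g in np.unique(labels) if g != labels[i]
        )
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


def _loo_nearest_centroid(coords: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out nearest-centroid classification accuracy."""
    groups = np.unique(labels)
    correct = 0
    for i in range(coords.shape[0]):
        best, best_d = None, np.inf
        for g in groups:
            member = (labels == g)
            member[i] = False
            if not member.any():
                continue
            d = np.linalg.norm(coords[member].mean(axis=0) - coords[i])
            if d < best_d:
                best, best_d = g, d
        correct += best == labels[i]
    return correct / coords.shape[0]


def separability_report(coords, labels, record_ids=None) -> dict:
    """Group-separability summary in a (typically 3-D) feature space.

    Reports pairwise centroid distances, a silhouette-style separation
    score and leave-one-out nearest-centroid accuracy, plus the scatter
    coordinates for plotting. Degenerate groups (fewer than 3 records)
    are reported, not fatal.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    if len(groups) < 2:
        raise ValueError("separability needs at least two groups")
    degenerate = [str(g) for g in groups if np.sum(labels == g) < 3]
    centroids = {str(g): coords[labels == g].mean(axis=0) for g in groups}
    dists = {
        f"{gi}|{gj}": float(np.linalg.norm(centroids[str(gi)] - centroids[str(gj)]))
        for a, gi in enumerate(groups)
        for gj in groups[a + 1:]
    }
    scatter = pd.DataFrame(
        coords, columns=[f"coord{j + 1}" for j in range(coords.shape[1])]
    )
    scatter.insert(0, "record", record_ids if record_ids is not None else np.arange(len(labels)))
    scatter["group"] = labels
    return {
        "centroid_distances": dists,
        "silhouette": _silhouette(coords, labels),
        "nearest_centroid_accuracy": _loo_nearest_centroid(coords, labels),
        "degenerate_groups": degenerate,
        "scatter": scatter,
    }


def group_compare(values, labels) -> dict:
    """Two-group location and spread comparison.

    Mann-Whitney rank-sum (exact for small samples without ties,
    normal approximation otherwise) and the Brown-Forsythe statistic
    (Levene's test on deviations from group medians). A constant
    feature leaves the spread test undefined and is flagged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("group_compare expects exactly two groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    u = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    out = {
        "rank_sum_stat": float(u.statistic),
        "rank_sum_p": float(u.pvalue),
        "brown_forsythe_stat": float("nan"),
        "brown_forsythe_p": float("nan"),
        "spread_test_defined": True,
    }
    if np.ptp(values) == 0:
        out["spread_test_defined"] = False
        return out
    bf = sstats.levene(a, b, center="median")
    out["brown_forsythe_stat"] = float(bf.statistic)
    out["brown_forsythe_p"] = float(bf.pvalue)
    return out


def flag_outliers(values, labels=None) -> np.ndarray:
    """Boxplot-rule outliers, at most one flagged per group.

    A point is an outlier candidate when it falls outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` of its group; only the single most
    distant candidate per group is flagged.
    """
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.zeros(values.size, dtype=int)
    labels = np.asarray(labels)
    flags = np.zeros(values.size, dtype=bool)
    for g in np.unique(labels):
        member = labels == g
        v = values[member]
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        dist = np.where(v < lo, lo - v, np.where(v > hi, v - hi, 0.0))
        if np.any(dist > 0):
            idx = np.flatnonzero(member)[np.argmax(dist)]
            flags[idx] = True
    return flags
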