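"""Cluster-validity metrics: homogeneity, silhouette and the Rand index.

Homogeneity (H_ave) measures tightness as the average distance of each point
to its cluster centre — the medoid in a k-medoid context, optionally the
mean centroid for partitions produced by other methods.  Values below 2 are
read as good tightness, above 3 as poor.

Separation and structure are measured by the average silhouette width
s(i) = (b - a) / max(a, b), with the usual reading: averages above 0.5
indicate strong structure, 0.25-0.5 reasonable structure, below 0.25 no
substantial structure.  Singleton clusters score 0 by Rousseeuw's convention.

Agreement between two partitions is the (plain) Rand index — the fraction of
point pairs co-clustered in both or separated in both.  Because the plain
index drifts towards 1 as cluster counts grow, the chance-corrected adjusted
Rand index is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, rand_score, silhouette_samples

from .pam_cluster import ClusterResult

__all__ = [
    "EvaluationReport",
    "homogeneity",
    "silhouette",
    "rand_index",
    "evaluate",
    "homogeneity_band",
    "silhouette_band",
]


def homogeneity_band(h: float) -> str:
    """Qualitative reading of an H_ave value (lower = tighter)."""
    if h < 2.0:
        return "good"
    if h > 3.0:
        return "poor"
    return "intermediate"


def silhouette_band(s: float) -> str:
    """Qualitative reading of an average silhouette width."""
    if s > 0.5:
        return "strong"
    if s >= 0.25:
        return "reasonable"
    return "none"


@dataclass
class EvaluationReport:
    """Within-method validity summary of one partition."""

    cardinalities: np.ndarray
    per_cluster_homogeneity: np.ndarray
    average_homogeneity: float
    per_cluster_silhouette: np.ndarray
    average_silhouette: float
    homogeneity_quality: str
    silhouette_quality: str

    def to_dict(self) -> dict:
        return {
            "cardinalities": self.cardinalities.tolist(),
            "per_cluster_homogeneity": [round(h, 6) for h in self.per_cluster_homogeneity],
            "average_homogeneity": round(self.average_homogeneity, 6),
            "per_cluster_silhouette": [round(s, 6) for s in self.per_cluster_silhouette],
            "average_silhouette": round(self.average_silhouette, 6),
            "homogeneity_quality": self.homogeneity_quality,
            "silhouette_quality": self.silhouette_quality,
        }


def _centers(
    X: np.ndarray, labels: np.ndarray, result: ClusterResult | None, center: str
) -> np.ndarray:
    ks = np.unique(labels)
    if center == "medoid":
        if result is None:
            raise ValueError("medoid centres require a ClusterResult")
        return X[result.medoids]
    if center == "mean":
        return np.vstack([X[labels == j].mean(axis=0) for j in ks])
    raise ValueError(f"unknown center {center!r}")


def homogeneity(
    X: np.ndarray,
    result: ClusterResult | np.ndarray,
    center: str = "medoid",
) -> tuple[np.ndarray, float]:
    """Per-cluster and overall average distance to the cluster centre.

    The overall value averages over *all* points (not over cluster means), so
    large clusters weigh in proportionally.  Accepts either a
    :class:`ClusterResult` (medoid centres) or a bare label vector, in which
    case mean centroids are used.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(result, ClusterResult):
        labels = result.assignment
    else:
        labels = np.asarray(result)
        result = None
        center = "mean"
    centers = _centers(X, labels, result, center)
    ks = np.unique(labels)
    d = np.empty(X.shape[0])
    per_cluster = np.empty(ks.size)
    for idx, j in enumerate(ks):
        members = labels == j
        dj = np.linalg.norm(X[members] - centers[idx], axis=1)
        d[members] = dj
        per_cluster[idx] = dj.mean()
    return per_cluster, float(d.mean())


def silhouette(
    X: np.ndarray, result: ClusterResult | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Silhouette widths s(i) under Euclidean distance.

    Returns (per-gene values, per-cluster averages, overall average).
    Requires at least two non-empty clusters; members of singleton clusters
    score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = result.assignment if isinstance(result, ClusterResult) else np.asarray(result)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    s = silhouette_samples(X, labels, metric="euclidean")
    per_cluster = np.array([s[labels == j].mean() for j in ks])
    return s, per_cluster, float(s.mean())


def rand_index(
    partition_a: np.ndarray, partition_b: np.ndarray, adjusted: bool = False
) -> float:
    """Pairwise-agreement Rand index between two partitions of one gene set.

    1 means identical partitions (up to relabelling), 0 total disagreement.
    ``adjusted=True`` returns the chance-corrected adjusted Rand index.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same gene set")
    if adjusted:
        return float(adjusted_rand_score(a, b))
    return float(rand_score(a, b))


def evaluate(
    X: np.ndarray, result: ClusterResult | np.ndarray, center: str = "medoid"
) -> EvaluationReport:
    """Full within-method report: cardinalities, homogeneity, silhouette."""
    labels = result.assignment if isinstance(result, ClusterResult) else np.asarray(result)
    ks = np.unique(labels)
    cardinalities = np.array([(labels == j).sum() for j in ks])
    per_h, h_ave = homogeneity(X, result, center=center)
    _, per_s, s_ave = silhouette(X, result)
    return EvaluationReport(
        cardinalities=cardinalities,
        per_cluster_homogeneity=per_h,
        average_homogeneity=h_ave,
        per_cluster_silhouette=per_s,
        average_silhouette=s_ave,
        homogeneity_quality=homogeneity_band(h_ave),
        silhouette_quality=silhouette_band(s_ave),
    )
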