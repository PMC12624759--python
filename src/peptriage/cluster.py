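"""Ensemble clustering of trajectory frames with quality metrics.

Frames are superposed once onto the first frame on the chosen selection
and the selection coordinates flattened into feature vectors, so that
Euclidean feature distance equals sqrt(n_sel) × selection RMSD (the
single-reference fit is the usual trajectory-clustering convention and
an approximation to true pairwise-fit RMSD). K-means and average-linkage
hierarchical clustering produce partitions that are scored with the
Davies–Bouldin index, the pseudo-F (Calinski–Harabasz) statistic, and
the explained-variance fraction R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .core_io import SelectionError, Trajectory, superpose
from .trajmetrics import _indices


@dataclass
class ClusteringResult:
    labels: np.ndarray              # cluster id per frame, 0-based
    k: int
    representatives: list[int]      # frame index nearest each centroid
    metrics: dict                   # {"DBI": ..., "psF": ..., "R2": ...}


def frame_features(traj: Trajectory, selection) -> np.ndarray:
    """Per-frame flattened selection coordinates after fitting to frame 0."""
    idx = _indices(selection)
    if len(idx) == 0:
        raise SelectionError("empty selection for clustering features")
    ref = traj.frames[0]
    feats = np.empty((traj.n_frames, 3 * len(idx)))
    for k, frame in enumerate(traj.frames):
        _, _, fitted = superpose(frame, ref, idx)
        feats[k] = fitted[idx].ravel()
    return feats


def _representatives(features: np.ndarray, labels: np.ndarray) -> list[int]:
    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        centroid = features[members].mean(axis=0)
        d = np.linalg.norm(features[members] - centroid, axis=1)
        reps.append(int(members[np.argmin(d)]))
    return reps


def cluster_metrics(features: np.ndarray, labels: np.ndarray) -> dict:
    """DBI (lower better), pseudo-F (higher better), and R² for a partition.

    DBI uses the mean intra-cluster distance-to-centroid as the scatter
    s_i and centroid separation as d_ij; psF is the Calinski–Harabasz
    ratio [(SST − SSE)/(k − 1)] / [SSE/(n − k)]; R² = 1 − SSE/SST.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(features)
    uniq = np.unique(labels)
    k = len(uniq)
    grand = features.mean(axis=0)
    sst = float(((features - grand) ** 2).sum())
    centroids = {}
    sse = 0.0
    for lab in uniq:
        members = features[labels == lab]
        c = members.mean(axis=0)
        centroids[lab] = c
        sse += float(((members - c) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    metrics = {"R2": r2, "DBI": None, "psF": None}
    if k >= 2:
        scatter = {
            lab: float(
                np.linalg.norm(features[labels == lab] - centroids[lab], axis=1).mean()
            )
            for lab in uniq
        }
        ratios = []
        for i in uniq:
            worst = max(
                (scatter[i] + scatter[j]) / np.linalg.norm(centroids[i] - centroids[j])
                for j in uniq
                if j != i
            )
            ratios.append(worst)
        metrics["DBI"] = float(np.mean(ratios))
        if n > k and sse > 0:
            metrics["psF"] = float(((sst - sse) / (k - 1)) / (sse / (n - k)))
        else:
            metrics["psF"] = float("inf")
    return metrics


def kmeans_cluster(
    features: np.ndarray,
    k: int = 10,
    n_init: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """K-means (k-means++ starts, best of ``n_init`` runs, seeded)."""
    features = np.asarray(features, dtype=float)
    if k > len(features):
        raise ValueError(f"k={k} exceeds n_frames={len(features)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    labels = km.fit_predict(features)
    return ClusteringResult(
        labels=labels,
        k=k,
        representatives=_representatives(features, labels),
        metrics=cluster_metrics(features, labels),
    )


def hierarchical_cluster(
    features: np.ndarray,
    rmsd_cutoff: float = 2.5,
    n_fit_atoms: int | None = None,
) -> ClusteringResult:
    """Average-linkage agglomerative clustering cut at an RMSD threshold.

    Distances between frames are selection RMSDs (feature distance /
    sqrt(n_fit_atoms)); the tree is cut where the average-linkage merge
    distance exceeds ``rmsd_cutoff``. ``n_fit_atoms`` defaults to
    n_features / 3.
    """
    features = np.asarray(features, dtype=float)
    if len(features) < 2:
        raise ValueError("need at least 2 frames")
    n_sel = n_fit_atoms if n_fit_atoms is not None else features.shape[1] // 3
    dists = pdist(features) / np.sqrt(n_sel)
    Z = linkage(dists, method="average")
    labels = fcluster(Z, t=rmsd_cutoff, criterion="distance") - 1
    return ClusteringResult(
        labels=labels,
        k=len(np.unique(labels)),
        representatives=_representatives(features, labels),
        metrics=cluster_metrics(features, labels),
    )


def most_populated_cluster(result: ClusteringResult) -> int:
    """Cluster id with the most frames; ties go to the lowest id."""
    ids, counts = np.unique(result.labels, return_counts=True)
    return int(ids[np.argmax(counts)])
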