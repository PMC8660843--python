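"""Conformational-state clustering in dPCA space, representative-frame
selection by farthest point sampling, and residue-importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, fcluster
from scipy.spatial.distance import cdist

from .dpca import DihedralFeatureMatrix, Projection, circular_embed

__all__ = [
    "ClusterModel",
    "ResidueImportance",
    "hierarchical_cluster",
    "farthest_point_sample",
    "residue_importance",
]


@dataclass
class ClusterModel:
    """Frame -> cluster assignment; ids contiguous from 0, ordered by size."""

    labels: np.ndarray
    linkage_method: str
    metric: str
    n_clusters: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class ResidueImportance:
    """Per-feature discrimination scores and the ranked per-residue table."""

    feature_scores: np.ndarray
    feature_labels: tuple[tuple[int, str], ...]
    table: pd.DataFrame  # columns residue, score, rank

    def top_residues(self, k: int) -> list[int]:
        return self.table["residue"].head(k).tolist()


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters by descending size; ties broken by first occurrence."""
    uniq, counts = np.unique(raw, return_counts=True)
    first_seen = np.array([np.argmax(raw == u) for u in uniq])
    order = np.lexsort((first_seen, -counts))
    mapping = {int(uniq[o]): new for new, o in enumerate(order)}
    return np.array([mapping[int(v)] for v in raw])


def hierarchical_cluster(
    projection: Projection | np.ndarray,
    n_clusters: int,
    method: str = "ward",
) -> ClusterModel:
    """Agglomerative clustering of PC scores (Ward/Euclidean by default).

    Deterministic for fixed input; labels are relabeled so cluster 0 is the
    largest.
    """
    scores = projection.scores if isinstance(projection, Projection) else np.asarray(projection)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n = len(scores)
    if n_clusters > n:
        raise ValueError("more clusters than frames")
    if n_clusters == n:
        raw = np.arange(n)
    elif n_clusters == 1:
        raw = np.zeros(n, dtype=int)
    else:
        z = scipy_linkage(scores, method=method, metric="euclidean")
        raw = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    labels = _relabel_by_size(raw)
    return ClusterModel(
        labels=labels,
        linkage_method=method,
        metric="euclidean",
        n_clusters=int(len(np.unique(labels))),
    )


def _cluster_medoid(points: np.ndarray, members: np.ndarray) -> int:
    d = cdist(points[members], points[members])
    return int(members[np.argmin(d.sum(axis=1))])


def farthest_point_sample(
    projection: Projection | np.ndarray,
    labels: np.ndarray,
    k_per_cluster: int,
) -> dict[int, list[int]]:
    """Greedy max-min representative frames per cluster, seeded at the medoid.

    At each step the frame maximizing its minimum distance to the already
    selected set is added; ties break toward the lowest frame index.
    """
    scores = projection.scores if isinstance(projection, Projection) else np.asarray(projection)
    labels = np.asarray(labels, dtype=int)
    out: dict[int, list[int]] = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        if k_per_cluster > members.size:
            raise ValueError(
                f"k_per_cluster={k_per_cluster} exceeds cluster {c} size {members.size}"
            )
        selected = [_cluster_medoid(scores, members)]
        taken = members == selected[0]
        min_dist = np.linalg.norm(scores[members] - scores[selected[0]], axis=1)
        while len(selected) < k_per_cluster:
            masked = np.where(taken, -np.inf, min_dist)
            best = int(np.argmax(masked))  # argmax ties -> lowest index
            cand = int(members[best])
            selected.append(cand)
            taken[best] = True
            min_dist = np.minimum(
                min_dist, np.linalg.norm(scores[members] - scores[cand], axis=1)
            )
        out[int(c)] = selected
    return out


def residue_importance(
    features: DihedralFeatureMatrix,
    labels: np.ndarray,
) -> ResidueImportance:
    """Rank residues by how strongly their dihedrals discriminate clusters.

    Each feature's score is an F-like between/within variance ratio
    computed on its (cos, sin) embedding: between-cluster scatter of the
    per-cluster mean vectors over within-cluster scatter, with mean-square
    normalization.  A feature with zero within-cluster scatter but nonzero
    separation dominates the ranking (the denominator is guarded by a tiny
    epsilon so scores stay finite).  A residue's score is the max over its
    features; ranking ties break toward the lower residue number.
    """
    labels = np.asarray(labels, dtype=int)
    if features.n_frames != len(labels):
        raise ValueError("labels must have one entry per frame")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if np.any(counts < 2):
        raise ValueError("every cluster needs at least 2 frames")
    emb = circular_embed(features)  # (n, 2D) interleaved
    n, k = len(labels), len(uniq)
    d = features.angles.shape[1]
    grand = emb.mean(axis=0)
    between = np.zeros(2 * d)
    within = np.zeros(2 * d)
    for c, nc in zip(uniq, counts):
        sub = emb[labels == c]
        mc = sub.mean(axis=0)
        between += nc * (mc - grand) ** 2
        within += ((sub - mc) ** 2).sum(axis=0)
    # pair cos/sin columns back into one score per dihedral
    between_f = between[0::2] + between[1::2]
    within_f = within[0::2] + within[1::2]
    total = between_f + within_f
    eps = 1e-12 * np.maximum(total, 1.0)
    scores = (between_f / (k - 1)) / (within_f / (n - k) + eps)

    residues = features.residues
    table = (
        pd.DataFrame({"residue": residues, "score": scores})
        .groupby("residue", sort=True)["score"]
        .max()
        .reset_index()
        .sort_values(["score", "residue"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ResidueImportance(
        feature_scores=scores,
        feature_labels=features.labels,
        table=table,
    )
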