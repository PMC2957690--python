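"""Average-linkage clustering of IDD compositions and cross-set cluster matching.

Sequences are clustered by UPGMA (average linkage) on the composition
pseudo-distance ``1 - Sim`` and the dendrogram is cut at a fixed height
(default 0.15), so the average pairwise distance within any cluster stays at
or below the cutoff. A cluster is summarized by the per-residue mean and
population standard deviation of its members' compositions; two clusters are
compared with the same Gaussian score, with the squared width per residue set
to the summed variances (falling back to the pairwise width for residues with
zero variance, which makes singleton-vs-singleton comparison coincide with
the plain pairwise score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .composition import DEFAULT_WIDTH, frequency_matrix, similarity_from_matrix


@dataclass(frozen=True)
class ClusterProfile:
    cluster_id: int
    member_ids: list[str]
    mean: np.ndarray  # per-residue mean composition, sums to 1
    std: np.ndarray  # per-residue population standard deviation

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ClusterMatch:
    cluster_a: int
    cluster_b: int
    score: float


def _profiles_from_labels(
    ids: list[str], F: np.ndarray, labels: np.ndarray
) -> list[ClusterProfile]:
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    # order clusters by decreasing size, ties by first-member input position
    ordered = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))
    out = []
    for cid, idx in enumerate(ordered):
        sub = F[idx]
        out.append(
            ClusterProfile(
                cluster_id=cid,
                member_ids=[ids[i] for i in idx],
                mean=sub.mean(axis=0),
                std=sub.std(axis=0),  # population std: singletons get 0
            )
        )
    return out


def cluster(
    seqs: Sequence, cutoff: float = 0.15, w: float = DEFAULT_WIDTH
) -> list[ClusterProfile]:
    """UPGMA-cluster sequences on the composition distance, cut at ``cutoff``.

    Every sequence lands in exactly one cluster; cluster ids are assigned by
    decreasing size, ties broken by first-member input order.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids, F = frequency_matrix(seqs)
    if len(seqs) == 1:
        return _profiles_from_labels(ids, F, np.array([0]))
    dist = 1.0 - similarity_from_matrix(F, w=w)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    return _profiles_from_labels(ids, F, labels)


def cluster_similarity(
    ca: ClusterProfile, cb: ClusterProfile, fallback_w: float = DEFAULT_WIDTH
) -> float:
    """Gaussian similarity between two cluster profiles.

    Per residue the squared Gaussian width is ``std_a^2 + std_b^2``; residues
    where both clusters have zero variance use ``fallback_w^2`` instead, so
    the score is defined for singleton clusters and equals the pairwise score
    in that limit.
    """
    ma, mb = ca.mean, cb.mean
    w2 = ca.std**2 + cb.std**2
    w2 = np.where(w2 > 0, w2, fallback_w**2)
    weight = ma + mb
    num = float((weight * np.exp(-((ma - mb) ** 2) / w2)).sum())
    return num / float(weight.sum())


def match_clusters(
    set_a: Sequence[ClusterProfile],
    set_b: Sequence[ClusterProfile],
    fallback_w: float = DEFAULT_WIDTH,
) -> list[ClusterMatch]:
    """Pair every set-A cluster with its most similar set-B cluster.

    Matching is an independent argmax per A cluster (many-to-one allowed:
    several A clusters may share a B partner). Ties break to the lowest
    set-B cluster id.
    """
    if not set_a or not set_b:
        raise ValueError("both cluster sets must be non-empty")
    out = []
    b_sorted = sorted(set_b, key=lambda c: c.cluster_id)
    for ca in set_a:
        best = max(
            b_sorted,
            key=lambda cb: (cluster_similarity(ca, cb, fallback_w), -cb.cluster_id),
        )
        out.append(
            ClusterMatch(
                cluster_a=ca.cluster_id,
                cluster_b=best.cluster_id,
                score=cluster_similarity(ca, best, fallback_w),
            )
        )
    return out


def cutoff_scan(
    seqs: Sequence, cutoffs: Sequence[float], w: float = DEFAULT_WIDTH
) -> pd.DataFrame:
    """Number of clusters as a function of the cutoff (non-increasing)."""
    rows = [
        {"cutoff": float(c), "n_clusters": len(cluster(seqs, cutoff=c, w=w))}
        for c in cutoffs
    ]
    return pd.DataFrame(rows)
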