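"""K-means co-expression clustering of upregulated non-TF genes.

Profiles are the raw log2-ratio vectors over the chilling time points;
distance is Euclidean by default (Pearson distance by flag).  The fit is
plain Lloyd iteration with k-means++ seeding, the best of ``n_restarts``
restarts by within-cluster sum of squares, and farthest-point re-seeding of
clusters that empty out; the within-cluster SSE is asserted non-increasing
across iterations.  Each cluster carries a binary consensus profile
(centroid thresholded at the induction cutoff), the phase of its earliest
consensus induction, and the fraction of members also responsive to H2O2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from chillregnet.expression_calls import CallConfig, assign_phase

__all__ = [
    "ExpressionCluster",
    "kmeans_cluster",
    "consensus_profile",
    "cluster_phase",
    "h2o2_fraction",
    "clusters_to_frames",
]


@dataclass
class ExpressionCluster:
    cluster_id: str
    members: list
    centroid: np.ndarray
    timepoints: tuple
    consensus: np.ndarray = field(default=None)
    degenerate: bool = False
    phase: int | None = None
    h2o2_fraction: float = 0.0
    tightness: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")


def _pearson_space(x: np.ndarray) -> np.ndarray:
    """Standardize rows so Euclidean distance is monotone in 1 - r."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _kmeanspp(x, k, rng):
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = cdist(x, np.asarray(centers)).min(axis=1) ** 2
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _lloyd(x, k, rng, max_iter):
    centers = _kmeanspp(x, k, rng)
    prev_sse = np.inf
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = cdist(x, centers)
        labels = d.argmin(axis=1)
        sse = float((d[np.arange(len(x)), labels] ** 2).sum())
        assert sse <= prev_sse + 1e-8 * max(1.0, prev_sse), "SSE increased"
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean(axis=0)
            else:  # re-seed an emptied cluster from the farthest point
                far = (d[np.arange(len(x)), labels]).argmax()
                centers[j] = x[far]
        d = cdist(x, centers)
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all() and abs(prev_sse - sse) < 1e-12:
            break
        prev_sse = sse
    d = cdist(x, centers)
    labels = d.argmin(axis=1)
    sse = float((d[np.arange(len(x)), labels] ** 2).sum())
    return labels, centers, sse


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 8,
    distance: str = "euclidean",
    call_config: CallConfig = CallConfig(),
) -> list:
    """Cluster gene expression profiles into ``k`` groups.

    ``profiles`` is genes x chilling time points (columns are hours).
    Returns :class:`ExpressionCluster` objects labelled C01..C<k> ordered by
    consensus onset then size, deterministic for a fixed seed.
    """
    n = len(profiles)
    if not 0 < k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    timepoints = tuple(float(c) for c in profiles.columns)
    x = profiles.to_numpy(dtype=float)
    space = _pearson_space(x) if distance == "pearson" else x
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, _centers, sse = _lloyd(space, k, rng, max_iter)
        if best is None or sse < best[1]:
            best = (labels, sse)
    labels = best[0]
    clusters = []
    genes = np.asarray(profiles.index)
    for j in range(k):
        sel = labels == j
        if not sel.any():
            continue
        centroid = x[sel].mean(axis=0)
        cl = ExpressionCluster(
            cluster_id=f"tmp{j}",
            members=list(genes[sel]),
            centroid=centroid,
            timepoints=timepoints,
            tightness=float(np.linalg.norm(x[sel] - centroid, axis=1).mean()),
        )
        consensus_profile(cl, call_config)
        cluster_phase(cl, call_config)
        clusters.append(cl)
    # stable labels: order by consensus onset, then descending size
    def onset(cl):
        hot = np.nonzero(cl.consensus)[0]
        return timepoints[hot[0]] if hot.size else np.inf

    clusters.sort(key=lambda cl: (onset(cl), -len(cl.members), cl.members[0]))
    for i, cl in enumerate(clusters, start=1):
        cl.cluster_id = f"C{i:02d}"
    return clusters


def consensus_profile(
    cluster: ExpressionCluster, config: CallConfig = CallConfig()
) -> np.ndarray:
    """Binary consensus: 1 where the centroid reaches the induction
    threshold; an all-zero consensus flags the cluster degenerate."""
    consensus = (cluster.centroid >= config.up_threshold).astype(int)
    cluster.consensus = consensus
    cluster.degenerate = not consensus.any()
    return consensus


def cluster_phase(
    cluster: ExpressionCluster, config: CallConfig = CallConfig()
) -> int | None:
    """Phase of the consensus profile's earliest induced time point."""
    if cluster.consensus is None:
        consensus_profile(cluster, config)
    if cluster.degenerate:
        cluster.phase = None
        return None
    hours = [t for t, c in zip(cluster.timepoints, cluster.consensus) if c]
    cluster.phase = assign_phase(hours, config)
    return cluster.phase


def h2o2_fraction(cluster: ExpressionCluster, h2o2_set) -> float:
    """Fraction of members also in the H2O2-responsive set (stored and
    returned as a proportion; reports print it as a percentage)."""
    h2o2_set = set(h2o2_set)
    frac = sum(1 for g in cluster.members if g in h2o2_set) / len(cluster.members)
    cluster.h2o2_fraction = frac
    return frac


def clusters_to_frames(clusters):
    """(membership, summary) DataFrames for TSV output."""
    membership = pd.DataFrame(
        [(g, cl.cluster_id) for cl in clusters for g in cl.members],
        columns=["gene", "cluster"],
    )
    summary = pd.DataFrame(
        [
            {
                "cluster": cl.cluster_id,
                "size": len(cl.members),
                "phase": cl.phase if cl.phase is not None else "none",
                "h2o2_pct": round(100 * cl.h2o2_fraction, 1),
                "consensus": "".join(map(str, cl.consensus)),
                "tightness": round(cl.tightness, 4),
            }
            for cl in clusters
        ]
    )
    return membership, summary
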