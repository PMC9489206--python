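"""Face-identity clustering and the cumulative-exposure adaptation regressor.

Face observations (time-stamped 512-d embeddings) are clustered into
identities with the Chinese Whispers label-propagation algorithm on a
distance-thresholded graph.  The worst (most diffuse) cluster can be
pruned, emulating manual curation of a noise cluster.  From the surviving
identities two regressors are built:

* ``any_faces`` — per sample, the maximum detection probability of any
  face visible in that sample;
* ``log_mean_time_cum`` — the natural log of the mean (over identities
  visible in the sample) cumulative on-screen time in seconds, modeling
  adaptation (repetition suppression) to familiar faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .stimio import FaceObservation, FeatureStream, ValidationError

__all__ = [
    "IdentityAssignment",
    "cluster_faces",
    "prune_clusters",
    "adaptation_stream",
    "any_faces_stream",
]

REMOVED = -1
"""Label marking observations whose cluster was pruned."""


@dataclass
class IdentityAssignment:
    """Cluster label per observation; pruned observations carry ``REMOVED``."""

    labels: np.ndarray
    n_clusters: int
    seed: int
    removed: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        kept = self.labels[self.labels != REMOVED]
        if len(kept) and (kept.min() < 0 or kept.max() >= self.n_clusters):
            raise ValidationError("cluster ids must be contiguous from 0")


def _pairwise_distances(obs: Sequence[FaceObservation]) -> np.ndarray:
    emb = np.array([o.embedding for o in obs])
    sq = np.sum(emb**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * emb @ emb.T
    return np.sqrt(np.maximum(d2, 0.0))


def cluster_faces(
    obs: Sequence[FaceObservation],
    edge_threshold: float,
    seed: int = 0,
    iterations: int = 20,
) -> IdentityAssignment:
    """Chinese Whispers clustering of face embeddings.

    Nodes are observations; edges connect pairs with Euclidean embedding
    distance below ``edge_threshold``, weighted 1/distance.  Each node
    starts in its own cluster and, for ``iterations`` passes over the nodes
    in seeded random order, adopts the label with the largest total edge
    weight among its neighbours (ties broken toward the smallest label).
    """
    if len(obs) == 0:
        raise ValidationError("need at least one observation")
    if edge_threshold <= 0:
        raise ValidationError("edge_threshold must be > 0")
    n = len(obs)
    dist = _pairwise_distances(obs)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.triu_indices(n, k=1)
    close = dist[ii, jj] < edge_threshold
    for i, j in zip(ii[close], jj[close]):
        d = dist[i, j]
        g.add_edge(int(i), int(j), weight=1.0 / max(d, 1e-12))

    labels = np.arange(n)
    rng = np.random.default_rng(seed)
    order = np.arange(n)
    for _ in range(iterations):
        rng.shuffle(order)
        changed = False
        for node in order:
            if g.degree(node) == 0:
                continue
            weight_by_label: dict[int, float] = {}
            for nbr in g.neighbors(node):
                lab = labels[nbr]
                weight_by_label[lab] = weight_by_label.get(lab, 0.0) + g[node][nbr]["weight"]
            best = min(
                weight_by_label, key=lambda lab: (-weight_by_label[lab], lab)
            )
            if best != labels[node]:
                labels[node] = best
                changed = True
        if not changed:
            break

    # relabel to contiguous ids ordered by first occurrence
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return IdentityAssignment(labels=out, n_clusters=len(remap), seed=seed)


def _cluster_dispersion(dist: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise embedding distance within a cluster (0 for singletons)."""
    if len(members) < 2:
        return 0.0
    sub = dist[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def prune_clusters(
    assign: IdentityAssignment, obs: Sequence[FaceObservation]
) -> IdentityAssignment:
    """Remove the most diffuse cluster (largest mean within-cluster distance).

    Mirrors the manual step of dropping the one noisy catch-all cluster.
    The sole cluster of a single-cluster assignment is never removed; ties
    in dispersion remove the lowest cluster id.  Surviving clusters are
    relabeled contiguously from 0.
    """
    if assign.n_clusters < 1:
        raise ValidationError("assignment has no clusters")
    if assign.n_clusters == 1:
        return IdentityAssignment(
            labels=assign.labels.copy(), n_clusters=1, seed=assign.seed, removed=[]
        )
    dist = _pairwise_distances(obs)
    dispersions = np.array(
        [
            _cluster_dispersion(dist, np.flatnonzero(assign.labels == c))
            for c in range(assign.n_clusters)
        ]
    )
    worst = int(np.argmax(dispersions))  # argmax takes the lowest index on ties
    labels = assign.labels.copy()
    labels[labels == worst] = REMOVED
    keep = [c for c in range(assign.n_clusters) if c != worst]
    remap = {c: i for i, c in enumerate(keep)}
    for old, new in remap.items():
        labels[assign.labels == old] = new
    return IdentityAssignment(
        labels=labels, n_clusters=len(keep), seed=assign.seed, removed=[worst]
    )


def _sample_bins(
    obs: Sequence[FaceObservation], rate: float, duration: float
) -> tuple[int, np.ndarray]:
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    n = int(round(duration * rate))
    bins = np.array([int(o.time * rate) for o in obs], dtype=int)
    if len(bins) and (bins.min() < 0 or (len(bins) and bins.max() >= n)):
        raise ValidationError("observation time outside [0, duration)")
    return n, bins


def adaptation_stream(
    assign: IdentityAssignment,
    obs: Sequence[FaceObservation],
    rate: float,
    duration: float,
) -> FeatureStream:
    """Cumulative-exposure ('log_mean_time_cum') adaptation regressor.

    Per output sample: for every non-removed identity visible in that
    sample, its cumulative on-screen time in seconds up to and including
    the sample; the cumulative times of co-visible identities are averaged
    and the natural log emitted.  Samples with no visible face emit 0.
    """
    n, bins = _sample_bins(obs, rate, duration)
    # presence[i, k]: identity i visible in sample k
    presence = np.zeros((assign.n_clusters, n), dtype=bool)
    for lab, b in zip(assign.labels, bins):
        if lab != REMOVED:
            presence[lab, b] = True
    cum_time = np.cumsum(presence, axis=1) / rate  # seconds, includes current sample
    values = np.zeros(n)
    n_visible = presence.sum(axis=0)
    visible_any = n_visible > 0
    mean_cum = np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cum[visible_any] = (
            np.where(presence, cum_time, 0.0).sum(axis=0)[visible_any]
            / n_visible[visible_any]
        )
        values[visible_any] = np.log(mean_cum[visible_any])
    return FeatureStream(
        name="log_mean_time_cum", kind="dense", values=values, sampling_rate=rate
    )


def any_faces_stream(
    obs: Sequence[FaceObservation], rate: float, duration: float
) -> FeatureStream:
    """Per-sample probability that at least one face is on screen.

    Takes the maximum detection probability over observations falling in
    each sample; 0 where no face was detected.
    """
    n, bins = _sample_bins(obs, rate, duration)
    values = np.zeros(n)
    for o, b in zip(obs, bins):
        values[b] = max(values[b], o.probability)
    return FeatureStream(name="any_faces", kind="dense", values=values, sampling_rate=rate)
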