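"""Partition distances, landscape summaries, and partition clustering.

The solution landscape of an ensemble is organised by the pairwise
weighted mean Jaccard distance between partitions,

    d_PP' = sum_i min_j (1 - |C_i ∩ C'_j| / |C_i ∪ C'_j|) * |C_i| / sum_k |C_k|

symmetrized as d = (d_PP' + d_P'P) / 2.  d = 0 means identical partitions;
d -> 1 means completely dissimilar.  (Triangle inequality is not
guaranteed and never assumed.)

Landscape-level statistics — the mean pairwise distance MD(d), its
variance, and the coefficient of variation CV(Q) of the qualities —
classify the landscape: low/low is a consistent landscape, high/high a
dissimilar one, and high Var(d) with low Var(Q) the degenerate case where
structurally different partitions are statistically indistinguishable by
quality.

Clustering tessellates the ensemble around quality-ordered centres: the
best partition seeds the first centre, any partition at distance >= d_max
from all existing centres seeds a new one, and the remainder join their
nearest centre.  The default d_max = 0.10 requires co-clustered
partitions' best-matching communities to share at least 90% of their
nodes on weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .ensemble import PartitionEnsemble
from .optimizer import Partition

__all__ = [
    "DEFAULT_D_MAX",
    "DistanceMatrix",
    "LandscapeSummary",
    "ClusterSet",
    "jaccard_directed",
    "jaccard_distance",
    "variation_of_information",
    "pairwise_distances",
    "summarize_landscape",
    "cluster_partitions",
]

DEFAULT_D_MAX = 0.10


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetrized pairwise partition distances over an ensemble."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", e)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("distance matrix must be square")

    def __len__(self) -> int:
        return self.entries.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self.entries[iu]


@dataclass(frozen=True)
class LandscapeSummary:
    """Variability statistics of an ensemble's distances and qualities."""

    mean_distance: float  # MD(d) over all partition pairs
    var_distance: float
    quality_cv: float  # CV(Q) = std(Q) / mean(Q)
    var_quality: float
    category: str  # consistent | dissimilar | degenerate | anomalous


@dataclass(frozen=True)
class ClusterSet:
    """Tessellation of an ensemble around quality-ordered cluster centres."""

    centres: list[int]  # partition indices, in creation (quality) order
    assignment: np.ndarray  # partition index -> position in `centres`
    d_max: float
    sizes: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.centres)

    def members(self, cluster: int) -> np.ndarray:
        """Partition indices assigned to cluster ``cluster`` (centre included)."""
        return np.flatnonzero(self.assignment == cluster)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _contingency(p: Partition, q: Partition):
    lp, lq = p.labels, q.labels
    if len(lp) != len(lq):
        raise ValueError("partitions cover different node sets")
    if (lp < 0).any() or (lq < 0).any():
        raise ValueError("partitions with unassigned nodes have no distance")
    n = len(lp)
    c = sparse.coo_matrix(
        (np.ones(n), (lp, lq)), shape=(lp.max() + 1, lq.max() + 1)
    ).tocsr()
    return c, np.bincount(lp), np.bincount(lq)


def jaccard_directed(p: Partition, q: Partition) -> float:
    """Directed weighted mean Jaccard distance d_PQ (not symmetric)."""
    c, sizes_p, sizes_q = _contingency(p, q)
    n = len(p.labels)
    total = 0.0
    for i in range(c.shape[0]):
        if sizes_p[i] == 0:
            continue
        row = c.getrow(i)
        overlaps = row.data
        js = row.indices
        jacc = overlaps / (sizes_p[i] + sizes_q[js] - overlaps)
        total += (1.0 - jacc.max()) * sizes_p[i] / n
    return float(total)


def jaccard_distance(p: Partition, q: Partition) -> float:
    """Symmetrized weighted mean Jaccard distance d = (d_PQ + d_QP) / 2."""
    return 0.5 * (jaccard_directed(p, q) + jaccard_directed(q, p))


def variation_of_information(p: Partition, q: Partition) -> float:
    """Variation of information in bits (optional alternative metric)."""
    c, _, _ = _contingency(p, q)
    n = len(p.labels)
    pij = np.asarray(c.todense()) / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    h_joint = -np.sum(pij[nz] * np.log2(pij[nz]))
    h_p = -np.sum(pi[pi > 0] * np.log2(pi[pi > 0]))
    h_q = -np.sum(pj[pj > 0] * np.log2(pj[pj > 0]))
    return float(2 * h_joint - h_p - h_q)


def pairwise_distances(
    ens: PartitionEnsemble, metric=jaccard_distance
) -> DistanceMatrix:
    """All-pairs symmetrized distances over an ensemble."""
    k = len(ens)
    d = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d[a, b] = d[b, a] = metric(ens[a], ens[b])
    return DistanceMatrix(entries=d)


# ---------------------------------------------------------------------------
# summaries and clustering
# ---------------------------------------------------------------------------


def summarize_landscape(
    ens: PartitionEnsemble,
    dm: DistanceMatrix,
    high_distance: float = DEFAULT_D_MAX,
    high_quality_cv: float = 1e-3,
) -> LandscapeSummary:
    """MD(d), Var(d), CV(Q), Var(Q) and the qualitative landscape category.

    "High" distance variability means MD(d) > ``high_distance``; "high"
    quality variability means CV(Q) > ``high_quality_cv``.  Both thresholds
    are configurable; the categories are qualitative labels, not tests.
    Variances use the unbiased (n-1) estimator.
    """
    if len(ens) < 2:
        raise ValueError("landscape summary needs at least 2 partitions")
    if len(dm) != len(ens):
        raise ValueError("distance matrix size does not match ensemble")
    d = dm.upper_triangle()
    q = ens.qualities
    md = float(d.mean())
    var_d = float(d.var(ddof=1)) if len(d) > 1 else 0.0
    mean_q = float(q.mean())
    cv_q = float(q.std(ddof=1) / mean_q) if mean_q != 0 else float("inf")
    var_q = float(q.var(ddof=1))
    high_d = md > high_distance
    high_q = cv_q > high_quality_cv
    category = {
        (False, False): "consistent",
        (True, True): "dissimilar",
        (True, False): "degenerate",
        (False, True): "anomalous",
    }[(high_d, high_q)]
    return LandscapeSummary(
        mean_distance=md,
        var_distance=var_d,
        quality_cv=cv_q,
        var_quality=var_q,
        category=category,
    )


def cluster_partitions(
    ens: PartitionEnsemble, dm: DistanceMatrix, d_max: float = DEFAULT_D_MAX
) -> ClusterSet:
    """Cluster an ensemble around quality-ordered centres.

    Partitions are visited in decreasing quality (ties broken by run id,
    stable).  The best partition forms the first centre; a partition
    becomes a new centre iff its distance to every existing centre is
    >= d_max; every other partition joins its nearest centre (ties go to
    the earlier-created, i.e. higher-quality, centre).
    """
    if not (0 < d_max < 1):
        raise ValueError("d_max must be in (0, 1)")
    if len(dm) != len(ens):
        raise ValueError("distance matrix size does not match ensemble")
    q = ens.qualities
    order = np.lexsort((np.arange(len(ens)), -q))  # by -Q, then run id
    centres: list[int] = []
    for idx in order:
        if not centres:
            centres.append(int(idx))
            continue
        if all(dm.entries[idx, c] >= d_max for c in centres):
            centres.append(int(idx))
    assignment = np.empty(len(ens), dtype=np.int64)
    for idx in range(len(ens)):
        dists = dm.entries[idx, centres]
        assignment[idx] = int(np.argmin(dists))  # argmin takes the earliest tie
    sizes = [int((assignment == c).sum()) for c in range(len(centres))]
    return ClusterSet(centres=centres, assignment=assignment, d_max=d_max, sizes=sizes)
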