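"""Generalized Louvain maximization of the parametric modularity.

The optimizer is the stochastic variant of the Louvain heuristic used for
landscape sampling: in the local-move phase, a node considers every
community that holds one of its (nonzero-B) neighbours plus a fresh
singleton, and among the moves with strictly positive modularity gain it
picks one at random with probability proportional to the gain — rather
than greedily taking the best move.  This samples the space of feasible
high-quality partitions instead of collapsing onto one local optimum,
which is exactly what solution-landscape analysis needs.  Aggregation
(phase 2) sums B over community blocks and recurses; the within-community
weight accumulates on the aggregated diagonal, which local moves ignore
(it travels with the super-node) but the quality bookkeeping keeps.

The only randomness is the per-sweep node order and the proportional move
sampling, both driven by the run seed, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .null_model import ModularityMatrix, quality_from_matrix

__all__ = ["Partition", "canonicalize", "delta_q", "louvain_run"]

# gains this close to zero are treated as zero (float noise guard)
_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """A node -> community labelling with its quality and provenance.

    ``labels[i]`` is the community id of retained bin ``i``.  After
    :func:`canonicalize`, ids are contiguous and numbered by first
    occurrence (i.e. by each community's smallest bin index).  A label of
    ``-1`` marks an unassigned node (only used by annotation-derived
    partitions).
    """

    labels: np.ndarray
    quality: float = float("nan")
    seed: int | None = None
    alpha: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels[self.labels >= 0]))

    @property
    def communities(self) -> list[np.ndarray]:
        """Node index sets per community, ordered by community id."""
        out = []
        for cid in np.unique(self.labels[self.labels >= 0]):
            out.append(np.flatnonzero(self.labels == cid))
        return out

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())


def canonicalize(p: Partition) -> Partition:
    """Relabel communities by first-node occurrence; idempotent, Q unchanged."""
    labels = p.labels
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab < 0:
            out[i] = -1
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return replace(p, labels=out)


def delta_q(B: ModularityMatrix, p: Partition, node: int, target: int) -> float:
    """Modularity change from moving ``node`` into community ``target``.

    ``target`` may be an existing community id or a fresh (empty) one.
    Moving the node and recomputing Q changes it by exactly this amount.
    """
    labels = p.labels
    if not (0 <= node < len(labels)):
        raise ValueError(f"node {node} not in partition")
    row = B.entries[node]
    cur = labels[node]
    to_target = float(row[labels == target].sum()) - (row[node] if cur == target else 0.0)
    if target == cur:
        return 0.0
    from_cur = float(row[labels == cur].sum()) - float(row[node])
    return (to_target - from_cur) / B.total_weight


def _local_moves(
    M: np.ndarray, labels: np.ndarray, two_m: float, rng: np.random.Generator,
    greedy: bool, max_sweeps: int | None,
) -> bool:
    """Phase 1: sweep nodes in random order until a sweep makes no move.

    ``M`` may carry self-loops (aggregated levels); they are excluded from
    move gains.  Returns True if any move was ever accepted.
    """
    n = M.shape[0]
    any_move = False
    sweeps = 0
    while True:
        moved = False
        for v in rng.permutation(n):
            row = M[v]
            cur = labels[v]
            n_comm = labels.max() + 1
            comm_w = np.bincount(labels, weights=row, minlength=n_comm + 1)
            comm_w[cur] -= row[v]  # exclude the self entry
            s_cur = comm_w[cur]
            # candidates: communities of nonzero-B neighbours + one empty
            neigh = np.flatnonzero(row != 0)
            cand = np.unique(labels[neigh]) if len(neigh) else np.empty(0, dtype=np.int64)
            cand = cand[cand != cur]
            empty = n_comm  # fresh singleton community
            cand = np.append(cand, empty)
            gains = 2.0 * (comm_w[cand] - s_cur) / two_m
            pos = gains > _GAIN_EPS
            if not pos.any():
                continue
            cand, gains = cand[pos], gains[pos]
            if greedy:
                choice = int(np.argmax(gains))
            else:
                choice = int(rng.choice(len(cand), p=gains / gains.sum()))
            labels[v] = cand[choice]
            moved = True
            any_move = True
        sweeps += 1
        if not moved or (max_sweeps is not None and sweeps >= max_sweeps):
            return any_move


def _compress(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(np.int64)


def _aggregate(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Sum B over community blocks; within-community weight lands on the diagonal."""
    n_comm = labels.max() + 1
    ind = np.zeros((n_comm, M.shape[0]))
    ind[labels, np.arange(M.shape[0])] = 1.0
    return ind @ M @ ind.T


def louvain_run(
    B: ModularityMatrix,
    seed: int,
    greedy: bool = False,
    max_sweeps: int | None = None,
    _check_aggregation: bool = False,
) -> Partition:
    """One full generalized-Louvain pass on modularity matrix ``B``.

    Starts from all singletons (Q = 0), alternates stochastic local moves
    and aggregation until neither changes anything, and returns the
    canonicalized partition with its recomputed quality.  Q never
    decreases across accepted moves, so the result has Q >= 0.

    With ``greedy=True`` the proportional move sampling is replaced by
    argmax (deterministic apart from sweep order) — a debugging aid.
    """
    rng = np.random.default_rng(seed)
    two_m = 2.0 * B.total_weight
    n0 = B.entries.shape[0]
    M = B.entries.copy()
    node_labels = np.arange(n0)  # original node -> community at current level
    while True:
        level_labels = np.arange(M.shape[0])
        _local_moves(M, level_labels, two_m, rng, greedy, max_sweeps)
        level_labels = _compress(level_labels)
        n_comm = level_labels.max() + 1
        if n_comm == M.shape[0]:
            break  # no merge at this level: done
        if _check_aggregation:
            q_before = _q_with_diag(M, level_labels, two_m)
        node_labels = level_labels[node_labels]
        M = _aggregate(M, level_labels)
        if _check_aggregation:
            q_after = _q_with_diag(M, np.arange(M.shape[0]), two_m)
            assert abs(q_before - q_after) < 1e-9, "aggregation changed Q"
    quality = quality_from_matrix(B, node_labels)
    return canonicalize(
        Partition(
            labels=node_labels,
            quality=quality,
            seed=int(seed),
            alpha=B.alpha,
            gamma=B.gamma,
        )
    )


def _q_with_diag(M: np.ndarray, labels: np.ndarray, two_m: float) -> float:
    """Quality on a (possibly aggregated) matrix, counting self-loops."""
    same = labels[:, None] == labels[None, :]
    return float(M[same].sum()) / two_m
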