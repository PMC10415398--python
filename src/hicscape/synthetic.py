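"""Synthetic contact maps with power-law decay and planted communities.

The generator emulates the two features of intra-chromosomal Hi-C maps
the method relies on: contact counts that decay as ``|i - j|^(-alpha)``
with linear bin separation, and block communities enriched above that
background.  For bins i < j the count is drawn as

    A_ij ~ Poisson( mu * (1 + epsilon * [same planted community]) * |i-j|^(-alpha) )

mirrored to a symmetric matrix with a zero diagonal.  Poisson noise
mimics Hi-C count statistics; epsilon = 0 gives a pure decay map.  Blocks
are contiguous runs of bins; optionally two distant blocks can share one
label to emulate delocalized communities that join linearly separated
DNA segments.

:func:`perturbed_ensemble` builds partition ensembles with exactly known
per-node flip statistics, so landscape and core analyses can be tested
against closed-form expectations without running the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import PartitionEnsemble
from .hic_io import ContactNetwork
from .optimizer import Partition, canonicalize

__all__ = ["SyntheticSpec", "generate_contacts", "perturbed_ensemble", "write_triplets"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-community contact map.

    ``merge_block_pairs`` lists (a, b) block-index pairs that share one
    community label (delocalized communities).
    """

    n_bins: int
    block_sizes: tuple
    alpha_true: float = 0.75
    mu: float = 50.0  # baseline intensity at separation 1
    epsilon: float = 5.0  # within-community enrichment
    seed: int = 0
    resolution: int = 100_000
    merge_block_pairs: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_bins:
            raise ValueError("block sizes must sum to n_bins")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")

    def planted_labels(self) -> np.ndarray:
        labels = np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)
        for a, b in self.merge_block_pairs:
            labels[labels == b] = a
        return labels


def generate_contacts(spec: SyntheticSpec) -> tuple[ContactNetwork, Partition]:
    """Draw one synthetic contact network plus its planted partition."""
    if spec.n_bins < 2:
        raise ValueError("need at least 2 bins")
    rng = np.random.default_rng(spec.seed)
    labels = spec.planted_labels()
    idx = np.arange(spec.n_bins)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(sep > 0, sep ** (-spec.alpha_true), 0.0)
    same = labels[:, None] == labels[None, :]
    lam = spec.mu * (1.0 + spec.epsilon * same) * decay
    upper = np.triu(rng.poisson(lam), k=1).astype(float)
    weights = upper + upper.T
    net = ContactNetwork(
        chromosome="synthetic",
        resolution=spec.resolution,
        n_bins_total=spec.n_bins,
        retained_bins=idx.astype(np.int64),
        weights=weights,
    )
    planted = canonicalize(
        Partition(labels=labels, alpha=spec.alpha_true, gamma=None, seed=spec.seed)
    )
    return net, planted


def perturbed_ensemble(
    planted: Partition, n_members: int, flip_rate: float, seed: int
) -> PartitionEnsemble:
    """Ensemble of noisy copies of a planted partition.

    Each member reassigns every node independently, with probability
    ``flip_rate``, to a uniformly random *other* community.  Qualities are
    descending placeholders (1, 1 - 1e-6, ...) so the unperturbed planted
    partition — member 0 — is always the quality-ordered cluster centre.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must be in [0, 0.5)")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    n = planted.n_nodes
    comm_ids = np.unique(planted.labels)
    partitions = [
        Partition(labels=planted.labels.copy(), quality=1.0, seed=seed,
                  alpha=planted.alpha, gamma=planted.gamma)
    ]
    for k in range(1, n_members):
        labels = planted.labels.copy()
        flip = rng.random(n) < flip_rate
        for v in np.flatnonzero(flip):
            others = comm_ids[comm_ids != planted.labels[v]]
            if len(others):
                labels[v] = rng.choice(others)
        partitions.append(
            Partition(labels=labels, quality=1.0 - 1e-6 * k, seed=seed,
                      alpha=planted.alpha, gamma=planted.gamma)
        )
    return PartitionEnsemble(
        partitions=partitions,
        alpha=planted.alpha if planted.alpha is not None else float("nan"),
        gamma=planted.gamma if planted.gamma is not None else float("nan"),
        seeds=[seed] * n_members,
    )


def write_triplets(net: ContactNetwork, path) -> None:
    """Dump a network as sparse triplet text (upper triangle, bp coordinates)."""
    res = net.resolution
    with open(path, "w") as fh:
        iu, ju = np.triu_indices(net.n_bins, k=1)
        for i, j in zip(iu, ju):
            w = net.weights[i, j]
            if w != 0:
                bi = int(net.retained_bins[i]) * res
                bj = int(net.retained_bins[j]) * res
                fh.write(f"{bi}\t{bj}\t{w:.10g}\n")
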