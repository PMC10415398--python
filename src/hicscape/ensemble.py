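"""Ensembles of independent optimizer runs at one (alpha, gamma).

Landscape analysis needs many feasible partitions, not one: the ensemble
holds the partitions from independent stochastic Louvain passes with
per-run seeds derived deterministically from a master seed, so any single
run can be reproduced from its stored seed and the whole ensemble is
byte-identical across reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic_io import ContactNetwork
from .null_model import build_null, modularity_matrix
from .optimizer import Partition, louvain_run

__all__ = ["PartitionEnsemble", "derive_seeds", "sample_ensemble", "save_ensemble", "load_ensemble"]


@dataclass(frozen=True)
class PartitionEnsemble:
    """Ordered partitions from independent runs at shared (alpha, gamma)."""

    partitions: list[Partition]
    alpha: float
    gamma: float
    seeds: list[int] = field(default_factory=list)
    network_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("ensemble must contain at least one partition")
        n = self.partitions[0].n_nodes
        if any(p.n_nodes != n for p in self.partitions):
            raise ValueError("all partitions must cover the same node set")

    def __len__(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __getitem__(self, i: int) -> Partition:
        return self.partitions[i]

    @property
    def qualities(self) -> np.ndarray:
        return np.array([p.quality for p in self.partitions])

    def best(self) -> Partition:
        """Maximum-quality partition (ties -> lowest run id)."""
        return self.partitions[int(np.argmax(self.qualities))]


def derive_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds from a master seed (each < 2^31)."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n_runs, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def sample_ensemble(
    net: ContactNetwork,
    alpha: float,
    gamma: float,
    n_runs: int,
    master_seed: int,
    greedy: bool = False,
) -> PartitionEnsemble:
    """Run ``n_runs`` independent Louvain passes at (alpha, gamma)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    null = build_null(net, alpha)
    B = modularity_matrix(net, null, gamma)
    seeds = derive_seeds(master_seed, n_runs)
    partitions = [louvain_run(B, seed, greedy=greedy) for seed in seeds]
    return PartitionEnsemble(
        partitions=partitions,
        alpha=float(alpha),
        gamma=float(gamma),
        seeds=seeds,
        network_fingerprint=net.fingerprint(),
    )


def save_ensemble(ens: PartitionEnsemble, path) -> None:
    """Write a columnar TSV: run_id, seed, alpha, gamma, Q, label per bin."""
    n = ens.partitions[0].n_nodes
    cols = ["run_id", "seed", "alpha", "gamma", "Q"] + [f"bin{i}" for i in range(n)]
    rows = []
    for rid, p in enumerate(ens.partitions):
        seed = ens.seeds[rid] if rid < len(ens.seeds) else -1
        rows.append([rid, seed, ens.alpha, ens.gamma, repr(p.quality)] + list(p.labels))
    with open(path, "w") as fh:
        fh.write(f"# fingerprint={ens.network_fingerprint}\n")
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_ensemble(path, net: ContactNetwork | None = None) -> PartitionEnsemble:
    """Read an ensemble TSV; warns if it was built from a different network."""
    with open(path) as fh:
        first = fh.readline().strip()
    fingerprint = ""
    skip = 0
    if first.startswith("# fingerprint="):
        fingerprint = first.split("=", 1)[1]
        skip = 1
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if df.empty:
        raise ValueError(f"no partitions in {path}")
    if net is not None and fingerprint and fingerprint != net.fingerprint():
        warnings.warn(
            "ensemble fingerprint does not match the supplied network", stacklevel=2
        )
    label_cols = [c for c in df.columns if c.startswith("bin")]
    partitions = []
    seeds = []
    for _, row in df.iterrows():
        partitions.append(
            Partition(
                labels=row[label_cols].to_numpy(dtype=np.int64),
                quality=float(row["Q"]),
                seed=int(row["seed"]),
                alpha=float(row["alpha"]),
                gamma=float(row["gamma"]),
            )
        )
        seeds.append(int(row["seed"]))
    return PartitionEnsemble(
        partitions=partitions,
        alpha=float(df["alpha"].iloc[0]),
        gamma=float(df["gamma"].iloc[0]),
        seeds=seeds,
        network_fingerprint=fingerprint,
    )
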