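"""Contact-matrix and annotation I/O, matrix balancing, and bin masking.

A Hi-C experiment counts 3D contacts between pairs of fixed-size genomic
bins.  This module turns the common text dumps of such counts (sparse
triplets or dense matrices) into :class:`ContactNetwork` objects — symmetric
weighted adjacency matrices over the retained bins — and provides the
standard pre-processing steps: masking unmappable/empty bins and
Knight–Ruiz-style matrix balancing.  BED-like interval annotations (TAD
calls, sub-compartment labels) are read into :class:`AnnotationTrack`
objects for later comparison with network communities.

Coordinate conventions: 0-based, half-open intervals; bin index =
floor(start / resolution).  Self-contacts (the matrix diagonal) are
discarded on load because the modularity quality function sums over
distinct bin pairs only.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContactNetwork",
    "AnnotationTrack",
    "read_contact_triplets",
    "read_dense_matrix",
    "write_dense_matrix",
    "mask_empty_bins",
    "kr_balance",
    "read_annotation",
    "write_partition",
    "read_partition",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactNetwork:
    """Symmetric weighted contact network over retained genomic bins.

    Parameters
    ----------
    chromosome:
        Chromosome identifier (e.g. ``"10"`` or ``"chr10"``).
    resolution:
        Bin length in base pairs.
    n_bins_total:
        Number of genomic bins before masking.
    retained_bins:
        Strictly increasing original bin indices kept after masking.
        Linear separations ``|i - j|`` are always computed from these
        original indices, so masking never shortens genomic distances.
    weights:
        Dense symmetric nonnegative matrix ``A`` over retained bins with a
        zero diagonal.
    """

    chromosome: str
    resolution: int
    n_bins_total: int
    retained_bins: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        retained = np.asarray(self.retained_bins, dtype=np.int64)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "retained_bins", retained)
        object.__setattr__(self, "weights", weights)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if retained.ndim != 1 or len(retained) != weights.shape[0]:
            raise ValueError("retained_bins length must match weights")
        if len(retained) and (np.diff(retained) <= 0).any():
            raise ValueError("retained_bins must be strictly increasing")
        if len(retained) and retained[-1] >= self.n_bins_total:
            raise ValueError("retained bin index exceeds n_bins_total")
        if not np.allclose(weights, weights.T):
            raise ValueError("weights must be symmetric")
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diagonal(weights)).max(initial=0.0) > 0:
            raise ValueError("weights must have a zero diagonal")

    @property
    def n_bins(self) -> int:
        """Number of retained bins (network nodes)."""
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths ``k_i = sum_j A_ij``."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """Total weight ``m = (1/2) * sum_{i != j} A_ij``."""
        return float(self.weights.sum()) / 2.0

    def fingerprint(self) -> str:
        """Stable hash of the matrix and bin bookkeeping."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(np.ascontiguousarray(self.retained_bins).tobytes())
        h.update(f"{self.chromosome}:{self.resolution}:{self.n_bins_total}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class AnnotationTrack:
    """Labelled genomic intervals (TAD calls, sub-compartment classes).

    ``intervals`` is a list of ``(start_bp, end_bp, label)`` with 0-based,
    half-open coordinates, sorted by start.
    """

    chromosome: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)
    resolution: int = 100_000

    def __post_init__(self) -> None:
        for start, end, _label in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval [{start}, {end})")

    def has_overlaps(self) -> bool:
        """True if any two intervals overlap (resolved at rasterization)."""
        prev_end = -1
        for start, end, _ in sorted(self.intervals):
            if start < prev_end:
                return True
            prev_end = max(prev_end, end)
        return False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _build_network(
    dense: np.ndarray, chromosome: str, resolution: int
) -> ContactNetwork:
    dense = (dense + dense.T) / 2.0
    np.fill_diagonal(dense, 0.0)
    n = dense.shape[0]
    return ContactNetwork(
        chromosome=str(chromosome),
        resolution=int(resolution),
        n_bins_total=n,
        retained_bins=np.arange(n, dtype=np.int64),
        weights=dense,
    )


def read_contact_triplets(
    path,
    resolution: int,
    chromosome: str,
    chrom_length_bp: int | None = None,
) -> ContactNetwork:
    """Read a sparse triplet dump ``pos_i  pos_j  count`` into a network.

    Each row holds the genomic start coordinates of two bins and their
    contact count; rows are mirrored into a symmetric matrix, repeated
    triplets accumulate, and the diagonal is dropped.  Rows whose
    coordinates exceed ``chrom_length_bp`` (when given) are rejected with a
    warning.

    Raises
    ------
    ValueError
        On malformed rows (with the 1-based line number), negative counts,
        or an empty file.
    """
    rows_i: list[int] = []
    rows_j: list[int] = []
    vals: list[float] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                pos_i = int(float(parts[0]))
                pos_j = int(float(parts[1]))
                count = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: cannot parse {line!r}") from exc
            if count < 0:
                raise ValueError(f"line {lineno}: negative count {count}")
            if np.isnan(count):
                continue
            if chrom_length_bp is not None and (
                pos_i >= chrom_length_bp or pos_j >= chrom_length_bp
            ):
                n_rejected += 1
                continue
            rows_i.append(pos_i // resolution)
            rows_j.append(pos_j // resolution)
            vals.append(count)
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} triplet rows beyond the chromosome extent",
            stacklevel=2,
        )
    if not rows_i:
        raise ValueError(f"no usable triplet rows in {path}")
    n = max(max(rows_i), max(rows_j)) + 1
    if chrom_length_bp is not None:
        n = max(n, -(-chrom_length_bp // resolution))
    half = np.zeros((n, n))
    np.add.at(half, (np.array(rows_i), np.array(rows_j)), np.array(vals))
    dense = half + half.T  # mirror each triplet; diagonal dropped next
    np.fill_diagonal(dense, 0.0)
    return ContactNetwork(
        chromosome=str(chromosome),
        resolution=int(resolution),
        n_bins_total=n,
        retained_bins=np.arange(n, dtype=np.int64),
        weights=dense,
    )


def read_dense_matrix(
    path, resolution: int, chromosome: str = "synthetic", atol_factor: float = 1e-6
) -> ContactNetwork:
    """Read a whitespace-separated dense square matrix.

    The matrix is symmetrized as ``(M + M^T)/2``; a warning is emitted when
    the asymmetry ``max|M - M^T|`` exceeds ``atol_factor * max(M)``.
    """
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix is not square: {mat.shape}")
    asym = np.abs(mat - mat.T).max()
    if mat.size and asym > atol_factor * max(mat.max(), 1e-300):
        warnings.warn(
            f"asymmetric input (max |M - M^T| = {asym:g}); symmetrizing",
            stacklevel=2,
        )
    return _build_network(mat, chromosome, resolution)


def write_dense_matrix(net: ContactNetwork, path) -> None:
    """Write the weight matrix as whitespace-separated text."""
    np.savetxt(path, net.weights, fmt="%.10g")


# ---------------------------------------------------------------------------
# masking and balancing
# ---------------------------------------------------------------------------


def mask_empty_bins(
    net: ContactNetwork, min_nonzero_fraction: float = 0.1
) -> ContactNetwork:
    """Drop empty and near-empty bins before balancing.

    Removes bins with zero strength and bins whose fraction of nonzero
    off-diagonal entries falls below ``min_nonzero_fraction``.  The
    surviving bins keep their original indices in ``retained_bins`` so
    genomic separations are preserved across the gaps.
    """
    if not (0 <= min_nonzero_fraction < 1):
        raise ValueError("min_nonzero_fraction must be in [0, 1)")
    n = net.n_bins
    if n == 0:
        raise ValueError("network has no bins")
    nonzero_frac = (net.weights > 0).sum(axis=1) / max(n - 1, 1)
    keep = (net.strengths > 0) & (nonzero_frac >= min_nonzero_fraction)
    if not keep.any():
        raise ValueError("masking removed every bin; lower the threshold")
    idx = np.flatnonzero(keep)
    return replace(
        net,
        retained_bins=net.retained_bins[idx],
        weights=net.weights[np.ix_(idx, idx)],
    )


def kr_balance(
    net: ContactNetwork, tolerance: float = 1e-6, max_iterations: int = 1000
) -> ContactNetwork:
    """Knight–Ruiz-style symmetric matrix balancing.

    Finds a positive diagonal scaling ``D`` such that every row sum of
    ``D A D`` equals the common mean row sum within ``tolerance`` (relative
    deviation).  The total weight of the matrix is preserved, and the
    original network is left unmodified.

    The scaling is computed by the symmetric fixed-point iteration
    ``d <- d / sqrt(rowsum(DAD))`` which converges for the fully
    indecomposable matrices produced by :func:`mask_empty_bins`.

    Raises
    ------
    ValueError
        If any retained bin has zero strength, or the iteration does not
        reach tolerance within ``max_iterations`` (mask more aggressively).
    """
    A = net.weights
    k = net.strengths
    if (k <= 0).any():
        raise ValueError("zero-strength row: mask empty bins before balancing")
    d = np.ones(net.n_bins)
    for _ in range(max_iterations):
        row = d * (A @ d)  # row sums of diag(d) A diag(d)
        if np.max(np.abs(row - 1.0)) < tolerance:
            break
        d /= np.sqrt(row)
    else:
        raise ValueError(
            "balancing did not converge; apply stricter bin masking first"
        )
    balanced = A * np.outer(d, d)
    # rescale so total weight matches the input (row sums stay equal)
    balanced *= A.sum() / balanced.sum()
    return replace(net, weights=balanced)


# ---------------------------------------------------------------------------
# annotations and partitions on disk
# ---------------------------------------------------------------------------


def read_annotation(path, resolution: int, chromosome: str) -> AnnotationTrack:
    """Read a BED-like TSV (chrom, start, end, label, ...) for one chromosome.

    Intervals on other chromosomes are skipped.  0-based half-open
    coordinates.  Overlapping intervals are allowed here; the overlap is
    resolved when the track is rasterized to bins.
    """
    intervals: list[tuple[int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 columns")
            chrom = parts[0]
            if chrom not in (chromosome, f"chr{chromosome}") and chromosome not in (
                chrom,
                f"chr{chrom}",
            ):
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable coordinates {parts[1]!r}, {parts[2]!r}"
                ) from exc
            label = parts[3] if len(parts) > 3 and parts[3] else f"iv{lineno}"
            intervals.append((start, end, label))
    if not intervals:
        warnings.warn(f"no intervals for chromosome {chromosome} in {path}", stacklevel=2)
    intervals.sort(key=lambda iv: (iv[0], iv[1]))
    return AnnotationTrack(
        chromosome=chromosome, intervals=intervals, resolution=resolution
    )


def write_partition(partition, net: ContactNetwork, path) -> None:
    """Write a partition as TSV over all original bins.

    Columns: bin_index, start_bp, end_bp, community_id (NA for masked
    bins), and — when the partition carries them — in_core and c.
    """
    labels = np.asarray(partition.labels)
    if len(labels) != net.n_bins:
        raise ValueError(
            f"partition covers {len(labels)} bins, network has {net.n_bins}"
        )
    if len(labels) == 0:
        raise ValueError("empty partition")
    pos = {int(b): i for i, b in enumerate(net.retained_bins)}
    rows = []
    for b in range(net.n_bins_total):
        i = pos.get(b)
        rows.append(
            {
                "bin_index": b,
                "start_bp": b * net.resolution,
                "end_bp": (b + 1) * net.resolution,
                "community_id": int(labels[i]) if i is not None else pd.NA,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_partition(path) -> pd.DataFrame:
    """Read a partition TSV written by :func:`write_partition`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
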