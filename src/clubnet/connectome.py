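"""Correlation matrices and sparsity-thresholded binary networks.

A subject's parcellated time series becomes an N x N Pearson matrix, which
is binarized at each value of a sparsity grid by keeping the K largest
positive correlations (K = round-half-up of S * N(N-1)/2).  Negative
correlations are never retained; ties break lexicographically on (i, j) so
outputs are bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import TimeSeriesMatrix

log = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with a zeroed diagonal."""

    r: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.isfinite(self.r).all():
            raise ValidationError("connectivity matrix has non-finite entries")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryNetwork:
    """Unweighted undirected graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not ((a == 0) | (a == 1)).all():
            raise ValidationError("adjacency must be 0/1")
        if (np.diag(a) != 0).any():
            raise ValidationError("adjacency must have a zero diagonal")
        if (a != a.T).any():
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of upper-triangle edges in lexicographic order."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass(frozen=True)
class SparsityGrid:
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 1 or any(not (0 < s <= 1) for s in t):
            raise ValidationError("sparsity thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("sparsity thresholds must be strictly increasing")

    @classmethod
    def default(cls) -> "SparsityGrid":
        """5% to 50% in 5% steps (10 thresholds)."""
        return cls.from_range(0.05, 0.50, 0.05)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "SparsityGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(round(start + k * step, 10) for k in range(n)))

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    def __contains__(self, s: float) -> bool:
        return any(abs(s - t) < 1e-9 for t in self.thresholds)


def pearson_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between region time courses.

    The diagonal is set to 0 so the matrix can feed directly into network
    construction.  A zero-variance region is an error naming the region.
    """
    values = ts.values
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_labels[i] for i in dead]
        raise ValidationError(f"zero-variance time series for region(s) {names}")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    # enforce exact symmetry against floating-point noise
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(r, subject_id=ts.subject_id)


def edge_count_for_sparsity(n_nodes: int, sparsity: float) -> int:
    """Target edge count: round-half-up of S * N(N-1)/2."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def binarize_by_sparsity(C: ConnectivityMatrix, sparsity: float) -> BinaryNetwork:
    """Keep the K largest positive off-diagonal correlations as edges.

    Entries <= 0 are never retained; if fewer than K positive entries exist
    the shortfall is logged and the network is sparser than requested.
    """
    if not 0 < sparsity <= 1:
        raise ValidationError(f"sparsity must be in (0, 1], got {sparsity}")
    n = C.n_regions
    k = edge_count_for_sparsity(n, sparsity)
    if k == 0:
        raise ValidationError(f"sparsity {sparsity} too low for N={n}: 0 edges")
    iu, ju = np.triu_indices(n, 1)
    vals = C.r[iu, ju]
    # sort by value desc, then (i, j) lexicographic asc
    order = np.lexsort((ju, iu, -vals))
    top = order[:k]
    keep = top[vals[top] > 0]
    shortfall = k - keep.size
    if shortfall:
        log.warning(
            "subject %s sparsity %.3g: dropped %d of %d requested edges "
            "(non-positive correlations)",
            C.subject_id, sparsity, shortfall, k,
        )
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, sparsity)


def density(G: BinaryNetwork) -> float:
    """Realized edge density 2E / N(N-1)."""
    n = G.n_nodes
    return 2.0 * G.n_edges / (n * (n - 1))
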