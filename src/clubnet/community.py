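"""Community detection and participation coefficients.

Communities come from repeated seeded Louvain runs combined through a
co-assignment consensus (agreement > 0.5, connected components).  The
participation coefficient is the Guimera-Amaral measure
pc(i) = 1 - sum_s (k_is / k_i)^2, which is 0 for a node whose edges all
stay inside its own community and bounded above by 1 - 1/m for m
communities (isolated nodes score 0 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import BinaryNetwork
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    assignment: np.ndarray
    n_communities: int
    modularity: float
    seed: int
    n_runs: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValidationError("community labels must be contiguous from 0")
        if self.n_communities != labels.size:
            raise ValidationError("n_communities does not match assignment")


def _to_nx(G: BinaryNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(G.n_nodes))
    g.add_edges_from(map(tuple, G.edge_list()))
    return g


def _canonical_labels(assignment: np.ndarray) -> np.ndarray:
    """Relabel communities 0..m-1 in order of first node appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(assignment)
    for i, lab in enumerate(assignment):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def detect_communities(
    G: BinaryNetwork, n_runs: int = 100, seed: int = 0
) -> CommunityPartition:
    """Consensus Louvain partition; deterministic for a fixed seed.

    Falls back to the best-modularity single run when the consensus is
    degenerate (single community although the best run found several, or
    negative modularity).
    """
    if G.n_edges == 0:
        raise ValidationError("cannot detect communities in an edgeless graph")
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    g = _to_nx(G)
    n = G.n_nodes
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    co = np.zeros((n, n))
    best_q = -np.inf
    best_assign: np.ndarray | None = None
    for rs in run_seeds:
        comms = nx.community.louvain_communities(g, seed=int(rs))
        assign = np.empty(n, dtype=int)
        for lab, nodes in enumerate(comms):
            assign[list(nodes)] = lab
        q = nx.community.modularity(g, comms)
        if q > best_q:
            best_q = q
            best_assign = assign
        same = assign[:, None] == assign[None, :]
        co += same
    co /= n_runs
    agree = nx.Graph()
    agree.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(co > 0.5, 1))
    agree.add_edges_from(zip(ii.tolist(), jj.tolist()))
    consensus = np.empty(n, dtype=int)
    comps = list(nx.connected_components(agree))
    for lab, nodes in enumerate(comps):
        consensus[list(nodes)] = lab
    assert best_assign is not None
    q_cons = nx.community.modularity(
        g, [set(np.flatnonzero(consensus == c)) for c in np.unique(consensus)]
    )
    best_m = np.unique(best_assign).size
    # the consensus components are only kept when they are at least as good
    # (by modularity) as the best single run; chained/degenerate agreement
    # graphs otherwise collapse communities
    degenerate = ((len(comps) == 1 and best_m > 1) or q_cons < 0
                  or q_cons < best_q - 1e-9)
    if degenerate:
        log.info("degenerate consensus (m=%d, Q=%.3f); using best run",
                 len(comps), q_cons)
        assignment, q = best_assign, best_q
    else:
        assignment, q = consensus, q_cons
    assignment = _canonical_labels(assignment)
    return CommunityPartition(
        assignment=assignment,
        n_communities=int(np.unique(assignment).size),
        modularity=float(q),
        seed=seed,
        n_runs=n_runs,
    )


def participation_coefficient(
    G: BinaryNetwork, part: CommunityPartition
) -> np.ndarray:
    """pc(i) = 1 - sum_s (k_is / k_i)^2; 0 for isolated nodes."""
    a = G.adjacency.astype(float)
    n = a.shape[0]
    if part.assignment.shape[0] != n:
        raise ValidationError("partition does not cover all nodes")
    onehot = np.zeros((n, part.n_communities))
    onehot[np.arange(n), part.assignment] = 1.0
    k_is = a @ onehot            # edges from node i into community s
    k = a.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = k_is / k[:, None]
    pc = 1.0 - np.nansum(frac**2, axis=1)
    pc[k == 0] = 0.0
    # clamp tiny negative floating-point residue
    return np.clip(pc, 0.0, 1.0)
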