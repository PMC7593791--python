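"""Rich-club / diverse-club definition, edge classification and strengths.

A club is the top floor(fraction * N) regions ranked by a per-node score
averaged over the reference group (nodal degree for the rich club,
participation coefficient for the diverse club), both taken at the
reference sparsity.  Edges are then club (both endpoints in the club),
feeder (exactly one) or local (neither), and per-subject connection
strengths sum the retained correlation weights of each class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .connectome import BinaryNetwork, ConnectivityMatrix
from .errors import ValidationError
from .graph_metrics import NodalMetrics
from .io import RegionAtlas

log = logging.getLogger(__name__)

EDGE_CLASSES = ("club", "feeder", "local")


@dataclass
class ClubDefinition:
    club_nodes: tuple[int, ...]
    fraction: float
    criterion: str                       # "degree" or "participation"
    ranking_scores: np.ndarray
    reference_group: str = "HC"
    reference_sparsity: float = 0.15

    def labels(self, atlas: RegionAtlas) -> list[str]:
        return [atlas.labels[i] for i in self.club_nodes]


@dataclass
class EdgeClassification:
    """Per-edge labels aligned with the network's lexicographic edge list."""

    edges: np.ndarray        # (E, 2) node index pairs, i < j
    labels: np.ndarray       # (E,) strings from EDGE_CLASSES

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in EDGE_CLASSES}


@dataclass
class ConnectionStrengths:
    club_strength: float
    feeder_strength: float
    local_strength: float

    @property
    def total(self) -> float:
        return self.club_strength + self.feeder_strength + self.local_strength


@dataclass
class OverlapAnalysis:
    overlap_nodes: tuple[int, ...]
    rich_only: tuple[int, ...]
    diverse_only: tuple[int, ...]


def select_club(
    ranking_scores: Sequence[float],
    fraction: float,
    criterion: str = "degree",
    reference_group: str = "HC",
    reference_sparsity: float = 0.15,
) -> ClubDefinition:
    """Top floor(fraction * N) nodes; ties broken by ascending node index."""
    scores = np.asarray(ranking_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValidationError("ranking scores must be finite")
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    n = scores.size
    size = int(np.floor(fraction * n))
    if size < 1:
        raise ValidationError(f"fraction {fraction} selects no nodes for N={n}")
    order = np.lexsort((np.arange(n), -scores))
    chosen = order[:size]
    if size < n and scores[order[size - 1]] == scores[order[size]]:
        log.warning(
            "club boundary tie at score %.6g (criterion %s); resolved by "
            "atlas order", scores[order[size]], criterion,
        )
    return ClubDefinition(
        club_nodes=tuple(int(i) for i in chosen),
        fraction=fraction,
        criterion=criterion,
        ranking_scores=scores,
        reference_group=reference_group,
        reference_sparsity=reference_sparsity,
    )


def average_ranking_scores(per_subject_scores: Sequence[Sequence[float]]) -> np.ndarray:
    """Unweighted per-node mean of the criterion across reference subjects."""
    if len(per_subject_scores) == 0:
        raise ValidationError("reference group is empty")
    mat = np.asarray(per_subject_scores, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("score vectors must all have the same length")
    return mat.mean(axis=0)


def classify_edges(G: BinaryNetwork, club: ClubDefinition) -> EdgeClassification:
    edges = G.edge_list()
    in_club = np.zeros(G.n_nodes, dtype=bool)
    idx = np.asarray(club.club_nodes, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= G.n_nodes):
        raise ValidationError("club nodes outside graph node range")
    in_club[idx] = True
    if edges.size == 0:
        return EdgeClassification(edges.reshape(0, 2), np.array([], dtype=object))
    n_in = in_club[edges[:, 0]].astype(int) + in_club[edges[:, 1]].astype(int)
    labels = np.array(EDGE_CLASSES, dtype=object)[2 - n_in]
    return EdgeClassification(edges, labels)


def connection_strengths(
    C: ConnectivityMatrix,
    G: BinaryNetwork,
    cls: EdgeClassification,
    weighting: str = "pearson",
) -> ConnectionStrengths:
    """Sum of retained edge weights per class.

    weighting="pearson" uses the correlation values; "binary" counts edges.
    """
    if C.n_regions != G.n_nodes:
        raise ValidationError(
            f"dimension mismatch: connectivity {C.n_regions}, network {G.n_nodes}")
    if weighting not in ("pearson", "binary"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    out = {}
    for label in EDGE_CLASSES:
        sel = cls.edges[cls.labels == label]
        if sel.size == 0:
            out[label] = 0.0
        elif weighting == "binary":
            out[label] = float(sel.shape[0])
        else:
            out[label] = float(C.r[sel[:, 0], sel[:, 1]].sum())
    return ConnectionStrengths(
        club_strength=out["club"],
        feeder_strength=out["feeder"],
        local_strength=out["local"],
    )


def overlap_analysis(rich: ClubDefinition, diverse: ClubDefinition) -> OverlapAnalysis:
    """Intersection and set differences of the two club definitions."""
    r = set(rich.club_nodes)
    d = set(diverse.club_nodes)
    return OverlapAnalysis(
        overlap_nodes=tuple(sorted(r & d)),
        rich_only=tuple(sorted(r - d)),
        diverse_only=tuple(sorted(d - r)),
    )


def mean_nodal_metrics_over(
    nodal: NodalMetrics, nodes: Sequence[int]
) -> dict[str, float | None]:
    """Unweighted mean of each nodal metric over a node set (None if empty)."""
    idx = np.asarray(list(nodes), dtype=int)
    metrics = {
        "degree": nodal.degree,
        "nodal_efficiency": nodal.nodal_efficiency,
        "nodal_clustering": nodal.nodal_clustering,
        "nodal_Lp": nodal.nodal_Lp,
        "betweenness": nodal.betweenness,
    }
    if idx.size == 0:
        log.info("empty node set: averaged nodal metrics are null")
        return {k: None for k in metrics}
    return {k: float(v[idx].mean()) for k, v in metrics.items()}
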