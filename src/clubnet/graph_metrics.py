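"""Global and nodal graph metrics with degree-preserving null normalization.

Conventions for possibly-disconnected graphs: the characteristic path
length averages over reachable ordered pairs only, while efficiencies use
1/inf = 0, so every metric stays finite down to very sparse thresholds.
Betweenness is Brandes' algorithm normalized by (N-1)(N-2)/2.

Null networks are Maslov-Sneppen rewirings (10 x E attempted double-edge
swaps per null) which preserve the degree sequence exactly.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import BinaryNetwork, SparsityGrid
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan
    sparsity: float = np.nan


@dataclass
class NodalMetrics:
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    nodal_clustering: np.ndarray
    nodal_Lp: np.ndarray
    betweenness: np.ndarray


@dataclass
class NullEnsemble:
    Cp_rand: float
    Lp_rand: float
    n_null: int
    seed: int


def clustering(G: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their unweighted mean Cp."""
    a = G.adjacency.astype(float)
    if a.shape[0] < 3:
        raise ValidationError("clustering needs at least 3 nodes")
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c, float(c.mean())


def shortest_paths(G: BinaryNetwork) -> np.ndarray:
    """All-pairs BFS distance matrix; unreachable pairs are +inf."""
    if G.n_edges == 0:
        d = np.full((G.n_nodes, G.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return _csgraph_shortest_path(
        csr_array(G.adjacency), method="D", unweighted=True, directed=False
    )


def characteristic_path_length(distances: np.ndarray) -> float:
    """Mean shortest-path distance over reachable ordered pairs."""
    n = distances.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(distances)
    if not finite.any():
        raise ValidationError("no reachable pairs: cannot compute path length")
    return float(distances[finite].mean())


def global_efficiency(distances: np.ndarray) -> float:
    """Mean inverse distance over all ordered pairs (1/inf = 0)."""
    n = distances.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / distances[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(G: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    a = G.adjacency
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = BinaryNetwork(a[np.ix_(nbrs, nbrs)], sparsity=G.sparsity)
        vals[i] = global_efficiency(shortest_paths(sub))
    return float(vals.mean())


def _brandes_betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness for an undirected 0/1 adjacency matrix."""
    n = a.shape[0]
    nbrs = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv = dist[v]
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # undirected: each pair counted twice


def nodal_metrics(G: BinaryNetwork) -> NodalMetrics:
    """Degree, efficiency, clustering, path length and betweenness per node."""
    a = G.adjacency
    n = a.shape[0]
    degree = a.sum(axis=1).astype(int)
    d = shortest_paths(G)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off, 1.0 / d, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1)
    finite = off & np.isfinite(d)
    reach = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        nodal_lp = np.where(reach > 0, sums / np.maximum(reach, 1), 0.0)
    if (reach == 0).any():
        log.warning("%d isolated node(s): nodal path length set to 0",
                    int((reach == 0).sum()))
    nodal_c, _ = clustering(G)
    bc = _brandes_betweenness(a)
    norm = (n - 1) * (n - 2) / 2.0
    return NodalMetrics(
        degree=degree,
        nodal_efficiency=nodal_eff,
        nodal_clustering=nodal_c,
        nodal_Lp=nodal_lp,
        betweenness=bc / norm if norm > 0 else bc,
    )


def maslov_sneppen_rewire(
    G: BinaryNetwork, rng: np.random.Generator, swap_factor: int = 10
) -> tuple[BinaryNetwork, int]:
    """One degree-preserving null: swap_factor x E attempted edge swaps.

    Returns the rewired network and the number of successful swaps (0 means
    the graph admits no swap, e.g. a star; the null then equals G).
    """
    edges = [tuple(e) for e in G.edge_list()]
    n_edges = len(edges)
    if n_edges < 2:
        raise ValidationError("need at least 2 edges to rewire")
    eset = set(edges)
    attempts = swap_factor * n_edges
    pick = rng.integers(0, n_edges, size=(attempts, 2))
    flip = rng.integers(0, 2, size=attempts)
    done = 0
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in eset or new2 in eset:
            continue
        eset.discard((a, b))
        eset.discard((c, d) if c < d else (d, c))
        eset.add(new1)
        eset.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        done += 1
    n = G.n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    if eset:
        idx = np.array(sorted(eset))
        adj[idx[:, 0], idx[:, 1]] = 1
        adj |= adj.T
    return BinaryNetwork(adj, sparsity=G.sparsity), done


def null_ensemble(G: BinaryNetwork, n_null: int, seed: int) -> NullEnsemble:
    """Ensemble means of Cp and Lp over degree-preserving rewirings."""
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    if G.n_edges < 2:
        raise ValidationError("null ensemble needs at least 2 edges")
    rng = np.random.default_rng(seed)
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    total_swaps = 0
    for r in range(n_null):
        null, done = maslov_sneppen_rewire(G, rng)
        total_swaps += done
        _, cps[r] = clustering(null)
        lps[r] = characteristic_path_length(shortest_paths(null))
    if total_swaps == 0:
        log.warning("graph admits no degree-preserving swap; nulls equal G")
    return NullEnsemble(
        Cp_rand=float(cps.mean()), Lp_rand=float(lps.mean()),
        n_null=n_null, seed=seed,
    )


def small_world(Cp: float, Lp: float, ens: NullEnsemble) -> tuple[float, float, float]:
    """gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    if ens.Cp_rand <= 0 or ens.Lp_rand <= 0:
        raise ValidationError("null ensemble means must be positive")
    gamma = Cp / ens.Cp_rand
    lam = Lp / ens.Lp_rand
    return gamma, lam, gamma / lam


def global_metrics(
    G: BinaryNetwork, n_null: int | None = None, seed: int = 0
) -> GlobalMetrics:
    """Convenience wrapper: Cp, Lp, Eg, Eloc and (optionally) gamma/lambda/sigma."""
    _, cp = clustering(G)
    d = shortest_paths(G)
    lp = characteristic_path_length(d)
    gm = GlobalMetrics(
        Cp=cp, Lp=lp, Eg=global_efficiency(d), Eloc=local_efficiency(G),
        sparsity=G.sparsity,
    )
    if n_null:
        ens = null_ensemble(G, n_null, seed)
        gm.gamma, gm.lambda_, gm.sigma = small_world(cp, lp, ens)
    return gm


def auc_over_sparsity(values, grid: SparsityGrid) -> float:
    """Trapezoidal area under a per-threshold metric curve."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(grid):
        raise ValidationError(
            f"{values.shape[0]} values for {len(grid)} thresholds")
    if len(grid) < 2:
        raise ValidationError("AUC needs at least 2 thresholds")
    return float(np.trapezoid(values, np.asarray(grid.thresholds)))
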