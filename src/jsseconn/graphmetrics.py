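"""Binary graph analysis of the metabolic connectome.

Each weighted network is binarized across a sparsity sweep (fraction of
strongest connections retained, 0.02-0.50 in steps of 0.01, 49
thresholds) and standard global and nodal graph metrics are computed on
every binary graph. Per metric, the sum of its 49 values across the
sweep ("area under the curve" in the threshold sense) gives one feature
per metric per subject. Hubs are nodes whose metric exceeds the mean
plus one standard deviation over all nodes.

Small-world normalization (gamma, lambda, sigma) divides the clustering
coefficient and characteristic path length by their means over a
degree-preserving (Maslov-Sneppen rewired) null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "BinaryGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "HubSet",
    "sparsity_sweep",
    "binarize_at_sparsity",
    "compute_global_metrics",
    "compute_nodal_metrics",
    "generate_null_ensemble",
    "auc_features",
    "identify_hubs",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = (
    "Cp", "Lp", "gamma", "lambda", "sigma",
    "Eglobal", "Elocal", "Q", "Ar", "Hr", "Sr",
)
NODAL_METRIC_NAMES = (
    "degree", "nodal_efficiency", "betweenness", "shortest_path", "clustering",
)

SWEEP_START = 0.02
SWEEP_STOP = 0.50
SWEEP_STEP = 0.01

#: Null-ensemble size for standalone small-world normalization.
DEFAULT_N_NULLS = 100

#: Attempted Maslov-Sneppen swaps per null, as a multiple of edge count.
SWAPS_PER_EDGE = 10


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency with no self-loops."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("no self-loops allowed")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_array(self) -> np.ndarray:
        """(E, 2) array of edges with i < j, lexicographic order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu] == 1
        return np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_array()))
        return g


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    gamma: float
    lam: float
    sigma: float
    Eglobal: float
    Elocal: float
    Q: float
    Ar: float
    Hr: float
    Sr: float

    def as_dict(self) -> dict[str, float]:
        attr = {name: name for name in GLOBAL_METRIC_NAMES}
        attr["lambda"] = "lam"
        return {name: getattr(self, attr[name]) for name in GLOBAL_METRIC_NAMES}


@dataclass
class NodalMetrics:
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    shortest_path: np.ndarray
    clustering: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_NAMES}


@dataclass
class HubSet:
    """Nodes whose metric value exceeds mean + SD over all nodes."""

    metric: str
    members: list[int]
    values: np.ndarray
    threshold: float


def sparsity_sweep() -> np.ndarray:
    """The 49 sparsity thresholds 0.02, 0.03, ..., 0.50."""
    n = int(round((SWEEP_STOP - SWEEP_START) / SWEEP_STEP)) + 1
    return np.round(SWEEP_START + SWEEP_STEP * np.arange(n), 10)


def binarize_at_sparsity(network, sparsity: float) -> BinaryGraph:
    """Retain exactly floor(sparsity * n_pairs) strongest connections.

    Ties are broken by lexicographic (i, j) pair order so the edge set
    is reproducible across runs.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    W = np.asarray(network.weights if hasattr(network, "weights") else network,
                   dtype=np.float64)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    m = int(np.floor(sparsity * n_pairs))
    w = W[iu]
    # stable sort on descending weight keeps lexicographic order among ties
    order = np.argsort(-w, kind="stable")[:m]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[0][order], iu[1][order]] = 1
    A |= A.T
    return BinaryGraph(adjacency=A, sparsity=float(sparsity))


@njit(cache=True)
def _bfs_all_pairs(A):  # pragma: no cover - jitted
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    queue = np.empty(n, dtype=np.int64)
    for src in range(n):
        D[src, src] = 0.0
        head, tail = 0, 1
        queue[0] = src
        while head < tail:
            v = queue[head]
            head += 1
            dv = D[src, v]
            for w in range(n):
                if A[v, w] and np.isinf(D[src, w]):
                    D[src, w] = dv + 1.0
                    queue[tail] = w
                    tail += 1
    return D


@njit(cache=True)
def _brandes(A):  # pragma: no cover - jitted
    """Unnormalized betweenness: sum over unordered pairs of
    sigma_st(v)/sigma_st (Brandes' accumulation)."""
    n = A.shape[0]
    bc = np.zeros(n)
    dist = np.empty(n, dtype=np.int64)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    for s in range(n):
        dist[:] = -1
        sigma[:] = 0.0
        delta[:] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            v = order[head]
            head += 1
            for w in range(n):
                if A[v, w]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        order[tail] = w
                        tail += 1
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
        for k in range(tail - 1, 0, -1):
            w = order[k]
            for v in range(n):
                if A[w, v] and dist[v] == dist[w] - 1 and sigma[w] > 0:
                    delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair counted from both endpoints


def _distances(A: np.ndarray) -> np.ndarray:
    return _bfs_all_pairs(np.ascontiguousarray(A, dtype=np.uint8))


def _clustering(A: np.ndarray) -> np.ndarray:
    Af = A.astype(np.float64)
    triangles = np.diag(Af @ Af @ Af)
    k = Af.sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _char_path_length(D: np.ndarray) -> float:
    off = ~np.eye(D.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        return float("nan")
    return float(D[finite].mean())


def _global_efficiency(D: np.ndarray) -> float:
    off = ~np.eye(D.shape[0], dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def _local_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    eff = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(A[v])
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        eff[v] = _global_efficiency(_distances(sub))
    return float(eff.mean())


def _hierarchy(A: np.ndarray) -> float:
    """Exponent beta of C(k) ~ k^(-beta) over nodes with k > 1, C > 0."""
    k = A.sum(axis=1).astype(np.float64)
    c = _clustering(A)
    use = (k > 1) & (c > 0)
    if use.sum() < 2 or np.unique(k[use]).size < 2:
        return float("nan")
    slope = np.polyfit(np.log(k[use]), np.log(c[use]), 1)[0]
    return float(-slope)


def _synchronization(A: np.ndarray) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max."""
    Af = A.astype(np.float64)
    L = np.diag(Af.sum(axis=1)) - Af
    ev = np.linalg.eigvalsh(L)
    if ev[-1] <= 0:
        return float("nan")
    return float(ev[1] / ev[-1])


def _modularity(g: nx.Graph) -> float:
    communities = nx.community.greedy_modularity_communities(g)
    return float(nx.community.modularity(g, communities))


def _assortativity(g: nx.Graph) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            value = nx.degree_assortativity_coefficient(g)
        except (ZeroDivisionError, ValueError):
            return float("nan")
    return float(value)


def compute_global_metrics(
    graph: BinaryGraph,
    null_ensemble: Optional[Sequence[BinaryGraph]] = None,
) -> GlobalMetrics:
    """All 11 global metrics of a binary graph.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma/lambda,
    with means over the degree-matched null ensemble; they are NaN when
    no ensemble is supplied or the null mean is degenerate.
    Disconnected graphs: Lp averages over connected pairs only;
    efficiencies count unreachable pairs as zero contribution.
    """
    A = graph.adjacency
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    D = _distances(A)
    Cp = float(_clustering(A).mean())
    Lp = _char_path_length(D)
    g = graph.to_networkx()

    gamma = lam = sigma = float("nan")
    if null_ensemble:
        cp_null = np.mean([_clustering(nb.adjacency).mean() for nb in null_ensemble])
        lp_null = np.mean([_char_path_length(_distances(nb.adjacency))
                           for nb in null_ensemble])
        if cp_null > 0:
            gamma = Cp / float(cp_null)
        if np.isfinite(lp_null) and lp_null > 0:
            lam = Lp / float(lp_null)
        if np.isfinite(gamma) and np.isfinite(lam) and lam > 0:
            sigma = gamma / lam

    return GlobalMetrics(
        Cp=Cp,
        Lp=Lp,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        Eglobal=_global_efficiency(D),
        Elocal=_local_efficiency(A),
        Q=_modularity(g),
        Ar=_assortativity(g),
        Hr=_hierarchy(A),
        Sr=_synchronization(A),
    )


def compute_nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    """Degree, nodal efficiency, betweenness, mean shortest path, clustering.

    Betweenness is the unnormalized Brandes sum of pair-fractions
    sigma_st(v)/sigma_st over unordered pairs. Isolated nodes get zero
    efficiency, path length, and clustering.
    """
    A = graph.adjacency
    n = graph.n_nodes
    D = _distances(A)
    degree = A.sum(axis=1).astype(np.float64)

    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    nodal_eff = inv.sum(axis=1) / (n - 1)

    reach = np.isfinite(D) & off
    n_reach = reach.sum(axis=1)
    dsum = np.where(reach, D, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        spl = np.where(n_reach > 0, dsum / np.maximum(n_reach, 1), 0.0)

    betweenness = _brandes(np.ascontiguousarray(A, dtype=np.uint8))

    return NodalMetrics(
        degree=degree,
        nodal_efficiency=nodal_eff,
        betweenness=betweenness,
        shortest_path=spl,
        clustering=_clustering(A),
    )


@njit(cache=True)
def _rewire_edges(edges, adj, n_attempts, seed):  # pragma: no cover - jitted
    state = seed | np.uint64(1)
    n_edges = edges.shape[0]
    for _ in range(n_attempts):
        # xorshift64* pseudo-random stream
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r1 = (state * np.uint64(2685821657736338717)) >> np.uint64(32)
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r2 = (state * np.uint64(2685821657736338717)) >> np.uint64(32)
        e1 = int(r1 % np.uint64(n_edges))
        e2 = int(r2 % np.uint64(n_edges))
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        # alternate the swap orientation pseudo-randomly
        if (r1 ^ r2) & np.uint64(1):
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
    return edges


def generate_null_ensemble(
    graph: BinaryGraph, n_nulls: int = DEFAULT_N_NULLS, seed: int = 0
) -> list[BinaryGraph]:
    """Degree-preserving Maslov-Sneppen rewired surrogates.

    Each null attempts 10x|E| edge swaps; the degree sequence is an
    invariant of the swap, and the ensemble is reproducible from the
    seed.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    base_edges = graph.edge_array()
    seeds = np.random.SeedSequence(seed).generate_state(n_nulls, dtype=np.uint64)
    nulls = []
    for s in seeds:
        edges = base_edges.copy()
        adj = graph.adjacency.astype(np.bool_).copy()
        _rewire_edges(edges, adj, SWAPS_PER_EDGE * edges.shape[0], np.uint64(s))
        A = np.zeros_like(graph.adjacency)
        A[edges[:, 0], edges[:, 1]] = 1
        A |= A.T
        nulls.append(BinaryGraph(adjacency=A, sparsity=graph.sparsity))
    return nulls


def auc_features(
    network,
    thresholds: Optional[np.ndarray] = None,
    n_nulls: int = 20,
    seed: int = 0,
    return_per_threshold: bool = False,
):
    """Sparsity-AUC features: the plain sum of each metric over the sweep.

    Returns ``(global_auc, nodal_auc)`` where ``global_auc`` maps each
    of the 11 global metric names to one value and ``nodal_auc`` maps
    each of the 5 nodal metric names to a per-node vector. Thresholds
    where a normalized metric is undefined (NaN) contribute zero to the
    sum. With ``return_per_threshold`` a tidy per-threshold DataFrame is
    returned as a third element.
    """
    if thresholds is None:
        thresholds = sparsity_sweep()
    n = network.weights.shape[0] if hasattr(network, "weights") else network.shape[0]
    global_series = {name: [] for name in GLOBAL_METRIC_NAMES}
    nodal_series = {name: [] for name in NODAL_METRIC_NAMES}
    for k, s in enumerate(thresholds):
        graph = binarize_at_sparsity(network, float(s))
        if graph.n_edges == 0:
            # tiny parcellations can produce empty graphs at the lowest
            # thresholds; they contribute nothing to the AUC sums
            gm = {name: float("nan") for name in GLOBAL_METRIC_NAMES}
            nm = {name: np.zeros(n) for name in NODAL_METRIC_NAMES}
        else:
            nulls = (generate_null_ensemble(graph, n_nulls=n_nulls,
                                            seed=seed + k)
                     if n_nulls > 0 and graph.n_edges >= 2 else None)
            gm = compute_global_metrics(graph, nulls).as_dict()
            nm = compute_nodal_metrics(graph).as_dict()
        for name in GLOBAL_METRIC_NAMES:
            global_series[name].append(gm[name])
        for name in NODAL_METRIC_NAMES:
            nodal_series[name].append(nm[name])
    global_auc = {name: float(np.nansum(global_series[name]))
                  for name in GLOBAL_METRIC_NAMES}
    nodal_auc = {name: np.asarray(nodal_series[name]).sum(axis=0)
                 for name in NODAL_METRIC_NAMES}
    if not return_per_threshold:
        return global_auc, nodal_auc
    rows = []
    for k, s in enumerate(thresholds):
        for name in GLOBAL_METRIC_NAMES:
            rows.append((float(s), name, "global", global_series[name][k]))
        for name in NODAL_METRIC_NAMES:
            for node in range(n):
                rows.append((float(s), name, node, nodal_series[name][k][node]))
    table = pd.DataFrame(rows, columns=["sparsity", "metric", "node_or_global",
                                        "value"])
    return global_auc, nodal_auc, table


def identify_hubs(
    values: np.ndarray, metric: str = "degree", ddof: int = 0
) -> HubSet:
    """Nodes with value > mean + SD (population SD by default)."""
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("hub values must be finite")
    sd = float(values.std(ddof=ddof))
    threshold = float(values.mean()) + sd
    if sd == 0:
        members: list[int] = []
    else:
        members = [int(i) for i in np.flatnonzero(values > threshold)]
    return HubSet(metric=metric, members=members, values=values,
                  threshold=threshold)
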