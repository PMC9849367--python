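"""Graph-theoretical metrics of thresholded connectivity matrices.

A weighted divergence matrix is binarized at each sparsity level of a grid
(default 0.02-0.50 in steps of 0.01) by keeping the strongest
floor(s * n(n-1)/2) edges, and global plus nodal metrics are computed on
each binary graph.  Per-metric values are aggregated over the grid by
summation (with the mean also reported), so each metric family contributes
one number (global) or one number per node (nodal) to the feature vector.

Global metrics: assortativity (Ar), modularity (Q), hierarchy (Hr), global
and local efficiency, clustering coefficient (Cp), small-world gamma/lambda/
sigma against degree-preserving rewired nulls, characteristic path length
(Lp), and synchronizability (Sr).  Hierarchy and synchronizability follow
the conventional definitions: Hr is the exponent of the power-law relation
between nodal clustering and degree (slope of ln NCp on -ln DC), and Sr is
the ratio of the second-smallest to the largest Laplacian eigenvalue.

Nodal metrics: degree (DC), betweenness (BC), nodal efficiency (Ne), nodal
local efficiency (NLe), nodal clustering (NCp), and nodal shortest path
length (NLp).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from jssenet.network import ConnectivityMatrix

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = (
    "assortativity",
    "modularity",
    "hierarchy",
    "global_efficiency",
    "local_efficiency",
    "clustering",
    "gamma",
    "lambda_",
    "sigma",
    "path_length",
    "synchronization",
)
NODAL_METRIC_NAMES = (
    "degree",
    "betweenness",
    "nodal_efficiency",
    "nodal_local_efficiency",
    "nodal_clustering",
    "nodal_path_length",
)


def default_sparsity_grid() -> np.ndarray:
    """The default threshold grid 0.02..0.50 in steps of 0.01 (49 levels)."""
    return np.round(np.arange(2, 51) * 0.01, 2)


@dataclass(frozen=True)
class BinaryGraph:
    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError("sparsity must lie in (0, 1)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        return G


def binarize_at_sparsity(W: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Keep the floor(s * n(n-1)/2) strongest edges of a weighted matrix.

    Ties are broken by ascending lexicographic (i, j) order so repeated runs
    produce the same graph.
    """
    if not (0.0 < s < 1.0):
        raise ValueError("sparsity must lie in (0, 1)")
    n = W.n_rois
    n_possible = n * (n - 1) // 2
    k = int(np.floor(s * n_possible))
    if k < 1:
        raise ValueError(f"sparsity {s} keeps zero edges for n={n}")
    iu, ju = np.triu_indices(n, k=1)
    w = W.values[iu, ju]
    # lexsort: last key is primary -> strongest weight first, then (i, j) asc
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BinaryGraph(adjacency=adj, sparsity=float(s))


# ---------------------------------------------------------------------------
# distances and efficiencies


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def _pairwise_efficiency(dist: np.ndarray) -> float:
    """Mean of 1/d over all ordered off-diagonal pairs (1/inf = 0)."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _triangles_and_clustering(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ncp = np.where(denom > 0, tri / denom, 0.0)
    return deg, ncp


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    nodal_efficiency: np.ndarray
    nodal_local_efficiency: np.ndarray
    nodal_clustering: np.ndarray
    nodal_path_length: np.ndarray

    def to_matrix(self) -> np.ndarray:
        """Stack the six families into a (6, n) array in canonical order."""
        return np.vstack([getattr(self, name) for name in NODAL_METRIC_NAMES])


def nodal_metrics(G: BinaryGraph) -> NodalMetrics:
    """Per-node metrics of a binary graph.

    Isolated nodes take the degenerate-node conventions: efficiency,
    clustering, and path length all zero.
    """
    adj = np.asarray(G.adjacency, dtype=np.int8)
    n = adj.shape[0]
    dist = _distances(adj)
    deg, ncp = _triangles_and_clustering(adj)

    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)

    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    nlp = np.zeros(n)
    for i in range(n):
        reach = finite[i]
        nlp[i] = dist[i, reach].mean() if reach.any() else 0.0

    nle = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        nle[i] = _pairwise_efficiency(_distances(sub))

    bc_dict = nx.betweenness_centrality(G.to_networkx(), normalized=False)
    bc = np.array([bc_dict[i] for i in range(n)], dtype=np.float64)
    return NodalMetrics(
        degree=deg,
        betweenness=bc,
        nodal_efficiency=ne,
        nodal_local_efficiency=nle,
        nodal_clustering=ncp,
        nodal_path_length=nlp,
    )


@dataclass(frozen=True)
class GlobalMetrics:
    assortativity: float
    modularity: float
    hierarchy: float
    global_efficiency: float
    local_efficiency: float
    clustering: float
    gamma: float
    lambda_: float
    sigma: float
    path_length: float
    synchronization: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in GLOBAL_METRIC_NAMES])


def _characteristic_path_length(dist: np.ndarray) -> float:
    """Mean shortest-path length over connected (finite) off-diagonal pairs."""
    n = dist.shape[0]
    mask = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    if not mask.any():
        return 0.0
    if not np.all(np.isfinite(dist[~np.eye(n, dtype=bool)])):
        logger.debug("graph disconnected; Lp computed over connected pairs only")
    return float(dist[mask].mean())


def _hierarchy(deg: np.ndarray, ncp: np.ndarray) -> float:
    """Slope of ln(NCp) on -ln(DC) over nodes with DC > 1 and NCp > 0."""
    mask = (deg > 1) & (ncp > 0)
    if mask.sum() < 2:
        return 0.0
    x = -np.log(deg[mask])
    y = np.log(ncp[mask])
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def _synchronization(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1).astype(np.float64)
    lap = np.diag(deg) - adj.astype(np.float64)
    eig = np.linalg.eigvalsh(lap)
    if eig[-1] <= 0:
        return 0.0
    return float(eig[1] / eig[-1])


def _assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over edges; 0 for regular graphs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(nx.from_numpy_array(adj))
    return 0.0 if not np.isfinite(r) else float(r)


def greedy_communities(Gnx: nx.Graph) -> list[frozenset]:
    """Deterministic greedy agglomerative modularity maximization (CNM)."""
    return [frozenset(c) for c in nx.community.greedy_modularity_communities(Gnx)]


def _modularity(Gnx: nx.Graph) -> float:
    """Modularity of the best partition found by greedy agglomeration."""
    return float(nx.community.modularity(Gnx, greedy_communities(Gnx)))


def rewire_null(G: BinaryGraph, n_swaps: int | None = None, seed=None) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts 10 * |E| swaps by default; each successful swap replaces edges
    (a, b), (c, d) with (a, d), (c, b) when this creates no self-loop or
    multi-edge.  The degree sequence is invariant.  Graphs admitting no swap
    (for example stars) come back unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    adj = np.array(G.adjacency, dtype=np.int8)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([iu, ju], axis=1)
    m = edges.shape[0]
    if m < 2:
        logger.warning("fewer than 2 edges; returning graph unchanged")
        return G
    attempts = int(n_swaps) if n_swaps is not None else 10 * m
    edge_set = {(int(a), int(b)) for a, b in edges}
    successes = 0
    pick = rng.integers(0, m, size=attempts * 2).reshape(attempts, 2)
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        na = (min(a, d), max(a, d))
        nb = (min(c, b), max(c, b))
        if na in edge_set or nb in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(na)
        edge_set.add(nb)
        edges[e1] = na
        edges[e2] = nb
        successes += 1
    if successes == 0:
        logger.warning("no admissible double-edge swap found; returning graph unchanged")
        return G
    out = np.zeros_like(adj)
    idx = np.array(sorted(edge_set))
    out[idx[:, 0], idx[:, 1]] = 1
    out[idx[:, 1], idx[:, 0]] = 1
    return BinaryGraph(adjacency=out, sparsity=G.sparsity)


def global_metrics(G: BinaryGraph, n_null: int = 100, seed=None) -> GlobalMetrics:
    """All eleven global metrics of one binary graph.

    gamma, lambda, and sigma normalize clustering and path length by the
    means of ``n_null`` degree-preserving rewired null graphs; sigma is the
    ratio gamma / lambda by definition.
    """
    adj = np.asarray(G.adjacency, dtype=np.int8)
    if adj.sum() == 0:
        raise ValueError("graph has no edges")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dist = _distances(adj)
    deg, ncp = _triangles_and_clustering(adj)
    cp = float(ncp.mean())
    lp = _characteristic_path_length(dist)
    eglob = _pairwise_efficiency(dist)

    nle = np.zeros(adj.shape[0])
    for i in range(adj.shape[0]):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        nle[i] = _pairwise_efficiency(_distances(sub))
    eloc = float(nle.mean())

    Gnx = nx.from_numpy_array(adj)
    q = _modularity(Gnx)
    ar = _assortativity(adj)
    hr = _hierarchy(deg, ncp)
    sr = _synchronization(adj)

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    null_seeds = ss.spawn(n_null)
    cp_nulls = np.empty(n_null)
    lp_nulls = np.empty(n_null)
    for k in range(n_null):
        null = rewire_null(G, seed=null_seeds[k])
        nadj = np.asarray(null.adjacency, dtype=np.int8)
        _, nncp = _triangles_and_clustering(nadj)
        cp_nulls[k] = nncp.mean()
        lp_nulls[k] = _characteristic_path_length(_distances(nadj))
    cp_null = float(cp_nulls.mean())
    lp_null = float(lp_nulls.mean())
    # ratio conventions: 0/0 -> 1 (graph indistinguishable from its null);
    # positive/0 cannot be normalized and is reported as NaN with a warning
    gamma = cp / cp_null if cp_null > 0 else (1.0 if cp == 0 else np.nan)
    lam = lp / lp_null if lp_null > 0 else (1.0 if lp == 0 else np.nan)
    if not (np.isfinite(gamma) and np.isfinite(lam)):
        logger.warning("null normalization undefined (cp=%.3g, null mean %.3g)", cp, cp_null)
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else np.nan
    return GlobalMetrics(
        assortativity=ar,
        modularity=q,
        hierarchy=hr,
        global_efficiency=eglob,
        local_efficiency=eloc,
        clustering=cp,
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
        path_length=lp,
        synchronization=sr,
    )


@dataclass
class MetricBundle:
    """Global and nodal metrics aggregated over the sparsity grid."""

    global_sum: np.ndarray  # (11,)
    nodal_sum: np.ndarray  # (6, n)
    global_mean: np.ndarray
    nodal_mean: np.ndarray
    grid: np.ndarray
    per_threshold: list | None = None

    @property
    def n_rois(self) -> int:
        return self.nodal_sum.shape[1]


def metrics_over_grid(
    W: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    n_null: int = 100,
    seed=None,
    keep_trace: bool = False,
) -> MetricBundle:
    """Binarize at every sparsity in ``grid`` and sum metrics across levels."""
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("sparsity grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly ascending")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    level_seeds = ss.spawn(grid.size)
    glob = np.zeros((grid.size, len(GLOBAL_METRIC_NAMES)))
    noda = np.zeros((grid.size, len(NODAL_METRIC_NAMES), W.n_rois))
    trace = [] if keep_trace else None
    for t, s in enumerate(grid):
        G = binarize_at_sparsity(W, float(s))
        gm = global_metrics(G, n_null=n_null, seed=level_seeds[t])
        nm = nodal_metrics(G)
        glob[t] = gm.to_array()
        noda[t] = nm.to_matrix()
        if trace is not None:
            trace.append((float(s), gm, nm))
    return MetricBundle(
        global_sum=glob.sum(axis=0),
        nodal_sum=noda.sum(axis=0),
        global_mean=glob.mean(axis=0),
        nodal_mean=noda.mean(axis=0),
        grid=grid,
        per_threshold=trace,
    )
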