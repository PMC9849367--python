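"""Independent brute-force graph metrics for small graphs.

Everything here is computed from first principles — Floyd-Warshall triple
loops for distances, explicit triple loops for triangles, shortest-path
counting by dynamic programming over distance layers, the Faddeev-LeVerrier
recursion for the Laplacian characteristic polynomial — deliberately
avoiding the code paths (networkx, scipy.csgraph, numpy eigensolvers) used
by the package, so the comparison is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def bf_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), INF)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if adj[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def bf_triangles(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    tri = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j != i and k != i and k != j and adj[i, j] and adj[j, k] and adj[i, k]:
                    tri[i] += 1
    return tri / 2.0  # each triangle counted twice per vertex


def bf_nodal_clustering(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1).astype(float)
    tri = bf_triangles(adj)
    out = np.zeros_like(tri)
    for i in range(len(out)):
        if deg[i] > 1:
            out[i] = tri[i] / (deg[i] * (deg[i] - 1) / 2.0)
    return out


def bf_path_length(dist: np.ndarray) -> float:
    n = dist.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n) if i != j and dist[i, j] < INF]
    return float(np.mean(vals)) if vals else 0.0


def bf_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] < INF:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i and dist[i, j] < INF:
                out[i] += 1.0 / dist[i, j]
        out[i] /= max(n - 1, 1)
    return out


def bf_nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = bf_efficiency(bf_distances(sub))
    return out


def bf_nodal_path_length(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    out = np.zeros(n)
    for i in range(n):
        vals = [dist[i, j] for j in range(n) if j != i and dist[i, j] < INF]
        out[i] = float(np.mean(vals)) if vals else 0.0
    return out


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: summed pair dependencies via path counting."""
    n = adj.shape[0]
    dist = bf_distances(adj)
    # number of shortest paths from s to every node, by distance layers
    nsp = np.zeros((n, n))
    for s in range(n):
        nsp[s, s] = 1.0
        order = sorted(range(n), key=lambda v: dist[s, v])
        for v in order:
            if v == s or dist[s, v] == INF:
                continue
            nsp[s, v] = sum(
                nsp[s, u] for u in range(n) if adj[u, v] and dist[s, u] == dist[s, v] - 1
            )
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s, t] == INF or nsp[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += nsp[s, v] * nsp[v, t] / nsp[s, t]
    return bc


def bf_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over edges (both orientations)."""
    deg = adj.sum(axis=1).astype(float)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs), np.array(ys)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def bf_hierarchy(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1).astype(float)
    ncp = bf_nodal_clustering(adj)
    pts = [(-np.log(deg[i]), np.log(ncp[i])) for i in range(len(deg)) if deg[i] > 1 and ncp[i] > 0]
    if len(pts) < 2:
        return 0.0
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    vx = ((x - x.mean()) ** 2).mean()
    if vx == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def _jacobi_eigenvalues(M: np.ndarray, sweeps: int = 100) -> np.ndarray:
    """Eigenvalues of a symmetric matrix by classical Jacobi rotations.

    Stable for repeated eigenvalues (unlike characteristic-polynomial root
    finding) and written out explicitly so it shares no code with the
    package's eigensolver.
    """
    A = M.astype(float).copy()
    n = A.shape[0]
    for _ in range(sweeps):
        off = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                off += A[p, q] ** 2
        if off < 1e-24:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(A[p, q]) < 1e-15:
                    continue
                theta = (A[q, q] - A[p, p]) / (2.0 * A[p, q])
                t = np.sign(theta) / (abs(theta) + np.sqrt(theta * theta + 1.0))
                if theta == 0.0:
                    t = 1.0
                c = 1.0 / np.sqrt(t * t + 1.0)
                s = t * c
                J = np.eye(n)
                J[p, p] = J[q, q] = c
                J[p, q] = s
                J[q, p] = -s
                A = J.T @ A @ J
    return np.sort(np.diag(A))


def bf_synchronization(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1).astype(float)
    lap = np.diag(deg) - adj.astype(float)
    eig = _jacobi_eigenvalues(lap)
    if eig[-1] <= 0:
        return 0.0
    return float(max(eig[1], 0.0) / eig[-1])


def bf_modularity(adj: np.ndarray, communities) -> float:
    """Newman modularity of a given partition, by the definition."""
    a = adj.astype(float)
    two_m = a.sum()
    deg = a.sum(axis=1)
    label = {}
    for c, nodes in enumerate(communities):
        for v in nodes:
            label[v] = c
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += a[i, j] - deg[i] * deg[j] / two_m
    return q / two_m
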