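"""Independent reference implementations used only to check voxelgraph.

These deliberately use different algorithms (brute force, BFS, dense linear
algebra) than the package so that agreement is informative.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pearson_matrix_bruteforce(data: np.ndarray) -> np.ndarray:
    """Per-pair Pearson correlation via the textbook formula, O(V^2) pairs."""
    T, V = data.shape
    out = np.eye(V)
    for a in range(V):
        for b in range(a + 1, V):
            x, y = data[:, a], data[:, b]
            xc, yc = x - x.mean(), y - y.mean()
            denom = np.sqrt((xc**2).sum() * (yc**2).sum())
            r = 0.0 if denom == 0 else float((xc * yc).sum() / denom)
            out[a, b] = out[b, a] = r
    return out


def components_bfs(n_vertices: int, edges: np.ndarray) -> np.ndarray:
    """Connected-component labels (min member id) by breadth-first search."""
    adj: list[list[int]] = [[] for _ in range(n_vertices)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    labels = np.full(n_vertices, -1, dtype=np.int64)
    for start in range(n_vertices):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = start  # start is the smallest unvisited id in its component
        while queue:
            v = queue.pop()
            for w in adj[v]:
                if labels[w] < 0:
                    labels[w] = start
                    queue.append(w)
    return labels


def triangles_bruteforce(n_vertices: int, edges: np.ndarray) -> np.ndarray:
    """Per-vertex triangle counts by O(n^3) enumeration of all vertex triples."""
    edge_set = {(int(i), int(j)) for i, j in edges}

    def connected(a, b):
        return (min(a, b), max(a, b)) in edge_set

    tc = np.zeros(n_vertices, dtype=np.int64)
    for a, b, c in combinations(range(n_vertices), 3):
        if connected(a, b) and connected(b, c) and connected(a, c):
            tc[a] += 1
            tc[b] += 1
            tc[c] += 1
    return tc


def pagerank_dense(
    n_vertices: int,
    edges: np.ndarray,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """PageRank by dense power iteration on the explicit Google matrix column view."""
    deg = np.zeros(n_vertices)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    M = np.zeros((n_vertices, n_vertices))
    for i, j in edges:
        M[j, i] = 1.0 / deg[i]
        M[i, j] = 1.0 / deg[j]
    M[:, deg == 0] = 1.0 / n_vertices  # dangling vertices spread uniformly
    p = np.full(n_vertices, 1.0 / n_vertices)
    for _ in range(max_iter):
        p_new = (1.0 - damping) / n_vertices + damping * (M @ p)
        if np.abs(p_new - p).sum() < tol:
            return p_new
        p = p_new
    return p


def random_simple_graph(rng: np.random.Generator, n_vertices: int, p: float):
    """Erdos-Renyi G(n, p) as a canonical (i < j) edge array."""
    iu, ju = np.triu_indices(n_vertices, k=1)
    keep = rng.random(iu.size) < p
    return np.column_stack([iu[keep], ju[keep]]).astype(np.int64)
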