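"""Independent brute-force oracles for weighted-graph metrics."""

import numpy as np

# ---------------------------------------------------------------------------

def brute_clustering(W):
    W = np.asarray(W, float)
    n = len(W)
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    What = W / wmax
    c = np.zeros(n)
    for i in range(n):
        k = np.sum(W[i] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j != i and l != i and j != l:
                    total += (What[i, j] * What[i, l] * What[j, l]) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return c


def brute_betweenness(W):
    """All-pairs shortest-path enumeration with fractional path counting."""
    W = np.asarray(W, float)
    n = len(W)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), np.inf)
    np.fill_diagonal(L, 0.0)
    # Floyd-Warshall distances
    D = L.copy()
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    # count shortest paths by DFS enumeration (tiny graphs only)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t or not np.isfinite(D[s, t]):
                continue
            paths = []

            def extend(node, dist, path):
                if node == t and abs(dist - D[s, t]) < 1e-9:
                    paths.append(list(path))
                    return
                for nxt in range(n):
                    if nxt in path or not np.isfinite(L[node, nxt]):
                        continue
                    nd = dist + L[node, nxt]
                    if nd <= D[s, t] + 1e-9:
                        extend(nxt, nd, path + [nxt])

            extend(s, 0.0, [s])
            if not paths:
                continue
            for p in paths:
                for node in p[1:-1]:
                    bc[node] += 1.0 / len(paths)
    return bc


def random_graph(rng, n):
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    mask = rng.random((n, n)) < 0.4
    mask = np.triu(mask, 1)
    W = W * (mask + mask.T)
    np.fill_diagonal(W, 0.0)
    return W
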