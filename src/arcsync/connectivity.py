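"""Within-subject dynamic functional connectivity and graph features.

Sliding tapered windows yield one Fisher-z correlation matrix per window
per subject (all channel pairs).  Each matrix is summarised per node by
three weighted-graph measures: node degree/strength (signed weight sum),
the Onnela weighted clustering coefficient (geometric-mean triangle
intensity on the positive graph), and weighted betweenness centrality
(shortest paths under inverse-weight edge lengths, fractional counting,
endpoints excluded).
"""

from __future__ import annotations

import numpy as np

from .isc import Taper, fisher_z, make_taper, sliding_weighted_corr, window_centers

__all__ = [
    "windowed_fc",
    "vectorize_fc",
    "pair_labels",
    "node_degree",
    "clustering_coefficient",
    "betweenness_centrality",
    "graph_feature_stack",
]


def windowed_fc(data: np.ndarray, fs_hz: float, taper: Taper | None = None, step: int = 1):
    """All-to-all windowed correlation of one subject's channels x time data.

    Returns ``(stack, centers_s)`` with ``stack`` windows x C x C Fisher-z
    matrices (symmetric, zero diagonal).  Cells whose window has zero
    variance in either channel are NaN and excluded downstream.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be channels x time")
    taper = taper or make_taper()
    # weighted Pearson for all ordered pairs via broadcasting over channels
    r = sliding_weighted_corr(data[:, None, :], data[None, :, :], taper, step)  # C,C,W
    z = fisher_z(r)
    z = np.moveaxis(z, -1, 0)  # W,C,C
    for w in range(z.shape[0]):
        np.fill_diagonal(z[w], 0.0)
    z = 0.5 * (z + np.swapaxes(z, 1, 2))
    centers = window_centers(data.shape[-1], taper.length, step, fs_hz)
    return z, centers


def pair_labels(channel_names) -> list:
    """Upper-triangle channel-pair labels in vectorisation order."""
    names = list(channel_names)
    return [f"{names[i]}-{names[j]}" for i in range(len(names)) for j in range(i + 1, len(names))]


def vectorize_fc(stack: np.ndarray) -> np.ndarray:
    """windows x C x C -> windows x C(C-1)/2 upper-triangle features."""
    C = stack.shape[-1]
    iu = np.triu_indices(C, k=1)
    return stack[..., iu[0], iu[1]]


def _positive_graph(W: np.ndarray, neg_mode: str) -> np.ndarray:
    W = np.asarray(W, float).copy()
    np.fill_diagonal(W, 0.0)
    if neg_mode == "zero":
        return np.where(W > 0, W, 0.0)
    if neg_mode == "abs":
        return np.abs(W)
    raise ValueError("neg_mode must be 'zero' or 'abs'")


def node_degree(W: np.ndarray) -> np.ndarray:
    """Signed node strength: row sums of the weight matrix (diagonal ignored)."""
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W.sum(axis=1)


def clustering_coefficient(W: np.ndarray, neg_mode: str = "zero") -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    Weights are restricted to the positive graph (or absolutised), rescaled
    by the maximum weight, and triangle intensities averaged as geometric
    means:  c_i = sum_{jk} (w_ij w_ik w_jk)^(1/3) / (k_i (k_i - 1)), with
    k_i the binary degree; nodes with fewer than two neighbours get 0.
    """
    Wp = _positive_graph(W, neg_mode)
    wmax = Wp.max()
    if wmax == 0:
        return np.zeros(Wp.shape[0])
    K = np.cbrt(Wp / wmax)
    numer = np.diag(K @ K @ K)
    deg = (Wp > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = numer / denom
    return np.where(denom > 0, c, 0.0)


def betweenness_centrality(W: np.ndarray, neg_mode: str = "zero") -> np.ndarray:
    """Weighted betweenness with inverse-weight lengths (Brandes, endpoints out).

    Stronger correlations mean shorter paths: edge length = 1/weight on the
    positive graph; absent edges are unreachable and contribute nothing.
    """
    import networkx as nx

    Wp = _positive_graph(W, neg_mode)
    C = Wp.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(C))
    ii, jj = np.nonzero(np.triu(Wp, k=1))
    G.add_weighted_edges_from(
        (int(i), int(j), 1.0 / Wp[i, j]) for i, j in zip(ii, jj)
    )
    bc = nx.betweenness_centrality(G, weight="weight", normalized=False)
    return np.array([bc[i] for i in range(C)])


def graph_feature_stack(fc_stack: np.ndarray, features=("nd", "cc", "bc"),
                        neg_mode: str = "zero") -> dict:
    """Per-window graph features of a windows x C x C Fisher-z stack.

    NaN cells (degenerate windows) are treated as absent edges.  Returns a
    dict feature -> windows x C.
    """
    fc_stack = np.nan_to_num(np.asarray(fc_stack, float), nan=0.0)
    W, C, _ = fc_stack.shape
    out = {f: np.empty((W, C)) for f in features}
    for w in range(W):
        M = fc_stack[w]
        if "nd" in out:
            out["nd"][w] = node_degree(M)
        if "cc" in out:
            out["cc"][w] = clustering_coefficient(M, neg_mode)
        if "bc" in out:
            out["bc"][w] = betweenness_centrality(M, neg_mode)
    return out
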