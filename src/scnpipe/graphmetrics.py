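"""Weighted graph metrics for SCN matrices (the "M" feature sets).

Metrics follow the weighted connectivity-toolbox conventions: shortest
paths use edge lengths 1/w, efficiency averages inverse path lengths
(unreachable pairs contribute zero), and transitivity uses geometric-mean
triangle intensities.  Because REF-SCN edges may be negative, weights are
first mapped to [0, 1] by taking absolute values and dividing by the
matrix maximum ("abs" policy; "clip" zeroes negative edges instead).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .scn import SCNMatrix

__all__ = [
    "prepare_weights",
    "strength",
    "global_efficiency",
    "transitivity",
    "eigenvector_centrality",
    "local_efficiency",
    "assemble_metric_features",
    "metric_feature_names",
]


def _as_matrix(W) -> np.ndarray:
    M = W.matrix if isinstance(W, SCNMatrix) else np.asarray(W, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("expected a symmetric square matrix")
    return M.astype(float)


def prepare_weights(W, negative: str = "abs") -> np.ndarray:
    """Map an SCN to non-negative weights normalized to [0, 1].

    ``negative='abs'`` (default) takes absolute values; ``'clip'`` zeroes
    negative edges.  The result is divided by its maximum; an all-zero
    matrix is returned unchanged.
    """
    M = _as_matrix(W).copy()
    np.fill_diagonal(M, 0.0)
    if negative == "abs":
        M = np.abs(M)
    elif negative == "clip":
        M = np.clip(M, 0.0, None)
    else:
        raise ValueError("negative must be 'abs' or 'clip'")
    mx = M.max()
    return M / mx if mx > 0 else M


def strength(Wn: np.ndarray) -> np.ndarray:
    """Node strength: sum of incident edge weights."""
    return _as_matrix(Wn).sum(axis=1)


def _shortest_path_lengths(Wn: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(Wn > 0, 1.0 / np.where(Wn > 0, Wn, 1.0), 0.0)
    return dijkstra(csr_matrix(L), directed=False)


def global_efficiency(Wn: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Path lengths use 1/w edge lengths; disconnected pairs contribute 0.
    """
    M = _as_matrix(Wn)
    n = M.shape[0]
    if n < 2:
        return 0.0
    D = _shortest_path_lengths(M)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def transitivity(Wn: np.ndarray) -> float:
    """Weighted transitivity: sum of geometric-mean triangle intensities
    over sum of k_i(k_i - 1) with k the binary degree; 0 if no node has
    degree >= 2."""
    M = _as_matrix(Wn)
    k = (M > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    C = np.cbrt(M)
    num = float(np.trace(C @ C @ C))
    return num / denom


def eigenvector_centrality(Wn: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 10000) -> np.ndarray:
    """Leading eigenvector by power iteration, scaled to max 1.

    All-zero matrices yield the zero vector.  For non-negative symmetric
    input the Perron vector is non-negative.
    """
    M = _as_matrix(Wn)
    n = M.shape[0]
    if M.max() <= 0:
        return np.zeros(n)
    # positive diagonal shift: eigenvectors unchanged, Perron value made
    # strictly dominant so bipartite components cannot oscillate
    M = M + np.eye(n) * M.max()
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = M @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(n)
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max()


def local_efficiency(Wn: np.ndarray) -> np.ndarray:
    """Per-node global efficiency of the neighbor-induced subgraph
    (0 for nodes with fewer than 2 neighbors)."""
    M = _as_matrix(Wn)
    n = M.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(M[i] > 0)
        if nb.size < 2:
            continue
        out[i] = global_efficiency(M[np.ix_(nb, nb)])
    return out


def assemble_metric_features(W, negative: str = "abs") -> np.ndarray:
    """Fixed-order metric vector of length 3d + 2.

    Order: strength block (d), eigenvector-centrality block (d), local-
    efficiency block (d), global efficiency (1), transitivity (1).
    """
    Wn = prepare_weights(W, negative=negative)
    return np.concatenate([
        strength(Wn),
        eigenvector_centrality(Wn),
        local_efficiency(Wn),
        [global_efficiency(Wn)],
        [transitivity(Wn)],
    ])


def metric_feature_names(d: int) -> list:
    return ([f"strength_{r}" for r in range(d)]
            + [f"eigcent_{r}" for r in range(d)]
            + [f"localeff_{r}" for r in range(d)]
            + ["globaleff", "transitivity"])
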