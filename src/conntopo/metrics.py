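"""Weighted graph-topology metrics for structural connectomes.

All functions operate on symmetric, zero-diagonal, non-negative adjacency
matrices (``numpy.ndarray``, shape ``(N, N)``).  Edge weights are
connection strengths; topological *distance* along an edge is the inverse
weight ``1/w``, the standard convention for FN·FA-weighted connectomes.

Conventions
-----------
* Clustering uses the Onnela geometric-mean triangle intensity with weights
  normalised by the graph-wide maximum, so that on binary graphs it reduces
  to triangles / possible triangles.
* Characteristic path length on disconnected graphs averages over finite
  pairs and reports the number of excluded (unreachable) unordered pairs.
* Efficiencies treat unreachable pairs as contributing zero.
* The small-world index is sigma = gamma / lambda with gamma and lambda
  normalised by the mean clustering / path length of matched random
  networks (degree sequence and weight multiset preserved).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "degree_centrality",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "clustering_coefficients",
    "local_efficiency",
    "betweenness_centrality",
    "matched_random_networks",
    "iter_matched_random",
    "small_world_indices",
    "auc_over_sparsity",
    "detect_hubs",
    "graph_global_metrics",
    "graph_nodal_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("Ne", "Bc", "Dc")


def _check_adjacency(W: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=tol):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency matrix must be non-negative")
    if np.any(np.diagonal(W) != 0):
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    return W


def degree_centrality(W: np.ndarray) -> np.ndarray:
    """Number of edges incident to each node (count of nonzero entries)."""
    W = _check_adjacency(W)
    return (W > 0).sum(axis=1).astype(int)


def shortest_path_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest topological distances with edge length 1/weight.

    Returns an ``(N, N)`` matrix with zeros on the diagonal and ``inf`` for
    unreachable pairs.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    rows, cols = np.nonzero(W)
    if rows.size == 0:
        D = np.full((n, n), np.inf)
        np.fill_diagonal(D, 0.0)
        return D
    lengths = 1.0 / W[rows, cols]
    graph = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    return _csgraph_shortest_path(graph, method="D", directed=False)


def characteristic_path_length(D: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path distance over reachable pairs.

    Returns ``(Lp, n_excluded)`` where ``n_excluded`` is the number of
    unordered node pairs with infinite distance (excluded from the mean).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    if not finite.any():
        raise ValueError("no finite shortest-path distances: graph fully disconnected")
    return float(vals[finite].mean()), n_excluded


def _inverse_distances(D: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        return 0.0
    inv = _inverse_distances(D)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(D: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes (Ne)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    inv = _inverse_distances(D)
    return inv.sum(axis=1) / (n - 1)


def clustering_coefficients(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and its mean Cp.

    Weights are scaled by the graph maximum before computing the
    geometric-mean triangle intensity; nodes of degree < 2 score 0.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    cr = np.cbrt(W / wmax)
    # diagonal of cr^3 counts each closed neighbour pair twice
    num = np.einsum("ij,jk,ki->i", cr, cr, cr)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def _floyd_warshall_dense(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on a small dense length matrix (inf = no edge)."""
    D = L.copy()
    for k in range(D.shape[0]):
        np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :], out=D)
    return D


def local_efficiency(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighbour-induced subgraph (Eloc).

    Nodes with fewer than two neighbours score 0 by convention.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i])
        m = nbrs.size
        if m < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        L = np.full((m, m), np.inf)
        nz = sub > 0
        L[nz] = 1.0 / sub[nz]
        np.fill_diagonal(L, 0.0)
        D = _floyd_warshall_dense(L)
        inv = _inverse_distances(D)
        eloc[i] = inv.sum() / (m * (m - 1))
    return eloc, float(eloc.mean()) if n else 0.0


def betweenness_centrality(W: np.ndarray) -> np.ndarray:
    """Unnormalised shortest-path betweenness (Brandes), distances 1/w.

    Each unordered source-target pair contributes its fraction of shortest
    paths through the node, so a star centre with ``m`` leaves scores
    ``C(m, 2)``.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    nz = W[iu, ju] > 0
    G.add_weighted_edges_from(
        zip(iu[nz].tolist(), ju[nz].tolist(), (1.0 / W[iu, ju][nz]).tolist()),
        weight="length",
    )
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[v] for v in range(n)])


# ---------------------------------------------------------------------------
# Matched random networks (degree sequence + weight multiset preserved)
# ---------------------------------------------------------------------------


def _rewire_edges(
    edges: list[tuple[int, int]],
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> tuple[list[tuple[int, int]], int]:
    """Degree-preserving double-edge swaps; returns (new edges, n swaps)."""
    E = len(edges)
    if E < 2:
        return list(edges), 0
    edges = [tuple(sorted(e)) for e in edges]
    edge_set = set(edges)
    target = swaps_per_edge * E
    max_tries = 40 * target
    swaps = 0
    tries = 0
    while swaps < target and tries < max_tries:
        batch = min(2 * (target - swaps) + 8, 8192)
        idx = rng.integers(0, E, size=(batch, 2)).tolist()
        flips = (rng.random(batch) < 0.5).tolist()
        for (e1, e2), flip in zip(idx, flips):
            tries += 1
            if swaps >= target or tries >= max_tries:
                break
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip:
                c, d = d, c
            if len({a, b, c, d}) < 4:
                continue
            new1 = (a, c) if a < c else (c, a)
            new2 = (b, d) if b < d else (d, b)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.remove(edges[e1])
            edge_set.remove(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps += 1
    return edges, swaps


def iter_matched_random(
    W: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> Iterator[np.ndarray]:
    """Yield matched random networks one at a time (memory-light path).

    Each member preserves the degree sequence exactly (double-edge swaps)
    and the edge-weight multiset (weights reassigned in random order to the
    rewired topology).  If the topology admits no swap (e.g. a complete
    graph), members are weight-shuffled copies and a warning is logged.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    nz = W[iu, ju] > 0
    base_edges = list(zip(iu[nz].tolist(), ju[nz].tolist()))
    weights = W[iu, ju][nz]
    warned = False
    for _ in range(n_random):
        edges, swaps = _rewire_edges(base_edges, rng, swaps_per_edge)
        if swaps == 0 and len(base_edges) >= 2 and not warned:
            warnings.warn(
                "no valid degree-preserving swap found; matched networks are "
                "weight-shuffled copies of the original topology",
                stacklevel=2,
            )
            warned = True
        R = np.zeros_like(W)
        perm = rng.permutation(len(weights))
        ea = np.fromiter((e[0] for e in edges), dtype=int, count=len(edges))
        eb = np.fromiter((e[1] for e in edges), dtype=int, count=len(edges))
        R[ea, eb] = weights[perm]
        R[eb, ea] = weights[perm]
        yield R


def matched_random_networks(
    W: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> list[np.ndarray]:
    """Materialised list of matched random networks (see iter_matched_random)."""
    return list(iter_matched_random(W, n_random, rng, swaps_per_edge))


def small_world_indices(
    W: np.ndarray, ensemble: Iterable[np.ndarray]
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of W against an ensemble of matched networks.

    gamma = Cp / mean(Cp_rand), lambda = Lp / mean(Lp_rand),
    sigma = gamma / lambda.
    """
    _, cp = clustering_coefficients(W)
    lp, _ = characteristic_path_length(shortest_path_matrix(W))
    cps, lps = [], []
    for R in ensemble:
        _, cpr = clustering_coefficients(R)
        lpr, _ = characteristic_path_length(shortest_path_matrix(R))
        cps.append(cpr)
        lps.append(lpr)
    if not cps:
        raise ValueError("ensemble is empty")
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    if cp_rand == 0:
        raise ValueError("mean clustering of the random ensemble is zero")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


def auc_over_sparsity(values: Sequence[float], grid: Sequence[float]) -> float:
    """Left Riemann sum of a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"values/grid length mismatch: {values.shape} vs {grid.shape}"
        )
    if grid.size < 2:
        raise ValueError("sparsity grid must have at least two thresholds")
    step = float(grid[1] - grid[0])
    return float(values.sum() * step)


def detect_hubs(values: Sequence[float]) -> np.ndarray:
    """Hub nodes: value >= mean + 1 sample SD (ddof=1) across regions.

    Returns node indices; empty when the SD is zero (all values equal).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("hub detection needs at least two regions")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(values >= values.mean() + sd)


# ---------------------------------------------------------------------------
# Per-graph bundles used by the pipeline
# ---------------------------------------------------------------------------


def graph_global_metrics(
    W: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> dict[str, float]:
    """Cp, Lp, Eg, Eloc plus gamma/lambda/sigma for one (thresholded) graph.

    With ``n_random == 0`` the normalised indices are NaN.
    """
    _, cp = clustering_coefficients(W)
    D = shortest_path_matrix(W)
    lp, _ = characteristic_path_length(D)
    eg = global_efficiency(D)
    _, eloc = local_efficiency(W)
    out = {"Cp": cp, "Lp": lp, "Eg": eg, "Eloc": eloc}
    if n_random > 0:
        cps, lps = [], []
        for R in iter_matched_random(W, n_random, rng, swaps_per_edge):
            _, cpr = clustering_coefficients(R)
            lpr, _ = characteristic_path_length(shortest_path_matrix(R))
            cps.append(cpr)
            lps.append(lpr)
        cp_rand = float(np.mean(cps))
        lp_rand = float(np.mean(lps))
        gamma = cp / cp_rand if cp_rand > 0 else np.nan
        lam = lp / lp_rand if lp_rand > 0 else np.nan
        out["gamma"] = gamma
        out["lambda"] = lam
        out["sigma"] = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) else np.nan
    else:
        out["gamma"] = out["lambda"] = out["sigma"] = np.nan
    return out


def graph_nodal_metrics(W: np.ndarray) -> dict[str, np.ndarray]:
    """Ne, Bc, Dc for one (thresholded) graph."""
    D = shortest_path_matrix(W)
    return {
        "Ne": nodal_efficiency(D),
        "Bc": betweenness_centrality(W),
        "Dc": degree_centrality(W).astype(float),
    }
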