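"""Brute-force reference implementations for small graphs.

These oracles are deliberately naive — Floyd-Warshall by triple loop,
exhaustive simple-path enumeration for betweenness, direct triangle
counting for clustering — and share no code with the package, so they can
serve as independent references for the fast implementations.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def fw_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances (length = 1/weight), triple loop."""
    n = W.shape[0]
    D = np.full((n, n), INF)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def char_path_length(W: np.ndarray) -> tuple[float, int]:
    D = fw_distances(W)
    n = D.shape[0]
    vals, excluded = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < INF:
                vals.append(D[i, j])
            else:
                excluded += 1
    if not vals:
        raise ValueError("fully disconnected")
    return sum(vals) / len(vals), excluded


def global_eff(W: np.ndarray) -> float:
    D = fw_distances(W)
    n = D.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] < INF:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def nodal_eff(W: np.ndarray) -> np.ndarray:
    D = fw_distances(W)
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] < INF:
                out[i] += 1.0 / D[i, j]
        out[i] /= max(n - 1, 1)
    return out


def degree(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    return np.array([sum(1 for j in range(n) if j != i and W[i, j] > 0)
                     for i in range(n)])


def clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering (max-normalised), direct triple loop."""
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    H = W / wmax
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                s += (H[i, j] * H[i, h] * H[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def local_eff(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = global_eff(sub)
    return out


def _simple_paths(W: np.ndarray, s: int, t: int) -> list[tuple[float, tuple[int, ...]]]:
    """All simple paths s->t with their lengths (sum of 1/w)."""
    n = W.shape[0]
    results = []

    def dfs(node, visited, length, path):
        if node == t:
            results.append((length, tuple(path)))
            return
        for nxt in range(n):
            if W[node, nxt] > 0 and nxt not in visited:
                dfs(nxt, visited | {nxt}, length + 1.0 / W[node, nxt], path + [nxt])

    dfs(s, {s}, 0.0, [s])
    return results


def betweenness(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Exhaustive-enumeration betweenness over unordered pairs."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _simple_paths(W, s, t)
            if not paths:
                continue
            dmin = min(length for length, _ in paths)
            shortest = [p for length, p in paths if length <= dmin + tol]
            total = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                bc[v] += through / total
    return bc


def bh_stepup(pvals: list[float], q: float) -> tuple[list[float], list[bool]]:
    """Hand-rolled Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    reject = [False] * m
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            kmax = rank
    for rank, i in enumerate(order, start=1):
        if rank <= kmax:
            reject[i] = True
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj, reject


def spearman_midrank(x, y) -> float:
    """Spearman rho via explicit midranks and the Pearson formula."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den
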