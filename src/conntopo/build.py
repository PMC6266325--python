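"""Construction of weighted structural networks from FN/FA matrices.

The edge weight between regions i and j is

    w_ij = FN_ij * FA_ij / ((vol_i + vol_j) / 2)

with connections carrying fewer than ``fn_threshold`` streamlines removed
(default 3).  Networks are then proportionally thresholded over a sparsity
grid: at sparsity ``s`` the ``round(s * N(N-1)/2)`` strongest edges are
retained with their weights (weighted analysis; no binarisation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics

__all__ = [
    "SubjectConnectome",
    "compute_edge_weights",
    "threshold_by_sparsity",
    "build_sparsity_grid",
    "sparsity_admissibility",
    "validate_sparsity_range",
]


@dataclass
class SubjectConnectome:
    """Per-subject connectivity data and the derived weight matrix."""

    subject_id: str
    fn: np.ndarray  # streamline counts, symmetric non-negative integers
    fa: np.ndarray  # mean fractional anisotropy per connection, in [0, 1]
    volumes: np.ndarray  # per-region volumes, positive
    weights: np.ndarray | None = field(default=None)

    def build_weights(self, fn_threshold: int = 3) -> np.ndarray:
        self.weights = compute_edge_weights(self.fn, self.fa, self.volumes, fn_threshold)
        return self.weights


def compute_edge_weights(
    fn: np.ndarray,
    fa: np.ndarray,
    volumes: np.ndarray,
    fn_threshold: int = 3,
) -> np.ndarray:
    """Weight matrix w = FN * FA / mean(volumes), FN below threshold zeroed."""
    fn = np.asarray(fn, dtype=float)
    fa = np.asarray(fa, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if fn.shape != fa.shape or fn.ndim != 2 or fn.shape[0] != fn.shape[1]:
        raise ValueError("FN and FA must be square matrices of identical shape")
    n = fn.shape[0]
    if volumes.shape != (n,):
        raise ValueError(f"volumes must have length {n}")
    if np.any(volumes <= 0):
        raise ValueError("region volumes must be positive")
    if not np.allclose(fn, fn.T) or not np.allclose(fa, fa.T):
        raise ValueError("FN and FA must be symmetric")
    pair_vol = (volumes[:, None] + volumes[None, :]) / 2.0
    W = np.where(fn >= fn_threshold, fn * fa / pair_vol, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def threshold_by_sparsity(W: np.ndarray, s: float) -> np.ndarray:
    """Retain the K = round(s * N(N-1)/2) strongest edges, weights kept.

    Ties at the cutoff are broken by lexicographic (i, j) order.  If fewer
    than K nonzero edges exist the matrix is returned with all of them (a
    warning is issued).
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must be in (0, 1)")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    k_target = int(math.floor(s * n * (n - 1) / 2 + 0.5))  # round half up
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    nz = w > 0
    n_nonzero = int(nz.sum())
    out = np.zeros_like(W)
    if n_nonzero <= k_target:
        if n_nonzero < k_target:
            warnings.warn(
                f"requested {k_target} edges at sparsity {s} but only "
                f"{n_nonzero} nonzero edges exist; retaining all",
                stacklevel=2,
            )
        keep = np.flatnonzero(nz)
    else:
        cand = np.flatnonzero(nz)
        order = np.lexsort((ju[cand], iu[cand], -w[cand]))
        keep = cand[order[:k_target]]
    out[iu[keep], ju[keep]] = w[keep]
    out[ju[keep], iu[keep]] = w[keep]
    return out


def build_sparsity_grid(
    sparsity_min: float, sparsity_max: float, sparsity_step: float
) -> np.ndarray:
    """Arithmetic sequence min, min+step, ... <= max (1e-9 tolerance)."""
    if sparsity_min > sparsity_max:
        raise ValueError("sparsity_min must not exceed sparsity_max")
    if sparsity_step <= 0:
        raise ValueError("sparsity_step must be positive")
    if not (0 < sparsity_min and sparsity_max < 1):
        raise ValueError("sparsity range must lie within (0, 1)")
    count = int(math.floor((sparsity_max - sparsity_min) / sparsity_step + 1e-9)) + 1
    return sparsity_min + sparsity_step * np.arange(count)


def sparsity_admissibility(
    sigmas: np.ndarray,
    grid: Sequence[float],
    n_nodes: int,
    log_base: str = "natural",
    sigma_min: float = 1.1,
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Admissible sparsity range from precomputed per-subject sigma values.

    ``sigmas`` has shape (n_subjects, n_thresholds).  A threshold is
    admissible when the analytic mean degree ``s * (N - 1)`` exceeds
    ``log(N)`` (base configurable) and every subject's small-world index
    exceeds ``sigma_min``.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if sigmas.ndim != 2 or sigmas.shape[1] != grid.size:
        raise ValueError("sigmas must be (n_subjects, n_thresholds)")
    if log_base == "natural":
        log_n = math.log(n_nodes)
    elif log_base == "base10":
        log_n = math.log10(n_nodes)
    else:
        raise ValueError("log_base must be 'natural' or 'base10'")
    mean_degree = grid * (n_nodes - 1)
    degree_ok = mean_degree > log_n
    min_sigma = sigmas.min(axis=0)
    sigma_ok = min_sigma > sigma_min
    admissible = degree_ok & sigma_ok
    diag = pd.DataFrame(
        {
            "sparsity": grid,
            "mean_degree": mean_degree,
            "log_n": log_n,
            "degree_ok": degree_ok,
            "min_sigma": min_sigma,
            "sigma_ok": sigma_ok,
            "admissible": admissible,
        }
    )
    if not admissible.any():
        warnings.warn("no sparsity threshold satisfies both admissibility rules",
                      stacklevel=2)
        return None, None, diag
    adm = grid[admissible]
    return float(adm.min()), float(adm.max()), diag


def validate_sparsity_range(
    weight_matrices: Sequence[np.ndarray],
    grid: Sequence[float],
    n_random: int,
    rng: np.random.Generator,
    log_base: str = "natural",
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Admissible sparsity range for a cohort of (unthresholded) networks.

    Applies the two selection rules: mean degree ``s (N-1) > log(N)`` at the
    low end and min-over-subjects sigma > 1.1 at the high end.  Sigma is
    computed against ``n_random`` matched random networks per subject per
    threshold, so this is the expensive diagnostic path; the pipeline reuses
    already-computed metric curves via :func:`sparsity_admissibility`.
    """
    grid = np.asarray(grid, dtype=float)
    n_nodes = weight_matrices[0].shape[0]
    sigmas = np.empty((len(weight_matrices), grid.size))
    for i, W in enumerate(weight_matrices):
        for j, s in enumerate(grid):
            Wt = threshold_by_sparsity(W, float(s))
            g = metrics.graph_global_metrics(Wt, n_random, rng)
            sigmas[i, j] = g["sigma"]
    return sparsity_admissibility(sigmas, grid, n_nodes, log_base)
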