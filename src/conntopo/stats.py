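"""Covariate-adjusted permutation inference for group comparisons.

The comparison of a network metric between patients and controls follows a
residualise-then-permute scheme: metric values (AUC across the sparsity
grid, or the value at a fixed sparsity) are residualised on an intercept
plus age, sex and education by pooled OLS, the observed statistic is the
difference of adjusted group means, and its two-sided p-value comes from
permuting group labels.  When the number of distinct label splits is small
enough the exact enumeration replaces Monte-Carlo sampling.  FDR control is
Benjamini-Hochberg within each metric family (the 7 global metrics; the N
nodes of each nodal metric; each hemisphere stratum).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import metrics as _metrics

__all__ = [
    "adjust_covariates",
    "permutation_test",
    "permutation_test_many",
    "bh_fdr",
    "compare_global_metrics",
    "compare_nodal_metrics",
    "hemisphere_analysis",
]

COVARIATE_COLUMNS = ("age", "sex", "education")


def _design_matrix(covariates) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    return X


def adjust_covariates(y: np.ndarray, covariates) -> np.ndarray:
    """OLS residuals of y on intercept + covariates, both groups pooled.

    ``y`` may be a vector or an ``(n, k)`` matrix (column-wise residuals).
    """
    y = np.asarray(y, dtype=float)
    X = _design_matrix(covariates)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("y and covariates must have the same number of rows")
    if n < X.shape[1] + 1:
        raise ValueError("too few subjects for covariate adjustment")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _exact_split_indices(n: int, n_a: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n_a)), dtype=int)


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test of mean(a) - mean(b).

    Uses exact enumeration of all C(n_a + n_b, n_a) splits when that count
    does not exceed ``n_perm`` (p = fraction of splits at least as extreme);
    otherwise Monte-Carlo sampling with the add-one estimator
    p = (1 + #extreme) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    obs, p = _group_diff_pvalues(
        np.concatenate([a, b])[:, None],
        np.arange(a.size + b.size) < a.size,
        n_perm,
        rng if rng is not None else np.random.default_rng(0),
    )
    return float(obs[0]), float(p[0])


def _group_diff_pvalues(
    V: np.ndarray,
    is_a: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed mean differences and permutation p-values, column-wise.

    ``V`` is (n_subjects, k); all columns share the same permutations.
    """
    V = np.asarray(V, dtype=float)
    is_a = np.asarray(is_a, dtype=bool)
    n = V.shape[0]
    n_a = int(is_a.sum())
    n_b = n - n_a
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    obs = V[is_a].mean(axis=0) - V[~is_a].mean(axis=0)
    tol = 1e-12
    total = comb(n, n_a)
    col_sums = V.sum(axis=0)
    if total <= n_perm:
        idx = _exact_split_indices(n, n_a)  # (total, n_a)
        sums_a = V[idx].sum(axis=1)  # (total, k)
        diffs = sums_a / n_a - (col_sums - sums_a) / n_b
        count = (np.abs(diffs) >= np.abs(obs) - tol).sum(axis=0)
        p = count / total
    else:
        keys = rng.random((n_perm, n))
        order = np.argsort(keys, axis=1)
        M = is_a[order]  # (n_perm, n) permuted labels
        sums_a = M.astype(float) @ V
        diffs = sums_a / n_a - (col_sums - sums_a) / n_b
        count = (np.abs(diffs) >= np.abs(obs) - tol).sum(axis=0)
        p = (1 + count) / (n_perm + 1)
    p = np.where(np.isfinite(obs), p, np.nan)  # undefined metric -> no test
    return obs, p


def permutation_test_many(
    V: np.ndarray,
    is_a: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised permutation tests over the columns of ``V``.

    All columns share the same label permutations; exact enumeration is
    used when feasible (see :func:`permutation_test`).
    """
    return _group_diff_pvalues(
        V, is_a, n_perm, rng if rng is not None else np.random.default_rng(0)
    )


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _fdr_with_nan(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """BH-FDR tolerating NaN p-values (excluded from the family)."""
    p = np.asarray(p, dtype=float)
    p_adj = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        p_adj[ok], reject[ok] = bh_fdr(p[ok], q)
    return p_adj, reject


# ---------------------------------------------------------------------------
# Cohort-level comparisons
# ---------------------------------------------------------------------------


def _subject_scalars(
    curves: np.ndarray, grid: np.ndarray, at_sparsity: float | None
) -> np.ndarray:
    """Per-subject scalar from a (n_subjects, n_thresholds) curve array."""
    if at_sparsity is None:
        step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
        return curves.sum(axis=1) * step
    j = int(np.argmin(np.abs(grid - at_sparsity)))
    return curves[:, j]


def compare_global_metrics(
    global_curves: dict[str, np.ndarray],
    is_patient: np.ndarray,
    covariates: np.ndarray,
    grid: Sequence[float],
    n_perm: int = 10000,
    q: float = 0.05,
    rng: np.random.Generator | None = None,
    at_sparsity: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group comparison of the seven global metrics.

    ``global_curves`` maps metric name to an (n_subjects, n_thresholds)
    array.  Each metric is summarised per subject by its AUC across the
    sparsity grid (or the value at ``at_sparsity``), residualised on the
    covariates, and compared by permutation test; BH-FDR is applied across
    the metric family.  Returns the primary table and a secondary
    per-threshold table (uncorrected p-values, for curve plots).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = np.asarray(grid, dtype=float)
    names = [m for m in _metrics.GLOBAL_METRIC_NAMES if m in global_curves]
    scalars = np.column_stack(
        [_subject_scalars(global_curves[m], grid, at_sparsity) for m in names]
    )
    resid = adjust_covariates(scalars, covariates)
    obs, p = permutation_test_many(resid, is_patient, n_perm, rng)
    p_adj, reject = _fdr_with_nan(p, q)
    primary = pd.DataFrame(
        {
            "metric": names,
            "observed_diff": obs,
            "p": p,
            "p_fdr": p_adj,
            "rejected": reject,
        }
    )
    # secondary: one test per (metric, threshold), shared permutations
    cols, meta = [], []
    for m in names:
        curves = global_curves[m]
        for j, s in enumerate(grid):
            cols.append(curves[:, j])
            meta.append((m, float(s)))
    resid_thr = adjust_covariates(np.column_stack(cols), covariates)
    obs_thr, p_thr = permutation_test_many(resid_thr, is_patient, n_perm, rng)
    secondary = pd.DataFrame(
        {
            "metric": [m for m, _ in meta],
            "sparsity": [s for _, s in meta],
            "observed_diff": obs_thr,
            "p": p_thr,
        }
    )
    return primary, secondary


def compare_nodal_metrics(
    nodal_curves: dict[str, np.ndarray],
    is_patient: np.ndarray,
    covariates: np.ndarray,
    grid: Sequence[float],
    n_perm: int = 10000,
    q: float = 0.05,
    rng: np.random.Generator | None = None,
    at_sparsity: float | None = None,
    node_labels: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-node group comparison for each nodal metric (Ne, Bc, Dc).

    ``nodal_curves`` maps metric name to an array of shape
    (n_subjects, n_thresholds, n_nodes).  FDR is applied within each metric
    family across its nodes.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = np.asarray(grid, dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for m, arr in nodal_curves.items():
        n_subj, n_thr, n_nodes = arr.shape
        if at_sparsity is None:
            step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
            scal = arr.sum(axis=1) * step  # (n_subj, n_nodes)
        else:
            j = int(np.argmin(np.abs(grid - at_sparsity)))
            scal = arr[:, j, :]
        resid = adjust_covariates(scal, covariates)
        obs, p = permutation_test_many(resid, is_patient, n_perm, rng)
        p_adj, reject = _fdr_with_nan(p, q)
        out[m] = pd.DataFrame(
            {
                "node": np.arange(1, n_nodes + 1),
                "label": (
                    list(node_labels)
                    if node_labels is not None
                    else [f"n{i}" for i in range(1, n_nodes + 1)]
                ),
                "observed_diff": obs,
                "p": p,
                "p_fdr": p_adj,
                "rejected": reject,
            }
        )
    return out


def hemisphere_analysis(
    nodal_comparisons: dict[str, pd.DataFrame],
    hemispheres: Sequence[str],
    q: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Hemisphere-stratified nodal results with FDR re-applied per stratum.

    Returns ``{"L": table, "R": table}`` (rows carry the metric name) and a
    summary of significant-node counts per metric and hemisphere.
    """
    hemis = np.asarray(hemispheres)
    strata: dict[str, list[pd.DataFrame]] = {"L": [], "R": []}
    counts = []
    for m, df in nodal_comparisons.items():
        for h in ("L", "R"):
            sub = df[hemis == h].copy()
            if len(sub):
                p_adj, reject = _fdr_with_nan(sub["p"].to_numpy(), q)
                sub["p_fdr"] = p_adj
                sub["rejected"] = reject
            sub.insert(0, "metric", m)
            strata[h].append(sub)
            counts.append(
                {
                    "metric": m,
                    "hemisphere": h,
                    "n_nodes": len(sub),
                    "n_significant": int(sub["rejected"].sum()) if len(sub) else 0,
                }
            )
    tables = {
        h: (pd.concat(parts, ignore_index=True) if parts else pd.DataFrame())
        for h, parts in strata.items()
    }
    return tables, pd.DataFrame(counts)
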