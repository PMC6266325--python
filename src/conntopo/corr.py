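"""Spearman correlations between hub nodal metrics and clinical scores.

Covariate removal follows the rank-after-residual convention: raw values
are residualised on intercept + age, sex and education by OLS, the
residual pair is ranked (midranks for ties) and the Pearson correlation of
the ranks is taken.  The p-value uses the t approximation with degrees of
freedom reduced by the number of covariates (df = n - 2 - n_cov).  The
alternative convention (rank first, then residualise the ranks) is
available behind a flag.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .stats import adjust_covariates

__all__ = ["spearman", "partial_spearman", "correlate_hub_metrics"]


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("zero variance in ranks; Spearman rho undefined", stacklevel=3)
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _t_pvalue(rho: float, df: int) -> float:
    if not np.isfinite(rho) or df <= 0:
        return np.nan
    if abs(rho) >= 1.0:
        return np.finfo(float).tiny
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(max(p, np.finfo(float).tiny))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks; p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    rho = _rank_corr(x, y)
    return rho, _t_pvalue(rho, x.size - 2)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates=None,
    rank_first: bool = False,
) -> tuple[float, float]:
    """Spearman correlation with covariates removed from both arguments.

    With ``covariates=None`` this is identical to :func:`spearman`.  The
    default residualises the raw values before ranking; ``rank_first=True``
    ranks first and residualises the ranks instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return spearman(x, y)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = x.size
    n_cov = C.shape[1]
    if n <= n_cov + 2:
        raise ValueError("too few observations for partial correlation")
    if rank_first:
        rx = adjust_covariates(sp_stats.rankdata(x), C)
        ry = adjust_covariates(sp_stats.rankdata(y), C)
        if rx.std() == 0 or ry.std() == 0:
            warnings.warn("zero variance after adjustment", stacklevel=2)
            return np.nan, np.nan
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        xr = adjust_covariates(x, C)
        yr = adjust_covariates(y, C)
        rho = _rank_corr(xr, yr)
    return rho, _t_pvalue(rho, n - 2 - n_cov)


def correlate_hub_metrics(
    nodal_values: dict[str, np.ndarray],
    unique_hubs: dict[str, Sequence[int]],
    scores: pd.DataFrame,
    covariates,
    node_labels: Sequence[str] | None = None,
    rank_first: bool = False,
) -> pd.DataFrame:
    """Partial Spearman between unique-hub nodal metrics and clinical scores.

    ``nodal_values[metric]`` is an (n_patients, n_nodes) array of patient
    nodal metric values; ``unique_hubs[metric]`` lists 0-based node indices
    of patient-only hubs.  ``scores`` has one row per patient (columns are
    clinical variables; NaN entries are excluded pairwise, the per-row n is
    reported).  Rows are sorted by \\|rho\\| descending.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    rows = []
    n_hubs = sum(len(v) for v in unique_hubs.values())
    if n_hubs == 0:
        warnings.warn("unique hub list is empty; no correlations computed",
                      stacklevel=2)
    for metric, hubs in unique_hubs.items():
        vals = nodal_values[metric]
        for node in hubs:
            x = vals[:, node]
            label = node_labels[node] if node_labels is not None else f"n{node + 1}"
            for var in scores.columns:
                y = scores[var].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                n = int(ok.sum())
                if n <= C.shape[1] + 2:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = partial_spearman(x[ok], y[ok], C[ok], rank_first)
                rows.append(
                    {
                        "region": label,
                        "node": node + 1,
                        "metric": metric,
                        "clinical_variable": var,
                        "n": n,
                        "rho": rho,
                        "p": p,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["region", "node", "metric", "clinical_variable", "n", "rho", "p"],
    )
    if len(df):
        df = df.reindex(
            df["rho"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)
    return df
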