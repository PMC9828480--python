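"""Trade-off analysis: correlations among log10-transformed competitive traits.

Pairwise Pearson correlations and partial correlations (1-3 covariates,
residual-on-residual method) across strains, with complete-case handling
per pair and a simple verdict layer: a significantly negative association
is a trade-off, a significantly positive one a concordance.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_correlations",
    "partial_correlation",
    "tradeoff_verdict",
    "DEFAULT_TRAITS",
]

log = logging.getLogger(__name__)

DEFAULT_TRAITS = ["I_star", "N_star", "P_star", "cell_size", "mu_max_max"]


def _pearson_p(r: float, n: int, k: int = 0) -> float:
    """Two-sided t-based p with df = n - 2 - k."""
    df = n - 2 - k
    if df < 1:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2 * stats.t.sf(abs(t), df))


def _log10_complete(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """log10 of complete cases; non-positive values are excluded with a log entry."""
    sub = df[cols].dropna()
    bad = (sub <= 0).any(axis=1)
    if bad.any():
        log.warning("excluding %d strain(s) with non-positive %s values",
                    int(bad.sum()), cols)
        sub = sub[~bad]
    return np.log10(sub)


def pairwise_correlations(traits: pd.DataFrame,
                          trait_cols: list[str] | None = None) -> pd.DataFrame:
    """Pearson r on log10 trait values, complete cases per pair.

    One row per unordered trait pair with r, two-sided p and n.
    """
    cols = trait_cols or [c for c in DEFAULT_TRAITS if c in traits.columns]
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = _log10_complete(traits, [a, b])
        n = len(sub)
        if n < 4:
            raise ValueError(f"pair ({a}, {b}): need >= 4 complete strains, have {n}")
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"pair ({a}, {b}): zero variance")
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"trait_a": a, "trait_b": b, "r": r,
                     "p": _pearson_p(r, n), "n": n, "n_covariates": 0})
    return pd.DataFrame(rows)


def partial_correlation(x, y, covariates=None) -> tuple[float, float, int]:
    """Partial correlation of x and y given covariates (residual method).

    Both variables are projected onto [1, Z] by least squares and the
    Pearson correlation of the residuals is returned with a t-based p at
    df = n - 2 - k.  An empty covariate set reduces exactly to the plain
    Pearson correlation.  Collinear covariates raise with the offending set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n, k = Z.shape
    if k > 3:
        raise ValueError("at most 3 covariates supported")
    if x.size != n or y.size != n:
        raise ValueError("length mismatch")
    if n < k + 3:
        raise ValueError(f"need n >= covariates + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear covariate set (rank-deficient design, k={k})")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, _pearson_p(r, n, k), n


def partial_correlations_table(traits: pd.DataFrame,
                               trait_cols: list[str] | None = None,
                               max_covariates: int = 3) -> pd.DataFrame:
    """All pairwise partial correlations with 1..max_covariates covariates."""
    cols = trait_cols or [c for c in DEFAULT_TRAITS if c in traits.columns]
    rows = []
    for a, b in itertools.combinations(cols, 2):
        others = [c for c in cols if c not in (a, b)]
        for k in range(1, max_covariates + 1):
            for covs in itertools.combinations(others, k):
                sub = _log10_complete(traits, [a, b, *covs])
                if len(sub) < k + 3:
                    continue
                r, p, n = partial_correlation(sub[a], sub[b], sub[list(covs)])
                rows.append({"trait_a": a, "trait_b": b,
                             "covariates": "+".join(covs), "r": r, "p": p,
                             "n": n, "n_covariates": k})
    return pd.DataFrame(rows)


def tradeoff_verdict(report: pd.DataFrame, alpha: float = 0.05,
                     holm: bool = False) -> pd.DataFrame:
    """Classify each pair: trade-off (r < 0), concordance (r > 0), or none.

    No multiple-testing correction by default; `holm=True` applies the
    Holm step-down adjustment before classification.
    """
    out = report.copy()
    pvals = out["p"].to_numpy(float)
    if holm:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
        pvals = adj
    else:
        out["p_adj"] = pvals
    verdicts = np.where(pvals >= alpha, "none",
                        np.where(out["r"] < 0, "trade-off", "concordance"))
    out["verdict"] = verdicts
    out["note"] = ("Holm-adjusted" if holm else
                   "no multiple-testing correction applied")
    return out
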