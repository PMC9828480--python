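"""Community composition summaries and permutation statistics.

Works on long-format count tables with columns
(week, mesocosm, treatment, taxon, count).  ANOSIM and IndVal are
implemented from first principles with the +1 permutation p-value
correction; the dissimilarity substrate is Bray-Curtis on relative
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from ._rng import substream

__all__ = [
    "DissimilarityMatrix",
    "relative_abundance",
    "delta_relative_abundance",
    "pielou_evenness",
    "hellinger",
    "bray_curtis",
    "anosim",
    "indval",
    "community_matrix",
]

SAMPLE_KEYS = ["week", "mesocosm"]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray          # square symmetric, zero diagonal, in [0, 1]
    labels: list
    groups: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        self.values = v


def community_matrix(table: pd.DataFrame, value: str = "count") -> pd.DataFrame:
    """Pivot the long table to samples (week, mesocosm) x taxa."""
    wide = table.pivot_table(index=SAMPLE_KEYS, columns="taxon",
                             values=value, aggfunc="sum", fill_value=0.0)
    return wide.sort_index()


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Add a `proportion` column: counts normalized within (week, mesocosm)."""
    totals = table.groupby(SAMPLE_KEYS)["count"].transform("sum")
    if (totals <= 0).any():
        bad = table.loc[totals <= 0, SAMPLE_KEYS].drop_duplicates()
        raise ValueError(f"all-zero sample(s): {bad.to_dict('records')}")
    out = table.copy()
    out["proportion"] = table["count"] / totals
    return out


def delta_relative_abundance(table: pd.DataFrame, taxon: str,
                             week_start: int = 1, week_end: int = 10) -> pd.DataFrame:
    """Change in a taxon's relative abundance between two weeks.

    Returns one row per treatment: the mean over replicate mesocosms of
    p(week_end) - p(week_start), with the per-replicate values retained in
    a `replicates` column.
    """
    if taxon not in set(table["taxon"]):
        raise KeyError(f"taxon {taxon!r} absent from table")
    for wk in (week_start, week_end):
        if wk not in set(table["week"]):
            raise ValueError(f"week {wk} not present in table")
    prop = relative_abundance(table)
    sub = prop[prop["week"].isin([week_start, week_end])]
    piv = sub[sub["taxon"] == taxon].pivot_table(
        index=["treatment", "mesocosm"], columns="week", values="proportion",
        fill_value=0.0)
    for wk in (week_start, week_end):
        if wk not in piv.columns:
            piv[wk] = 0.0
    delta = (piv[week_end] - piv[week_start]).rename("delta").reset_index()
    rows = []
    for treatment, g in delta.groupby("treatment"):
        rows.append({"treatment": treatment, "taxon": taxon,
                     "delta": g["delta"].mean(),
                     "sd": g["delta"].std(ddof=1) if len(g) > 1 else np.nan,
                     "replicates": g["delta"].tolist()})
    return pd.DataFrame(rows)


def pielou_evenness(proportions) -> float:
    """Pielou's J = H' / ln S over the nonzero proportions (NaN if S < 2)."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size < 2:
        return float("nan")
    p = p / p.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(p.size))


def hellinger(matrix) -> np.ndarray:
    """sqrt of row-relative abundances; rows acquire unit Euclidean norm."""
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    totals = x.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero row total")
    return np.sqrt(x / totals)


def bray_curtis(table: pd.DataFrame, week: int | None = None,
                relative: bool = True) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between (week, mesocosm) samples."""
    if week is not None:
        table = table[table["week"] == week]
        if table.empty:
            raise ValueError(f"no samples at week {week}")
    wide = community_matrix(table)
    x = wide.to_numpy(float)
    if relative:
        x = x / x.sum(axis=1, keepdims=True)
    d = squareform(pdist(x, metric="braycurtis"))
    groups_map = table.drop_duplicates(SAMPLE_KEYS).set_index(SAMPLE_KEYS)["treatment"]
    labels = list(wide.index)
    return DissimilarityMatrix(d, labels, [groups_map.loc[l] for l in labels])


def _anosim_r_from_ranks(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(d: DissimilarityMatrix, groups=None, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """ANOSIM R and permutation p-value.

    R = (mean rank between - mean rank within) / (M/2), ties mid-ranked,
    M = n(n-1)/2; p = (1 + #{perm R >= observed}) / (1 + n_perm).
    """
    groups = np.asarray(d.groups if groups is None else groups)
    n = groups.size
    if n != d.values.shape[0]:
        raise ValueError("groups length must match matrix size")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.values[iu])  # mid-ranks
    within = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r_from_ranks(ranks, within)

    rng = substream(seed, "anosim", n, n_perm)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pg = groups[perms]                       # (n_perm, n)
    within_perm = pg[:, iu[0]] == pg[:, iu[1]]  # (n_perm, M)
    m = ranks.size
    rw = (ranks * within_perm).sum(axis=1) / within_perm.sum(axis=1)
    rb = (ranks * ~within_perm).sum(axis=1) / (~within_perm).sum(axis=1)
    r_perm = (rb - rw) / (m / 2.0)
    p = (1 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1 + n_perm)
    return float(r_obs), float(p)


def _indval_stats(x: np.ndarray, gidx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Dufrene-Legendre IndVal and best group index per taxon.

    x: samples x taxa abundances; gidx: sample indices per group.
    A (specificity) = group mean / sum of group means;
    B (fidelity) = occurrence fraction within the group.
    """
    means = np.stack([x[ix].mean(axis=0) for ix in gidx])       # (G, T)
    pres = np.stack([(x[ix] > 0).mean(axis=0) for ix in gidx])  # (G, T)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    iv = a * pres
    best = iv.argmax(axis=0)
    return iv.max(axis=0), best


def indval(table: pd.DataFrame, week: int | None = None, n_perm: int = 999,
           seed: int = 0) -> pd.DataFrame:
    """Indicator value per taxon for the treatment groups at one week.

    Returns (taxon, group, indval, p); p is permutational with the +1
    correction.  Taxa absent everywhere get IndVal 0 and p 1.
    """
    if week is not None:
        table = table[table["week"] == week]
    wide = community_matrix(table)
    x = wide.to_numpy(float)
    groups_map = table.drop_duplicates(SAMPLE_KEYS).set_index(SAMPLE_KEYS)["treatment"]
    groups = np.asarray([groups_map.loc[l] for l in wide.index])
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    gidx = [np.flatnonzero(groups == g) for g in uniq]

    iv_obs, best = _indval_stats(x, gidx)

    rng = substream(seed, "indval", x.shape[0], n_perm)
    n = x.shape[0]
    exceed = np.zeros(x.shape[1], dtype=int)
    sizes = [ix.size for ix in gidx]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        pidx = []
        for s in sizes:
            pidx.append(perm[start:start + s])
            start += s
        iv_p, _ = _indval_stats(x, pidx)
        exceed += iv_p >= iv_obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)

    absent = x.sum(axis=0) == 0
    out = pd.DataFrame({
        "taxon": wide.columns,
        "group": uniq[best],
        "indval": iv_obs,
        "p": p,
    })
    out.loc[absent, "indval"] = 0.0
    out.loc[absent, "p"] = 1.0
    out.loc[absent, "group"] = ""
    return out.reset_index(drop=True)
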