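"""Within-species R* change across selection treatments.

One-way fixed-effects ANOVA per resource (selection treatment as the
predictor, replicate R* estimates as the response) followed by Tukey HSD
pairwise contrasts (Tukey-Kramer form for unbalanced groups, studentized
range distribution).  The report classifies each resource's focal
treatment as decline / increase / no-change relative to both the Initial
and the balanced-supply (Redfield) condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "anova_by_resource",
    "one_way_anova",
    "tukey_hsd",
    "evolution_report",
    "FOCAL_TREATMENT",
]

#: selection treatment whose trait is expected to respond, per resource
FOCAL_TREATMENT = {"light": "L-lim", "N": "N-lim", "P": "P-lim"}


@dataclass
class ContrastResult:
    resource: str
    f_stat: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False  # zero within-group variance


def _groups_from(df: pd.DataFrame, resource: str,
                 group_col: str = "selection", value_col: str = "r_star"
                 ) -> dict[str, np.ndarray]:
    sub = df[df["resource"] == resource] if "resource" in df.columns else df
    groups = {g: s[value_col].to_numpy(float) for g, s in sub.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError(f"resource {resource!r}: need >= 2 selection conditions")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"resource {resource!r}, condition {g!r}: "
                             "need >= 2 replicate estimates")
    return groups


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, int, int, float, bool]:
    """F = MS_between / MS_within via the explicit sum-of-squares decomposition."""
    k = len(groups)
    values = np.concatenate(list(groups.values()))
    n = values.size
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    degenerate = ss_within <= 0
    if degenerate:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p, degenerate


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer simultaneous pairwise comparisons.

    q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)); adjusted p from
    the studentized range distribution with k groups and N-k df.
    """
    names = sorted(groups)
    k = len(names)
    n_total = sum(v.size for v in groups.values())
    df_w = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    msw = ss_within / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            va, vb = groups[a], groups[b]
            diff = va.mean() - vb.mean()
            if msw <= 0:
                p_adj = 1.0 if diff == 0 else 0.0
                q = np.inf if diff != 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            rows.append({"a": a, "b": b, "diff": float(diff),
                         "q": float(q), "p_adj": min(max(p_adj, 0.0), 1.0)})
    return pd.DataFrame(rows)


def anova_by_resource(df: pd.DataFrame, group_col: str = "selection",
                      value_col: str = "r_star") -> dict[str, ContrastResult]:
    """One ContrastResult (ANOVA + Tukey pairwise table) per resource."""
    out = {}
    for resource in sorted(df["resource"].unique()):
        groups = _groups_from(df, resource, group_col, value_col)
        f, df_b, df_w, p, degenerate = one_way_anova(groups)
        out[resource] = ContrastResult(
            resource=resource, f_stat=f, df_between=df_b, df_within=df_w, p=p,
            group_means={g: float(v.mean()) for g, v in groups.items()},
            pairwise=tukey_hsd(groups), degenerate=degenerate,
        )
    return out


def _pair_p(pairwise: pd.DataFrame, a: str, b: str) -> float:
    hit = pairwise[((pairwise["a"] == a) & (pairwise["b"] == b)) |
                   ((pairwise["a"] == b) & (pairwise["b"] == a))]
    if hit.empty:
        raise KeyError(f"missing contrast {a!r} vs {b!r}")
    return float(hit["p_adj"].iloc[0])


def evolution_report(contrasts: dict[str, ContrastResult],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-resource verdict on trait change in the focal selection treatment.

    decline: focal mean below both Initial and Redfield with both Tukey
    adjusted p < alpha; increase: the mirrored pattern; otherwise no-change.
    """
    rows = []
    for resource, cr in contrasts.items():
        focal = FOCAL_TREATMENT.get(resource)
        if focal is None or focal not in cr.group_means:
            raise ValueError(f"resource {resource!r}: missing focal condition {focal!r}")
        for ref in ("Initial", "Redfield"):
            if ref not in cr.group_means:
                raise ValueError(f"resource {resource!r}: missing condition {ref!r}")
        mean_f = cr.group_means[focal]
        p_init = _pair_p(cr.pairwise, focal, "Initial")
        p_redf = _pair_p(cr.pairwise, focal, "Redfield")
        lower = mean_f < cr.group_means["Initial"] and mean_f < cr.group_means["Redfield"]
        higher = mean_f > cr.group_means["Initial"] and mean_f > cr.group_means["Redfield"]
        signif = p_init < alpha and p_redf < alpha
        if lower and signif:
            verdict = "decline"
        elif higher and signif:
            verdict = "increase"
        else:
            verdict = "no-change"
        rows.append({"resource": resource, "focal": focal, "verdict": verdict,
                     "p_vs_initial": p_init, "p_vs_redfield": p_redf,
                     "f_stat": cr.f_stat, "p_anova": cr.p})
    return pd.DataFrame(rows)
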