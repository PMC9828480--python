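"""Self-verification suite: property-based end-to-end checks.

Each function recomputes one verifiable quantity from scratch — generating
synthetic inputs, running the pipeline, and measuring the result against an
independent oracle (closed form, root finding, exhaustive enumeration or
simulation).  The test suite asserts the documented tolerances; the
``scripts/acceptance.py`` entry point reports the measured numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import community_metrics as cm
from . import growth_models as gm
from . import monod_rstar as mr
from . import rct_inference as ri
from . import rct_simulator as sim
from . import synthetic_data as sd
from . import tradeoffs as to
from . import trait_evolution as te
from ._rng import substream

__all__ = [
    "rstar_vs_root_oracle",
    "chemostat_equilibrium_error",
    "competitive_exclusion",
    "end_to_end_winner_prediction",
    "monod_recovery",
    "model_selection_rates",
    "anosim_oracle_agreement",
    "anosim_null_uniformity",
    "indval_oracle_agreement",
    "mixed_model_recovery",
    "anova_type_one_error",
    "tukey_two_group_identity",
    "statistic_identities",
]


# --- criterion 1: closed-form R* vs root-finding oracle ---------------------

def rstar_vs_root_oracle(n_grid: int = 100, m: float = 0.013) -> float:
    """Max |closed form - bisection root of mu(R) = m| over a parameter grid."""
    rng = np.random.default_rng(12345)
    mu_max = rng.uniform(m * 5, 2.0, n_grid)
    ks = rng.uniform(0.01, 50.0, n_grid)
    worst = 0.0
    for mm, kk in zip(mu_max, ks):
        fit = mr.MonodFit("g", "R", mm, kk, 0, 0, 1.0, 10)
        closed = mr.r_star(fit, m).r_star
        root = brentq(lambda R: mm * R / (kk + R) - m, 1e-15, 1e9,
                      xtol=1e-15, rtol=8.9e-16)
        worst = max(worst, abs(closed - root))
    return worst


# --- criterion 2: chemostat equilibrium -------------------------------------

def chemostat_equilibrium_error() -> float:
    """|simulated long-run resource - analytic R*|, worst of three scenarios."""
    cases = [(1.0, 1.0, 0.1), (0.8, 5.0, 0.05), (1.2, 0.3, 0.013)]
    worst = 0.0
    for mm, kk, m in cases:
        sp = sim.SpeciesParams("A", {"R": (mm, kk)}, {"R": 1.0}, b0=0.1)
        sc = sim.SimScenario(
            [sp], [sim.ResourceSupply("R", 10.0, "chemostat", dilution=m)],
            m=m, horizon=3000.0, output_step=10.0)
        res = sim.simulate(sc)
        analytic = m * kk / (mm - m)
        worst = max(worst, abs(res.resources[-1, 0] - analytic))
    return worst


# --- criterion 3: competitive exclusion + end-to-end prediction -------------

def _draw_pair(seed: int, m: float = 0.1):
    """Two species on one resource with true R* ratio >= 2."""
    rng = substream(seed, "pair")
    mu1, mu2 = rng.uniform(0.8, 1.2, 2)
    ks1 = rng.uniform(0.2, 0.6)
    r1 = m * ks1 / (mu1 - m)
    r2 = r1 * rng.uniform(2.0, 4.0)
    ks2 = r2 * (mu2 - m) / m
    a = sim.SpeciesParams("A", {"R": (mu1, ks1)}, {"R": 1.0}, b0=0.1)
    b = sim.SpeciesParams("B", {"R": (mu2, ks2)}, {"R": 1.0}, b0=0.1)
    return a, b, {"A": r1, "B": r2}


def competitive_exclusion(n_scenarios: int = 100, seed: int = 0) -> tuple[int, int]:
    """How often the min-R* species excludes the other (>0.99 by 500 d)."""
    wins = 0
    for i in range(n_scenarios):
        a, b, truth = _draw_pair(seed * 100003 + i)
        sc = sim.SimScenario(
            [a, b], [sim.ResourceSupply("R", 10.0, "chemostat", dilution=0.1)],
            m=0.1, horizon=500.0, output_step=5.0)
        res = sim.simulate(sc)
        expected = min(truth, key=truth.get)
        wins += res.winner == expected
    return wins, n_scenarios


def end_to_end_winner_prediction(n_runs: int = 100, seed: int = 0,
                                 sigma: float = 0.05) -> tuple[int, int]:
    """predict_winner from noisy re-estimated R* vs the simulated victor.

    Per run: generate 10-level growth assays (3 replicates, daily reads,
    sigma on ln RFU), estimate mu per series, fit Monod, compute R*, rank —
    then integrate the true dynamics and compare.
    """
    times = np.arange(0.0, 15.0)
    agree = 0
    for i in range(n_runs):
        run_seed = seed * 999983 + i
        a, b, truth = _draw_pair(run_seed)
        sc = sim.SimScenario(
            [a, b], [sim.ResourceSupply("R", 10.0, "chemostat", dilution=0.1)],
            m=0.1, horizon=500.0, output_step=5.0)
        res = sim.simulate(sc)
        if res.winner is None:
            continue

        est = {}
        ok = True
        for spp in (a, b):
            mm, kk = spp.kinetics["R"]
            spec = sd.StrainSpec(spp.name, spp.name, {"R": (mm, kk)})
            levels = np.geomspace(kk / 20.0, kk * 20.0, 10)
            series = sd.gen_growth_series(
                spec, "R", levels, times, n_rep=3,
                noise=sd.NoiseModel(sigma_log_rfu=sigma, seed=run_seed))
            rates = gm.growth_rate_table(series)
            try:
                fit = mr.fit_monod(rates)
                est[spp.name] = mr.r_star(fit, 0.1).r_star
            except (mr.NonViableError, mr.MonodFitError):
                ok = False
        if not ok:
            continue
        traits = pd.DataFrame({"R_star": [est["A"], est["B"]]}, index=["A", "B"])
        predicted = ri.predict_winner(traits, "R_star").iloc[0, 0]
        agree += predicted == res.winner
    return agree, n_runs


# --- criterion 4: Monod / R* parameter recovery -----------------------------

def monod_recovery(n_seeds: int = 100, sigma_mu: float = 0.02) -> dict[str, float]:
    """Median relative errors of (mu_max, Ks, R*) from noisy 10-level assays."""
    errs = {"mu_max": [], "Ks": [], "r_star": []}
    for i in range(n_seeds):
        rng = substream(i, "monod_recovery")
        mm = rng.uniform(0.5, 1.2)
        kk = rng.uniform(0.5, 10.0)
        levels = np.geomspace(kk / 20.0, kk * 20.0, 10)
        mu_obs = np.concatenate([
            mr.monod_mu(levels, mm, kk) + rng.normal(0, sigma_mu, 10)
            for _ in range(3)])
        fit = mr.fit_monod(levels=np.tile(levels, 3), mu=mu_obs)
        truth = sd.true_r_star(mm, kk, 0.013)
        errs["mu_max"].append(abs(fit.mu_max - mm) / mm)
        errs["Ks"].append(abs(fit.Ks - kk) / kk)
        errs["r_star"].append(abs(mr.r_star(fit, 0.013).r_star - truth) / truth)
    return {k: float(np.median(v)) for k, v in errs.items()}


# --- criterion 5: growth-model selection consistency ------------------------

def model_selection_rates(n_fixtures: int = 200, sigma: float = 0.05
                          ) -> dict[str, float]:
    """Fraction of lag fixtures picking a lag model, and exp fixtures exp."""
    times = np.arange(0.0, 15.0)
    lag_hits = exp_hits = 0
    for i in range(n_fixtures):
        rng = substream(i, "model_selection")
        t_lag = rng.uniform(3.0, 6.0)
        mu = rng.uniform(0.4, 0.8)
        ln = np.where(times < t_lag, 1.0, 1.0 + mu * (times - t_lag))
        ln = ln + rng.normal(0, sigma, times.size)
        s = gm.GrowthSeries("s", "N", 1.0, "r", times, np.exp(ln))
        best = gm.select_best(gm.fit_growth_models(s))
        lag_hits += best.model in ("lag", "lagsat")

        ln = 1.0 + mu * times + rng.normal(0, sigma, times.size)
        s = gm.GrowthSeries("s", "N", 1.0, "r", times, np.exp(ln))
        best = gm.select_best(gm.fit_growth_models(s))
        exp_hits += best.model == "exp"
    return {"lag_rate": lag_hits / n_fixtures, "exp_rate": exp_hits / n_fixtures}


# --- criterion 6: permutation statistics ------------------------------------

def _anosim_r_bruteforce(d: np.ndarray, groups) -> float:
    """Independent oracle: pure-python rank computation."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [d[i, j] for i, j in pairs]
    order = sorted(range(len(vals)), key=lambda k: vals[k])
    ranks = [0.0] * len(vals)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[k]]:
            j += 1
        for t in range(k, j + 1):
            ranks[order[t]] = (k + j) / 2.0 + 1.0
        k = j + 1
    w = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    b = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    return (sum(b) / len(b) - sum(w) / len(w)) / (len(pairs) / 2.0)


def anosim_oracle_agreement(n_fixtures: int = 50) -> float:
    """Max |ANOSIM R - brute-force oracle| over random 6-sample fixtures."""
    worst = 0.0
    groups = ["A"] * 3 + ["B"] * 3
    for i in range(n_fixtures):
        rng = substream(i, "anosim_fix")
        x = rng.random((6, 4))
        d = np.zeros((6, 6))
        for a in range(6):
            for b in range(a + 1, 6):
                d[a, b] = d[b, a] = (np.abs(x[a] - x[b]).sum()
                                     / (x[a] + x[b]).sum())
        dm = cm.DissimilarityMatrix(d, list(range(6)), groups)
        r, _ = cm.anosim(dm, n_perm=99, seed=i)
        worst = max(worst, abs(r - _anosim_r_bruteforce(d, groups)))
    return worst


def anosim_null_uniformity(n_datasets: int = 500, n_perm: int = 999,
                           seed: int = 0) -> float:
    """KS p-value of null ANOSIM p-values against U(0,1)."""
    pvals = []
    groups = ["A"] * 4 + ["B"] * 4
    for i in range(n_datasets):
        rng = substream(seed, "anosim_null", i)
        x = rng.random((8, 4))
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
        np.fill_diagonal(d, 0.0)
        dm = cm.DissimilarityMatrix(d / d.max(), list(range(8)), groups)
        _, p = cm.anosim(dm, n_perm=n_perm, seed=seed * 7919 + i)
        pvals.append(p)
    return float(stats.kstest(pvals, "uniform").pvalue)


def indval_oracle_agreement(n_fixtures: int = 30) -> float:
    """Max |IndVal - direct Dufrene-Legendre formula| over random tables."""
    worst = 0.0
    for i in range(n_fixtures):
        rng = substream(i, "indval_fix")
        n_groups, n_per, n_taxa = 3, 3, 6
        rows = []
        meso = 0
        for g in range(n_groups):
            for _ in range(n_per):
                meso += 1
                counts = rng.poisson(30, n_taxa)
                for t in range(n_taxa):
                    rows.append({"week": 1, "mesocosm": f"M{meso:02d}",
                                 "treatment": f"G{g}", "taxon": f"t{t}",
                                 "count": int(counts[t])})
        table = pd.DataFrame(rows)
        if (table.groupby(["week", "mesocosm"])["count"].sum() == 0).any():
            continue
        out = cm.indval(table, week=1, n_perm=9, seed=i).set_index("taxon")
        wide = cm.community_matrix(table)
        gmap = table.drop_duplicates(["week", "mesocosm"]).set_index(
            ["week", "mesocosm"])["treatment"]
        groups = [gmap.loc[l] for l in wide.index]
        x = wide.to_numpy(float)
        for t_i, taxon in enumerate(wide.columns):
            best = 0.0
            for g in sorted(set(groups)):
                rows_g = [r for r, gg in enumerate(groups) if gg == g]
                mean_g = sum(x[r, t_i] for r in rows_g) / len(rows_g)
                denom = sum(
                    sum(x[r, t_i] for r, gg in enumerate(groups) if gg == g2)
                    / sum(1 for gg in groups if gg == g2)
                    for g2 in sorted(set(groups)))
                a_spec = mean_g / denom if denom > 0 else 0.0
                b_fid = sum(1 for r in rows_g if x[r, t_i] > 0) / len(rows_g)
                best = max(best, a_spec * b_fid)
            worst = max(worst, abs(out.loc[taxon, "indval"] - best))
    return worst


# --- criterion 7: mixed-model slope recovery --------------------------------

def mixed_model_recovery(n_datasets: int = 200, true_slope: float = -0.2,
                         seed: int = 0) -> dict[str, float]:
    """Mean prediction-1 slope estimate over synthetic study-scale datasets.

    7 species x 3 resources, resource intercepts ~ N(0, 0.05), replicate
    noise N(0, 0.1) averaged over 4 mesocosms per treatment.
    """
    slopes = []
    for i in range(n_datasets):
        rng = substream(seed, "mm_recovery", i)
        rows = []
        for res in ("light", "N", "P"):
            b = rng.normal(0, 0.05)
            z = rng.normal(0, 1, 7)
            z = (z - z.mean()) / z.std(ddof=1)
            for s in range(7):
                reps = b + true_slope * z[s] + rng.normal(0, 0.1, 4)
                rows.append({"resource": res, "z": z[s],
                             "delta": float(np.mean(reps))})
        fit = ri.fit_prediction1(pd.DataFrame(rows))
        slopes.append(fit.slope)
    return {"mean_slope": float(np.mean(slopes)),
            "bias": float(np.mean(slopes) - true_slope)}


# --- criterion 8: ANOVA / Tukey calibration ---------------------------------

def anova_type_one_error(n_sim: int = 500, seed: int = 0) -> float:
    """Fraction of null one-way ANOVAs with p < 0.05 (5 groups, n=4)."""
    rej = 0
    for i in range(n_sim):
        rng = substream(seed, "anova_null", i)
        groups = {c: rng.normal(0, 1, 4) for c in "abcde"}
        _, _, _, p, _ = te.one_way_anova(groups)
        rej += p < 0.05
    return rej / n_sim


def tukey_two_group_identity(n_fixtures: int = 20) -> float:
    """Max |Tukey p - pooled two-sample t-test p| over two-group fixtures."""
    worst = 0.0
    for i in range(n_fixtures):
        rng = substream(i, "tukey_id")
        a = rng.normal(0, 1, int(rng.integers(3, 8)))
        b = rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(3, 8)))
        out = te.tukey_hsd({"a": a, "b": b})
        _, p_t = stats.ttest_ind(a, b, equal_var=True)
        worst = max(worst, abs(out["p_adj"].iloc[0] - p_t))
    return worst


# --- criterion 9: closed-form statistic identities --------------------------

def statistic_identities() -> dict[str, float]:
    """Deviations of quick identities; all should be ~ machine precision."""
    out = {}
    out["pielou_uniform_minus_1"] = abs(cm.pielou_evenness([0.2] * 5) - 1.0)

    x = np.random.default_rng(0).poisson(20, (6, 4)) + 1
    norms = np.linalg.norm(cm.hellinger(x), axis=1)
    out["hellinger_norm_dev"] = float(np.max(np.abs(norms - 1.0)))

    rng = np.random.default_rng(1)
    a, b = rng.normal(size=15), rng.normal(size=15)
    r0, _, _ = to.partial_correlation(a, b)
    out["partial_null_covariates_dev"] = abs(r0 - np.corrcoef(a, b)[0, 1])

    rho, _ = ri.spearman([1, 2, 3, 4, 5, 6], [1, 3, 2, 4, 5, 6])
    out["spearman_adjacent_swap_dev"] = abs(rho - (1 - 12.0 / 210.0))
    return out
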