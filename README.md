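# rstarcomp

Trait-based resource-competition analysis for phytoplankton growth assays and
mesocosm community experiments, built around the minimum resource requirement
R\* = m·Ks/(μmax − m).

The package covers the full pipeline:

| stage | module | what it does |
|---|---|---|
| synthetic inputs | `rstarcomp.synthetic_data` | seeded growth assays, community count tables, true trait tables |
| growth rates | `rstarcomp.growth_models` | per-replicate μ from ln(RFU) time series; exp/lag/sat/lagsat family, AICc selection |
| kinetics & R\* | `rstarcomp.monod_rstar` | Monod NLS fits, closed-form R\* (I\*, N\*, P\*), bootstrap 95% CIs, species means |
| community stats | `rstarcomp.community_metrics` | relative/Δ abundance, Pielou J, Hellinger, Bray–Curtis, ANOSIM & IndVal (999 perms) |
| predictions 1–2 | `rstarcomp.rct_inference` | Δ abundance ~ z-scored R\* mixed model; Spearman vs μmax; winner ranking |
| prediction 3 | `rstarcomp.trait_evolution` | per-resource one-way ANOVA + Tukey HSD across selection treatments |
| prediction 4 | `rstarcomp.tradeoffs` | pairwise & partial correlations of log₁₀ traits, trade-off verdicts |
| ground truth | `rstarcomp.rct_simulator` | Liebig/Monod ODE competition under chemostat or weekly-pulse (mesocosm) supply |

## CLI

```bash
rstarcomp gen-data --out synthetic --seed 1           # synthetic growth + community CSVs
rstarcomp fit-growth synthetic/growth.csv --out rates.csv --report fits.json
rstarcomp fit-monod rates.csv --out monod.csv
rstarcomp rstar rates.csv --m 0.013 --n-boot 1000 --seed 1 --out rstar.csv
rstarcomp community-stats synthetic/community.csv --week 10 --n-perm 999 --seed 1
rstarcomp simulate --scenario scenario.json --out sim_out   # add --suite for the 4 treatments
rstarcomp predict traits.csv --resource N
rstarcomp test-predictions traits.csv synthetic/community.csv
rstarcomp evolve-test rstar_selection.csv --alpha 0.05
rstarcomp tradeoffs traits.csv --covariates 3
```

The default mortality is m = 0.013 day⁻¹ (weekly mesocosm dilution of 10 L of
110 L); every command that uses it exposes `--m`.

## File formats

- growth CSV (long): `strain, species, resource, level, replicate, day, rfu`
- growth-rate CSV: `strain, resource, level, replicate, mu, model`
- R\* CSV: `strain_id, resource, r_star, ci_low, ci_high, m_used`
- community CSV (long): `week, mesocosm, treatment, taxon, count`
- trait CSV: index `species` (or strain), columns `I_star, N_star, P_star, mu_max_max, cell_size, ...`
- simulator scenarios: JSON/YAML (see `rstarcomp.rct_simulator.scenario_from_dict`)
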