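"""Seeded synthetic inputs for every pipeline stage.

Growth trajectories are generated in ln(RFU) space as piecewise-linear
curves (lag plateau -> exponential slope from the Monod response ->
optional ceiling), which is exactly the model family the estimation stage
fits, so round-trip identities are exact at zero noise.  Community tables
wrap simulator trajectories with multinomial count sampling.  A single
global seed fans out to per-series substreams by hashing
(strain, resource, level, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .growth_models import GrowthSeries
from .rct_simulator import SimScenario, SimResult, run_treatment_suite

__all__ = [
    "StrainSpec",
    "NoiseModel",
    "gen_growth_series",
    "gen_community_tables",
    "gen_trait_table",
    "true_r_star",
    "write_growth_csv",
    "write_community_csv",
]

RESOURCES = ("light", "N", "P")


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth kinetics of one strain (per resource: mu_max, Ks)."""

    strain_id: str
    species_id: str
    kinetics: dict[str, tuple[float, float]]
    lag_days: float = 0.0
    sat_log_ceiling: float | None = None
    ln_b0: float = 2.0
    cell_size: float = 10.0
    cn_ratio: float = 6.6
    cp_ratio: float = 106.0

    def __post_init__(self) -> None:
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        for res, (mm, ks) in self.kinetics.items():
            if mm <= 0 or ks <= 0:
                raise ValueError(
                    f"strain {self.strain_id!r}, resource {res!r}: "
                    "mu_max and Ks must be positive")


@dataclass(frozen=True)
class NoiseModel:
    sigma_log_rfu: float = 0.05
    count_sampling: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log_rfu < 0:
            raise ValueError("sigma_log_rfu must be >= 0")
        if self.count_sampling < 1:
            raise ValueError("count_sampling must be >= 1")


def _ln_trajectory(times: np.ndarray, mu: float, ln_b0: float,
                   lag: float, ceiling: float | None) -> np.ndarray:
    ln = ln_b0 + mu * np.clip(times - lag, 0.0, None)
    if ceiling is not None and mu > 0:
        ln = np.minimum(ln, ceiling)
    return ln


def gen_growth_series(spec: StrainSpec, resource: str, levels, times,
                      n_rep: int = 3, noise: NoiseModel = NoiseModel()
                      ) -> list[GrowthSeries]:
    """Generate replicate fluorescence time courses along a resource gradient.

    RFU(t) = exp(piecewise-linear ln trajectory with Monod slope) * exp(eps),
    eps ~ N(0, sigma^2).  Identical (spec, seed) give identical output.
    """
    levels = np.asarray(levels, dtype=float)
    times = np.asarray(times, dtype=float)
    if levels.size == 0 or times.size == 0:
        raise ValueError("levels and times must be non-empty")
    if np.any(levels < 0):
        raise ValueError("levels must be non-negative")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing from 0")
    if resource not in spec.kinetics:
        raise KeyError(f"strain {spec.strain_id!r} has no kinetics for {resource!r}")
    mu_max, ks = spec.kinetics[resource]

    out = []
    for li, level in enumerate(levels):
        mu = mu_max * level / (ks + level)
        for rep in range(n_rep):
            rng = substream(noise.seed, "growth", spec.strain_id, resource, li, rep)
            ln = _ln_trajectory(times, mu, spec.ln_b0, spec.lag_days,
                                spec.sat_log_ceiling)
            eps = rng.normal(0.0, noise.sigma_log_rfu, size=times.size) \
                if noise.sigma_log_rfu > 0 else 0.0
            out.append(GrowthSeries(
                strain_id=spec.strain_id, resource=resource, level=float(level),
                replicate_id=f"r{rep + 1}", times=times.copy(),
                rfu=np.exp(ln + eps),
            ))
    return out


def gen_community_tables(scenario: SimScenario, noise: NoiseModel = NoiseModel(),
                         n_replicates: int = 4, weeks=range(1, 11),
                         results: dict[str, SimResult] | None = None) -> pd.DataFrame:
    """Weekly community count tables from simulated treatment trajectories.

    Counts per (week, mesocosm, taxon) are multinomial draws of size
    ``noise.count_sampling`` from the simulated relative biomasses; the
    four replicate mesocosms per treatment share a trajectory and differ
    only in sampling noise.
    """
    weeks = list(weeks)
    if len(weeks) < 2:
        raise ValueError("need >= 2 weekly time points")
    if results is None:
        results = run_treatment_suite(scenario)
    rows = []
    meso = 0
    for treatment in sorted(results):
        res = results[treatment]
        taxa = res.species_names
        for rep in range(n_replicates):
            meso += 1
            mid = f"M{meso:02d}"
            for week in weeks:
                day = week * 7.0
                i = int(np.argmin(np.abs(res.t - day)))
                b = res.biomass[i]
                tot = b.sum()
                if tot <= 0:
                    raise ValueError(
                        f"zero total biomass in treatment {treatment!r} at week {week}")
                rng = substream(noise.seed, "community", treatment, rep, week)
                counts = rng.multinomial(noise.count_sampling, b / tot)
                for taxon, c in zip(taxa, counts):
                    rows.append({"week": week, "mesocosm": mid,
                                 "treatment": treatment, "taxon": taxon,
                                 "count": int(c)})
    return pd.DataFrame(rows)


def true_r_star(mu_max: float, ks: float, m: float) -> float:
    """Ground-truth minimum resource requirement for known kinetics."""
    if mu_max <= m:
        raise ValueError(f"mu_max={mu_max:g} <= m={m:g}: R* undefined")
    return m * ks / (mu_max - m)


_COL = {"light": "I_star", "N": "N_star", "P": "P_star"}


def gen_trait_table(specs, m: float = 0.013) -> pd.DataFrame:
    """True trait table (I*, N*, P*, mu_max_max, stoichiometry) per strain."""
    rows = []
    for spec in specs:
        row = {"strain": spec.strain_id, "species": spec.species_id,
               "cell_size": spec.cell_size, "cn_ratio": spec.cn_ratio,
               "cp_ratio": spec.cp_ratio}
        for res, (mm, ks) in spec.kinetics.items():
            if mm <= m:
                raise ValueError(
                    f"strain {spec.strain_id!r}, resource {res!r}: "
                    f"mu_max={mm:g} <= m={m:g}")
            row[_COL.get(res, f"{res}_star")] = true_r_star(mm, ks, m)
        row["mu_max_max"] = max(mm for mm, _ in spec.kinetics.values())
        rows.append(row)
    return pd.DataFrame(rows)


def write_growth_csv(series, path, strain_to_species: dict[str, str] | None = None) -> None:
    """Long-format CSV: strain, species, resource, level, replicate, day, rfu."""
    rows = []
    for s in series:
        species = (strain_to_species or {}).get(s.strain_id, "")
        for t, y in zip(s.times, s.rfu):
            rows.append({"strain": s.strain_id, "species": species,
                         "resource": s.resource, "level": s.level,
                         "replicate": s.replicate_id, "day": t, "rfu": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_community_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
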