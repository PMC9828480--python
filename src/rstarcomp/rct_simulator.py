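"""Multi-species resource-competition simulator.

Dynamics (essential resources, Liebig's minimum over Monod terms):

    dB_i/dt = B_i * (min_j mu_ij(R_j) - m)
    dR_j/dt = supply_j - sum_i q_ij * B_i * g_i

where ``g_i`` is the realized (Liebig) growth rate and ``q_ij`` the amount
of resource j consumed per unit biomass grown.  Supply modes per resource:

- ``chemostat``: continuous ``D * (S_j - R_j)``; biomass washout is folded
  into the mortality ``m`` of the scenario.
- ``pulse``: no continuous supply; a discrete weekly event multiplies
  biomass by ``1 - f`` and moves resources toward the fresh medium,
  ``R <- (1 - f) * R + f * S`` (mesocosm-style dilution).
- ``constant``: non-depletable, held at its supply level (light: fixed
  incident irradiance, no self-shading).

All pulsed resources in a scenario must share one fraction and period; the
pulse is a whole-mesocosm dilution event.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ResourceSupply",
    "SpeciesParams",
    "SimScenario",
    "SimResult",
    "SimulationError",
    "simulate",
    "equilibrium_resource",
    "effective_loss_rate",
    "run_treatment_suite",
    "mesocosm_supplies",
    "MESOCOSM_PULSE_FRACTION",
]

#: weekly 10 L exchange of a 110 L mesocosm
MESOCOSM_PULSE_FRACTION = 10.0 / 110.0

_TREATMENTS = ("L-lim", "N-lim", "P-lim", "Redfield")


class SimulationError(RuntimeError):
    pass


@dataclass
class ResourceSupply:
    name: str
    supply: float                      # fresh-medium concentration S_j
    kind: str = "chemostat"            # chemostat | pulse | constant
    dilution: float = 0.0              # D, day^-1 (chemostat)
    pulse_fraction: float = 0.0        # f in (0,1) (pulse)
    pulse_period: float = 7.0          # days between pulses
    initial: float | None = None       # R_j(0); defaults to supply

    def __post_init__(self) -> None:
        if self.kind not in ("chemostat", "pulse", "constant"):
            raise ValueError(f"unknown resource kind {self.kind!r}")
        if self.kind == "pulse" and not (0.0 < self.pulse_fraction < 1.0):
            raise ValueError("pulse fraction must lie in (0, 1)")
        if self.initial is None:
            self.initial = self.supply


@dataclass
class SpeciesParams:
    name: str
    kinetics: dict[str, tuple[float, float]]   # resource -> (mu_max, Ks)
    quotas: dict[str, float] = field(default_factory=dict)  # resource -> q
    b0: float = 1.0

    def __post_init__(self) -> None:
        for res, (mm, ks) in self.kinetics.items():
            if mm <= 0 or ks <= 0:
                raise ValueError(f"species {self.name!r}, resource {res!r}: "
                                 "mu_max and Ks must be positive")


@dataclass
class SimScenario:
    species: list[SpeciesParams]
    resources: list[ResourceSupply]
    m: float = 0.013
    horizon: float = 100.0
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-12
    output_step: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        fracs = {(r.pulse_fraction, r.pulse_period)
                 for r in self.resources if r.kind == "pulse"}
        if len(fracs) > 1:
            raise ValueError("all pulsed resources must share fraction and period")

    def resource(self, name: str) -> ResourceSupply:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass
class SimResult:
    t: np.ndarray                      # (n_t,)
    biomass: np.ndarray                # (n_t, n_species)
    resources: np.ndarray              # (n_t, n_resources)
    species_names: list[str]
    resource_names: list[str]
    events: list[dict]
    winner: str | None

    def final_relative_abundance(self) -> np.ndarray:
        b = self.biomass[-1]
        tot = b.sum()
        if tot <= 0:
            raise SimulationError("zero total biomass at horizon")
        return b / tot


def _liebig_growth(R: np.ndarray, sp: SpeciesParams, res_index: dict[str, int]) -> float:
    g = np.inf
    for res, (mm, ks) in sp.kinetics.items():
        r = max(R[res_index[res]], 0.0)
        g = min(g, mm * r / (ks + r))
    return 0.0 if g is np.inf else g


def simulate(scenario: SimScenario) -> SimResult:
    """Integrate the scenario deterministically and report the outcome.

    Pulses are handled as discrete events between stiff-safe adaptive
    integration segments (LSODA, rtol/atol from the scenario).  The winner
    is the species exceeding 0.99 relative abundance at the horizon, if any.
    """
    sp_names = [s.name for s in scenario.species]
    res_names = [r.name for r in scenario.resources]
    res_index = {n: i for i, n in enumerate(res_names)}
    n_sp, n_res = len(sp_names), len(res_names)

    pulsed = [i for i, r in enumerate(scenario.resources) if r.kind == "pulse"]
    if pulsed:
        f = scenario.resources[pulsed[0]].pulse_fraction
        period = scenario.resources[pulsed[0]].pulse_period
        pulse_times = np.arange(period, scenario.horizon + 1e-9, period)
    else:
        f, pulse_times = 0.0, np.array([])

    def rhs(t, y):
        B = y[:n_sp]
        R = y[n_sp:]
        dB = np.empty(n_sp)
        cons = np.zeros(n_res)
        for i, sp in enumerate(scenario.species):
            g = _liebig_growth(R, sp, res_index)
            dB[i] = B[i] * (g - scenario.m)
            grown = max(B[i], 0.0) * g
            for res, q in sp.quotas.items():
                cons[res_index[res]] += q * grown
        dR = np.empty(n_res)
        for j, r in enumerate(scenario.resources):
            if r.kind == "chemostat":
                dR[j] = r.dilution * (r.supply - R[j]) - cons[j]
            elif r.kind == "pulse":
                dR[j] = -cons[j]
            else:  # constant (e.g. light)
                dR[j] = 0.0
        return np.concatenate([dB, dR])

    y = np.concatenate([
        np.array([s.b0 for s in scenario.species], dtype=float),
        np.array([r.initial for r in scenario.resources], dtype=float),
    ])
    t_grid = np.arange(0.0, scenario.horizon + 1e-9, scenario.output_step)
    if t_grid[-1] < scenario.horizon - 1e-9:
        t_grid = np.append(t_grid, scenario.horizon)

    segments = np.concatenate([[0.0], pulse_times, [scenario.horizon]])
    segments = np.unique(segments[segments <= scenario.horizon + 1e-9])

    ts, Bs, Rs, events = [], [], [], []
    for a, b in zip(segments[:-1], segments[1:]):
        t_eval = t_grid[(t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b - 1e-12:
            t_eval = np.append(t_eval, b)  # segment endpoint carries the state
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=scenario.rtol, atol=scenario.atol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            t_last = sol.t[-1] if sol.t.size else a
            raise SimulationError(f"solver failed at t={t_last:g}: {sol.message}")
        ts.append(sol.t)
        Y = np.clip(sol.y.T, 0.0, None)
        Bs.append(Y[:, :n_sp])
        Rs.append(Y[:, n_sp:])
        y = np.clip(sol.y[:, -1], 0.0, None)
        if b in pulse_times:
            y[:n_sp] *= 1.0 - f
            for j in pulsed:
                y[n_sp + j] = (1.0 - f) * y[n_sp + j] + f * scenario.resources[j].supply
            events.append({"t": float(b), "type": "pulse", "fraction": f})

    t = np.concatenate(ts)
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t = t[keep]
    B = np.concatenate(Bs)[keep]
    R = np.concatenate(Rs)[keep]

    winner = None
    tot = B[-1].sum()
    if tot > 0:
        rel = B[-1] / tot
        i = int(np.argmax(rel))
        if rel[i] > 0.99:
            winner = sp_names[i]
    return SimResult(t, B, R, sp_names, res_names, events, winner)


def effective_loss_rate(scenario: SimScenario) -> float:
    """Average per-capita biomass loss: m plus the pulsed-dilution rate."""
    loss = scenario.m
    for r in scenario.resources:
        if r.kind == "pulse":
            loss += -np.log(1.0 - r.pulse_fraction) / r.pulse_period
            break  # one whole-mesocosm pulse event
    return loss


def equilibrium_resource(scenario: SimScenario, species: SpeciesParams) -> dict[str, float]:
    """Analytic equilibrium resource concentration R* per resource.

    At steady state the ambient concentration of the limiting resource
    equals ``loss * Ks / (mu_max - loss)`` with the scenario's effective
    per-capita loss rate.
    """
    loss = effective_loss_rate(scenario)
    out = {}
    for res, (mm, ks) in species.kinetics.items():
        if mm <= loss:
            raise NonViableScenarioError(
                f"species {species.name!r} cannot persist on {res!r}: "
                f"mu_max={mm:g} <= loss={loss:g}")
        out[res] = loss * ks / (mm - loss)
    return out


class NonViableScenarioError(ValueError):
    pass


def mesocosm_supplies(treatment: str, light_full: float = 300.0,
                      light_limited_factor: float = 0.1) -> dict[str, float]:
    """Nutrient and light supplies per treatment.

    Redfield: 160 uM N, 10 uM P (16:1); N-lim: 80 uM N (8:1); P-lim: 5 uM P
    (32:1); L-lim: Redfield nutrients with incident light scaled down.
    """
    if treatment not in _TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    n, p, light = 160.0, 10.0, light_full
    if treatment == "N-lim":
        n = 80.0
    elif treatment == "P-lim":
        p = 5.0
    elif treatment == "L-lim":
        light = light_full * light_limited_factor
    return {"N": n, "P": p, "light": light}


def run_treatment_suite(base: SimScenario, light_limited_factor: float = 0.1
                        ) -> dict[str, SimResult]:
    """Run the four mesocosm treatments from one base scenario.

    Scenarios differ only in their supplies: N 160 -> 80 uM under N-lim,
    P 10 -> 5 uM under P-lim, light scaled down under L-lim.
    """
    for required in ("N", "P", "light"):
        try:
            base.resource(required)
        except KeyError:
            raise ValueError(f"base scenario missing resource {required!r}") from None
    full_light = base.resource("light").supply
    results = {}
    for treatment in _TREATMENTS:
        sup = mesocosm_supplies(treatment, light_full=full_light,
                                light_limited_factor=light_limited_factor)
        sc = copy.deepcopy(base)
        for r in sc.resources:
            if r.name in sup:
                scale = sup[r.name] / (full_light if r.name == "light" else
                                       base.resource(r.name).supply)
                r.supply = sup[r.name]
                if r.name == "light":
                    r.initial = sup[r.name]
                else:
                    r.initial = base.resource(r.name).initial * scale
        results[treatment] = simulate(sc)
    return results


def scenario_from_dict(cfg: dict) -> SimScenario:
    """Build a scenario from a plain dict (JSON/YAML config)."""
    species = [SpeciesParams(name=s["name"],
                             kinetics={k: tuple(v) for k, v in s["kinetics"].items()},
                             quotas=s.get("quotas", {}),
                             b0=s.get("b0", 1.0))
               for s in cfg["species"]]
    resources = [ResourceSupply(**r) for r in cfg["resources"]]
    keys = {k: cfg[k] for k in ("m", "horizon", "seed", "rtol", "atol", "output_step")
            if k in cfg}
    return SimScenario(species=species, resources=resources, **keys)


def write_trajectories_csv(result: SimResult, path) -> None:
    import pandas as pd

    df = pd.DataFrame({"time": result.t})
    for i, n in enumerate(result.species_names):
        df[f"B_{n}"] = result.biomass[:, i]
    for j, n in enumerate(result.resource_names):
        df[f"R_{n}"] = result.resources[:, j]
    df.to_csv(path, index=False)


def write_event_log(result: SimResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.events, fh, indent=1)
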