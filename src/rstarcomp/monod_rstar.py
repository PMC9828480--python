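"""Monod kinetics fitting and minimum resource requirements (R*).

The Monod response ``mu(R) = mu_max * R / (Ks + R)`` is fitted by nonlinear
least squares to replicate growth rates across a resource gradient.  The
minimum resource requirement at a density-independent mortality rate ``m``
is the closed form

    R* = m * Ks / (mu_max - m)

i.e. the concentration where net growth ``mu(R) - m`` is zero.  For light
this value is the compensation irradiance I*.  Uncertainty comes from a
nonparametric bootstrap that resamples replicates within each level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._rng import substream

__all__ = [
    "MonodFit",
    "RStarEstimate",
    "NonViableError",
    "MonodFitError",
    "monod_mu",
    "fit_monod",
    "r_star",
    "bootstrap_r_star",
    "species_mean_traits",
    "DEFAULT_MORTALITY",
]

#: mortality imposed by the weekly mesocosm dilution, day^-1
DEFAULT_MORTALITY = 0.013

_KS_FLOOR_FRAC = 1e-6  # Ks lower bound as a fraction of the largest level


class NonViableError(ValueError):
    """No positive growth anywhere along the gradient."""


class MonodFitError(RuntimeError):
    """Optimizer failed to converge after restarts."""


@dataclass
class MonodFit:
    strain_id: str
    resource: str
    mu_max: float
    Ks: float
    se_mu_max: float
    se_Ks: float
    r_squared: float
    n_points: int
    saturated_gradient: bool = False


@dataclass
class RStarEstimate:
    strain_id: str
    resource: str
    r_star: float
    ci_low: float
    ci_high: float
    m_used: float


def monod_mu(R, mu_max: float, Ks: float):
    """Monod growth response."""
    R = np.asarray(R, dtype=float)
    return mu_max * R / (Ks + R)


def _prepare(levels, mu) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(levels, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if levels.size != mu.size:
        raise ValueError("levels and mu must have equal length")
    if np.unique(levels).size < 3:
        raise ValueError("need >= 3 distinct resource levels")
    if not np.any(mu > 0):
        raise NonViableError("all growth rates <= 0: strain non-viable on this gradient")
    return levels, mu


def _init_guesses(levels: np.ndarray, mu: np.ndarray) -> list[tuple[float, float]]:
    """Deterministic initialization: mu_max0 = max mu; Ks0 = level at half mu_max0."""
    mu_max0 = float(mu.max())
    order = np.argsort(levels)
    lv, mv = levels[order], mu[order]
    # mean per level, interpolate level at mu_max0 / 2
    df = pd.DataFrame({"l": lv, "m": mv}).groupby("l", sort=True)["m"].mean()
    half = mu_max0 / 2.0
    ks0 = float(np.interp(half, df.to_numpy(), df.index.to_numpy()))
    if not np.isfinite(ks0) or ks0 <= 0:
        ks0 = float(np.median(levels[levels > 0]))
    return [(mu_max0, ks0), (mu_max0 * 1.2, ks0 * 0.5), (mu_max0 * 1.05, ks0 * 2.0)]


def fit_monod(rates: pd.DataFrame | None = None, *, levels=None, mu=None,
              strain_id: str = "", resource: str = "") -> MonodFit:
    """Nonlinear least squares of the Monod model over replicate growth rates.

    `rates` is a growth-rate table slice with columns (level, mu) for one
    strain x resource; alternatively pass `levels` and `mu` arrays.
    Negative rates are retained: they anchor the low-resource limb.
    Deterministic: fixed multi-start initialization, best-rss fit returned.
    """
    if rates is not None:
        if strain_id == "" and "strain" in rates:
            strain_id = str(rates["strain"].iloc[0])
        if resource == "" and "resource" in rates:
            resource = str(rates["resource"].iloc[0])
        levels = rates["level"].to_numpy(float)
        mu = rates["mu"].to_numpy(float)
    levels, mu = _prepare(levels, mu)

    ks_floor = _KS_FLOOR_FRAC * float(levels.max())
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for p0 in _init_guesses(levels, mu):
        p0 = (max(p0[0], 1e-9), max(p0[1], ks_floor))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    monod_mu, levels, mu, p0=p0,
                    bounds=([1e-12, ks_floor], [np.inf, np.inf]),
                    maxfev=10000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((mu - monod_mu(levels, *popt)) ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, popt, pcov)
    if best is None:
        raise MonodFitError(
            f"Monod fit failed to converge for strain={strain_id!r} resource={resource!r} "
            f"(n={levels.size}, levels=[{levels.min():g}, {levels.max():g}])"
        )
    rss, popt, pcov = best
    mu_max_hat, ks_hat = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    tss = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    saturated = ks_hat <= ks_floor * 10.0
    return MonodFit(
        strain_id=strain_id, resource=resource,
        mu_max=mu_max_hat, Ks=ks_hat,
        se_mu_max=float(se[0]), se_Ks=float(se[1]),
        r_squared=r2, n_points=int(np.unique(levels).size),
        saturated_gradient=saturated,
    )


def r_star(fit: MonodFit, m: float = DEFAULT_MORTALITY) -> RStarEstimate:
    """Closed-form minimum resource requirement R* = m*Ks/(mu_max - m)."""
    if m < 0:
        raise ValueError("mortality m must be >= 0")
    if fit.mu_max <= m:
        raise NonViableError(
            f"mortality exceeds maximal growth for strain={fit.strain_id!r} "
            f"resource={fit.resource!r}: mu_max={fit.mu_max:g} <= m={m:g}"
        )
    rs = m * fit.Ks / (fit.mu_max - m)
    return RStarEstimate(fit.strain_id, fit.resource, rs, rs, rs, m)


def bootstrap_r_star(rates: pd.DataFrame, m: float = DEFAULT_MORTALITY,
                     n_boot: int = 1000, seed: int = 0) -> RStarEstimate:
    """Percentile bootstrap CI for R*, resampling replicates within levels.

    The point estimate comes from the full-data fit; each bootstrap draw
    resamples (level, mu) pairs with replacement stratified by level, so
    the gradient design is preserved.  Draws for which the fit degenerates
    are redrawn (at most 100 retries each).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    full = fit_monod(rates)
    point = r_star(full, m)
    rng = substream(seed, "bootstrap_r_star", full.strain_id, full.resource)
    levels = rates["level"].to_numpy(float)
    mu = rates["mu"].to_numpy(float)
    by_level = {lv: np.flatnonzero(levels == lv) for lv in np.unique(levels)}

    ks_floor = _KS_FLOOR_FRAC * float(levels.max())
    p0 = (full.mu_max, max(full.Ks, ks_floor))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(100):
            idx = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in by_level.values()]
            )
            lv, mv = levels[idx], mu[idx]
            if np.unique(lv).size < 3 or not np.any(mv > 0):
                continue
            try:
                # single start at the full-data optimum: cheap, deterministic
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(monod_mu, lv, mv, p0=p0,
                                        bounds=([1e-12, ks_floor], [np.inf, np.inf]),
                                        maxfev=5000)
                if popt[0] <= m:
                    continue
                draws[b] = m * popt[1] / (popt[0] - m)
                break
            except (RuntimeError, ValueError):
                continue
        else:
            raise MonodFitError(
                f"bootstrap failed 100 consecutive resamples for "
                f"strain={full.strain_id!r} resource={full.resource!r}"
            )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo = min(float(lo), point.r_star)
    hi = max(float(hi), point.r_star)
    return RStarEstimate(full.strain_id, full.resource, point.r_star, lo, hi, m)


_RESOURCE_COL = {"light": "I_star", "N": "N_star", "P": "P_star"}


def species_mean_traits(estimates: list[RStarEstimate],
                        strain_to_species: dict[str, str],
                        monod_fits: list[MonodFit] | None = None) -> pd.DataFrame:
    """Average strain R*s to species level; mu_max_max is the max across fits.

    Species missing a resource get NaN in that column (explicit missing
    marker), never a silent drop.
    """
    rows: dict[str, dict[str, float]] = {}
    acc: dict[tuple[str, str], list[float]] = {}
    for est in estimates:
        sp = strain_to_species[est.strain_id]
        acc.setdefault((sp, est.resource), []).append(est.r_star)
    for (sp, resource), vals in acc.items():
        col = _RESOURCE_COL.get(resource, f"{resource}_star")
        rows.setdefault(sp, {})[col] = float(np.mean(vals))
    if monod_fits:
        for fit in monod_fits:
            sp = strain_to_species[fit.strain_id]
            d = rows.setdefault(sp, {})
            d["mu_max_max"] = max(d.get("mu_max_max", -np.inf), fit.mu_max)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "species"
    for col in ["I_star", "N_star", "P_star"]:
        if col not in df:
            df[col] = np.nan
    return df
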