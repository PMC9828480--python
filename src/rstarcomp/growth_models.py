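"""Per-capita growth-rate estimation from fluorescence time series.

Each replicate series is fitted, on the natural-log scale, with a family of
four piecewise-linear models and the best one is chosen by small-sample
corrected AIC (AICc):

====== ==================================================== ========
model  ln B(t)                                               k
====== ==================================================== ========
exp    ln_b0 + mu * t                                        3
lag    ln_b0 for t < t_lag, then slope mu                    4
sat    slope mu from ln_b0 until ln_ceiling, then flat       4
lagsat lag plateau, slope mu, ceiling plateau                5
====== ==================================================== ========

``k`` counts shape parameters plus one for the residual variance.  The
exponential-phase slope ``mu`` of the selected model is the growth-rate
estimate for the series.  Breakpoints are located by a deterministic
grid search over observation midpoints followed by a fine local grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "GrowthFitError",
    "fit_growth_models",
    "select_best",
    "growth_rate_table",
    "read_growth_csv",
    "write_fit_report",
]

MODEL_K = {"exp": 3, "lag": 4, "sat": 4, "lagsat": 5}
_MODEL_ORDER = {"exp": 0, "lag": 1, "sat": 2, "lagsat": 3}
_RSS_FLOOR = 1e-300  # keeps AICc finite on exact fits
_N_FINE = 25  # fine-grid points per breakpoint refinement


class GrowthFitError(ValueError):
    """Raised when a series violates the fitting preconditions."""


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate fluorescence time course at one resource level."""

    strain_id: str
    resource: str
    level: float
    replicate_id: str
    times: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rfu", y)
        if t.size != y.size:
            raise GrowthFitError("times and rfu must have equal length")
        if t.size < 4:
            raise GrowthFitError(
                f"series {self.key()} has {t.size} observations; >= 4 required"
            )
        if np.any(np.diff(t) <= 0):
            raise GrowthFitError(f"series {self.key()}: times must be strictly increasing")
        if np.any(y <= 0) or not np.all(np.isfinite(y)):
            raise GrowthFitError(f"series {self.key()}: rfu must be positive and finite")

    def key(self) -> tuple[str, str, float, str]:
        return (self.strain_id, self.resource, float(self.level), self.replicate_id)


@dataclass
class GrowthFit:
    """One fitted growth model for one series."""

    model: str
    mu: float
    ln_b0: float
    t_lag: float | None = None
    ln_ceiling: float | None = None
    rss: float = np.nan
    n_obs: int = 0
    k_params: int = 0
    aicc: float = np.nan
    selected: bool = False


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian-residual closed form; guard n - k - 1 >= 1 upstream.
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _lstsq_basis(basis: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return coef, float(resid @ resid)


def _piecewise_rss(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, float]:
    """LSQ of ln y on the ramp clip(t, lo, hi): plateau-slope-plateau."""
    basis = np.column_stack([np.ones_like(t), np.clip(t, lo, hi) - lo])
    return _lstsq_basis(basis, y)


def _grid_1d(t: np.ndarray) -> np.ndarray:
    # interior observation midpoints: breakpoints that change the fit
    return (t[1:-1] + t[2:]) / 2.0 if t.size > 3 else np.array([])


def _refine(t: np.ndarray, candidates: np.ndarray, best: float) -> np.ndarray:
    """Fine grid around `best` spanning its neighbouring candidates."""
    lo = candidates[candidates < best]
    hi = candidates[candidates > best]
    a = lo.max() if lo.size else t[0] + 1e-9
    b = hi.min() if hi.size else t[-1] - 1e-9
    return np.linspace(a, b, _N_FINE)


def _fit_exp(t: np.ndarray, y: np.ndarray) -> GrowthFit:
    coef, rss = _lstsq_basis(np.column_stack([np.ones_like(t), t]), y)
    return GrowthFit("exp", mu=float(coef[1]), ln_b0=float(coef[0]), rss=rss)


def _fit_one_break(t: np.ndarray, y: np.ndarray, kind: str) -> GrowthFit | None:
    mids = np.concatenate([[(t[0] + t[1]) / 2.0], _grid_1d(t)])
    # t[0] (lag) / t[-1] (sat) reproduce the exponential model, so the
    # breakpoint families nest it and rss is monotone along the family.
    cands = np.concatenate([[t[0]], mids]) if kind == "lag" else np.concatenate([mids, [t[-1]]])
    if cands.size == 0:
        return None

    def rss_at(bp: float) -> float:
        lo, hi = (bp, t[-1] + 1.0) if kind == "lag" else (t[0] - 1.0, bp)
        return _piecewise_rss(t, y, lo, hi)[1]

    coarse = np.array([rss_at(b) for b in cands])
    best = cands[int(np.argmin(coarse))]
    pool = np.concatenate([[best], _refine(t, cands, best)])
    pool_rss = np.array([rss_at(b) for b in pool])
    bp = float(pool[int(np.argmin(pool_rss))])

    if kind == "lag":
        coef, rss = _piecewise_rss(t, y, bp, t[-1] + 1.0)
        return GrowthFit("lag", mu=float(coef[1]), ln_b0=float(coef[0]), t_lag=bp, rss=rss)
    coef, rss = _piecewise_rss(t, y, t[0] - 1.0, bp)
    ceiling = float(coef[0] + coef[1] * (bp - (t[0] - 1.0)))
    return GrowthFit("sat", mu=float(coef[1]), ln_b0=float(coef[0]), ln_ceiling=ceiling, rss=rss)


def _fit_lagsat(t: np.ndarray, y: np.ndarray) -> GrowthFit | None:
    cands = np.unique(np.concatenate([[t[0]], [(t[0] + t[1]) / 2.0], _grid_1d(t), [t[-1]]]))
    if cands.size < 2:
        return None
    best = (np.inf, None)
    for i, lo in enumerate(cands[:-1]):
        for hi in cands[i + 1 :]:
            rss = _piecewise_rss(t, y, lo, hi)[1]
            if rss < best[0]:
                best = (rss, (lo, hi))
    if best[1] is None:  # degenerate data (e.g. non-finite rss everywhere)
        return None
    lo, hi = best[1]
    # coordinate-wise fine refinement of the two breakpoints
    for _ in range(2):
        fine_lo = _refine(t, cands, lo)
        pool = np.concatenate([[lo], fine_lo[fine_lo < hi]])
        r = [_piecewise_rss(t, y, b, hi)[1] for b in pool]
        lo = float(pool[int(np.argmin(r))])
        fine_hi = _refine(t, cands, hi)
        pool = np.concatenate([[hi], fine_hi[fine_hi > lo]])
        r = [_piecewise_rss(t, y, lo, b)[1] for b in pool]
        hi = float(pool[int(np.argmin(r))])
    coef, rss = _piecewise_rss(t, y, lo, hi)
    ceiling = float(coef[0] + coef[1] * (hi - lo))
    return GrowthFit(
        "lagsat", mu=float(coef[1]), ln_b0=float(coef[0]), t_lag=float(lo),
        ln_ceiling=ceiling, rss=rss,
    )


def fit_growth_models(series: GrowthSeries) -> list[GrowthFit]:
    """Fit the four-model family to one series by least squares on ln(rfu).

    The exponential model is always returned; the lag / sat / lagsat
    variants are returned only when ``n_obs > k_params + 1`` so that the
    AICc correction term stays defined.
    """
    t = series.times
    y = np.log(series.rfu)
    n = t.size

    fits: list[GrowthFit] = [_fit_exp(t, y)]
    if n > MODEL_K["lag"] + 1:
        for kind in ("lag", "sat"):
            f = _fit_one_break(t, y, kind)
            if f is not None:
                fits.append(f)
    if n > MODEL_K["lagsat"] + 1:
        f = _fit_lagsat(t, y)
        if f is not None:
            fits.append(f)

    for f in fits:
        f.n_obs = n
        f.k_params = MODEL_K[f.model]
        f.aicc = _aicc(f.rss, n, f.k_params)
    return fits


def select_best(fits: Sequence[GrowthFit]) -> GrowthFit:
    """Return the fit with minimal AICc.

    Ties break toward fewer parameters, then toward the exponential model.
    """
    if not fits:
        raise GrowthFitError("no fits to select from")
    valid = [f for f in fits if np.isfinite(f.aicc)]
    if not valid:
        raise GrowthFitError("all fits have non-finite AICc")
    best = min(valid, key=lambda f: (f.aicc, f.k_params, _MODEL_ORDER[f.model]))
    for f in fits:
        f.selected = f is best
    return best


def growth_rate_table(all_series: Iterable[GrowthSeries]) -> pd.DataFrame:
    """One selected-model mu per series, sorted by (strain, resource, level)."""
    rows = []
    for s in all_series:
        try:
            best = select_best(fit_growth_models(s))
        except (GrowthFitError, np.linalg.LinAlgError, ValueError) as err:
            raise GrowthFitError(f"series {s.key()}: {err}") from err
        rows.append(
            {
                "strain": s.strain_id,
                "resource": s.resource,
                "level": float(s.level),
                "replicate": s.replicate_id,
                "mu": best.mu,
                "model": best.model,
            }
        )
    df = pd.DataFrame(rows, columns=["strain", "resource", "level", "replicate", "mu", "model"])
    if len(df):
        df = df.sort_values(["strain", "resource", "level", "replicate"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def read_growth_csv(path) -> list[GrowthSeries]:
    """Read the long-format growth CSV written by synthetic_data."""
    df = pd.read_csv(path)
    out = []
    keys = ["strain", "resource", "level", "replicate"]
    for (strain, resource, level, rep), g in df.groupby(keys, sort=True):
        g = g.sort_values("day")
        out.append(
            GrowthSeries(
                strain_id=str(strain),
                resource=str(resource),
                level=float(level),
                replicate_id=str(rep),
                times=g["day"].to_numpy(float),
                rfu=g["rfu"].to_numpy(float),
            )
        )
    return out


def write_fit_report(all_series: Iterable[GrowthSeries], path) -> None:
    """Per-series JSON report with every candidate model's AICc."""
    report = []
    for s in all_series:
        fits = fit_growth_models(s)
        select_best(fits)
        report.append(
            {
                "strain": s.strain_id,
                "resource": s.resource,
                "level": float(s.level),
                "replicate": s.replicate_id,
                "fits": [asdict(f) for f in fits],
            }
        )
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
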