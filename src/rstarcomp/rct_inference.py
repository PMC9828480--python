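"""Do lab-measured competitive traits predict community outcomes?

Prediction 1: change in relative abundance under a limiting resource is
negatively related to the (z-scored) R* for that resource — random-intercept
linear model with resource identity as the grouping factor.

Prediction 2: change in relative abundance under balanced supply correlates
positively with the species' maximum growth rate — Spearman rank
correlation (exact permutation p for n <= 9).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InferenceResult",
    "zscore_by_resource",
    "fit_prediction1",
    "fit_prediction2",
    "spearman",
    "predict_winner",
    "TREATMENT_RESOURCE",
]

log = logging.getLogger(__name__)

#: which trait column pairs with which limiting-resource treatment
TREATMENT_RESOURCE = {"L-lim": "light", "N-lim": "N", "P-lim": "P"}


@dataclass
class InferenceResult:
    model: str
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    p_slope: float
    r_squared: float
    n: int
    random_intercept_var: float = np.nan
    residuals: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def zscore_by_resource(traits: pd.DataFrame, value: str = "r_star") -> pd.DataFrame:
    """Standardize trait values within each resource (sample sd, ddof=1)."""
    def _z(g: pd.Series) -> pd.Series:
        if g.size < 2:
            raise ValueError("need >= 2 species per resource to z-score")
        sd = g.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance within a resource: {g.name!r}")
        return (g - g.mean()) / sd

    out = traits.copy()
    out["z"] = traits.groupby("resource")[value].transform(_z)
    return out


def fit_prediction1(data: pd.DataFrame) -> InferenceResult:
    """Random-intercept model: delta ~ slope * z(R*) + (1 | resource), ML fit.

    `data` needs columns delta, z, resource.  With a single resource the
    design is degenerate and the fit falls back to ordinary least squares
    (logged).  The reported R^2 is the squared correlation of fitted vs
    observed values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = data.dropna(subset=["delta", "z", "resource"]).copy()
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 observations")
    n_resources = data["resource"].nunique()

    use_ols = n_resources < 2
    if use_ols:
        log.warning("single resource: falling back to ordinary least squares")
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("delta ~ z", data, groups=data["resource"])
                fit = md.fit(reml=False, method="lbfgs")
            float(fit.bse["z"])  # may be nan/raise on singular designs
            if not np.isfinite(fit.params["z"]):
                raise np.linalg.LinAlgError("non-finite estimate")
        except (np.linalg.LinAlgError, ValueError) as err:
            log.warning("mixed model failed (%s): falling back to OLS", err)
            use_ols = True

    if use_ols:
        X = sm.add_constant(data["z"].to_numpy())
        ols = sm.OLS(data["delta"].to_numpy(), X).fit()
        fitted = ols.fittedvalues
        resid = ols.resid
        result = InferenceResult(
            model="ols", slope=float(ols.params[1]), intercept=float(ols.params[0]),
            se_slope=float(ols.bse[1]), se_intercept=float(ols.bse[0]),
            p_slope=float(ols.pvalues[1]),
            r_squared=_fit_r2(data["delta"].to_numpy(), fitted), n=n,
            residuals=np.asarray(resid),
        )
    else:
        try:
            fitted = np.asarray(fit.fittedvalues)
        except (ValueError, np.linalg.LinAlgError):
            # zero random-intercept variance: fixed-effects fit only
            fitted = np.asarray(md.exog @ fit.fe_params)
        resid = data["delta"].to_numpy() - fitted
        result = InferenceResult(
            model="mixed", slope=float(fit.params["z"]),
            intercept=float(fit.params["Intercept"]),
            se_slope=float(fit.bse["z"]), se_intercept=float(fit.bse["Intercept"]),
            p_slope=float(fit.pvalues["z"]),
            r_squared=_fit_r2(data["delta"].to_numpy(), fitted), n=n,
            random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
            residuals=resid,
        )
    result.diagnostics = _residual_diagnostics(result.residuals, fitted)
    return result


def _fit_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    if np.std(fitted) == 0 or np.std(observed) == 0:
        return 0.0
    return float(np.corrcoef(observed, fitted)[0, 1] ** 2)


def _residual_diagnostics(resid: np.ndarray, fitted: np.ndarray) -> dict:
    """Normality (Shapiro) and homoscedasticity (|resid| vs fitted) checks."""
    out = {}
    if resid is not None and len(resid) >= 3 and np.ptp(resid) > 0:
        try:
            w, p = stats.shapiro(resid)
            out["shapiro_w"], out["shapiro_p"] = float(w), float(p)
        except ValueError:
            pass
        if np.std(fitted) > 0 and np.std(np.abs(resid)) > 0:
            rho, p = stats.spearmanr(np.abs(resid), fitted)
            out["scale_trend_rho"], out["scale_trend_p"] = float(rho), float(p)
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with mid-ranks; exact permutation p for n <= 9.

    For larger n the usual t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with df = n-2 is used (two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    if n < 4:
        raise ValueError("need >= 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(rx_c[list(perm)] @ ry_c)
            if stat >= obs - 1e-9 * denom:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def fit_prediction2(delta_redfield, mu_max_max) -> tuple[float, float]:
    """Spearman correlation of Redfield-supply abundance change vs mu_max."""
    return spearman(delta_redfield, mu_max_max)


_RES_COL = {"light": "I_star", "N": "N_star", "P": "P_star"}


def predict_winner(traits: pd.DataFrame, resource: str) -> pd.DataFrame:
    """Rank species by R* for the limiting resource (rank 1 = predicted winner).

    Ties share rank 1 and are flagged.  Rankings are invariant to monotone
    rescaling of R* within the resource.
    """
    col = _RES_COL.get(resource, resource)
    if col not in traits.columns:
        raise KeyError(f"no trait column for resource {resource!r}")
    sub = traits[[col]].dropna()
    if sub.empty:
        raise ValueError(f"no trait data for resource {resource!r}")
    sub = sub.sort_values(col, kind="mergesort")
    ranks = stats.rankdata(sub[col], method="min")
    out = sub.reset_index()
    out["rank"] = ranks
    out["tied"] = pd.Series(ranks).duplicated(keep=False).to_numpy()
    return out
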