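"""Exponential behavioral-economic demand: fitting, normalization, ANOVA.

The model relates consumption Q to price C (the fixed-ratio response
requirement):

    log10 Q = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

Q0 is demand intensity (consumption as price approaches zero), alpha the
elasticity rate, and k the range of consumption in log10 units. Essential
value — the commodity's resistance to price — is 1/alpha. Fitting is
nonlinear least squares of log10(Q + 0.1) (the 0.1 offset keeps zero
consumption representable) with Q0 and alpha free per curve and k either
fixed or shared across all curves of a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

CONSUMPTION_OFFSET = 0.1
_ALPHA_STARTS = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class DemandFit:
    """Fitted parameters and diagnostics for one consumption-vs-price curve."""

    subject: str
    group: str
    milk_pct: float
    q0: float
    alpha: float
    k: float
    r2: float
    ss: float
    df: int
    cov: np.ndarray  # 2x2 over (q0, alpha), k treated as fixed
    se_q0: float
    se_alpha: float
    converged: bool
    status: str = "ok"  # ok | rejected_zero | not_converged

    @property
    def essential_value(self) -> float:
        return 1.0 / self.alpha


def model_log10(params: np.ndarray, k: float, prices: np.ndarray) -> np.ndarray:
    """Model prediction on the fitted scale, log10(Q_pred + 0.1).

    The 0.1 offset is applied to predictions and observations alike, so
    noiseless model data is reproduced exactly and zero consumption stays
    representable.
    """
    q0, alpha = params
    pred = 10.0 ** (np.log10(q0) + k * (np.exp(-alpha * q0 * prices) - 1.0))
    return np.log10(pred + CONSUMPTION_OFFSET)


def param_se(ss: float, df: int, cov: np.ndarray) -> np.ndarray:
    """SE_i = sqrt((SS / DF) * Cov_ii) for each free parameter."""
    if df <= 0:
        raise ValueError("residual degrees of freedom must be > 0")
    return np.sqrt(np.maximum(ss / df, 0.0) * np.diag(cov))


def _fit_single(
    prices: np.ndarray, y: np.ndarray, k: float
) -> tuple[np.ndarray, float, bool]:
    """Best (q0, alpha), SS, and convergence for fixed k, multi-start."""
    q_obs = 10.0**y - CONSUMPTION_OFFSET
    q0_start = max(float(np.max(q_obs)), 1.0)
    best = None
    # optimize in log space: (Q0, alpha) differ by orders of magnitude and
    # the objective has a mild ridge between them
    for a0 in _ALPHA_STARTS:
        for q0_0 in (q0_start, 5.0 * q0_start):
            try:
                res = least_squares(
                    lambda u: model_log10(np.exp(u), k, prices) - y,
                    x0=np.log([q0_0, a0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
                )
            except Exception:
                continue
            ss = float(2.0 * res.cost)
            if best is None or ss < best[1]:
                best = (np.exp(res.x), ss, bool(res.success))
    if best is None:
        return np.array([q0_start, 1e-3]), float("inf"), False
    return best


def _curve_groups(observations: pd.DataFrame):
    return observations.groupby(["subject", "group", "milk_pct"], sort=True)


def estimate_shared_k(
    observations: pd.DataFrame, bounds: tuple[float, float] = (0.3, 8.0)
) -> float:
    """One k for the whole dataset, by profiling the pooled residual SS.

    For each candidate k the per-curve (Q0, alpha) minimizers are nested out;
    the outer 1-D problem is solved by bounded scalar minimization.
    """
    curves = [
        (sub["price"].to_numpy(float),
         np.log10(sub["consumption"].to_numpy(float) + CONSUMPTION_OFFSET))
        for _, sub in _curve_groups(observations)
        if sub["consumption"].sum() > 0
    ]
    if not curves:
        raise ValueError("no fittable curves (all consumption zero)")

    def pooled_ss(k: float) -> float:
        return sum(_fit_single(p, y, k)[1] for p, y in curves)

    # coarse scan first: the profiled objective need not be unimodal
    grid = np.linspace(bounds[0], bounds[1], 32)
    ss = [pooled_ss(k) for k in grid]
    i = int(np.argmin(ss))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(pooled_ss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def fit_demand(
    observations: pd.DataFrame, k_mode: str | float = "shared"
) -> list[DemandFit]:
    """Fit every (subject, milk_pct) curve in a tidy demand table.

    ``k_mode`` is "shared" (a single k estimated jointly across all curves)
    or a fixed positive value. Requires >= 3 distinct prices per curve.
    All-zero curves are rejected with status "rejected_zero" and excluded
    from the shared-k estimate.
    """
    if isinstance(k_mode, str):
        if k_mode != "shared":
            raise ValueError("k_mode must be 'shared' or a positive number")
        k = estimate_shared_k(observations)
    else:
        k = float(k_mode)
        if k <= 0:
            raise ValueError("fixed k must be positive")

    fits: list[DemandFit] = []
    for (subject, group, milk), sub in _curve_groups(observations):
        prices = sub["price"].to_numpy(float)
        q = sub["consumption"].to_numpy(float)
        if len(np.unique(prices)) < 3:
            raise ValueError(
                f"curve {subject}/{milk}: need >= 3 distinct prices"
            )
        y = np.log10(q + CONSUMPTION_OFFSET)
        df = len(y) - 2
        if np.all(q == 0):
            fits.append(
                DemandFit(subject, group, milk, np.nan, np.nan, k, np.nan,
                          np.nan, df, np.full((2, 2), np.nan), np.nan, np.nan,
                          False, status="rejected_zero")
            )
            continue
        params, ss, ok = _fit_single(prices, y, k)
        resid_var = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss / resid_var if resid_var > 0 else np.nan
        # covariance of (q0, alpha) at the optimum, k fixed
        jac = _numeric_jacobian(params, k, prices)
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            ok = False
        se = (param_se(ss, df, cov) if df > 0 and np.all(np.isfinite(cov))
              else np.array([np.nan, np.nan]))
        fits.append(
            DemandFit(subject, group, milk, float(params[0]), float(params[1]),
                      k, float(r2), ss, df, cov, float(se[0]), float(se[1]),
                      ok, status="ok" if ok else "not_converged")
        )
    return fits


def _numeric_jacobian(params: np.ndarray, k: float, prices: np.ndarray) -> np.ndarray:
    eps = np.maximum(np.abs(params), 1e-8) * 1e-7
    jac = np.empty((len(prices), 2))
    for i in range(2):
        hi, lo = params.copy(), params.copy()
        hi[i] += eps[i]
        lo[i] -= eps[i]
        jac[:, i] = (model_log10(hi, k, prices) - model_log10(lo, k, prices)) / (
            2 * eps[i]
        )
    return jac


def fits_table(fits: list[DemandFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "subject": f.subject, "group": f.group, "milk_pct": f.milk_pct,
                "q0": f.q0, "alpha": f.alpha, "k": f.k,
                "essential_value": (f.essential_value if np.isfinite(f.alpha)
                                    else np.nan),
                "r2": f.r2, "ss": f.ss, "df": f.df,
                "se_q0": f.se_q0, "se_alpha": f.se_alpha,
                "converged": f.converged, "status": f.status,
            }
        )
    return pd.DataFrame(rows)


def normalize_demand(fit: DemandFit, observations: pd.DataFrame) -> pd.DataFrame:
    """Express consumption as % of Q0 and price in units buying 1% of Q0.

    normalized consumption = 100 * Q / Q0; normalized price = C * Q0 / 100.
    """
    if fit.status != "ok" or not np.isfinite(fit.q0) or fit.q0 <= 0:
        raise ValueError("normalization requires a converged fit with Q0 > 0")
    out = observations.copy()
    out["norm_consumption"] = 100.0 * out["consumption"] / fit.q0
    out["norm_price"] = out["price"] * fit.q0 / 100.0
    return out


def demand_anova(
    parameter_table: pd.DataFrame, value_col: str
) -> dict[str, dict[str, float]]:
    """Two-way fixed-effects ANOVA of a demand parameter.

    ``parameter_table`` holds one row per subject x group x milk_pct with the
    fitted value in ``value_col``. Returns F, numerator/denominator df, and p
    for the milk-concentration effect, the treatment-group effect, and their
    interaction. Unbalanced tables are computed with type-II sums of squares
    and flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = parameter_table.rename(columns={value_col: "value"}).copy()
    counts = data.groupby(["group", "milk_pct"]).size()
    balanced = counts.nunique() == 1

    if data["value"].nunique() == 1:
        return {
            "milk_pct": {"F": 0.0, "df_num": np.nan, "df_den": np.nan,
                         "p": np.nan, "zero_variance": True},
            "group": {"F": 0.0, "df_num": np.nan, "df_den": np.nan,
                      "p": np.nan, "zero_variance": True},
            "interaction": {"F": 0.0, "df_num": np.nan, "df_den": np.nan,
                            "p": np.nan, "zero_variance": True},
        }

    model = smf.ols("value ~ C(group) * C(milk_pct)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])

    def effect(name: str) -> dict[str, float]:
        row = table.loc[name]
        return {
            "F": float(row["F"]),
            "df_num": float(row["df"]),
            "df_den": df_resid,
            "p": float(row["PR(>F)"]),
            "balanced": bool(balanced),
        }

    return {
        "milk_pct": effect("C(milk_pct)"),
        "group": effect("C(group)"),
        "interaction": effect("C(group):C(milk_pct)"),
    }
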