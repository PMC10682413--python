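"""Pairwise Granger causality on short per-subject neurotransmitter series.

A series A "Granger-causes" B when lagged values of A improve the prediction
of B beyond B's own lags. For each lag order m up to ``max_lag`` the test
compares nested OLS models on the common sample of T_eff = T - m usable
observations:

    restricted:    B_t ~ 1 + B_{t-1..t-m}
    unrestricted:  B_t ~ 1 + B_{t-1..t-m} + A_{t-1..t-m}

    F = ((SSR_r - SSR_u) / m) / (SSR_u / (T_eff - 2m - 1))

with p from F(m, T_eff - 2m - 1). Per-lag p-values are aggregated to one
p-value per ordered pair (minimum over lags 1..max_lag by default, or the
max-lag-only p). The per-subject 16-sample K+ session (all blocks in time
order) is the unit series; group-level summaries are distributions of
per-subject aggregated p-values, with emphasis on the eight DA-centric
ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import NEUROTRANSMITTERS


class SeriesTooShortError(ValueError):
    pass


class CollinearSeriesError(ValueError):
    pass


@dataclass(frozen=True)
class GrangerSpec:
    """Test settings: maximum lag, decision level, lag aggregation rule."""

    max_lag: int = 3
    alpha: float = 0.05
    aggregation: str = "min"  # "min" over lags 1..max_lag, or "maxlag" only

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.aggregation not in ("min", "maxlag"):
            raise ValueError("aggregation must be 'min' or 'maxlag'")

    def min_length(self) -> int:
        """Smallest series length with >= 2 residual df at max_lag."""
        return 3 * self.max_lag + 2


@dataclass(frozen=True)
class GrangerResult:
    subject: str
    group: str
    source: str
    target: str
    lag_p: dict[int, float]
    lag_f: dict[int, float]
    p: float
    n_obs: int


def _lag_matrix(x: np.ndarray, m: int) -> np.ndarray:
    """Columns x_{t-1}..x_{t-m} aligned with x_t for t = m..T-1."""
    return np.column_stack([x[m - j - 1 : len(x) - j - 1] for j in range(m)])


def _ols_ssr(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise CollinearSeriesError("perfectly collinear lag regressors")
    resid = y - X @ coef
    return float(resid @ resid)


def granger_test(
    series_a: np.ndarray,
    series_b: np.ndarray,
    spec: GrangerSpec | None = None,
    subject: str = "",
    group: str = "",
    source: str = "A",
    target: str = "B",
) -> GrangerResult:
    """Test whether ``series_a`` Granger-causes ``series_b``.

    Both series must be equal-length, time-ordered observations from the
    same subject. Raises SeriesTooShortError / CollinearSeriesError on
    degenerate input.
    """
    spec = GrangerSpec() if spec is None else spec
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    T = len(a)
    if T < spec.min_length():
        raise SeriesTooShortError(
            f"series length {T} < minimum {spec.min_length()} "
            f"for max_lag={spec.max_lag}"
        )
    if np.allclose(a, b):
        raise CollinearSeriesError("source and target series are identical")

    lag_p: dict[int, float] = {}
    lag_f: dict[int, float] = {}
    for m in range(1, spec.max_lag + 1):
        y = b[m:]
        t_eff = T - m
        ones = np.ones((t_eff, 1))
        Xr = np.hstack([ones, _lag_matrix(b, m)])
        Xu = np.hstack([Xr, _lag_matrix(a, m)])
        ssr_r = _ols_ssr(Xr, y)
        ssr_u = _ols_ssr(Xu, y)
        df_den = t_eff - 2 * m - 1
        if df_den < 1:
            raise SeriesTooShortError(
                f"no residual degrees of freedom at lag {m} (T={T})"
            )
        if ssr_u <= 0:
            # unrestricted model interpolates: maximal evidence
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((ssr_r - ssr_u) / m) / (ssr_u / df_den)
            f_stat = max(f_stat, 0.0)
            p = float(stats.f.sf(f_stat, m, df_den))
        lag_f[m] = float(f_stat)
        lag_p[m] = p

    agg = min(lag_p.values()) if spec.aggregation == "min" else lag_p[spec.max_lag]
    return GrangerResult(
        subject=subject, group=group, source=source, target=target,
        lag_p=lag_p, lag_f=lag_f, p=float(agg), n_obs=T,
    )


# ---------------------------------------------------------------------------
# group-level aggregation
# ---------------------------------------------------------------------------

#: The eight DA-centric ordered pairs reported in the study.
DA_PAIRS: tuple[tuple[str, str], ...] = tuple(
    [(nt, "DA") for nt in NEUROTRANSMITTERS if nt != "DA"]
    + [("DA", nt) for nt in NEUROTRANSMITTERS if nt != "DA"]
)


def subject_series(table: pd.DataFrame) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Per-subject time-ordered concentration series for each NT.

    Returns {(group, subject): {nt: series}} using the full session (all K+
    blocks concatenated in time order).
    """
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (group, subject), sub in table.groupby(["group", "subject"], sort=False):
        series = {}
        for nt, rows in sub.groupby("neurotransmitter", sort=False):
            series[nt] = rows.sort_values("sample_index")["conc_nM"].to_numpy(float)
        out[(group, subject)] = series
    return out


@dataclass
class PairDistribution:
    group: str
    source: str
    target: str
    p_values: list[float]
    excluded: int = 0

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values)) if self.p_values else float("nan")

    def decision(self, alpha: float = 0.05) -> bool:
        """True when the group-median p falls below the decision level."""
        return bool(self.p_values) and self.median_p < alpha


def causal_matrix(
    table: pd.DataFrame, spec: GrangerSpec | None = None
) -> dict[tuple[str, str, str], PairDistribution]:
    """Per-group distributions of per-subject aggregated p-values.

    Keys are (group, source, target) over all 20 ordered NT pairs. Subjects
    whose series fail the test preconditions are excluded and counted.
    """
    spec = GrangerSpec() if spec is None else spec
    per_subj = subject_series(table)
    out: dict[tuple[str, str, str], PairDistribution] = {}
    for (group, subject), series in sorted(per_subj.items()):
        for source in NEUROTRANSMITTERS:
            for target in NEUROTRANSMITTERS:
                if source == target:
                    continue
                key = (group, source, target)
                dist = out.setdefault(
                    key, PairDistribution(group, source, target, [])
                )
                try:
                    res = granger_test(
                        series[source], series[target], spec,
                        subject=subject, group=group,
                        source=source, target=target,
                    )
                except (SeriesTooShortError, CollinearSeriesError, KeyError):
                    dist.excluded += 1
                    continue
                dist.p_values.append(res.p)
    return out


def results_table(
    matrix: dict[tuple[str, str, str], PairDistribution], alpha: float = 0.05
) -> pd.DataFrame:
    """Long-format summary: group, source, target, n, median_p, decision."""
    rows = [
        {
            "group": d.group,
            "source": d.source,
            "target": d.target,
            "n_subjects": len(d.p_values),
            "n_excluded": d.excluded,
            "median_p": d.median_p,
            "causal": d.decision(alpha),
            "da_centric": (d.source, d.target) in DA_PAIRS,
        }
        for d in matrix.values()
    ]
    return pd.DataFrame(rows)


def boxplot_summary(values) -> dict[str, float]:
    """Median, quartiles, and Tukey whiskers (most extreme data within
    1.5 * IQR of the box) of a p-value distribution."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty value set")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr]
    hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo[0]),
        "whisker_high": float(hi[-1]),
    }
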