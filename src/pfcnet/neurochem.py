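"""Microdialysis summaries: basal levels, cumulative K+ blocks, percent-basal
time courses, and the group statistics computed from them.

Basal level = mean of the four 4 mM baseline samples. Cumulative level =
sum of the four samples within one K+ block (a mean-based variant is
available for sensitivity checks). Percent-basal series retain 13 points:
the last baseline sample (t = 0) plus the 12 post-baseline samples.
Group contrasts are pooled-variance unpaired two-tailed t tests per
neurotransmitter x K+ (Welch optional) and a two-way treatment x time
fixed-effects ANOVA per neurotransmitter with Tukey post-hocs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .design import GROUPS, K_SCHEDULE, NEUROTRANSMITTERS

BASELINE_K = 4


def compute_basal(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the four baseline (4 mM) samples per subject x NT.

    Returns columns subject, group, neurotransmitter, basal_nM, n_baseline.
    Raises if any subject x NT is missing baseline samples.
    """
    base = table[table["k_mM"] == BASELINE_K]
    if base.empty:
        raise ValueError("no baseline (4 mM) samples present")
    out = (
        base.groupby(["subject", "group", "neurotransmitter"], sort=True)["conc_nM"]
        .agg(basal_nM="mean", n_baseline="size")
        .reset_index()
    )
    expected = base.groupby(["subject", "neurotransmitter"]).size()
    if expected.nunique() != 1:
        raise ValueError("ragged baseline block: unequal sample counts")
    return out


def cumulative_levels(table: pd.DataFrame, method: str = "sum") -> pd.DataFrame:
    """Per-block cumulative level per subject x NT x K+.

    ``method`` is "sum" (default: the cumulative level of all four samples)
    or "mean" (sensitivity variant). Raises if any subject is missing a
    block.
    """
    if method not in ("sum", "mean"):
        raise ValueError("method must be 'sum' or 'mean'")
    agg = (
        table.groupby(
            ["subject", "group", "neurotransmitter", "k_mM"], sort=True
        )["conc_nM"]
        .agg(cumulative_nM=method, n_samples="size")
        .reset_index()
    )
    blocks_per = agg.groupby(["subject", "neurotransmitter"])["k_mM"].nunique()
    if blocks_per.nunique() != 1:
        raise ValueError("missing K+ block for some subject x neurotransmitter")
    return agg


def percent_basal_series(table: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-basal time courses, 13 points per subject x NT.

    Points retained: the last baseline sample as t = 0 plus all
    post-baseline samples; pct_basal = 100 * conc / basal. Series with zero
    basal are excluded and reported in the ``excluded`` attribute of the
    returned frame (``df.attrs["excluded"]``).
    """
    basal = compute_basal(table).set_index(["subject", "neurotransmitter"])
    merged = table.merge(
        basal["basal_nM"].reset_index(), on=["subject", "neurotransmitter"]
    )
    keep = (merged["k_mM"] != BASELINE_K) | (merged["time_min"] == 0.0)
    merged = merged[keep].copy()
    zero = merged["basal_nM"] <= 0
    excluded = (
        merged.loc[zero, ["subject", "neurotransmitter"]]
        .drop_duplicates()
        .to_records(index=False)
        .tolist()
    )
    merged = merged[~zero].copy()
    merged["pct_basal"] = 100.0 * merged["conc_nM"] / merged["basal_nM"]
    out = merged[
        ["subject", "group", "neurotransmitter", "sample_index",
         "time_min", "k_mM", "basal_nM", "pct_basal"]
    ].sort_values(["subject", "neurotransmitter", "sample_index"]).reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


def _pooled_t(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float]:
    if (np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0
            and np.mean(x) == np.mean(y)):
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        # degenerate zero-variance groups trip a scipy precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def compare_cumulative(
    levels: pd.DataFrame, welch: bool = False
) -> pd.DataFrame:
    """Unpaired two-tailed t tests between groups per NT x K+.

    Pooled-variance by default (``welch=True`` switches to Welch's t).
    fold_change is the ratio of group means (first group over second).
    """
    rows = []
    for (nt, k), sub in levels.groupby(["neurotransmitter", "k_mM"], sort=True):
        by_group = {g: s["cumulative_nM"].to_numpy(float)
                    for g, s in sub.groupby("group")}
        for g1, g2 in itertools.combinations(
            [g for g in GROUPS if g in by_group], 2
        ):
            x, y = by_group[g1], by_group[g2]
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"need >= 2 subjects per group ({g1}/{g2})")
            t, p = _pooled_t(y, x, welch)  # sign: second group relative to first
            rows.append(
                {
                    "neurotransmitter": nt, "k_mM": k,
                    "group_a": g1, "group_b": g2,
                    "t": t, "p": p,
                    "fold_change": float(np.mean(y) / np.mean(x)),
                    "n_a": len(x), "n_b": len(y),
                }
            )
    return pd.DataFrame(rows)


def timecourse_anova(
    series: pd.DataFrame, nt: str, alpha: float = 0.05
) -> dict:
    """Two-way treatment x time ANOVA on one NT's percent-basal series.

    Subjects are treated as replicates within cells (fixed-effects layout).
    Tukey post-hocs compare groups within each time point and each group's
    time points against its t = 0 baseline when the omnibus passes.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = series[series["neurotransmitter"] == nt].copy()
    if data.empty:
        raise ValueError(f"no series for {nt!r}")
    points_per = data.groupby("subject")["time_min"].nunique()
    if points_per.nunique() != 1:
        raise ValueError("ragged series: unequal time points across subjects")
    data = data.rename(columns={"pct_basal": "value"})

    if data["value"].nunique() == 1:
        return {"treatment": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "time": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "interaction": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "tukey_groups": {}, "tukey_vs_basal": {}}

    model = smf.ols("value ~ C(group) * C(time_min)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])

    def effect(name: str) -> dict[str, float]:
        row = table.loc[name]
        return {"F": float(row["F"]), "df_num": float(row["df"]),
                "df_den": df_resid, "p": float(row["PR(>F)"])}

    out = {
        "treatment": effect("C(group)"),
        "time": effect("C(time_min)"),
        "interaction": effect("C(group):C(time_min)"),
        "tukey_groups": {},
        "tukey_vs_basal": {},
    }
    if out["treatment"]["p"] < alpha or out["interaction"]["p"] < alpha:
        for time, sub in data.groupby("time_min"):
            if sub["group"].nunique() < 2 or sub["value"].nunique() == 1:
                continue
            res = pairwise_tukeyhsd(sub["value"], sub["group"], alpha=alpha)
            out["tukey_groups"][float(time)] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        for group, sub in data.groupby("group"):
            if sub["value"].nunique() == 1:
                continue
            res = pairwise_tukeyhsd(
                sub["value"], sub["time_min"].astype(str), alpha=alpha
            )
            frame = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
            vs_basal = frame[(frame["group1"] == "0.0") | (frame["group2"] == "0.0")]
            out["tukey_vs_basal"][group] = vs_basal.reset_index(drop=True)
    return out
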