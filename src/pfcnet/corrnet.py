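"""Thresholded Pearson correlation networks per group x K+ level.

Each network's nodes are the five neurotransmitters; an edge joins a pair
when the Pearson correlation of their per-subject cumulative levels is both
strong (r >= 0.5, signed) and significant (two-tailed p < 0.05 from the
exact t transform with n - 2 df). Cross-group comparison is a one-way ANOVA
on each group's ten pairwise r values with Tukey post-hocs.
"""

from __future__ import annotations

import itertools

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from .design import NEUROTRANSMITTERS

R_THRESHOLD = 0.5
P_THRESHOLD = 0.05


def pairwise_correlations(levels: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-tailed p for each of the 10 NT pairs.

    ``levels`` holds one group x K+ slice of the cumulative-levels table
    (one record per subject x NT). Correlations are computed across
    subjects. Pairs with zero variance are returned flagged
    (``valid=False``) with r/p = NaN.
    """
    wide = levels.pivot_table(
        index="subject", columns="neurotransmitter", values="cumulative_nM"
    )
    missing = [nt for nt in NEUROTRANSMITTERS if nt not in wide.columns]
    if missing:
        raise ValueError(f"missing neurotransmitters: {missing}")
    if wide.isna().any().any():
        raise ValueError("unequal subject sets across neurotransmitters")
    n = len(wide)
    if n < 3:
        raise ValueError("need >= 3 subjects for a correlation")
    rows = []
    for a, b in itertools.combinations(NEUROTRANSMITTERS, 2):
        x, y = wide[a].to_numpy(float), wide[b].to_numpy(float)
        if np.var(x) == 0 or np.var(y) == 0:
            rows.append({"nt_a": a, "nt_b": b, "r": np.nan, "p": np.nan,
                         "n": n, "valid": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"nt_a": a, "nt_b": b, "r": float(r), "p": float(p),
                     "n": n, "valid": True})
    return pd.DataFrame(rows)


def build_network(
    pairs: pd.DataFrame,
    group: str = "",
    k_mM: float = np.nan,
    r_min: float = R_THRESHOLD,
    p_alpha: float = P_THRESHOLD,
) -> nx.Graph:
    """Undirected network keeping edges with r >= r_min AND p < p_alpha.

    The threshold applies to signed r, so strong negative correlations do
    not form edges. Edge weight = r. Invalid (zero-variance) pairs are
    skipped.
    """
    g = nx.Graph(group=group, k_mM=float(k_mM), r_min=r_min, p_alpha=p_alpha)
    g.add_nodes_from(NEUROTRANSMITTERS)
    for row in pairs.itertuples():
        if not row.valid:
            continue
        if row.r >= r_min and row.p < p_alpha:
            g.add_edge(row.nt_a, row.nt_b, weight=float(row.r), p=float(row.p))
    return g


def correlation_networks(
    levels: pd.DataFrame,
    r_min: float = R_THRESHOLD,
    p_alpha: float = P_THRESHOLD,
) -> dict[tuple[str, float], nx.Graph]:
    """One thresholded network per group x K+ from a cumulative-levels table."""
    out = {}
    for (group, k), sub in levels.groupby(["group", "k_mM"], sort=True):
        pairs = pairwise_correlations(sub)
        out[(group, float(k))] = build_network(pairs, group, k, r_min, p_alpha)
    return out


def compare_correlation_distributions(
    pairs_by_group: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict:
    """One-way ANOVA across groups on the 10 pairwise r values, plus Tukey.

    Each group must contribute its full set of valid pair correlations.
    """
    groups = sorted(pairs_by_group)
    samples = []
    for g in groups:
        r = pairs_by_group[g]["r"].to_numpy(float)
        if np.isnan(r).any() or len(r) != 10:
            raise ValueError(f"group {g!r}: expected 10 valid pair correlations")
        samples.append(r)
    if all(np.var(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return {"F": 0.0, "p": np.nan, "df_num": len(groups) - 1,
                "df_den": sum(map(len, samples)) - len(groups),
                "zero_variance": True, "tukey": None}
    f, p = stats.f_oneway(*samples)
    out = {
        "F": float(f), "p": float(p),
        "df_num": len(groups) - 1,
        "df_den": sum(map(len, samples)) - len(groups),
    }
    res = stats.tukey_hsd(*samples)
    out["tukey"] = pd.DataFrame(
        [
            {
                "group_a": groups[i], "group_b": groups[j],
                "diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p": float(res.pvalue[i, j]),
            }
            for i, j in itertools.combinations(range(len(groups)), 2)
        ]
    )
    return out
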