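"""Iterative random forest (iRF) regression and iRF-LOOP directed networks.

iRF re-fits a random forest several times, biasing each round's feature
selection toward the features the previous round found important. Round 1
is a plain random forest with uniform feature weights; in later rounds each
tree sees a feature subset drawn with probability proportional to the
previous round's normalized impurity importances, so unimportant features
are progressively squeezed out. The final round's importances (normalized
to sum 1) are returned.

iRF-LOOP ("leave one out prediction") runs one iRF per target variable,
predicting each neurotransmitter from the other four over the rows of one
group x K+ block, and assembles the per-target importances into a directed
network: an edge source -> target is kept when the source's importance in
the target's model reaches the threshold. Edge signs come from the
univariate OLS slope of target on source. Difference networks take
edge-wise absolute differences between two groups' networks at the same K+
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .design import GROUPS, NEUROTRANSMITTERS


@dataclass(frozen=True)
class IRFConfig:
    n_trees: int = 500
    n_iterations: int = 5
    train_frac: float = 0.8
    importance_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if not (0 <= self.importance_threshold <= 1):
            raise ValueError("importance_threshold must be in [0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class DirectedEdge:
    source: str
    target: str
    importance: float
    sign: int  # +1, -1, or 0 when the OLS slope is degenerate


@dataclass
class DirectedNetwork:
    group: str
    k_mM: float
    edges: list[DirectedEdge]
    #: pre-threshold importances for every ordered (source, target) pair
    importances: dict[tuple[str, str], float]
    #: held-out R^2 per target model (metadata, never an edge filter)
    test_scores: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DifferenceNetwork:
    group_a: str
    group_b: str
    k_mM: float
    #: |importance_a - importance_b| per ordered pair (0 for absent edges)
    differences: dict[tuple[str, str], float]

    def thresholded(self, threshold: float) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.differences.items() if v >= threshold}


def irf_fit(
    X: np.ndarray, y: np.ndarray, config: IRFConfig | None = None
) -> np.ndarray:
    """Iterative random forest importances, normalized to sum 1.

    Iteration 1 fits a plain random forest (uniform feature weights).
    Iterations t > 1 draw, for each tree, a candidate-feature subset with
    inclusion probability proportional to iteration t-1's importances, fit
    a bootstrap decision tree on that subset, and average the impurity
    importances mapped back onto the full feature set.
    """
    config = IRFConfig() if config is None else config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 8:
        raise ValueError("need >= 8 rows")
    if p < 2:
        raise ValueError("need >= 2 features")
    if np.all(y == y[0]):
        raise ValueError("constant target")

    rng = np.random.default_rng(config.seed)
    rf = RandomForestRegressor(
        n_estimators=config.n_trees,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    weights = _normalize(rf.feature_importances_)

    for _ in range(1, config.n_iterations):
        acc = np.zeros(p)
        probs = _sampling_probs(weights)
        for _tree in range(config.n_trees):
            # per-tree feature subset drawn from the importance distribution
            draw = rng.choice(p, size=p, replace=True, p=probs)
            subset = np.unique(draw)
            rows = rng.integers(0, n, size=n)  # bootstrap
            tree = DecisionTreeRegressor(
                random_state=int(rng.integers(2**31 - 1))
            )
            yb = y[rows]
            if np.all(yb == yb[0]):
                continue
            tree.fit(X[np.ix_(rows, subset)], yb)
            imp = tree.feature_importances_
            full = np.zeros(p)
            full[subset] = imp
            acc += full
        weights = _normalize(acc) if acc.sum() > 0 else weights
    return weights


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else np.full_like(v, 1.0 / len(v))


def _sampling_probs(weights: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Importance-proportional sampling with a tiny floor so no feature's
    probability is exactly zero (keeps re-entry possible)."""
    probs = weights + floor
    return probs / probs.sum()


def _train_test_split(n: int, train_frac: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    if n_train < 8 or n - n_train < 1:
        raise ValueError(
            f"too few rows after split (n={n}, train={n_train})"
        )
    return perm[:n_train], perm[n_train:]


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form univariate OLS slope of y on x; NaN for constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return float("nan")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


def irf_loop(
    samples: pd.DataFrame,
    config: IRFConfig | None = None,
    group: str = "",
    k_mM: float = np.nan,
) -> DirectedNetwork:
    """Directed importance network for one group x K+ block.

    ``samples`` has one row per subject x sample with one column per
    neurotransmitter (per-sample records, 4 per subject within the block).
    For each target NT the remaining four are features: rows are split
    train/test, an iRF is fit on the training rows, the held-out R^2 is
    recorded as metadata, and importances >= threshold become edges. Signs
    come from the univariate OLS slope of target on source over all rows.
    """
    config = IRFConfig() if config is None else config
    missing = [nt for nt in NEUROTRANSMITTERS if nt not in samples.columns]
    if missing:
        raise ValueError(f"missing neurotransmitter columns: {missing}")
    data = samples[list(NEUROTRANSMITTERS)].to_numpy(float)
    n = len(data)
    rng = np.random.default_rng(config.seed)

    importances: dict[tuple[str, str], float] = {}
    scores: dict[str, float] = {}
    for t_idx, target in enumerate(NEUROTRANSMITTERS):
        sources = [nt for nt in NEUROTRANSMITTERS if nt != target]
        s_idx = [NEUROTRANSMITTERS.index(nt) for nt in sources]
        train, test = _train_test_split(n, config.train_frac, rng)
        sub_cfg = IRFConfig(
            n_trees=config.n_trees,
            n_iterations=config.n_iterations,
            train_frac=config.train_frac,
            importance_threshold=config.importance_threshold,
            seed=int(rng.integers(2**31 - 1)),
        )
        imp = irf_fit(data[np.ix_(train, s_idx)], data[train, t_idx], sub_cfg)
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(data[np.ix_(train, s_idx)], data[train, t_idx])
        scores[target] = float(
            rf.score(data[np.ix_(test, s_idx)], data[test, t_idx])
        )
        for src, w in zip(sources, imp):
            importances[(src, target)] = float(w)

    edges = []
    for (src, target), w in importances.items():
        if w >= config.importance_threshold:
            slope = ols_slope(
                data[:, NEUROTRANSMITTERS.index(src)],
                data[:, NEUROTRANSMITTERS.index(target)],
            )
            sign = 0 if not np.isfinite(slope) or slope == 0 else int(np.sign(slope))
            edges.append(DirectedEdge(src, target, w, sign))
    return DirectedNetwork(group, float(k_mM), edges, importances, scores)


def sign_edges(network: DirectedNetwork, samples: pd.DataFrame) -> DirectedNetwork:
    """Re-derive edge signs from univariate OLS slopes over ``samples``."""
    signed = []
    for e in network.edges:
        slope = ols_slope(
            samples[e.source].to_numpy(float), samples[e.target].to_numpy(float)
        )
        sign = 0 if not np.isfinite(slope) or slope == 0 else int(np.sign(slope))
        signed.append(DirectedEdge(e.source, e.target, e.importance, sign))
    network.edges = signed
    return network


def block_samples(table: pd.DataFrame, group: str, k_mM: float) -> pd.DataFrame:
    """Wide per-sample rows (columns = NTs) for one group x K+ block."""
    sub = table[(table["group"] == group) & (table["k_mM"] == k_mM)]
    wide = sub.pivot_table(
        index=["subject", "sample_index"],
        columns="neurotransmitter",
        values="conc_nM",
    ).reset_index()
    return wide


def irf_networks(
    table: pd.DataFrame, config: IRFConfig | None = None
) -> dict[tuple[str, float], DirectedNetwork]:
    """One directed network per group x K+ level (12 under the default
    3-group, 4-level design)."""
    config = IRFConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    out = {}
    for group in GROUPS:
        for k in sorted(table["k_mM"].unique()):
            samples = block_samples(table, group, float(k))
            if samples.empty:
                continue
            cfg = IRFConfig(
                n_trees=config.n_trees,
                n_iterations=config.n_iterations,
                train_frac=config.train_frac,
                importance_threshold=config.importance_threshold,
                seed=int(rng.integers(2**31 - 1)),
            )
            out[(group, float(k))] = irf_loop(samples, cfg, group, float(k))
    return out


def difference_network(net_a: DirectedNetwork, net_b: DirectedNetwork) -> DifferenceNetwork:
    """Edge-wise |importance_a - importance_b| at one K+ level.

    Retained-edge importances are compared; an edge absent from one network
    contributes 0 on that side.
    """
    if not np.isclose(net_a.k_mM, net_b.k_mM, equal_nan=True):
        raise ValueError("difference networks require matching K+ levels")
    kept_a = {(e.source, e.target): e.importance for e in net_a.edges}
    kept_b = {(e.source, e.target): e.importance for e in net_b.edges}
    diffs = {}
    for src in NEUROTRANSMITTERS:
        for tgt in NEUROTRANSMITTERS:
            if src == tgt:
                continue
            diffs[(src, tgt)] = abs(
                kept_a.get((src, tgt), 0.0) - kept_b.get((src, tgt), 0.0)
            )
    return DifferenceNetwork(net_a.group, net_b.group, net_a.k_mM, diffs)
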