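"""iRF importances, LOOP networks, signs, and difference networks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from pfcnet import irfnet
from pfcnet.design import NEUROTRANSMITTERS


def _signal_data(rng, n=200, sigma=0.1):
    X = rng.standard_normal((n, 4))
    y = 3.0 * X[:, 0] + sigma * rng.standard_normal(n)
    return X, y


def test_single_iteration_matches_plain_random_forest():
    """n_iterations = 1 is definitionally a plain random forest."""
    rng = np.random.default_rng(0)
    X, y = _signal_data(rng)
    cfg = irfnet.IRFConfig(n_trees=60, n_iterations=1, seed=123)
    imp = irfnet.irf_fit(X, y, cfg)
    oracle_state = int(np.random.default_rng(123).integers(2**31 - 1))
    rf = RandomForestRegressor(n_estimators=60, random_state=oracle_state,
                               n_jobs=1)
    rf.fit(X, y)
    expected = rf.feature_importances_ / rf.feature_importances_.sum()
    assert np.allclose(imp, expected)


def test_importances_sum_to_one_and_determinism():
    rng = np.random.default_rng(5)
    X, y = _signal_data(rng, n=60, sigma=1.0)
    cfg = irfnet.IRFConfig(n_trees=40, n_iterations=3, seed=9)
    a = irfnet.irf_fit(X, y, cfg)
    b = irfnet.irf_fit(X, y, cfg)
    assert np.allclose(a, b)
    assert a.sum() == pytest.approx(1.0, abs=1e-9)


def test_signal_feature_dominates():
    """y = 3 x1 + small noise: x1 takes nearly all the importance."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X, y = _signal_data(rng)
        imp = irfnet.irf_fit(X, y, irfnet.IRFConfig(n_trees=80, n_iterations=2,
                                                    seed=seed))
        if imp[0] > 0.8 and np.all(imp[1:] < 0.1):
            wins += 1
    assert wins >= 19


def test_duplicated_feature_splits_importance():
    """A duplicated signal column shares importance; jointly they dominate."""
    rng = np.random.default_rng(2)
    X = rng.standard_normal((200, 4))
    X[:, 1] = X[:, 0]  # duplicate
    y = X[:, 0] + 0.05 * rng.standard_normal(200)
    imp = irfnet.irf_fit(X, y, irfnet.IRFConfig(n_trees=100, n_iterations=2,
                                                seed=3))
    assert imp[0] + imp[1] > 0.9


def test_permutation_null_destroys_importance_concentration():
    """Permuting the target spreads importance below threshold for the
    previously dominant feature in nearly all runs."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X, y = _signal_data(rng)
        y_perm = rng.permutation(y)
        imp = irfnet.irf_fit(X, y_perm,
                             irfnet.IRFConfig(n_trees=60, n_iterations=2,
                                              seed=seed))
        if imp[0] < 0.2 + 0.25:  # no longer dominant
            hits += 1
    assert hits >= 19


def test_irf_fit_input_validation():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 4))
    with pytest.raises(ValueError, match="constant"):
        irfnet.irf_fit(X, np.ones(20))
    with pytest.raises(ValueError, match="8 rows"):
        irfnet.irf_fit(X[:5], rng.standard_normal(5))
    with pytest.raises(ValueError, match="2 features"):
        irfnet.irf_fit(X[:, :1], rng.standard_normal(20))


def _wide_samples(rng, n_rows=40, coupling=0.0):
    data = rng.lognormal(0, 0.3, size=(n_rows, 5))
    if coupling:
        data[:, 2] = data[:, 0] ** coupling * rng.lognormal(0, 0.05, n_rows)
    return pd.DataFrame(data, columns=list(NEUROTRANSMITTERS))


def test_irf_loop_importances_normalized_and_threshold_one_empty():
    rng = np.random.default_rng(4)
    samples = _wide_samples(rng)
    cfg = irfnet.IRFConfig(n_trees=40, n_iterations=2, seed=0,
                           importance_threshold=1.0)
    net = irfnet.irf_loop(samples, cfg)
    # importances per target sum to 1 pre-threshold
    for target in NEUROTRANSMITTERS:
        total = sum(v for (s, t), v in net.importances.items() if t == target)
        assert total == pytest.approx(1.0, abs=1e-9)
    # threshold 1.0 leaves no edges (importances sum to 1 over 4 sources)
    assert net.edges == []
    assert len(net.importances) == 20


def test_irf_loop_seeded_determinism():
    rng = np.random.default_rng(6)
    samples = _wide_samples(rng)
    cfg = irfnet.IRFConfig(n_trees=30, n_iterations=2, seed=11)
    a = irfnet.irf_loop(samples, cfg)
    b = irfnet.irf_loop(samples, cfg)
    assert a.importances == b.importances
    assert [e.__dict__ for e in a.edges] == [e.__dict__ for e in b.edges]


def test_irf_networks_count_is_twelve(default_cohort):
    cfg = irfnet.IRFConfig(n_trees=15, n_iterations=1, seed=0)
    nets = irfnet.irf_networks(default_cohort, cfg)
    assert len(nets) == 12
    assert {g for g, _ in nets} == {"control", "acute", "chronic"}
    assert {k for _, k in nets} == {4.0, 30.0, 60.0, 120.0}


def test_monotone_thresholding():
    rng = np.random.default_rng(7)
    samples = _wide_samples(rng, coupling=1.0)
    base = irfnet.irf_loop(samples, irfnet.IRFConfig(n_trees=40, n_iterations=2,
                                                     seed=1,
                                                     importance_threshold=0.1))
    prev = {(e.source, e.target) for e in base.edges}
    for thr in (0.2, 0.4, 0.8):
        net = irfnet.irf_loop(samples, irfnet.IRFConfig(n_trees=40,
                                                        n_iterations=2, seed=1,
                                                        importance_threshold=thr))
        edges = {(e.source, e.target) for e in net.edges}
        assert edges <= prev
        prev = edges


def test_sign_edges_ols_slope_oracle():
    samples = pd.DataFrame(
        {
            "DA": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "5HT": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],     # +2 slope
            "NE": [5.0, 4.5, 4.0, 3.5, 3.0, 2.5],        # -0.5 slope
            "Glu": [1.0, 1.2, 0.8, 1.1, 0.9, 1.0],
            "GABA": [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],      # constant
        }
    )
    net = irfnet.DirectedNetwork(
        "control", 4.0,
        edges=[irfnet.DirectedEdge("DA", "5HT", 0.5, 0),
               irfnet.DirectedEdge("DA", "NE", 0.5, 0),
               irfnet.DirectedEdge("GABA", "Glu", 0.5, 0)],
        importances={},
    )
    net = irfnet.sign_edges(net, samples)
    signs = {(e.source, e.target): e.sign for e in net.edges}
    assert signs[("DA", "5HT")] == 1
    assert signs[("DA", "NE")] == -1
    assert signs[("GABA", "Glu")] == 0  # constant source flagged
    # closed-form slope check
    x, y = samples["DA"].to_numpy(), samples["NE"].to_numpy()
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert irfnet.ols_slope(x, y) == pytest.approx(slope, abs=1e-12)
    assert slope == pytest.approx(-0.5, abs=1e-12)


def test_difference_network_arithmetic():
    net_a = irfnet.DirectedNetwork(
        "acute", 30.0,
        edges=[irfnet.DirectedEdge("DA", "NE", 0.6, 1),
               irfnet.DirectedEdge("Glu", "GABA", 0.3, 1),
               irfnet.DirectedEdge("5HT", "DA", 0.25, -1)],
        importances={},
    )
    net_b = irfnet.DirectedNetwork(
        "control", 30.0,
        edges=[irfnet.DirectedEdge("Glu", "GABA", 0.5, 1)],
        importances={},
    )
    diff = irfnet.difference_network(net_a, net_b)
    assert diff.differences[("DA", "NE")] == pytest.approx(0.6)
    assert diff.differences[("Glu", "GABA")] == pytest.approx(0.2)
    assert diff.differences[("5HT", "DA")] == pytest.approx(0.25)
    assert diff.differences[("NE", "DA")] == 0.0
    assert all(0 <= v <= 1 for v in diff.differences.values())
    # identical networks -> all zero
    same = irfnet.difference_network(net_a, net_a)
    assert all(v == 0 for v in same.differences.values())
    # mismatched K+ rejected
    net_c = irfnet.DirectedNetwork("control", 60.0, edges=[], importances={})
    with pytest.raises(ValueError, match="K"):
        irfnet.difference_network(net_a, net_c)


def test_designed_da_ne_coupling_recovered():
    """Cohorts with a single strong DA->NE coupling put DA's importance
    above threshold in the NE model."""
    from pfcnet import synthetic as syn

    hits = 0
    n_seeds = 15
    for seed in range(n_seeds):
        df = syn.generate_dialysate(
            syn.SimCohortConfig(seed=seed, noise_cv=0.2),
            syn.flat_profiles(),
            syn.single_drive_coupling("DA", "NE"),
        )
        samples = irfnet.block_samples(df, "control", 30.0)
        net = irfnet.irf_loop(samples, irfnet.IRFConfig(150, 2, seed=seed))
        hits += ("DA", "NE") in {(e.source, e.target) for e in net.edges}
    assert hits / n_seeds >= 0.9
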