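"""Demand-curve fitting: exact recovery, oracles, normalization, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from pfcnet import demand as dm
from pfcnet import synthetic as syn
from pfcnet.design import PRICES

PRICE_ARR = np.array(PRICES, dtype=float)


def _curve_df(q0, alpha, k, subject="s1", group="control", milk=20):
    q = syn.demand_curve(q0, alpha, k, PRICE_ARR)
    return pd.DataFrame(
        {"subject": subject, "group": group, "milk_pct": milk,
         "price": PRICES, "consumption": q}
    )


def test_noiseless_recovery_exact():
    """Exact model data returns the generating parameters and R^2 = 1."""
    df = _curve_df(100.0, 0.005, 2.0)
    fit = dm.fit_demand(df, k_mode=2.0)[0]
    assert fit.q0 == pytest.approx(100.0, rel=1e-6)
    assert fit.alpha == pytest.approx(0.005, rel=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    assert fit.essential_value == pytest.approx(200.0, rel=1e-6)
    assert fit.converged


def test_shared_k_estimated_jointly():
    """Two noiseless curves from a common k: the shared-k fit recovers it."""
    df = pd.concat(
        [_curve_df(100.0, 0.005, 2.5, subject="s1"),
         _curve_df(40.0, 0.008, 2.5, subject="s2")],
        ignore_index=True,
    )
    fits = dm.fit_demand(df, k_mode="shared")
    assert fits[0].k == pytest.approx(2.5, abs=1e-3)
    for fit, (q0, alpha) in zip(fits, [(100.0, 0.005), (40.0, 0.008)]):
        assert fit.q0 == pytest.approx(q0, rel=1e-4)
        assert fit.alpha == pytest.approx(alpha, rel=1e-3)


def test_all_zero_consumption_rejected():
    df = _curve_df(100.0, 0.005, 2.0)
    df["consumption"] = 0
    fit = dm.fit_demand(df, k_mode=2.0)[0]
    assert fit.status == "rejected_zero"
    assert not fit.converged


def test_grid_search_oracle_three_point_curve():
    """The least-squares optimum matches a dense brute-force grid search."""
    prices = np.array([2.0, 10.0, 50.0])
    y_obs = np.log10(np.array([80.0, 40.0, 5.0]) + 0.1)
    k = 2.0
    df = pd.DataFrame(
        {"subject": "s", "group": "control", "milk_pct": 0,
         "price": prices, "consumption": [80.0, 40.0, 5.0]}
    )
    fit = dm.fit_demand(df, k_mode=k)[0]

    q0_grid = np.linspace(40, 200, 401)
    a_grid = np.geomspace(1e-4, 1e-1, 601)
    best = (None, np.inf)
    for q0 in q0_grid:
        pred = 10 ** (np.log10(q0) + k * (np.exp(-a_grid[:, None] * q0 * prices) - 1))
        ss = np.sum((np.log10(pred + 0.1) - y_obs) ** 2, axis=1)
        i = int(np.argmin(ss))
        if ss[i] < best[1]:
            best = ((q0, a_grid[i]), ss[i])
    (q0_star, a_star), ss_star = best
    # agreement to within the grid resolution (~1.2% steps in alpha)
    assert fit.q0 == pytest.approx(q0_star, rel=1.5e-2)
    assert fit.alpha == pytest.approx(a_star, rel=1.5e-2)
    assert fit.ss <= ss_star + 1e-9


def test_normalization_examples_and_round_trip():
    df = _curve_df(100.0, 0.005, 2.0)
    fit = dm.fit_demand(df, k_mode=2.0)[0]
    norm = dm.normalize_demand(fit, df)
    # Q = Q0 at zero price equivalent: normalized consumption = 100
    assert norm["norm_consumption"].iloc[0] == pytest.approx(
        100.0 * df["consumption"].iloc[0] / fit.q0
    )
    # Q0 = 100 -> normalized price equals raw price
    assert np.allclose(norm["norm_price"], df["price"] * fit.q0 / 100.0)
    # round trip recovers the original (C, Q) exactly
    assert np.allclose(norm["norm_price"] * 100.0 / fit.q0, df["price"])
    assert np.allclose(norm["norm_consumption"] * fit.q0 / 100.0,
                       df["consumption"])


def test_normalized_price_formula():
    fit = dm.DemandFit("s", "control", 0, 40.0, 0.01, 2.0, 1.0, 0.0, 3,
                       np.eye(2), 0.0, 0.0, True)
    norm = dm.normalize_demand(
        fit, pd.DataFrame({"subject": "s", "group": "control", "milk_pct": 0,
                           "price": [50.0], "consumption": [10.0]})
    )
    assert norm["norm_price"].iloc[0] == pytest.approx(20.0)


def test_param_se_properties_and_ols_oracle():
    # SS = 0 -> all SEs 0; doubling SS scales SEs by sqrt(2)
    cov = np.array([[4.0, 0.0], [0.0, 9.0]])
    assert np.allclose(dm.param_se(0.0, 3, cov), 0.0)
    se1 = dm.param_se(1.0, 4, cov)
    se2 = dm.param_se(2.0, 4, cov)
    assert np.allclose(se2, np.sqrt(2) * se1)
    with pytest.raises(ValueError):
        dm.param_se(1.0, 0, cov)

    # closed-form OLS oracle on a 5-point line: SE(slope) from
    # sqrt(sigma^2 / Sxx) must match (SS/DF) * Cov form
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([1.1, 2.9, 5.2, 6.8, 9.1])
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    ss, df = float(resid @ resid), len(x) - 2
    cov = np.linalg.inv(X.T @ X)
    se = dm.param_se(ss, df, cov)
    sxx = np.sum((x - x.mean()) ** 2)
    assert se[1] == pytest.approx(np.sqrt(ss / df / sxx), rel=1e-12)


def test_essential_value_is_reciprocal_alpha():
    fit = dm.DemandFit("s", "control", 0, 50.0, 0.004, 2.0, 1.0, 0.0, 3,
                       np.eye(2), 0.0, 0.0, True)
    assert fit.essential_value == 250.0


def _balanced_param_table(rng):
    rows = []
    for g_i, group in enumerate(["control", "acute", "chronic"]):
        for milk in [0, 5, 20, 50]:
            for s in range(8):
                rows.append(
                    {"subject": f"{group}_{s}", "group": group,
                     "milk_pct": milk,
                     "value": milk * 2.0 + g_i + rng.normal(0, 1.0)}
                )
    return pd.DataFrame(rows)


def test_demand_anova_df_shape():
    """8 subjects x 3 groups x 4 concentrations: denominator df 84,
    concentration df 3, group df 2, interaction df 6."""
    table = _balanced_param_table(np.random.default_rng(0))
    out = dm.demand_anova(table, "value")
    assert out["milk_pct"]["df_num"] == 3
    assert out["group"]["df_num"] == 2
    assert out["interaction"]["df_num"] == 6
    for eff in ("milk_pct", "group", "interaction"):
        assert out[eff]["df_den"] == 84


def test_demand_anova_zero_variance_flag():
    table = _balanced_param_table(np.random.default_rng(0))
    table["value"] = 5.0
    out = dm.demand_anova(table, "value")
    assert out["group"]["zero_variance"]
    assert out["group"]["F"] == 0.0


def test_two_way_anova_matches_hand_computation():
    """2x2 design with 2 replicates against textbook sums of squares."""
    data = {
        ("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [3.0, 4.0],
        ("a2", "b1"): [5.0, 6.0], ("a2", "b2"): [9.0, 10.0],
    }
    rows = [
        {"subject": f"s{i}{a}{b}", "group": a, "milk_pct": b, "value": v}
        for (a, b), vals in data.items() for i, v in enumerate(vals)
    ]
    table = pd.DataFrame(rows)
    out = dm.demand_anova(table, "value")

    # textbook two-way ANOVA by explicit sums of squares
    all_v = np.array([v for vals in data.values() for v in vals])
    grand = all_v.mean()
    mean_a = {a: np.mean(data[(a, "b1")] + data[(a, "b2")]) for a in ("a1", "a2")}
    mean_b = {b: np.mean(data[("a1", b)] + data[("a2", b)]) for b in ("b1", "b2")}
    ss_a = 4 * sum((m - grand) ** 2 for m in mean_a.values())
    ss_b = 4 * sum((m - grand) ** 2 for m in mean_b.values())
    cell_means = {k: np.mean(v) for k, v in data.items()}
    ss_cells = 2 * sum((m - grand) ** 2 for m in cell_means.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        (v - cell_means[k]) ** 2 for k, vals in data.items() for v in vals
    )
    f_a = (ss_a / 1) / (ss_err / 4)
    f_b = (ss_b / 1) / (ss_err / 4)
    f_ab = (ss_ab / 1) / (ss_err / 4)
    assert out["group"]["F"] == pytest.approx(f_a, abs=1e-10)
    assert out["milk_pct"]["F"] == pytest.approx(f_b, abs=1e-10)
    assert out["interaction"]["F"] == pytest.approx(f_ab, abs=1e-10)


def test_fitted_essential_value_monotone_in_milk():
    """Noiseless generated cohort: essential value rises with concentration."""
    params = syn.DemandGenParams(noise="none", subject_sd=0.0)
    df = syn.generate_demand(params, n_per_group=2, seed=0,
                             groups=("control",))
    fits = dm.fits_table(dm.fit_demand(df, k_mode=params.k))
    ev = fits.groupby("milk_pct")["essential_value"].mean()
    assert ev.is_monotonic_increasing
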