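"""Titration engine oracles, session metric arithmetic, and the ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from pfcnet import design, synthetic as syn, vigilance as vg


class FixedLatencyAgent(syn.SubjectAgent):
    """Deterministic agent responding at a constant latency."""

    def __new__(cls, latency, subject="s1", group="control"):
        params = syn.AgentParams(initial_rt_mean=10.0, asymptote_rt_mean=0.1,
                                 learning_tau=1.0, rt_cv=0.0, lapse_prob=0.0)
        obj = super().__new__(cls)
        syn.SubjectAgent.__init__(obj, subject, group, params)
        object.__setattr__(obj, "latency", latency)
        return obj

    def __init__(self, *a, **k):
        pass

    def respond(self, session, rng):
        return self.latency


def _limits(records):
    return [r.limit_s for r in records]


def test_instant_responder_reaches_floor_on_trial_40():
    """10 s start, every trial a hit: limit hits the 0.25 s floor at trial
    40 (10 - 0.25 * 39 = 0.25) and stays there."""
    records = vg.titrate_session(FixedLatencyAgent(0.0), 10.0, seed_or_rng=0)
    limits = _limits(records)
    assert limits[39] == pytest.approx(0.25)
    assert all(l == pytest.approx(0.25) for l in limits[39:])
    assert limits[38] == pytest.approx(0.5)
    assert all(r.outcome == "hit" for r in records)


def test_never_responder_climbs_to_22_seconds():
    records = vg.titrate_session(FixedLatencyAgent(math.inf), 10.0, 0)
    assert all(r.outcome == "miss" for r in records)
    summary = vg.titrated_reaction_time(records)
    assert summary.final_limit_s == pytest.approx(10.0 + 0.25 * 48)
    # all-miss metric equals the mean of the limit trajectory
    assert summary.titrated_rt_s == pytest.approx(np.mean(_limits(records)))


def test_fixed_latency_trajectory_matches_hand_trace():
    """Latency 3.0 s from 10 s: descend by 0.25 until a miss at 2.75,
    then alternate 3.00 / 2.75."""
    records = vg.titrate_session(FixedLatencyAgent(3.0), 10.0, 0)
    limits = _limits(records)
    # hand trace: hits while limit >= 3.0 (10.0 down to 3.0 is 29 trials),
    # trial 30 at 2.75 misses, then alternation
    expected = [10.0 - 0.25 * i for i in range(29)]  # trials 1..29 hit
    t = 2.75
    while len(expected) < 48:
        expected.append(t)
        t = 3.0 if t == 2.75 else 2.75
    assert np.allclose(limits, expected)
    outcomes = [r.outcome for r in records]
    assert outcomes[:29] == ["hit"] * 29
    assert outcomes[29] == "miss"


def test_limit_lattice_walk_property():
    """Limits move on a +-0.25 lattice bounded below by 0.25 s."""
    agents = syn.generate_vigilance_agents(n_per_group=2, seed=3)
    trials, _ = vg.run_cohort(agents, n_sessions=3, seed=3)
    steps = trials.groupby(["subject", "session"])["limit_s"].apply(
        lambda s: np.diff(s.to_numpy())
    )
    for arr in steps:
        assert np.all(np.isin(np.round(np.abs(arr), 10), [0.0, 0.25]))
    assert (trials["limit_s"] >= 0.25 - 1e-12).all()


def test_session_carryover():
    agents = syn.generate_vigilance_agents(n_per_group=2, seed=1)
    trials, summaries = vg.run_cohort(agents, n_sessions=4, seed=1)
    for subject, sub in trials.groupby("subject"):
        for s in range(1, 4):
            final = summaries[(summaries.subject == subject)
                              & (summaries.session == s)].final_limit_s.iloc[0]
            first_next = sub[(sub.session == s + 1) & (sub.trial == 1)]
            assert first_next.limit_s.iloc[0] == pytest.approx(final)


def test_titrated_rt_mixed_toy_session():
    """4-trial toy: (hit 1.0, miss at 2.0, hit 0.5, miss at 2.25) -> 1.4375."""
    mk = lambda i, limit, outcome, rt: vg.TrialRecord(
        "s", "control", 1, i, 1, 15.0, limit, outcome, rt
    )
    records = [mk(1, 3.0, "hit", 1.0), mk(2, 2.0, "miss", None),
               mk(3, 2.5, "hit", 0.5), mk(4, 2.25, "miss", None)]
    summary = vg.titrated_reaction_time(records)
    assert summary.titrated_rt_s == pytest.approx((1.0 + 2.0 + 0.5 + 2.25) / 4)
    assert summary.hits == 2


def test_all_hits_metric_equals_mean_rt():
    mk = lambda i: vg.TrialRecord("s", "control", 2, i, 1, 15.0, 5.0, "hit", 1.0)
    summary = vg.titrated_reaction_time([mk(i) for i in range(1, 49)])
    assert summary.titrated_rt_s == pytest.approx(1.0)


def test_empty_records_error():
    with pytest.raises(ValueError):
        vg.titrated_reaction_time([])


def test_negative_latency_rejected():
    with pytest.raises(ValueError, match="negative"):
        vg.titrate_session(FixedLatencyAgent(-1.0), 10.0, 0)


def test_long_run_limit_tracks_latency_distribution():
    """For a stationary stochastic agent the titrated limit hovers in the
    upper-quantile region of the latency distribution."""
    params = syn.AgentParams(initial_rt_mean=3.0, asymptote_rt_mean=3.0,
                             learning_tau=1.0, rt_cv=0.3, lapse_prob=0.0)
    agent = syn.SubjectAgent("s", "control", params)
    rng = np.random.default_rng(8)
    limit, limits = 10.0, []
    for _ in range(42):  # ~2000 trials chained with carryover
        records = vg.titrate_session(agent, limit, rng)
        summary = vg.titrated_reaction_time(records)
        limit = summary.final_limit_s
        limits.extend(r.limit_s for r in records)
    sigma = math.sqrt(math.log(1 + 0.3**2))
    mu = math.log(3.0) - sigma**2 / 2
    latencies = np.exp(mu + sigma * rng.standard_normal(100_000))
    p40, p90 = np.percentile(latencies, [40, 90])
    median_limit = np.median(limits[500:])
    assert p40 <= median_limit <= p90


def test_vigilance_anova_df_and_zero_variance():
    """3 groups x 8 subjects x 15 sessions: treatment df (2, 315)."""
    rng = np.random.default_rng(0)
    rows = [
        {"subject": f"{g}_{i}", "group": g, "session": s,
         "titrated_rt_s": 2.5 + 0.1 * gi + rng.normal(0, 0.2)}
        for gi, g in enumerate(design.GROUPS)
        for i in range(8)
        for s in range(1, 16)
    ]
    out = vg.vigilance_anova(pd.DataFrame(rows))
    assert out["treatment"]["df_num"] == 2
    assert out["treatment"]["df_den"] == 315

    flat = pd.DataFrame(rows).assign(titrated_rt_s=2.0)
    out2 = vg.vigilance_anova(flat)
    assert out2["treatment"]["zero_variance"]


def test_vigilance_anova_matches_hand_computation():
    """2 groups x 2 sessions x 2 subjects vs textbook sums of squares."""
    cells = {
        ("control", 1): [2.0, 2.4], ("control", 2): [1.6, 1.8],
        ("acute", 1): [3.0, 3.4], ("acute", 2): [2.8, 3.2],
    }
    rows = [
        {"subject": f"{g}_{i}", "group": g, "session": s, "titrated_rt_s": v}
        for (g, s), vals in cells.items() for i, v in enumerate(vals)
    ]
    out = vg.vigilance_anova(pd.DataFrame(rows))

    all_v = np.array(sum(cells.values(), []))
    grand = all_v.mean()
    m_g = {g: np.mean(cells[(g, 1)] + cells[(g, 2)]) for g in ("control", "acute")}
    m_s = {s: np.mean(cells[("control", s)] + cells[("acute", s)]) for s in (1, 2)}
    ss_g = 4 * sum((m - grand) ** 2 for m in m_g.values())
    ss_s = 4 * sum((m - grand) ** 2 for m in m_s.values())
    cell_m = {k: np.mean(v) for k, v in cells.items()}
    ss_int = 2 * sum((m - grand) ** 2 for m in cell_m.values()) - ss_g - ss_s
    ss_err = sum((v - cell_m[k]) ** 2 for k, vals in cells.items() for v in vals)
    assert out["treatment"]["F"] == pytest.approx((ss_g / 1) / (ss_err / 4), abs=1e-10)
    assert out["session"]["F"] == pytest.approx((ss_s / 1) / (ss_err / 4), abs=1e-10)
    assert out["interaction"]["F"] == pytest.approx((ss_int / 1) / (ss_err / 4), abs=1e-10)


def test_missing_sessions_error():
    rows = [
        {"subject": "a", "group": "control", "session": 1, "titrated_rt_s": 2.0},
        {"subject": "a", "group": "control", "session": 2, "titrated_rt_s": 2.0},
        {"subject": "b", "group": "acute", "session": 1, "titrated_rt_s": 2.0},
    ]
    with pytest.raises(ValueError, match="missing sessions"):
        vg.vigilance_anova(pd.DataFrame(rows))


def test_cohort_separation_about_one_second():
    """Default control vs exposure agents separate by ~1 s late in testing."""
    agents = syn.generate_vigilance_agents(n_per_group=8, seed=5)
    _, summaries = vg.run_cohort(agents, n_sessions=15, seed=5)
    late = summaries[summaries.session >= 11]
    means = late.groupby("group")["titrated_rt_s"].mean()
    gap = (means["acute"] + means["chronic"]) / 2 - means["control"]
    assert 0.5 < gap < 1.8
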