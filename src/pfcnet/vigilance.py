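"""Titrating psychomotor vigilance task: engine, session metric, ANOVA.

Each 48-trial session presents a brief stimulus whose maximum duration
(the "limit") titrates on the subject's performance: a hit (response within
the limit) shortens the next limit by 0.25 s, a miss lengthens it by 0.25 s,
with a hard floor of 0.25 s and no ceiling. The first trial of a subject's
first session starts at 10 s; later sessions carry over the final limit of
the previous session. The session metric — the titrated reaction time —
averages hit latencies together with the full stimulus limit on miss
trials, so failures to attend count at their full cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design
from .synthetic import SubjectAgent


@dataclass(frozen=True)
class TrialRecord:
    subject: str
    group: str
    session: int
    trial: int
    location: int
    iti_s: float
    limit_s: float
    outcome: str  # "hit" | "miss"
    rt_s: float | None  # hits only


@dataclass(frozen=True)
class SessionSummary:
    subject: str
    group: str
    session: int
    titrated_rt_s: float
    hits: int
    final_limit_s: float


def titrate_session(
    agent: SubjectAgent,
    starting_limit_s: float,
    seed_or_rng: int | np.random.Generator,
    session: int = 1,
) -> list[TrialRecord]:
    """Run one 48-trial session and return its trial records.

    The agent is queried once per trial for a response latency (inf = lapse,
    treated as a miss at any finite limit). Limits move on a +-0.25 s
    lattice clipped below at 0.25 s.
    """
    if starting_limit_s < design.LIMIT_FLOOR_S:
        raise ValueError("starting limit must be >= 0.25 s")
    rng = (np.random.default_rng(seed_or_rng)
           if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng)
    limit = float(starting_limit_s)
    records: list[TrialRecord] = []
    for trial in range(1, design.TRIALS_PER_SESSION + 1):
        iti = float(rng.choice(design.ITI_CHOICES_S))
        location = int(rng.integers(1, design.N_LOCATIONS + 1))
        latency = agent.respond(session, rng)
        if latency < 0:
            raise ValueError("agent returned a negative latency")
        hit = latency <= limit
        records.append(
            TrialRecord(
                subject=agent.subject, group=agent.group, session=session,
                trial=trial, location=location, iti_s=iti, limit_s=limit,
                outcome="hit" if hit else "miss",
                rt_s=float(latency) if hit else None,
            )
        )
        step = -design.TITRATION_STEP_S if hit else design.TITRATION_STEP_S
        limit = max(limit + step, design.LIMIT_FLOOR_S)
    return records


def titrated_reaction_time(records: list[TrialRecord]) -> SessionSummary:
    """Session metric: mean over all trials of (hit RT; full limit on miss)."""
    if not records:
        raise ValueError("empty trial record list")
    sessions = {r.session for r in records}
    if len(sessions) != 1:
        raise ValueError("records must come from exactly one session")
    values = [r.rt_s if r.outcome == "hit" else r.limit_s for r in records]
    hits = sum(r.outcome == "hit" for r in records)
    last = records[-1]
    final_limit = last.limit_s + (
        -design.TITRATION_STEP_S if last.outcome == "hit" else design.TITRATION_STEP_S
    )
    final_limit = max(final_limit, design.LIMIT_FLOOR_S)
    return SessionSummary(
        subject=last.subject, group=last.group, session=last.session,
        titrated_rt_s=float(np.mean(values)), hits=hits,
        final_limit_s=final_limit,
    )


def run_cohort(
    agents: list[SubjectAgent],
    n_sessions: int = design.N_SESSIONS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, session summaries) tables.

    Session s+1 starts at the final limit of session s, as in the task.
    """
    rng = np.random.default_rng(seed)
    trial_rows, summary_rows = [], []
    for agent in agents:
        limit = design.FIRST_SESSION_START_LIMIT_S
        for session in range(1, n_sessions + 1):
            records = titrate_session(agent, limit, rng, session=session)
            summary = titrated_reaction_time(records)
            limit = summary.final_limit_s
            trial_rows.extend(records)
            summary_rows.append(summary)
    trials = pd.DataFrame([r.__dict__ for r in trial_rows])
    summaries = pd.DataFrame([s.__dict__ for s in summary_rows])
    return trials, summaries


def summaries_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-session summaries from a tidy trial table."""
    rows = []
    for (subject, group, session), sub in trials.groupby(
        ["subject", "group", "session"], sort=True
    ):
        records = [
            TrialRecord(subject, group, int(session), int(r.trial),
                        int(r.location), float(r.iti_s), float(r.limit_s),
                        r.outcome, None if pd.isna(r.rt_s) else float(r.rt_s))
            for r in sub.sort_values("trial").itertuples()
        ]
        rows.append(titrated_reaction_time(records).__dict__)
    return pd.DataFrame(rows)


def vigilance_anova(
    summaries: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Two-way (treatment x session) ANOVA on titrated RTs with Tukey HSD.

    Expects a complete subject x session grid. Tukey's pairwise group
    comparisons are run per session when the omnibus treatment effect
    passes ``alpha``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = summaries.rename(columns={"titrated_rt_s": "value"}).copy()
    per_subject = data.groupby("subject")["session"].nunique()
    if per_subject.nunique() != 1:
        raise ValueError("missing sessions: ragged subject x session grid")

    if data["value"].nunique() == 1:
        return {"treatment": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "session": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "interaction": {"F": 0.0, "p": np.nan, "zero_variance": True},
                "tukey": {}}

    model = smf.ols("value ~ C(group) * C(session)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])

    def effect(name: str) -> dict[str, float]:
        row = table.loc[name]
        return {"F": float(row["F"]), "df_num": float(row["df"]),
                "df_den": df_resid, "p": float(row["PR(>F)"])}

    out = {
        "treatment": effect("C(group)"),
        "session": effect("C(session)"),
        "interaction": effect("C(group):C(session)"),
        "tukey": {},
    }
    if out["treatment"]["p"] < alpha:
        for session, sub in data.groupby("session"):
            res = pairwise_tukeyhsd(sub["value"], sub["group"], alpha=alpha)
            out["tukey"][int(session)] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    return out
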