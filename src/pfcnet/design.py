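"""Study-design constants shared across the pipeline.

The experimental design being emulated: three treatment groups of mice
(unirradiated controls, an acute single-session exposure, and a chronic
four-week exposure to a simulated galactic-cosmic-ray field), five
prefrontal-cortex neurotransmitters sampled by in vivo microdialysis under a
stepped K+ perfusate schedule, a behavioral-economic demand task, and a
titrating psychomotor vigilance task.
"""

from __future__ import annotations

GROUPS: tuple[str, ...] = ("control", "acute", "chronic")

#: Neurotransmitter labels as written in data files. Serotonin is written
#: "5HT" in files (no hyphen, to avoid parsing hazards); the display name
#: retains the hyphen.
NEUROTRANSMITTERS: tuple[str, ...] = ("DA", "5HT", "NE", "Glu", "GABA")

DISPLAY_NAMES: dict[str, str] = {
    "DA": "DA",
    "5HT": "5-HT",
    "NE": "NE",
    "Glu": "Glu",
    "GABA": "GABA",
}

#: Perfusate K+ steps (mM); 4 mM is the baseline block, higher steps evoke
#: depolarization-driven release.
K_SCHEDULE: tuple[int, ...] = (4, 30, 60, 120)
SAMPLES_PER_BLOCK: int = 4
SAMPLE_INTERVAL_MIN: float = 20.0

#: Fixed-ratio price ladder of the within-session demand task.
PRICES: tuple[int, ...] = (2, 5, 10, 30, 50)

#: Sweetened-condensed-milk concentrations (%) tested in the demand task.
MILK_PCTS: tuple[int, ...] = (0, 5, 20, 50)

#: Vigilance task shape.
TRIALS_PER_SESSION: int = 48
N_SESSIONS: int = 15
ITI_CHOICES_S: tuple[int, ...] = (15, 30, 45)
N_LOCATIONS: int = 6
TITRATION_STEP_S: float = 0.25
LIMIT_FLOOR_S: float = 0.25
FIRST_SESSION_START_LIMIT_S: float = 10.0

#: Irradiation regimens (cGy). The acute regimen delivers its total dose in a
#: single session; the chronic regimen spreads its total over 4 weeks of
#: 6 exposure days each.
ACUTE_TOTAL_DOSE_CGY: float = 40.0
CHRONIC_TOTAL_DOSE_CGY: float = 49.9
CHRONIC_WEEKS: int = 4
CHRONIC_DAYS_PER_WEEK: int = 6


def chronic_daily_dose_cgy(
    total_cgy: float = CHRONIC_TOTAL_DOSE_CGY,
    weeks: int = CHRONIC_WEEKS,
    days_per_week: int = CHRONIC_DAYS_PER_WEEK,
) -> float:
    """Mean daily dose (cGy/day) of a fractionated regimen.

    With the default chronic regimen (49.9 cGy over 4 weeks x 6 days/week =
    24 exposure days) this is 2.079..., i.e. 2.08 cGy/day at two decimals.
    """
    n_days = weeks * days_per_week
    if n_days <= 0:
        raise ValueError("regimen must contain at least one exposure day")
    return total_cgy / n_days
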