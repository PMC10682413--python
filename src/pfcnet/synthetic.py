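"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The study's raw data are unreleased, so every downstream stage is exercised
against generated cohorts instead:

* ``generate_dialysate`` builds the long-format microdialysis table. Each
  subject x neurotransmitter series is ``basal_mean x group fold x
  deterministic K+ response kernel x subject random effect x coupled
  lognormal noise``; the noise innovations are propagated through a per-group
  5x5 lag-1 (VAR) coupling matrix, which is what induces the
  correlation/causality structure the network stages recover.
* ``generate_demand`` draws consumption counts around the exponential demand
  model at the task's fixed-ratio price ladder.
* ``generate_vigilance_agents`` builds latent-reaction-time agents whose
  session-wise learning curves mirror the observed group separation.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design
from .design import GROUPS, K_SCHEDULE, NEUROTRANSMITTERS, PRICES


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimCohortConfig:
    """Cohort-level settings for the dialysate generator.

    noise_cv is the coefficient of variation of the multiplicative
    (lognormal) measurement noise per sample; subject_sd is the SD of the
    between-subject random effect on log basal level. With a zero coupling
    matrix the empirical CV of replicate samples converges to ``noise_cv``;
    cross-series coupling amplifies the marginal spread beyond it.
    """

    n_control: int = 10
    n_acute: int = 10
    n_chronic: int = 8
    seed: int = 0
    k_schedule: tuple[int, ...] = K_SCHEDULE
    samples_per_block: int = design.SAMPLES_PER_BLOCK
    sample_interval_min: float = design.SAMPLE_INTERVAL_MIN
    noise_cv: float = 0.3
    subject_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_control", "n_acute", "n_chronic"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.samples_per_block < 1 or self.sample_interval_min <= 0:
            raise ValueError("invalid sampling schedule")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "acute": self.n_acute,
            "chronic": self.n_chronic,
        }

    @property
    def n_samples(self) -> int:
        return len(self.k_schedule) * self.samples_per_block


@dataclass(frozen=True)
class ResponseKernel:
    """Gamma-shaped K+-evoked response for one perfusate block.

    ``amp_pct`` is the peak level as percent of basal (100 = no response,
    394 = peak at 3.94x basal, 53 = dip to 0.53x basal). The kernel rises to
    its peak at ``latency_min`` minutes after the block switch and then
    decays exponentially at ``decay_per_min``:

        shape(tau) = (tau / L)^a * exp(a * (1 - tau / L)),  a = decay * L

    so shape peaks at exactly 1 when tau = L and behaves like
    exp(-decay * tau) in the tail.
    """

    amp_pct: float = 100.0
    latency_min: float = 20.0
    decay_per_min: float = 0.1

    def __post_init__(self) -> None:
        if self.amp_pct < 0:
            raise ValueError("amp_pct must be >= 0")
        if self.latency_min <= 0 or self.decay_per_min <= 0:
            raise ValueError("latency_min and decay_per_min must be > 0")

    def shape(self, tau_min: np.ndarray | float) -> np.ndarray:
        tau = np.asarray(tau_min, dtype=float)
        a = self.decay_per_min * self.latency_min
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                tau > 0,
                np.exp(
                    a * (np.log(np.maximum(tau, 1e-300) / self.latency_min) + 1.0)
                    - self.decay_per_min * tau
                ),
                0.0,
            )
        return out

    def deviation(self, tau_min: np.ndarray | float) -> np.ndarray:
        """Signed percent-of-basal deviation, (amp/100 - 1) * shape(tau)."""
        return (self.amp_pct / 100.0 - 1.0) * self.shape(tau_min)


FLAT = ResponseKernel()  # amp 100% = no evoked response


@dataclass(frozen=True)
class GroupNTProfile:
    """Basal level and per-block response kinetics for one group x NT."""

    group: str
    nt: str
    basal_mean: float
    fold_vs_control: float = 1.0
    responses: dict[int, ResponseKernel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.nt not in NEUROTRANSMITTERS:
            raise ValueError(f"unknown neurotransmitter {self.nt!r}")
        if self.basal_mean <= 0:
            raise ValueError("basal_mean must be > 0")
        if self.fold_vs_control <= 0:
            raise ValueError("fold_vs_control must be > 0")
        if self.group == "control" and self.fold_vs_control != 1.0:
            raise ValueError("control profiles must have fold_vs_control = 1")


@dataclass(frozen=True)
class CouplingSpec:
    """Lag-1 coupling among the noise innovations of the five NT series.

    ``matrix[i, j]`` propagates yesterday's deviation of NT ``j`` into
    today's deviation of NT ``i`` (row order = design.NEUROTRANSMITTERS).
    Stationarity requires spectral radius < 1.
    """

    group: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (5, 5):
            raise ValueError("coupling matrix must be 5x5")
        object.__setattr__(self, "matrix", m)
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                f"coupling matrix for {self.group!r} is non-stationary "
                f"(spectral radius {self.spectral_radius():.3f} >= 1)"
            )

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.matrix))))


class ConfigurationError(ValueError):
    """A profile or coupling required by the cohort config is missing."""


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

# Control basal means (nM). Order-of-magnitude realistic for mouse PFC
# dialysate: monoamines around 1 nM, amino acids orders of magnitude higher.
_BASAL_NM = {"DA": 1.2, "5HT": 0.8, "NE": 1.5, "Glu": 1500.0, "GABA": 150.0}

# Baseline fold-changes vs control. DA and 5-HT are elevated in both exposed
# groups, NE in the chronic group; Glu and GABA baselines are unchanged.
_FOLDS = {
    "acute": {"DA": 2.71, "5HT": 1.75, "NE": 1.0, "Glu": 1.0, "GABA": 1.0},
    "chronic": {"DA": 2.14, "5HT": 1.96, "NE": 1.60, "Glu": 1.0, "GABA": 1.0},
}


def _kernels(spec: dict[int, tuple[float, float, float]]) -> dict[int, ResponseKernel]:
    return {k: ResponseKernel(*v) for k, v in spec.items()}


# Response kinetics per group x NT x K+ block, (amp_pct, latency_min,
# decay_per_min). Features: the control DA 30 mM peak of 394% basal at the
# first post-switch sample, the control GABA 515% and chronic GABA 957%
# late-session peaks at 120 mM, the control Glu dip to 53% during 60 mM, and
# the abolished (flat) DA responsiveness in both exposed groups.
_RESPONSES: dict[str, dict[str, dict[int, ResponseKernel]]] = {
    "control": {
        "DA": _kernels({30: (394, 20, 0.15), 60: (259, 40, 0.10), 120: (293, 40, 0.10)}),
        "NE": _kernels({30: (157, 20, 0.15), 60: (207, 40, 0.10), 120: (221, 40, 0.10)}),
        "5HT": _kernels({120: (200, 80, 0.02)}),
        "Glu": _kernels({30: (70, 40, 0.05), 60: (53, 40, 0.05)}),
        "GABA": _kernels({120: (515, 40, 0.08)}),
    },
    "acute": {
        "DA": {},  # abolished responsiveness
        "NE": _kernels({30: (157, 20, 0.15), 60: (207, 40, 0.10), 120: (221, 40, 0.10)}),
        "5HT": _kernels({120: (200, 80, 0.02)}),
        "Glu": _kernels({30: (70, 40, 0.05), 60: (53, 40, 0.05)}),
        "GABA": _kernels({120: (223, 40, 0.08)}),
    },
    "chronic": {
        "DA": {},  # abolished responsiveness
        "NE": _kernels({30: (130, 20, 0.15), 60: (160, 40, 0.10), 120: (170, 40, 0.10)}),
        "5HT": _kernels({120: (200, 80, 0.02)}),
        "Glu": _kernels({120: (134, 40, 0.05)}),
        "GABA": _kernels({120: (957, 60, 0.08)}),
    },
}


def default_profiles() -> dict[tuple[str, str], GroupNTProfile]:
    """Default group x NT profiles keyed by (group, nt)."""
    out: dict[tuple[str, str], GroupNTProfile] = {}
    for group in GROUPS:
        for nt in NEUROTRANSMITTERS:
            fold = 1.0 if group == "control" else _FOLDS[group][nt]
            out[(group, nt)] = GroupNTProfile(
                group=group,
                nt=nt,
                basal_mean=_BASAL_NM[nt],
                fold_vs_control=fold,
                responses=_RESPONSES[group][nt],
            )
    return out


def _mat(entries: dict[tuple[str, str], float], diag: float = 0.5) -> np.ndarray:
    """Build a 5x5 coupling matrix from {(target, source): coeff}."""
    idx = {nt: i for i, nt in enumerate(NEUROTRANSMITTERS)}
    m = np.eye(5) * diag
    for (target, source), coeff in entries.items():
        m[idx[target], idx[source]] = coeff
    return m


def default_couplings() -> dict[str, CouplingSpec]:
    """Default per-group lag-1 coupling among noise innovations.

    Control: autocorrelated series with one strong symmetric Glu-GABA
    coupling and no monoamine cross-terms. Acute: added symmetric coupling
    among the monoamines (DA, 5-HT, NE). Chronic: DA's intrinsic dynamics
    are abolished (zero own-lag) and DA is instead slaved to a strong
    correlated GABA/NE drive, with a weak residual Glu-GABA link.
    """
    control = _mat({("Glu", "GABA"): 0.48, ("GABA", "Glu"): 0.48})
    acute = _mat(
        {
            ("DA", "NE"): 0.22, ("NE", "DA"): 0.22,
            ("DA", "5HT"): 0.22, ("5HT", "DA"): 0.22,
            ("NE", "5HT"): 0.22, ("5HT", "NE"): 0.22,
            ("Glu", "GABA"): 0.20, ("GABA", "Glu"): 0.20,
        }
    )
    chronic = _mat(
        {
            ("DA", "DA"): 0.0,
            ("DA", "GABA"): 1.32, ("DA", "NE"): 1.28,
            ("GABA", "NE"): 0.45, ("NE", "GABA"): 0.45,
            ("Glu", "GABA"): 0.15, ("GABA", "Glu"): 0.15,
        }
    )
    return {
        "control": CouplingSpec("control", control),
        "acute": CouplingSpec("acute", acute),
        "chronic": CouplingSpec("chronic", chronic),
    }


def zero_couplings() -> dict[str, CouplingSpec]:
    """Couplings with all-zero matrices (independent white-noise deviations)."""
    return {g: CouplingSpec(g, np.zeros((5, 5))) for g in GROUPS}


def flat_profiles(basal: float = 1.0) -> dict[tuple[str, str], GroupNTProfile]:
    """Profiles with no K+ response and no group folds.

    Used by designed-recovery scenarios that isolate the stochastic coupling
    channel from the deterministic population response kernels.
    """
    return {
        (g, nt): GroupNTProfile(g, nt, basal_mean=basal)
        for g in GROUPS
        for nt in NEUROTRANSMITTERS
    }


def single_drive_coupling(
    source: str,
    target: str,
    drive: float = 2.2,
    source_autocorr: float = 0.85,
    base_autocorr: float = 0.5,
) -> dict[str, CouplingSpec]:
    """Couplings where one NT strongly drives another, identically per group.

    The driver keeps an elevated own-lag so its past carries information;
    every other series is plain AR(1) noise. Designed for directed-edge
    recovery checks.
    """
    idx = {nt: i for i, nt in enumerate(NEUROTRANSMITTERS)}
    m = np.eye(5) * base_autocorr
    m[idx[source], idx[source]] = source_autocorr
    m[idx[target], idx[source]] = drive
    return {g: CouplingSpec(g, m) for g in GROUPS}


# ---------------------------------------------------------------------------
# dialysate generation
# ---------------------------------------------------------------------------

_BURN_IN = 50  # VAR burn-in steps so sample 1 is already stationary


def sample_times(config: SimCohortConfig) -> np.ndarray:
    """Absolute sample times (min), t = 0 at the last baseline sample."""
    n = config.n_samples
    dt = config.sample_interval_min
    first = -dt * (config.samples_per_block - 1)
    return first + dt * np.arange(n)


def block_k(config: SimCohortConfig) -> np.ndarray:
    """Per-sample K+ level following the block schedule."""
    return np.repeat(np.asarray(config.k_schedule), config.samples_per_block)


def _block_starts(config: SimCohortConfig) -> np.ndarray:
    """Block switch times: 20 min before each block's first sample."""
    times = sample_times(config)
    return times[:: config.samples_per_block] - config.sample_interval_min


def response_factor(
    profile: GroupNTProfile, config: SimCohortConfig
) -> np.ndarray:
    """Deterministic percent-of-basal multiplier at each sample time.

    Kernels from successive blocks are superposed additively on the running
    percent-basal baseline, so a slowly decaying response carries into later
    blocks.
    """
    times = sample_times(config)
    starts = _block_starts(config)
    factor = np.ones_like(times)
    for k, start in zip(config.k_schedule, starts):
        kernel = profile.responses.get(int(k))
        if kernel is None:
            continue
        factor = factor + kernel.deviation(times - start)
    if np.any(factor <= 0):
        raise ValueError(
            f"response superposition for {profile.group}/{profile.nt} "
            "drives the series non-positive"
        )
    return factor


def _coupled_log_noise(
    rng: np.random.Generator,
    coupling: np.ndarray,
    n_samples: int,
    noise_cv: float,
) -> np.ndarray:
    """(n_samples, 5) log-noise from a lag-1 VAR, mean-one on the level scale.

    Innovation SD is sqrt(log(1 + cv^2)); each series is re-centered by half
    its stationary log-variance so E[exp(z)] = 1 exactly (unbiased sample
    means; with zero coupling the level-scale CV equals ``noise_cv``).
    """
    if noise_cv == 0:
        return np.zeros((n_samples, 5))
    from scipy.linalg import solve_discrete_lyapunov

    sigma2 = math.log(1.0 + noise_cv**2)
    stat_var = np.diag(solve_discrete_lyapunov(coupling, sigma2 * np.eye(5)))
    eps = rng.standard_normal((_BURN_IN + n_samples, 5)) * math.sqrt(sigma2)
    z = np.zeros(5)
    out = np.empty((n_samples, 5))
    for t in range(_BURN_IN + n_samples):
        z = coupling @ z + eps[t]
        if t >= _BURN_IN:
            out[t - _BURN_IN] = z
    return out - stat_var / 2.0


def generate_dialysate(
    config: SimCohortConfig,
    profiles: dict[tuple[str, str], GroupNTProfile] | None = None,
    couplings: dict[str, CouplingSpec] | None = None,
) -> pd.DataFrame:
    """Generate the long-format dialysate table for a full cohort.

    Returns columns: subject, group, sample_index (1-based), time_min, k_mM,
    neurotransmitter, conc_nM. 16 samples per subject per neurotransmitter
    under the default 4-block schedule. Deterministic given ``config.seed``.
    """
    profiles = default_profiles() if profiles is None else profiles
    couplings = default_couplings() if couplings is None else couplings

    for group in GROUPS:
        if group not in couplings:
            raise ConfigurationError(f"missing coupling for group {group!r}")
        for nt in NEUROTRANSMITTERS:
            if (group, nt) not in profiles:
                raise ConfigurationError(f"missing profile for {group}/{nt}")

    rng = np.random.default_rng(config.seed)
    times = sample_times(config)
    ks = block_k(config)
    n = config.n_samples

    factors = {
        (g, nt): response_factor(profiles[(g, nt)], config)
        for g in GROUPS
        for nt in NEUROTRANSMITTERS
    }

    rows: list[pd.DataFrame] = []
    for group in GROUPS:
        c = couplings[group].matrix
        for i in range(config.group_sizes[group]):
            subject = f"{group}_{i + 1:02d}"
            subj_effect = np.exp(
                config.subject_sd * rng.standard_normal(5)
                - config.subject_sd**2 / 2.0
            )
            z = _coupled_log_noise(rng, c, n, config.noise_cv)
            for j, nt in enumerate(NEUROTRANSMITTERS):
                prof = profiles[(group, nt)]
                conc = (
                    prof.basal_mean
                    * prof.fold_vs_control
                    * factors[(group, nt)]
                    * subj_effect[j]
                    * np.exp(z[:, j])
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "group": group,
                            "sample_index": np.arange(1, n + 1),
                            "time_min": times,
                            "k_mM": ks,
                            "neurotransmitter": nt,
                            "conc_nM": conc,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# demand generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemandGenParams:
    """Per-milk-concentration demand model means plus heterogeneity/noise.

    Q0 must increase and alpha decrease with milk concentration, so essential
    value (1/alpha) increases with concentration. ``subject_sd`` is a
    lognormal heterogeneity SD applied to each subject's Q0 and alpha;
    ``noise`` is the count-noise model ("poisson" or "none").
    """

    q0_mean: dict[int, float] = field(
        default_factory=lambda: {0: 50.0, 5: 75.0, 20: 100.0, 50: 150.0}
    )
    alpha_mean: dict[int, float] = field(
        default_factory=lambda: {0: 4.5e-4, 5: 2.6e-4, 20: 1.5e-4, 50: 8.5e-5}
    )
    k: float = 2.0
    subject_sd: float = 0.15
    noise: str = "poisson"

    def __post_init__(self) -> None:
        if set(self.q0_mean) != set(self.alpha_mean):
            raise ValueError("q0_mean and alpha_mean must cover the same concentrations")
        concs = sorted(self.q0_mean)
        q0s = [self.q0_mean[c] for c in concs]
        alphas = [self.alpha_mean[c] for c in concs]
        if any(v <= 0 for v in q0s + alphas) or self.k <= 0 or self.subject_sd < 0:
            raise ValueError("demand parameters must be positive")
        if any(b <= a for a, b in zip(q0s, q0s[1:])):
            raise ValueError("Q0 must increase with milk concentration")
        if any(b >= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("alpha must decrease with milk concentration")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


def demand_curve(q0: float, alpha: float, k: float, prices: np.ndarray) -> np.ndarray:
    """Exponential-demand consumption on the natural scale.

    log10 Q = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)
    """
    if q0 <= 0 or alpha <= 0:
        raise ValueError("Q0 and alpha must be positive")
    prices = np.asarray(prices, dtype=float)
    return 10.0 ** (np.log10(q0) + k * (np.exp(-alpha * q0 * prices) - 1.0))


def generate_demand(
    params: DemandGenParams | None = None,
    n_per_group: int = 8,
    seed: int = 0,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Draw per-subject consumption counts at the fixed-ratio price ladder.

    Returns columns: subject, group, milk_pct, price, consumption
    (nonnegative integers under poisson noise; exact model values, rounded,
    under "none").
    """
    params = DemandGenParams() if params is None else params
    rng = np.random.default_rng(seed)
    prices = np.asarray(PRICES, dtype=float)
    rows = []
    for group in groups:
        for i in range(n_per_group):
            subject = f"{group}_{i + 1:02d}"
            het = np.exp(params.subject_sd * rng.standard_normal(2))
            for milk in sorted(params.q0_mean):
                q0 = params.q0_mean[milk] * het[0]
                alpha = params.alpha_mean[milk] * het[1]
                mu = demand_curve(q0, alpha, params.k, prices)
                if params.noise == "poisson":
                    q = rng.poisson(mu)
                else:
                    q = np.round(mu).astype(int)
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "group": group,
                            "milk_pct": milk,
                            "price": PRICES,
                            "consumption": q.astype(int),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# vigilance agents
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentParams:
    """Latent reaction-time model of one vigilance subject (or group mean).

    Session-s mean latent RT = asymptote + (initial - asymptote) * exp(-s/tau);
    per-trial RTs are lognormal around that mean with CV ``rt_cv``; with
    probability ``lapse_prob`` the agent lapses (no response within any
    finite limit).
    """

    initial_rt_mean: float = 8.0
    asymptote_rt_mean: float = 2.5
    learning_tau: float = 3.0
    rt_cv: float = 0.25
    lapse_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.asymptote_rt_mean <= self.initial_rt_mean):
            raise ValueError("need 0 < asymptote_rt_mean <= initial_rt_mean")
        if not (0 <= self.lapse_prob < 1):
            raise ValueError("need 0 <= lapse_prob < 1")
        if self.learning_tau <= 0:
            raise ValueError("learning_tau must be > 0")
        if self.rt_cv < 0:
            raise ValueError("rt_cv must be >= 0")

    def session_mean_rt(self, session: int) -> float:
        return self.asymptote_rt_mean + (
            self.initial_rt_mean - self.asymptote_rt_mean
        ) * math.exp(-session / self.learning_tau)


#: Group-mean agent defaults: controls asymptote near 2.5 s; exposed groups
#: plateau about 1 s slower and learn more slowly.
DEFAULT_AGENT_PARAMS: dict[str, AgentParams] = {
    "control": AgentParams(asymptote_rt_mean=2.5, learning_tau=3.0),
    "acute": AgentParams(asymptote_rt_mean=3.5, learning_tau=5.0),
    "chronic": AgentParams(asymptote_rt_mean=3.5, learning_tau=5.0),
}


@dataclass(frozen=True)
class SubjectAgent:
    """An AgentParams bound to a subject id and group."""

    subject: str
    group: str
    params: AgentParams

    def respond(self, session: int, rng: np.random.Generator) -> float:
        """Latency (s) for one trial; ``inf`` encodes a lapse."""
        if self.params.lapse_prob > 0 and rng.random() < self.params.lapse_prob:
            return math.inf
        mean = self.params.session_mean_rt(session)
        if self.params.rt_cv == 0:
            return mean
        sigma = math.sqrt(math.log(1.0 + self.params.rt_cv**2))
        mu = math.log(mean) - sigma**2 / 2.0
        return float(np.exp(mu + sigma * rng.standard_normal()))


def generate_vigilance_agents(
    group_params: dict[str, AgentParams] | None = None,
    n_per_group: int = 8,
    seed: int = 0,
    jitter_sd: float = 0.10,
) -> list[SubjectAgent]:
    """Bind per-subject agents, lognormally jittered around group means.

    Jitter applies to the asymptote and learning time-constant; the initial
    RT, CV, and lapse probability are shared within a group.
    """
    group_params = (
        dict(DEFAULT_AGENT_PARAMS) if group_params is None else group_params
    )
    rng = np.random.default_rng(seed)
    agents = []
    for group, base in group_params.items():
        for i in range(n_per_group):
            g = np.exp(jitter_sd * rng.standard_normal(2))
            asym = min(base.asymptote_rt_mean * g[0], base.initial_rt_mean)
            params = replace(
                base,
                asymptote_rt_mean=asym,
                learning_tau=base.learning_tau * g[1],
            )
            agents.append(SubjectAgent(f"{group}_{i + 1:02d}", group, params))
    return agents
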