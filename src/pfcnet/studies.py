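"""Repeated-seed validation studies over the synthetic generator.

These are the package's own calibration and recovery experiments: parameter
recovery for the demand fit, type-I/power calibration of the Granger test,
and designed-coupling recovery for the correlation and iRF-LOOP networks.
They are consumed by the test suite and the reproduction script; problem
sizes are arguments so callers choose their precision/runtime trade-off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import causality as cz
from . import corrnet, demand, irfnet, neurochem
from . import synthetic as syn


def demand_recovery_study(n_cohorts: int = 200, seed: int = 0) -> dict[str, float]:
    """Median relative recovery error of alpha and Q0 over simulated cohorts.

    Each cohort is drawn by ``generate_demand`` with default count noise and
    heterogeneity and re-fit with k fixed at the generating range constant.
    Errors are measured against each subject's own (heterogeneous) true
    parameters.
    """
    params = syn.DemandGenParams()
    alpha_errs: list[float] = []
    q0_errs: list[float] = []
    root = np.random.SeedSequence(seed)
    for cohort_seed in root.generate_state(n_cohorts) % (2**31 - 1):
        rng = np.random.default_rng(int(cohort_seed))
        # mirror the generator's per-subject heterogeneity to know the truth
        truth = {}
        rows = []
        for i in range(8):
            subject = f"control_{i + 1:02d}"
            het = np.exp(params.subject_sd * rng.standard_normal(2))
            for milk in sorted(params.q0_mean):
                q0 = params.q0_mean[milk] * het[0]
                alpha = params.alpha_mean[milk] * het[1]
                truth[(subject, milk)] = (q0, alpha)
                mu = syn.demand_curve(q0, alpha, params.k,
                                      np.array(syn.PRICES, float))
                rows.append((subject, milk, rng.poisson(mu)))
        obs = pd.concat(
            [pd.DataFrame({"subject": s, "group": "control", "milk_pct": m,
                           "price": syn.PRICES, "consumption": q.astype(int)})
             for s, m, q in rows],
            ignore_index=True,
        )
        for fit in demand.fit_demand(obs, k_mode=params.k):
            if fit.status != "ok":
                continue
            q0_true, a_true = truth[(fit.subject, fit.milk_pct)]
            q0_errs.append(abs(fit.q0 - q0_true) / q0_true)
            alpha_errs.append(abs(fit.alpha - a_true) / a_true)
    return {
        "alpha_median_rel_error": float(np.median(alpha_errs)),
        "q0_median_rel_error": float(np.median(q0_errs)),
        "n_fits": len(alpha_errs),
    }


def granger_type_i_study(n_seeds: int = 2000, t_len: int = 40,
                         seed: int = 0) -> float:
    """Lag-1 rejection rate at alpha = 0.05 on independent white noise."""
    spec = cz.GrangerSpec(max_lag=1)
    root = np.random.SeedSequence(seed)
    rejections = 0
    for s in root.generate_state(n_seeds) % (2**31 - 1):
        rng = np.random.default_rng(int(s))
        a, b = rng.standard_normal(t_len), rng.standard_normal(t_len)
        rejections += cz.granger_test(a, b, spec).p < 0.05
    return rejections / n_seeds


def granger_power_study(n_seeds: int = 500, t_len: int = 40,
                        noise: float = 1e-3, seed: int = 0) -> float:
    """Detection rate of the designed causal process B_t = A_{t-1}."""
    spec = cz.GrangerSpec(max_lag=3)
    root = np.random.SeedSequence(seed)
    detected = 0
    for s in root.generate_state(n_seeds) % (2**31 - 1):
        rng = np.random.default_rng(int(s))
        a = rng.standard_normal(t_len + 1)
        b = a[:-1] + noise * rng.standard_normal(t_len)
        detected += cz.granger_test(a[1:], b, spec).p < 0.05
    return detected / n_seeds


def corr_glu_gaba_recovery(n_seeds: int = 100, seed: int = 0) -> float:
    """Fraction of seeded default cohorts whose control 4 mM correlation
    network contains the designed Glu-GABA edge."""
    hits = 0
    root = np.random.SeedSequence(seed)
    for s in root.generate_state(n_seeds) % (2**31 - 1):
        df = syn.generate_dialysate(syn.SimCohortConfig(seed=int(s)))
        levels = neurochem.cumulative_levels(df)
        sub = levels[(levels.group == "control") & (levels.k_mM == 4)]
        net = corrnet.build_network(corrnet.pairwise_correlations(sub))
        hits += net.has_edge("Glu", "GABA")
    return hits / n_seeds


def irf_da_ne_recovery(n_seeds: int = 100, seed: int = 0,
                       n_trees: int = 150, n_iterations: int = 2) -> float:
    """Fraction of designed single-coupling cohorts (DA drives NE) whose
    iRF-LOOP network retains the DA->NE edge."""
    hits = 0
    root = np.random.SeedSequence(seed)
    for s in root.generate_state(n_seeds) % (2**31 - 1):
        df = syn.generate_dialysate(
            syn.SimCohortConfig(seed=int(s), noise_cv=0.2),
            syn.flat_profiles(),
            syn.single_drive_coupling("DA", "NE"),
        )
        samples = irfnet.block_samples(df, "control", 30.0)
        net = irfnet.irf_loop(
            samples, irfnet.IRFConfig(n_trees, n_iterations, seed=int(s))
        )
        hits += ("DA", "NE") in {(e.source, e.target) for e in net.edges}
    return hits / n_seeds


def granger_chronic_recovery(n_seeds: int = 100, seed: int = 0) -> dict[str, float]:
    """Recovery rates of the chronic coupling's directed drives onto DA.

    Cohorts use the default chronic coupling with flat response kernels so
    the stochastic lag-1 channel is isolated. Reports the fraction of seeds
    whose chronic-group median p falls below 0.05 for GABA->DA, NE->DA, and
    (as a negative control) Glu->DA.
    """
    spec = cz.GrangerSpec()
    pairs = [("GABA", "DA"), ("NE", "DA"), ("Glu", "DA")]
    hits = {p: 0 for p in pairs}
    root = np.random.SeedSequence(seed)
    for s in root.generate_state(n_seeds) % (2**31 - 1):
        df = syn.generate_dialysate(syn.SimCohortConfig(seed=int(s)),
                                    syn.flat_profiles())
        per = cz.subject_series(df[df.group == "chronic"])
        for src, tgt in pairs:
            ps = [cz.granger_test(series[src], series[tgt], spec).p
                  for series in per.values()]
            hits[(src, tgt)] += float(np.median(ps)) < 0.05
    return {f"{a}->{b}": h / n_seeds for (a, b), h in hits.items()}
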