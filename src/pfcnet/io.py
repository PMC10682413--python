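"""File schemas, validated readers/writers, network export, and the
end-to-end pipeline runner.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator, missing values as empty fields. Column names are normative:

* dialysate: subject, group, sample_index, time_min, k_mM,
  neurotransmitter, conc_nM
* demand: subject, group, milk_pct, price, consumption
* vigilance: subject, group, session, trial, location, iti_s, limit_s,
  outcome, rt_s

Group labels are restricted to {control, acute, chronic} and
neurotransmitters to {DA, 5HT, NE, Glu, GABA}.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__, causality, corrnet, demand, design, irfnet, neurochem
from . import synthetic, vigilance
from .design import GROUPS, K_SCHEDULE, NEUROTRANSMITTERS

log = logging.getLogger("pfcnet")

DIALYSATE_COLUMNS = [
    "subject", "group", "sample_index", "time_min", "k_mM",
    "neurotransmitter", "conc_nM",
]
DEMAND_COLUMNS = ["subject", "group", "milk_pct", "price", "consumption"]
VIGILANCE_COLUMNS = [
    "subject", "group", "session", "trial", "location", "iti_s", "limit_s",
    "outcome", "rt_s",
]


class SchemaError(ValueError):
    """A table violates its documented schema; message names row and rule."""


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _check_values(df: pd.DataFrame, col: str, allowed, name: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based with header row
        raise SchemaError(
            f"{name} row {row}: {col}={df.loc[df.index[bad][0], col]!r} "
            f"not in allowed set {sorted(allowed)}"
        )


def read_dialysate(path: str | Path) -> pd.DataFrame:
    """Read and validate a dialysate CSV."""
    df = pd.read_csv(path)
    _check_columns(df, DIALYSATE_COLUMNS, "dialysate")
    _check_values(df, "group", set(GROUPS), "dialysate")
    _check_values(df, "neurotransmitter", set(NEUROTRANSMITTERS), "dialysate")
    _check_values(df, "k_mM", set(K_SCHEDULE), "dialysate")
    neg = df["conc_nM"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise SchemaError(f"dialysate row {row}: negative conc_nM")
    # within-subject time grid: samples 20 min apart in sample order
    for (subj, nt), sub in df.groupby(["subject", "neurotransmitter"]):
        t = sub.sort_values("sample_index")["time_min"].to_numpy(float)
        if len(t) > 1 and not np.allclose(np.diff(t), design.SAMPLE_INTERVAL_MIN):
            raise SchemaError(
                f"dialysate: broken time grid for subject {subj!r}/{nt} "
                f"(samples must be {design.SAMPLE_INTERVAL_MIN:g} min apart)"
            )
    return df


def read_demand(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DEMAND_COLUMNS, "demand")
    _check_values(df, "group", set(GROUPS), "demand")
    _check_values(df, "price", set(design.PRICES), "demand")
    neg = df["consumption"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise SchemaError(f"demand row {row}: negative consumption")
    return df


def read_vigilance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, VIGILANCE_COLUMNS, "vigilance")
    _check_values(df, "group", set(GROUPS), "vigilance")
    _check_values(df, "outcome", {"hit", "miss"}, "vigilance")
    low = df["limit_s"] < design.LIMIT_FLOOR_S
    if low.any():
        row = int(df.index[low][0]) + 2
        raise SchemaError(f"vigilance row {row}: limit_s below 0.25 s floor")
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def _as_digraph(net: irfnet.DirectedNetwork) -> nx.DiGraph:
    g = nx.DiGraph(group=net.group, k_mM=float(net.k_mM))
    g.add_nodes_from(NEUROTRANSMITTERS)
    for e in net.edges:
        g.add_edge(e.source, e.target, importance=e.importance, sign=e.sign)
    return g


def network_to_dict(net: nx.Graph) -> dict:
    return {
        "directed": bool(net.is_directed()),
        "graph": {k: v for k, v in net.graph.items()},
        "nodes": sorted(net.nodes),
        "edges": [
            {"source": u, "target": v, **{k: w for k, w in d.items()}}
            for u, v, d in sorted(net.edges(data=True))
        ],
    }


def network_from_dict(payload: dict) -> nx.Graph:
    g = nx.DiGraph(**payload["graph"]) if payload["directed"] else nx.Graph(
        **payload["graph"]
    )
    g.add_nodes_from(payload["nodes"])
    for e in payload["edges"]:
        attrs = {k: v for k, v in e.items() if k not in ("source", "target")}
        g.add_edge(e["source"], e["target"], **attrs)
    return g


def export_network(
    network: nx.Graph | irfnet.DirectedNetwork, path: str | Path, fmt: str = "json"
) -> Path:
    """Serialize a network losslessly as JSON, GraphML, or edge-list CSV."""
    if isinstance(network, irfnet.DirectedNetwork):
        network = _as_digraph(network)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(network_to_dict(network), indent=1, sort_keys=True))
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "csv":
        rows = [
            {"source": u, "target": v, **d}
            for u, v, d in sorted(network.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (json, graphml, csv)")
    return path


def import_network(path: str | Path, fmt: str = "json") -> nx.Graph:
    path = Path(path)
    if fmt == "json":
        return network_from_dict(json.loads(path.read_text()))
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

ALL_STAGES = (
    "simulate", "neurochem", "corrnet", "irfnet", "granger",
    "demand", "vigilance",
)
#: Stages that consume the dialysate table.
_NEEDS_DIALYSATE = {"neurochem", "corrnet", "irfnet", "granger"}


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs or a simulation block, stage
    toggles, thresholds, output directory, and the global seed."""

    outdir: str | Path = "pfcnet_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # input CSVs; when None the corresponding tables are simulated
    dialysate_path: str | None = None
    demand_path: str | None = None
    vigilance_path: str | None = None
    # simulation block
    sim: synthetic.SimCohortConfig | None = None
    n_per_group_behavior: int = 8
    # threshold overrides
    r_min: float = corrnet.R_THRESHOLD
    p_alpha: float = corrnet.P_THRESHOLD
    importance_threshold: float = 0.2
    max_lag: int = 3
    # iRF problem size
    n_trees: int = 500
    n_iterations: int = 5
    k_mode: str | float = "shared"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.p_alpha < 1) or not (-1 <= self.r_min <= 1):
            raise ValueError("thresholds out of range")
        if not (0 <= self.importance_threshold <= 1) or self.max_lag < 1:
            raise ValueError("thresholds out of range")
        if self.dialysate_path is not None and self.sim is not None:
            raise ValueError(
                "provide either a dialysate path or a simulation block, not both"
            )


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file (keys mirror the dataclass)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("sim", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "stages"},
                    stages=tuple(raw.get("stages", ALL_STAGES)))
    if sim is not None:
        cfg.sim = synthetic.SimCohortConfig(**sim)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    A failed stage halts its dependents; independent stages continue. The
    manifest records inputs, seed, thresholds, per-stage status, and every
    output file written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": int(config.seed),
        "thresholds": {
            "r_min": config.r_min, "p_alpha": config.p_alpha,
            "importance_threshold": config.importance_threshold,
            "max_lag": config.max_lag,
        },
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, detail: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "detail": detail}
        log.info("stage=%s seed=%d status=%s %s", stage, config.seed, status, detail)

    def emit(df: pd.DataFrame, name: str) -> None:
        path = write_csv(df, outdir / name)
        manifest["outputs"].append(str(path.relative_to(outdir)))

    dialysate = demand_tab = vigilance_tab = None
    failed: set[str] = set()

    # ---- simulate -------------------------------------------------------
    if "simulate" in config.stages:
        try:
            sim = config.sim or synthetic.SimCohortConfig(seed=int(seeds[0]))
            dialysate = synthetic.generate_dialysate(sim)
            demand_tab = synthetic.generate_demand(
                n_per_group=config.n_per_group_behavior, seed=int(seeds[1])
            )
            agents = synthetic.generate_vigilance_agents(
                n_per_group=config.n_per_group_behavior, seed=int(seeds[2])
            )
            vigilance_trials, vigilance_tab = vigilance.run_cohort(
                agents, seed=int(seeds[3])
            )
            emit(dialysate, "dialysate.csv")
            emit(demand_tab, "demand.csv")
            emit(vigilance_trials, "vigilance_trials.csv")
            emit(vigilance_tab, "vigilance_sessions.csv")
            record("simulate", "ok")
        except Exception as exc:  # halt dependents, keep independents
            failed.add("simulate")
            record("simulate", "failed", repr(exc))

    if config.dialysate_path:
        dialysate = read_dialysate(config.dialysate_path)
        manifest["inputs"] = {"dialysate": str(config.dialysate_path)}
    if config.demand_path:
        demand_tab = read_demand(config.demand_path)
    if config.vigilance_path:
        trials = read_vigilance(config.vigilance_path)
        vigilance_tab = vigilance.summaries_from_trials(trials)

    levels = None

    # ---- neurochemistry -------------------------------------------------
    if "neurochem" in config.stages:
        if dialysate is None:
            record("neurochem", "skipped", "no dialysate table")
        else:
            try:
                basal = neurochem.compute_basal(dialysate)
                levels = neurochem.cumulative_levels(dialysate)
                series = neurochem.percent_basal_series(dialysate)
                comparisons = neurochem.compare_cumulative(levels)
                anovas = {
                    nt: _strip_frames(neurochem.timecourse_anova(series, nt))
                    for nt in NEUROTRANSMITTERS
                }
                emit(basal, "basal_levels.csv")
                emit(levels, "cumulative_levels.csv")
                emit(series, "percent_basal.csv")
                emit(comparisons, "cumulative_comparisons.csv")
                _write_json(anovas, outdir / "timecourse_anova.json", manifest, outdir)
                record("neurochem", "ok")
            except Exception as exc:
                failed.add("neurochem")
                record("neurochem", "failed", repr(exc))

    # ---- correlation networks ------------------------------------------
    if "corrnet" in config.stages:
        if levels is None:
            record("corrnet", "skipped", "no cumulative levels")
        else:
            try:
                nets = corrnet.correlation_networks(
                    levels, r_min=config.r_min, p_alpha=config.p_alpha
                )
                all_pairs = []
                for (group, k), sub in levels.groupby(["group", "k_mM"]):
                    pairs = corrnet.pairwise_correlations(sub)
                    pairs.insert(0, "group", group)
                    pairs.insert(1, "k_mM", k)
                    all_pairs.append(pairs)
                emit(pd.concat(all_pairs, ignore_index=True), "correlations.csv")
                for (group, k), net in nets.items():
                    name = f"corr_network_{group}_{int(k)}mM"
                    p = export_network(net, outdir / f"{name}.json", "json")
                    manifest["outputs"].append(str(p.relative_to(outdir)))
                    p = export_network(net, outdir / f"{name}.graphml", "graphml")
                    manifest["outputs"].append(str(p.relative_to(outdir)))
                record("corrnet", "ok", f"{len(nets)} networks")
            except Exception as exc:
                failed.add("corrnet")
                record("corrnet", "failed", repr(exc))

    # ---- iRF-LOOP networks ---------------------------------------------
    if "irfnet" in config.stages:
        if dialysate is None:
            record("irfnet", "skipped", "no dialysate table")
        else:
            try:
                cfg = irfnet.IRFConfig(
                    n_trees=config.n_trees,
                    n_iterations=config.n_iterations,
                    importance_threshold=config.importance_threshold,
                    seed=int(seeds[4]),
                )
                nets = irfnet.irf_networks(dialysate, cfg)
                for (group, k), net in nets.items():
                    name = f"irf_network_{group}_{int(k)}mM"
                    p = export_network(net, outdir / f"{name}.json", "json")
                    manifest["outputs"].append(str(p.relative_to(outdir)))
                    p = export_network(net, outdir / f"{name}.graphml", "graphml")
                    manifest["outputs"].append(str(p.relative_to(outdir)))
                diff_rows = []
                ks = sorted({k for (_, k) in nets})
                for k in ks:
                    for ga, gb in (("acute", "control"), ("chronic", "control"),
                                   ("acute", "chronic")):
                        if (ga, k) in nets and (gb, k) in nets:
                            d = irfnet.difference_network(nets[(ga, k)], nets[(gb, k)])
                            for (src, tgt), v in sorted(d.differences.items()):
                                diff_rows.append(
                                    {"group_a": ga, "group_b": gb, "k_mM": k,
                                     "source": src, "target": tgt,
                                     "abs_difference": v}
                                )
                emit(pd.DataFrame(diff_rows), "irf_difference_networks.csv")
                record("irfnet", "ok", f"{len(nets)} networks")
            except Exception as exc:
                failed.add("irfnet")
                record("irfnet", "failed", repr(exc))

    # ---- Granger causality ---------------------------------------------
    if "granger" in config.stages:
        if dialysate is None:
            record("granger", "skipped", "no dialysate table")
        else:
            try:
                spec = causality.GrangerSpec(max_lag=config.max_lag)
                matrix = causality.causal_matrix(dialysate, spec)
                table = causality.results_table(matrix, alpha=spec.alpha)
                emit(table, "granger_results.csv")
                decisions = {
                    f"{g}:{s}->{t}": bool(d.decision(spec.alpha))
                    for (g, s, t), d in sorted(matrix.items())
                }
                _write_json(decisions, outdir / "granger_decisions.json",
                            manifest, outdir)
                record("granger", "ok")
            except Exception as exc:
                failed.add("granger")
                record("granger", "failed", repr(exc))

    # ---- demand ---------------------------------------------------------
    if "demand" in config.stages:
        if demand_tab is None:
            record("demand", "skipped", "no demand table")
        else:
            try:
                fits = demand.fit_demand(demand_tab, k_mode=config.k_mode)
                ftab = demand.fits_table(fits)
                emit(ftab, "demand_fits.csv")
                ok = ftab[ftab["status"] == "ok"]
                anova = {
                    "q0": demand.demand_anova(ok, "q0"),
                    "essential_value": demand.demand_anova(ok, "essential_value"),
                }
                _write_json(anova, outdir / "demand_anova.json", manifest, outdir)
                record("demand", "ok", f"{len(ftab)} curves")
            except Exception as exc:
                failed.add("demand")
                record("demand", "failed", repr(exc))

    # ---- vigilance ------------------------------------------------------
    if "vigilance" in config.stages:
        if vigilance_tab is None:
            record("vigilance", "skipped", "no vigilance table")
        else:
            try:
                anova = vigilance.vigilance_anova(vigilance_tab)
                _write_json(_strip_frames(anova), outdir / "vigilance_anova.json",
                            manifest, outdir)
                record("vigilance", "ok")
            except Exception as exc:
                failed.add("vigilance")
                record("vigilance", "failed", repr(exc))

    manifest["ok"] = not failed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _strip_frames(obj):
    """Replace DataFrames with row-record lists so dicts are JSON-safe."""
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _strip_frames(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_json(payload, path: Path, manifest: dict, outdir: Path) -> None:
    path.write_text(json.dumps(_strip_frames(payload), indent=1, sort_keys=True,
                               default=str))
    manifest["outputs"].append(str(path.relative_to(outdir)))
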