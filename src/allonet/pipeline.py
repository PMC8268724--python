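"""End-to-end drivers: the before-intervention and delta network experiments.

``run_analysis`` executes, per group: baseline network → subject-level
delta table (with the baseline-substitution rule for variables not
re-measured post-intervention) → delta network → the six node metrics for
all four networks → Mann-Whitney comparison of the two baseline networks
and of the two delta networks → assumption-routed baseline variable
comparison. All artifacts are written to the output directory; a
provenance block records every analysis-shaping choice so a run can be
repeated identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cohort import generate_cohort, preset_scenarios
from .compare import ComparisonReport, baseline_compare, compare_networks
from .correlation import spearman_matrix
from .io import (
    export_cytoscape_json,
    export_graphml,
    read_measurement_csv,
    write_comparison_report,
    write_correlation_csvs,
    write_measurement_csv,
    write_metrics_csv,
)
from .metrics import compute_all_metrics
from .network import build_network, delta_table
from .panel import default_panel

__all__ = ["AnalysisConfig", "RunReport", "run_analysis"]

logger = logging.getLogger(__name__)

P_VALUE_MODES = ("auto", "approx", "exact")


@dataclass
class AnalysisConfig:
    """Everything that shapes one analysis run.

    Exactly one input source: either a named synthetic ``scenario`` (with
    ``seed``) or ``before_path``/``after_path`` CSVs.
    """

    scenario: str | None = None
    before_path: str | None = None
    after_path: str | None = None
    alpha: float = 0.05
    p_value_mode: str = "auto"
    exact_threshold: int = 9
    substitute_baseline_for: list[list[str]] | None = None
    include_isolated: bool = True
    ordered_pair_stress: bool = False
    outdir: str = "allonet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.p_value_mode not in P_VALUE_MODES:
            raise ValueError(f"p_value_mode must be one of {P_VALUE_MODES}")
        synthetic = self.scenario is not None
        files = self.before_path is not None and self.after_path is not None
        if synthetic == files:
            raise ValueError(
                "provide exactly one input source: a scenario name or "
                "before/after CSV paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    """Handles on every computed object plus the paths written for them."""

    networks: dict  # (group, stage) -> nx.Graph
    metrics: dict  # (group, stage) -> DataFrame
    comparison_before: ComparisonReport
    comparison_delta: ComparisonReport
    baseline: pd.DataFrame
    provenance: dict
    paths: dict = field(default_factory=dict)


def _load_tables(cfg: AnalysisConfig, panel):
    if cfg.scenario is not None:
        scenarios = preset_scenarios(panel)
        if cfg.scenario not in scenarios:
            raise ValueError(
                f"unknown scenario {cfg.scenario!r}; available: {sorted(scenarios)}"
            )
        from dataclasses import replace

        spec = replace(scenarios[cfg.scenario], seed=cfg.seed)
        before, after = generate_cohort(spec)
        substitution = cfg.substitute_baseline_for
        if substitution is None:
            substitution = [list(t) for t in sorted(spec.missing_after)]
        return before, after, substitution, spec
    before = read_measurement_csv(cfg.before_path, panel)
    after = read_measurement_csv(cfg.after_path, panel)
    return before, after, cfg.substitute_baseline_for or [], None


def run_analysis(cfg: AnalysisConfig, panel=None) -> RunReport:
    """Run the full two-experiment analysis and write all artifacts."""
    panel = panel or default_panel()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"[{name}] {err}") from err

    before, after, substitution, spec = stage("load", _load_tables, cfg, panel)
    sub_set = {(g, v) for g, v in substitution}
    if cfg.scenario is not None:
        paths["cohort_before"] = write_measurement_csv(before, outdir / "cohort_before.csv")
        paths["cohort_after"] = write_measurement_csv(after, outdir / "cohort_after.csv")

    groups = sorted(before["group"].unique())
    if len(groups) != 2:
        raise RuntimeError(f"[load] expected exactly two groups, found {groups}")

    networks: dict[tuple[str, str], nx.Graph] = {}
    metrics: dict[tuple[str, str], pd.DataFrame] = {}
    for g in groups:
        b_g = before[before["group"] == g]
        a_g = after[after["group"] == g]
        tables = {"before": b_g}
        sub_g = {(gr, v) for gr, v in sub_set if gr == g}
        dt = stage(f"delta:{g}", delta_table, b_g, a_g, sub_g)
        tables["delta"] = dt.data
        if dt.substituted.to_numpy().any():
            flagged = sorted(dt.substituted.columns[dt.substituted.any()])
            logger.info("group %s: baseline carried forward for %s", g, flagged)
        for stage_name, tbl in tables.items():
            key = f"{g}_{stage_name}"
            corr = stage(
                f"correlation:{key}",
                spearman_matrix,
                tbl,
                panel,
                method=cfg.p_value_mode,
                exact_threshold=cfg.exact_threshold,
            )
            paths[f"{key}_corr"] = write_correlation_csvs(corr, outdir / key)[0]
            net = stage(f"network:{key}", build_network, corr, cfg.alpha, panel)
            m = stage(
                f"metrics:{key}",
                compute_all_metrics,
                net,
                ordered_pairs=cfg.ordered_pair_stress,
            )
            networks[(g, stage_name)] = net
            metrics[(g, stage_name)] = m
            paths[f"{key}_graphml"] = export_graphml(net, m, outdir / f"{key}.graphml")
            paths[f"{key}_json"] = export_cytoscape_json(net, outdir / f"{key}.json")
            paths[f"{key}_metrics"] = write_metrics_csv(m, net, outdir / f"{key}_metrics.csv")

    cmp_kwargs = dict(include_isolated=cfg.include_isolated)
    comparison_before = stage(
        "compare:before",
        compare_networks,
        metrics[(groups[0], "before")],
        metrics[(groups[1], "before")],
        **cmp_kwargs,
    )
    comparison_delta = stage(
        "compare:delta",
        compare_networks,
        metrics[(groups[0], "delta")],
        metrics[(groups[1], "delta")],
        **cmp_kwargs,
    )
    paths["comparison_before"] = write_comparison_report(
        comparison_before, outdir / "comparison_before"
    )[0]
    paths["comparison_delta"] = write_comparison_report(
        comparison_delta, outdir / "comparison_delta"
    )[0]

    baseline = stage(
        "baseline",
        baseline_compare,
        before[before["group"] == groups[0]],
        before[before["group"] == groups[1]],
        list(panel.names),
    )
    baseline_path = outdir / "baseline_comparison.csv"
    baseline.to_csv(baseline_path)
    paths["baseline"] = baseline_path

    provenance = {
        "config": cfg.to_dict(),
        "substitution": substitution,
        "node_inclusion": "all" if cfg.include_isolated else "non-isolated",
        "p_value_mode": cfg.p_value_mode,
        "stress_pair_convention": "ordered" if cfg.ordered_pair_stress else "unordered",
        "effect_size_n": "total node count of both networks",
        "versions": {
            "allonet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
            "python": platform.python_version(),
        },
        "seed": cfg.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1), encoding="utf-8")
    paths["provenance"] = prov_path

    return RunReport(
        networks=networks,
        metrics=metrics,
        comparison_before=comparison_before,
        comparison_delta=comparison_delta,
        baseline=baseline,
        provenance=provenance,
        paths=paths,
    )
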