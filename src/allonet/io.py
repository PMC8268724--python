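"""Reading and writing of the standard artifact formats.

Measurement tables travel as UTF-8 CSV (``subject_id, group, timepoint``
then panel variables; missing values as empty fields). Networks are
exported as GraphML (via networkx, round-trippable with attribute types
preserved) and as Cytoscape-style JSON node/edge lists; matrices, metric
tables and comparison reports as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .compare import ComparisonReport, format_comparison
from .correlation import CorrelationResult
from .metrics import METRIC_NAMES
from .network import META_COLUMNS
from .panel import VariablePanel

__all__ = [
    "write_measurement_csv",
    "read_measurement_csv",
    "write_correlation_csvs",
    "export_graphml",
    "read_graphml",
    "export_cytoscape_json",
    "write_metrics_csv",
    "write_comparison_report",
]


def write_measurement_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")
    return path


def read_measurement_csv(path, panel: VariablePanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV {path} lacks columns {missing}")
    if panel is not None:
        absent = [v for v in panel.names if v not in df.columns]
        if absent:
            raise ValueError(f"measurement CSV {path} lacks panel variables {absent}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, timepoint) rows: "
            f"{df.loc[dup, 'subject_id'].tolist()}"
        )
    return df


def write_correlation_csvs(corr: CorrelationResult, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rho_path = prefix.with_name(prefix.name + "_rho.csv")
    p_path = prefix.with_name(prefix.name + "_p.csv")
    corr.rho.to_csv(rho_path)
    corr.p.to_csv(p_path)
    return rho_path, p_path


def export_graphml(network: nx.Graph, metrics: pd.DataFrame | None, path) -> Path:
    """Write GraphML with category/degree/metric node attributes.

    ``metrics`` (if given) must cover exactly the network's node set; its
    six metric columns are merged into the node attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = network.copy()
    if metrics is not None:
        if set(metrics.index) != set(g.nodes):
            raise ValueError("metrics table and network have different node sets")
        for node in g.nodes:
            for m in METRIC_NAMES:
                g.nodes[node][m] = float(metrics.loc[node, m])
    nx.write_graphml(g, path, named_key_ids=True)
    return path


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def export_cytoscape_json(network: nx.Graph, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nodes = [
        {"data": {"id": n, **network.nodes[n]}} for n in sorted(network.nodes)
    ]
    edges = [
        {"data": {"source": u, "target": v, **d}}
        for u, v, d in sorted(network.edges(data=True))
    ]
    payload = {"elements": {"nodes": nodes, "edges": edges}}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    return path


def write_metrics_csv(metrics: pd.DataFrame, network: nx.Graph, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = metrics.copy()
    out.insert(0, "category", [network.nodes[n].get("category", "") for n in out.index])
    out.to_csv(path)
    return path


def write_comparison_report(report: ComparisonReport, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_name(prefix.name + ".csv")
    md_path = prefix.with_name(prefix.name + ".md")
    report.table.to_csv(csv_path)
    lines = ["# Network metric comparison", ""]
    lines += [f"- {k}: {v}" for k, v in report.metadata.items()]
    lines += ["", "```", format_comparison(report), "```", ""]
    md_path.write_text("\n".join(lines), encoding="utf-8")
    return csv_path, md_path
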