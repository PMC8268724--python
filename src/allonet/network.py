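"""Significance-filtered signed correlation networks and delta tables.

An edge is drawn between two variables exactly when the two-sided Spearman
p-value falls below the chosen alpha; the edge carries the signed rho, the
p-value and a ``sign`` label. Every panel variable remains in the graph as a
node even when isolated — isolated nodes are informative (a variable
decoupled from the rest of the system) and enter downstream metric
comparisons with zero-valued metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationResult
from .panel import VariablePanel

__all__ = ["DeltaTable", "build_network", "delta_table"]

META_COLUMNS = ["subject_id", "group", "timepoint"]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up), NaNs passed through."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv)
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    ranked = np.empty(m)
    ranked[order] = np.minimum(adj, 1.0)
    out[ok] = ranked
    return out


def build_network(
    corr: CorrelationResult,
    alpha: float,
    panel: VariablePanel,
    *,
    fdr_correction: bool = False,
) -> nx.Graph:
    """Build the signed network: edge (u, v) iff p(u, v) < alpha.

    Node attributes: ``category``, ``degree`` (the quantity that scales the
    node dots in the usual rendering). Edge attributes: ``rho``, ``p``,
    ``sign`` in {"positive", "negative"}. The graph records ``alpha``.

    ``fdr_correction`` thresholds Benjamini-Hochberg-adjusted p-values
    instead of the raw ones. It is off by default: the reproduced
    procedure applies no multiplicity correction, and the stored edge
    ``p`` attribute always remains the raw pairwise p-value.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    g = nx.Graph(alpha=float(alpha), fdr_correction=fdr_correction)
    for name in panel.names:
        g.add_node(name, category=panel.category_of(name))
    pmat, rmat = corr.p, corr.rho
    names = list(corr.variables)
    if fdr_correction:
        k = len(names)
        iu = np.triu_indices(k, 1)
        raw = pmat.to_numpy()[iu]
        adj = _benjamini_hochberg(raw)
        adj_mat = np.full((k, k), np.nan)
        adj_mat[iu] = adj
        adj_mat[(iu[1], iu[0])] = adj
        pmat = pd.DataFrame(adj_mat, index=names, columns=names)
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            p = pmat.loc[u, v]
            if np.isnan(p) or p >= alpha:
                continue
            rho = float(rmat.loc[u, v])
            g.add_edge(
                u,
                v,
                rho=rho,
                p=float(corr.p.loc[u, v]),
                sign="negative" if rho < 0 else "positive",
            )
    for name in g.nodes:
        g.nodes[name]["degree"] = g.degree(name)
    return g


@dataclass(frozen=True)
class DeltaTable:
    """Per-subject after-minus-before changes, with substitution flags.

    ``data`` mirrors the measurement-table layout (timepoint = "delta").
    ``substituted`` is a boolean frame of the same shape marking cells where
    the baseline value was carried forward because the variable was not
    measured post-intervention.
    """

    data: pd.DataFrame
    substituted: pd.DataFrame


def delta_table(
    before: pd.DataFrame,
    after: pd.DataFrame,
    substitute_baseline_for: set[tuple[str, str]] | frozenset = frozenset(),
) -> DeltaTable:
    """Compute subject-level deltas, carrying the baseline where substituted.

    For every (group, variable) in ``substitute_baseline_for`` the before
    value itself is used in place of the (missing) change score and flagged.
    Requesting substitution for a variable that does have post data is an
    error (ambiguous intent), as is an after-subject with no before record.
    """
    b = before.set_index("subject_id")
    a = after.set_index("subject_id")
    unmatched = sorted(set(a.index) - set(b.index))
    if unmatched:
        raise ValueError(f"after-subjects without a before record: {unmatched}")
    a = a.loc[b.index.intersection(a.index)]
    b = b.loc[a.index]
    variables = [c for c in before.columns if c not in META_COLUMNS]

    for group, var in substitute_baseline_for:
        col = a.loc[a["group"] == group, var]
        if col.notna().any():
            raise ValueError(
                f"substitution requested for ({group!r}, {var!r}) but "
                "post-intervention data exist for it"
            )

    delta = a[variables] - b[variables]
    flags = pd.DataFrame(False, index=delta.index, columns=variables)
    for group, var in substitute_baseline_for:
        mask = b["group"] == group
        delta.loc[mask, var] = b.loc[mask, var]
        flags.loc[mask, var] = True

    out = delta.reset_index()
    out.insert(1, "group", b["group"].to_numpy())
    out.insert(2, "timepoint", "delta")
    return DeltaTable(data=out, substituted=flags.reset_index(drop=True))
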