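"""Nonparametric comparison of two networks' node-metric distributions.

The Mann-Whitney U statistic is the number of (x_i, y_j) pairs with
x_i > y_j plus half the tied pairs. Z comes from the normal approximation
with tie-corrected variance and a 0.5 continuity correction; the two-sided
p is exact (enumeration of all group assignments of the pooled sample) for
small totals. Effect size follows the Rosenthal convention r = |Z| / sqrt(N)
with N the total number of observations entering the comparison, signed by
the direction of the group difference.

Node-level metric values within one network are not independent samples;
the comparison reproduces the standard procedure as-is and records this
caveat in the report metadata rather than correcting for it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

__all__ = [
    "MWUResult",
    "ComparisonReport",
    "mann_whitney_u",
    "effect_size_r",
    "compare_networks",
    "baseline_compare",
    "format_comparison",
]

logger = logging.getLogger(__name__)

#: largest pooled sample for which the exact permutation p is computed
DEFAULT_EXACT_THRESHOLD = 12

INDEPENDENCE_CAVEAT = (
    "node-level metric values within a network are not independent "
    "observations; p-values are descriptive"
)


class MWUResult(NamedTuple):
    U: float
    Z: float
    p: float
    n1: int
    n2: int
    exact: bool


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x via pooled mid-ranks (equals pair counting with half-ties)."""
    n1 = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]), method="average")
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _tie_sigma(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return math.sqrt(max(var, 0.0))


def _p_exact(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p: share of group assignments at least as extreme.

    Extremeness is |U - n1*n2/2| measured against the observed value; all
    C(n1+n2, n1) assignments of the pooled values to the first group are
    enumerated.
    """
    n = len(pooled)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    ranks = stats.rankdata(pooled, method="average")
    offset = n1 * (n1 + 1) / 2.0
    threshold = abs(u_obs - mu) - 1e-9
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= threshold:
            count += 1
        total += 1
    return count / total


def mann_whitney_u(
    x,
    y,
    *,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    continuity: bool = True,
) -> MWUResult:
    """Mann-Whitney U test of two independent samples (two-sided).

    Exact p by assignment enumeration when ``n1 + n2 <= exact_threshold``,
    otherwise the tie-corrected normal approximation with continuity
    correction. Z is reported from the normal approximation in both modes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2.0
    sigma = _tie_sigma(pooled, n1, n2)
    if sigma == 0.0:
        z = 0.0
    else:
        shift = abs(u - mu)
        if continuity:
            shift = max(shift - 0.5, 0.0)
        z = math.copysign(shift / sigma, u - mu) if u != mu else 0.0
    exact = n1 + n2 <= exact_threshold
    if exact:
        p = _p_exact(pooled, n1, u)
    else:
        p = float(2.0 * stats.norm.sf(abs(z))) if sigma > 0 else 1.0
    return MWUResult(U=u, Z=z, p=min(p, 1.0), n1=n1, n2=n2, exact=exact)


def effect_size_r(Z: float, n_total: int, direction: float = 1.0) -> float:
    """Rosenthal effect size r = |Z| / sqrt(N), signed by ``direction``."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    r = abs(Z) / math.sqrt(n_total)
    if r > 1.0:
        logger.warning("effect size %.3f clipped to 1", r)
        r = 1.0
    if direction == 0:
        return 0.0
    return math.copysign(r, direction)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-metric Mann-Whitney comparison of two networks' node values.

    ``table`` columns: mean/sd per network, U, Z, p, effect size r (signed
    positive when network A's values run higher), n1, n2, direction.
    """

    table: pd.DataFrame
    include_isolated: bool
    metadata: dict = field(default_factory=dict)


def _direction(u: float, n1: int, n2: int, mean_a: float, mean_b: float) -> float:
    d = u - n1 * n2 / 2.0
    if d != 0:
        return math.copysign(1.0, d)
    if mean_a != mean_b:
        return math.copysign(1.0, mean_a - mean_b)
    return 0.0


def compare_networks(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    metric_names: list[str] | None = None,
    *,
    include_isolated: bool = True,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> ComparisonReport:
    """Compare per-node metric distributions of two networks.

    With ``include_isolated=False``, degree-0 nodes are dropped from each
    network's vectors before testing (the alternative node-inclusion
    policy; it materially changes means on sparse networks).
    """
    metric_names = list(metric_names or METRIC_NAMES)
    for m in metric_names:
        for tbl, lbl in ((metrics_a, "A"), (metrics_b, "B")):
            if m not in tbl.columns:
                raise KeyError(f"metric {m!r} missing from network {lbl} table")
    a, b = metrics_a, metrics_b
    if not include_isolated:
        a = a[a["degree"] > 0]
        b = b[b["degree"] > 0]
    rows = []
    for m in metric_names:
        x = a[m].to_numpy(dtype=float)
        y = b[m].to_numpy(dtype=float)
        res = mann_whitney_u(x, y, exact_threshold=exact_threshold)
        mean_a, mean_b = float(x.mean()), float(y.mean())
        direction = _direction(res.U, res.n1, res.n2, mean_a, mean_b)
        r = effect_size_r(res.Z, res.n1 + res.n2, direction)
        rows.append(
            {
                "metric": m,
                "mean_a": mean_a,
                "sd_a": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "mean_b": mean_b,
                "sd_b": float(y.std(ddof=1)) if len(y) > 1 else 0.0,
                "U": res.U,
                "Z": res.Z,
                "p": res.p,
                "r": r,
                "n1": res.n1,
                "n2": res.n2,
                "direction": {1.0: "A higher", -1.0: "B higher", 0.0: "tie"}[direction],
            }
        )
    table = pd.DataFrame(rows).set_index("metric")
    meta = {
        "node_inclusion": "all" if include_isolated else "non-isolated",
        "effect_size_n": "total node count of both networks",
        "caveat": INDEPENDENCE_CAVEAT,
    }
    return ComparisonReport(table=table, include_isolated=include_isolated, metadata=meta)


def format_comparison(report: ComparisonReport) -> str:
    """Human-readable "mean ± SD vs. mean ± SD, p, r" lines per metric."""
    lines = []
    for m, row in report.table.iterrows():
        lines.append(
            f"{m}: {row.mean_a:.3g} ± {row.sd_a:.3g} vs. "
            f"{row.mean_b:.3g} ± {row.sd_b:.3g}, p = {row.p:.3g}, r = {row.r:.2f}"
            f" ({row.direction})"
        )
    return "\n".join(lines)


def baseline_compare(
    before_a: pd.DataFrame,
    before_b: pd.DataFrame,
    variables: list[str],
    *,
    alpha_assumptions: float = 0.05,
) -> pd.DataFrame:
    """Assumption-routed per-variable group comparison at baseline.

    Each variable goes to the independent two-sample t-test when both
    groups pass Shapiro-Wilk normality and Levene's homogeneity-of-variance
    test (all at ``alpha_assumptions``); otherwise to Mann-Whitney. The
    routing flags are recorded alongside the p-value so the choice is
    auditable per variable.
    """
    rows = []
    for var in variables:
        x = before_a[var].dropna().to_numpy(dtype=float)
        y = before_b[var].dropna().to_numpy(dtype=float)
        row = {
            "variable": var,
            "mean_a": float(x.mean()) if len(x) else np.nan,
            "sd_a": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
            "mean_b": float(y.mean()) if len(y) else np.nan,
            "sd_b": float(y.std(ddof=1)) if len(y) > 1 else np.nan,
            "n_a": len(x),
            "n_b": len(y),
        }
        if len(x) < 3 or len(y) < 3:
            row.update(
                normal_a=np.nan, normal_b=np.nan, equal_var=np.nan,
                test="insufficient", p=np.nan,
            )
            logger.warning("variable %r: insufficient data for comparison", var)
            rows.append(row)
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            normal_a = normal_b = False  # degenerate: Shapiro undefined
            equal_var = False
        else:
            normal_a = stats.shapiro(x).pvalue > alpha_assumptions
            normal_b = stats.shapiro(y).pvalue > alpha_assumptions
            equal_var = stats.levene(x, y).pvalue > alpha_assumptions
        if normal_a and normal_b and equal_var:
            test = "t-test"
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        else:
            test = "mann-whitney"
            p = mann_whitney_u(x, y).p
        row.update(
            normal_a=bool(normal_a), normal_b=bool(normal_b),
            equal_var=bool(equal_var), test=test, p=p,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
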