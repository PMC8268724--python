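"""Pairwise Spearman correlation with two-sided p-values.

rho is the product-moment correlation of mid-ranks (average ranks on ties).
The two-sided p-value comes from the t approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2`` degrees of freedom,
or — for small samples — from exact enumeration of all permutations of one
margin (the null distribution of rho under exchangeability, ties preserved).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import VariablePanel

__all__ = [
    "CorrelationResult",
    "ConstantInputError",
    "InsufficientDataError",
    "spearman_pair",
    "spearman_matrix",
]

logger = logging.getLogger(__name__)

#: largest n for which "auto" p-value mode enumerates all n! permutations
DEFAULT_EXACT_THRESHOLD = 9


class ConstantInputError(ValueError):
    """All values tied in one vector: the rank correlation is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than 3 complete observation pairs."""


def _midranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0.0:
        raise ConstantInputError("constant vector: rank correlation undefined")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def _p_approx(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _p_exact(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided p by full enumeration of permutations of one margin.

    With ties, the permutations of the observed (tied) rank values are
    enumerated, so the null distribution conditions on both tie patterns.
    """
    n = len(ry)
    rxc = rx - rx.mean()
    sx = math.sqrt(rxc @ rxc)
    ryc = ry - ry.mean()
    sy = math.sqrt(ryc @ ryc)
    threshold = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    for perm in itertools.permutations(ryc):
        r = (rxc @ np.asarray(perm)) / (sx * sy)
        if abs(r) >= threshold:
            count += 1
        total += 1
    assert total == math.factorial(n)
    return count / total


def spearman_pair(
    x,
    y,
    *,
    method: str = "auto",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    pair_name: str | None = None,
) -> tuple[float, float, int]:
    """Spearman rho and two-sided p for one variable pair.

    Incomplete pairs (NaN in either vector) are dropped (pairwise deletion).
    ``method`` is ``"approx"``, ``"exact"`` or ``"auto"`` (exact when the
    complete-pair count is at most ``exact_threshold``).

    Returns ``(rho, p, n_used)``.
    """
    if method not in ("auto", "approx", "exact"):
        raise ValueError(f"unknown p-value method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    label = f" for pair {pair_name}" if pair_name else ""
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 complete observations{label}, got {n}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(f"constant vector{label}: correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)
    exact = method == "exact" or (method == "auto" and n <= exact_threshold)
    p = _p_exact(rx, ry, rho) if exact else _p_approx(rho, n)
    return rho, p, n


@dataclass(frozen=True)
class CorrelationResult:
    """Symmetric Spearman rho and p matrices over a variable panel.

    ``rho`` and ``p`` are square DataFrames indexed by variable name;
    ``n_used`` holds the per-pair complete-observation count. Pairs whose
    correlation is undefined (constant column, too few observations) carry
    NaN in all three matrices.
    """

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame


def spearman_matrix(
    table: pd.DataFrame,
    panel: VariablePanel,
    *,
    method: str = "auto",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> CorrelationResult:
    """All-pairs Spearman correlation over the panel columns of a table.

    Pairwise deletion per pair. A pair failing (constant values,
    insufficient data) is logged as a warning and recorded as NaN rather
    than aborting the whole matrix.
    """
    names = list(panel.names)
    data = table[names].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise InsufficientDataError("need at least 3 subjects")
    k = len(names)

    complete = not np.isnan(data).any()
    use_fast = complete and (
        method == "approx" or (method == "auto" and data.shape[0] > exact_threshold)
    )
    if use_fast:
        ranks = np.apply_along_axis(_midranks, 0, data)
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        n = data.shape[0]
        p = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                if np.isnan(rho[i, j]):
                    logger.warning(
                        "correlation undefined for pair (%s, %s)", names[i], names[j]
                    )
                    continue
                p[i, j] = p[j, i] = _p_approx(float(rho[i, j]), n)
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        n_used = np.full((k, k), n)
    else:
        rho = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        n_used = np.zeros((k, k), dtype=int)
        np.fill_diagonal(rho, 1.0)
        for i in range(k):
            for j in range(i + 1, k):
                try:
                    r, pv, nu = spearman_pair(
                        data[:, i],
                        data[:, j],
                        method=method,
                        exact_threshold=exact_threshold,
                        pair_name=f"({names[i]}, {names[j]})",
                    )
                except (ConstantInputError, InsufficientDataError) as err:
                    logger.warning("%s", err)
                    continue
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = pv
                n_used[i, j] = n_used[j, i] = nu
        np.fill_diagonal(n_used, data.shape[0])

    def frame(m):
        return pd.DataFrame(m, index=names, columns=names)

    return CorrelationResult(
        variables=tuple(names), rho=frame(rho), p=frame(p), n_used=frame(n_used)
    )
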