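"""Synthetic two-group paired-cohort generator with prescribed Spearman structure.

Subjects are drawn from a Gaussian copula: the target Spearman correlation
matrix is converted entrywise to the latent Pearson matrix via
``2 * sin(pi * rho_s / 6)``, repaired to positive definite if needed, and a
multivariate normal is sampled. Spearman correlations are invariant to
monotone marginal transforms, so the sampled data attain the target rank
structure regardless of the (optional) marginal transform applied.

Post-intervention values are generated additively — ``after = before +
delta`` with the delta drawn from its own correlation structure — so that
subject-level change scores exist, which the delta-network stage requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import VariablePanel, default_panel

__all__ = [
    "CohortSpec",
    "PDRepairError",
    "spearman_to_pearson",
    "nearest_positive_definite",
    "generate_cohort",
    "preset_scenarios",
]

GROUPS = ("A", "B")


class PDRepairError(ValueError):
    """Raised when a correlation matrix cannot be repaired to positive definite."""


def spearman_to_pearson(rho_s):
    """Convert a Spearman correlation to the latent bivariate-normal Pearson value.

    Uses the Gaussian-copula identity ``rho_p = 2 * sin(pi * rho_s / 6)``.
    Accepts scalars or arrays; values must lie in [-1, 1].
    """
    arr = np.asarray(rho_s, dtype=float)
    if np.any(np.isnan(arr)) or np.any(np.abs(arr) > 1.0):
        raise ValueError("Spearman correlation must be in [-1, 1]")
    out = 2.0 * np.sin(np.pi * arr / 6.0)
    if np.ndim(rho_s) == 0:
        return float(out)
    return out


def nearest_positive_definite(
    matrix: np.ndarray, floor: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped to ``floor`` and the diagonal renormalized to 1;
    the two steps alternate until the smallest eigenvalue clears the floor.
    The result is the closest candidate (Frobenius) among the iterates.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    out = (m + m.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        if w.min() >= floor:
            return out
        w_clipped = np.clip(w, floor, None)
        out = (v * w_clipped) @ v.T
        out = (out + out.T) / 2.0
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    w = np.linalg.eigvalsh(out)
    if w.min() >= floor * 0.5:  # renormalization may leave it a hair under
        return out
    raise PDRepairError(
        f"could not reach eigenvalue floor {floor} after {max_iter} iterations; "
        f"min eigenvalue {w.min():.3e}; offending matrix:\n{np.array_str(m, precision=3)}"
    )


def _check_target_matrix(mat: np.ndarray, p: int, label: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (p, p):
        raise ValueError(f"{label}: expected shape {(p, p)}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{label}: matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{label}: diagonal must be 1")
    if np.abs(mat).max() > 1.0 + 1e-12:
        raise ValueError(f"{label}: entries must lie in [-1, 1]")
    return mat


_TRANSFORMS = {
    None: lambda x: x,
    "exp": np.exp,  # skewed positive marginals; monotone, Spearman-invariant
}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic paired two-group cohort.

    ``target_spearman_before`` and ``delta_spearman`` map group label to a
    symmetric Spearman correlation matrix over the panel variables.
    ``delta_effect_means`` gives the per-variable mean shift of the
    after-minus-before change, ``noise_scale`` the per-variable spread.
    ``missing_after`` lists (group, variable) cells not measured
    post-intervention (emitted as missing values).
    """

    panel: VariablePanel
    n_per_group: tuple[int, int] = (32, 18)
    target_spearman_before: dict[str, np.ndarray] | None = None
    delta_spearman: dict[str, np.ndarray] | None = None
    delta_effect_means: dict[str, np.ndarray] | None = None
    noise_scale: np.ndarray | None = None
    seed: int = 0
    transform: str | None = None
    missing_after: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        p = len(self.panel)
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 4:
            raise ValueError("n_per_group must be two integers >= 4")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        for g, v in self.missing_after:
            if g not in GROUPS or v not in self.panel.names:
                raise ValueError(f"invalid missing_after entry {(g, v)}")
        for attr in ("target_spearman_before", "delta_spearman"):
            mats = getattr(self, attr)
            if mats is not None:
                for g in GROUPS:
                    _check_target_matrix(mats[g], p, f"{attr}[{g}]")

    def resolved(self) -> "CohortSpec":
        """Fill optional fields with their defaults (identity / zero / unit)."""
        p = len(self.panel)
        eye = {g: np.eye(p) for g in GROUPS}
        return replace(
            self,
            target_spearman_before=self.target_spearman_before or eye,
            delta_spearman=self.delta_spearman or {g: np.eye(p) for g in GROUPS},
            delta_effect_means=self.delta_effect_means
            or {g: np.zeros(p) for g in GROUPS},
            noise_scale=self.noise_scale if self.noise_scale is not None else np.ones(p),
        )


def _latent_cholesky(target_spearman: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    pearson = spearman_to_pearson(target_spearman)
    np.fill_diagonal(pearson, 1.0)
    pearson = nearest_positive_definite(pearson, floor=floor)
    return np.linalg.cholesky(pearson)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the paired cohort; returns (before, after) measurement tables.

    Deterministic given ``spec.seed``. Each table has columns
    ``subject_id, group, timepoint`` followed by the panel variables.
    """
    spec = spec.resolved()
    panel = spec.panel
    p = len(panel)
    rng = np.random.default_rng(spec.seed)
    f = _TRANSFORMS[spec.transform]

    rows_before, rows_after = [], []
    for g, n in zip(GROUPS, spec.n_per_group):
        L_before = _latent_cholesky(spec.target_spearman_before[g])
        L_delta = _latent_cholesky(spec.delta_spearman[g])
        z_before = rng.standard_normal((n, p)) @ L_before.T
        z_delta = rng.standard_normal((n, p)) @ L_delta.T
        before = z_before * spec.noise_scale
        delta = spec.delta_effect_means[g] + z_delta * spec.noise_scale
        after = before + delta
        before, after = f(before), f(after)
        for var in (v for grp, v in spec.missing_after if grp == g):
            after[:, panel.index(var)] = np.nan
        width = max(2, len(str(n)))
        ids = [f"{g}{i + 1:0{width}d}" for i in range(n)]
        rows_before.append((ids, g, before))
        rows_after.append((ids, g, after))

    def assemble(rows, timepoint):
        frames = []
        for ids, g, vals in rows:
            df = pd.DataFrame(vals, columns=list(panel.names))
            df.insert(0, "timepoint", timepoint)
            df.insert(0, "group", g)
            df.insert(0, "subject_id", ids)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    return assemble(rows_before, "before"), assemble(rows_after, "after")


# ---------------------------------------------------------------------------
# Preset scenarios


def _block(mat: np.ndarray, idx: list[int], rho: float) -> None:
    """Set equicorrelation rho inside the index block (diagonal untouched)."""
    for a in idx:
        for b in idx:
            if a != b:
                mat[a, b] = rho


def _set(mat: np.ndarray, panel: VariablePanel, u: str, v: str, rho: float) -> None:
    i, j = panel.index(u), panel.index(v)
    mat[i, j] = mat[j, i] = rho


def _hub_vs_balanced(panel: VariablePanel) -> CohortSpec:
    p = len(panel)
    # Group A concentrates correlation on two hub variables.
    # Nodes 0-10: a two-level "spider" — hub 0 correlated 0.38 with inner
    # nodes 1-5, each inner node correlated 0.38 with one outer node 6-10.
    # Geodesics between outer nodes all run through the hub, so its stress
    # is large and outer nodes sit far from the rest (high eccentricity).
    a = np.eye(p)
    for inner, outer in zip(range(1, 6), range(6, 11)):
        a[0, inner] = a[inner, 0] = 0.38
        a[inner, outer] = a[outer, inner] = 0.38
    # Nodes 11-17: a strong star — hub 11 correlated 0.52 with six spokes.
    # The weak spoke-spoke 0.13 is required for positive definiteness of
    # six spokes at >= 0.5. Nodes 18-20 stay uncorrelated.
    for s in range(12, 18):
        a[11, s] = a[s, 11] = 0.52
    _block(a, list(range(12, 18)), 0.13)
    # Group B spreads information perfectly evenly: every pair at a
    # moderate 0.40 (equicorrelation). The detected network is close to
    # complete — eccentricity 1, stress 0 for every node — the polar
    # opposite of the hub-concentrated group.
    b = np.full((p, p), 0.40)
    np.fill_diagonal(b, 1.0)
    return CohortSpec(
        panel=panel,
        n_per_group=(150, 150),
        target_spearman_before={"A": a, "B": b},
        seed=0,
    )


def _paper_like(panel: VariablePanel) -> CohortSpec:
    p = len(panel)
    names = panel.names
    cat_idx = {
        c: [i for i, n in enumerate(names) if panel.category_of(n) == c]
        for c in ("fatigue", "cognitive", "cardiac", "vascular")
    }

    # Group A (patient-like, uneven/hub structure): fatigue tied to
    # baroreflex function, baroreflex to aortic stiffness, central systolic
    # pressure to cognition; LF/HF isolated.
    a = np.eye(p)
    _block(a, cat_idx["fatigue"], 0.5)
    _block(a, cat_idx["cognitive"], 0.4)
    _block(a, cat_idx["cardiac"], 0.3)
    _block(a, [panel.index(v) for v in ("TPRI", "mBP", "PWVaortic")], 0.3)
    for fat in ("CFQ", "FSS", "FIS"):
        _set(a, panel, fat, "Total BEI", 0.45)
    _set(a, panel, "Total BEI", "PWVaortic", 0.5)
    for cog in ("TMT A", "TMT B", "TMT B-A"):
        _set(a, panel, "SBPaortic", cog, 0.4)

    # Group B (control-like, balanced): fatigue related to cognition, LF/HF
    # connected to blood-pressure regulation and cognition.
    b = np.eye(p)
    _block(b, cat_idx["fatigue"], 0.5)
    _block(b, cat_idx["cognitive"], 0.4)
    _block(b, cat_idx["cardiac"], 0.3)
    _block(b, [panel.index(v) for v in ("TPRI", "mBP", "SBPaortic")], 0.3)
    for fat, cog in (("CFQ", "TMT A"), ("FSS", "TMT A"), ("FIS", "Coding I")):
        _set(b, panel, fat, cog, 0.45)
    for v in ("mBP", "SBPaortic", "TMT B"):
        _set(b, panel, "LF/HF", v, 0.45)

    # Delta structure. Patient-like: fatigue changes track baroreflex and
    # aortic-stiffness changes. Control-like: fatigue (baseline carried
    # forward) relates to autonomic change, TMT A change negatively to
    # fatigue.
    da = np.eye(p)
    _block(da, cat_idx["fatigue"], 0.5)
    for fat in ("CFQ", "FSS", "FIS"):
        _set(da, panel, fat, "Total BEI", 0.5)
    _set(da, panel, "Total BEI", "PWVaortic", 0.5)

    db = np.eye(p)
    _block(db, cat_idx["fatigue"], 0.5)
    for fat in ("CFQ", "FSS"):
        _set(db, panel, fat, "TMT A", -0.45)
    _set(db, panel, "FIS", "LF/HF", 0.45)

    # Mild fatigue reduction in the patient-like group, in SD units.
    means_a = np.zeros(p)
    for fat in ("CFQ", "FSS", "FIS"):
        means_a[panel.index(fat)] = -0.5
    means_b = np.zeros(p)

    return CohortSpec(
        panel=panel,
        n_per_group=(32, 18),
        target_spearman_before={"A": a, "B": b},
        delta_spearman={"A": da, "B": db},
        delta_effect_means={"A": means_a, "B": means_b},
        seed=0,
        missing_after=frozenset(
            ("B", v) for v in ("CFQ", "FSS", "FIS")
        ),  # fatigue not re-measured in the control-like group
    )


def preset_scenarios(panel: VariablePanel | None = None) -> dict[str, CohortSpec]:
    """Named cohort scenarios.

    - ``null``: both groups independent variables (identity structure).
    - ``hub_vs_balanced``: group A concentrates correlation on three hub
      variables; group B spreads moderate correlation evenly.
    - ``paper_like``: qualitative reconstruction of the patient vs control
      contrast (named edges only; the underlying matrices were never
      published).
    """
    panel = panel or default_panel()
    return {
        "null": CohortSpec(panel=panel, n_per_group=(32, 18), seed=0),
        "hub_vs_balanced": _hub_vs_balanced(panel),
        "paper_like": _paper_like(panel),
    }
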