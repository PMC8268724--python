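"""Variable panel: the measured variables and their physiological categories.

The default panel covers the 21 variables of a multi-system assessment of
fatigue, cognition, hemodynamics, arterial stiffness and autonomic function:
fatigue questionnaires (CFQ, FSS, FIS), cognitive speed/flexibility tests
(TMT A/B, coding), impedance-cardiography hemodynamics (HR, SI, CI, HI, PEP,
LVET, LVWI), vascular load and stiffness (TPRI, mBP, PWVaortic, SBPaortic)
and autonomic/baroreflex readouts (Total BEI, LF/HF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = ("cognitive", "fatigue", "vascular", "cardiac", "autonomic")

_DEFAULT_VARIABLES: tuple[tuple[str, str], ...] = (
    ("CFQ", "fatigue"),
    ("FSS", "fatigue"),
    ("FIS", "fatigue"),
    ("TMT A", "cognitive"),
    ("TMT B", "cognitive"),
    ("TMT B-A", "cognitive"),
    ("Coding I", "cognitive"),
    ("Coding II", "cognitive"),
    ("HR", "cardiac"),
    ("SI", "cardiac"),
    ("CI", "cardiac"),
    ("HI", "cardiac"),
    ("PEP", "cardiac"),
    ("LVET", "cardiac"),
    ("LVWI", "cardiac"),
    ("TPRI", "vascular"),
    ("mBP", "vascular"),
    ("PWVaortic", "vascular"),
    ("SBPaortic", "vascular"),
    ("Total BEI", "autonomic"),
    ("LF/HF", "autonomic"),
)


@dataclass(frozen=True)
class VariablePanel:
    """Ordered set of variable names with a category for each.

    Invariants: names are unique, and every name maps to exactly one of
    the five physiological categories.
    """

    names: tuple[str, ...]
    categories: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("panel variable names must be unique")
        missing = [n for n in self.names if n not in self.categories]
        if missing:
            raise ValueError(f"variables without a category: {missing}")
        bad = {n: c for n, c in self.categories.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {bad}; allowed: {CATEGORIES}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def category_of(self, name: str) -> str:
        return self.categories[name]


def default_panel() -> VariablePanel:
    """The 21-variable multi-system panel."""
    names = tuple(n for n, _ in _DEFAULT_VARIABLES)
    return VariablePanel(names=names, categories=dict(_DEFAULT_VARIABLES))
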