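"""PD-L1 immunohistochemistry scoring (SP142-style TC/IC ladders).

TC score bins the percentage of PD-L1-expressing tumor cells
(TC3 >= 50%; TC2 5 to < 50%; TC1 >= 1 to < 5%; TC0 < 1%) and the IC score
bins the percentage of tumor area occupied by PD-L1-positive immune cells
(IC3 >= 10%; IC2 >= 5 to < 10%; IC1 >= 1 to < 5%; IC0 < 1%). Category 0 is
negative; 1/2/3 map to weak/moderate/strong positive; "any+" means any
nonzero category. TC and IC are scored independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

Grade = Literal["negative", "weak", "moderate", "strong"]
_GRADES: tuple[Grade, ...] = ("negative", "weak", "moderate", "strong")

TC_BIN_EDGES = (1.0, 5.0, 50.0)  # lower bounds of TC1, TC2, TC3
IC_BIN_EDGES = (1.0, 5.0, 10.0)  # lower bounds of IC1, IC2, IC3


@dataclass(frozen=True)
class IHCReadout:
    patient_id: str
    tc_pct: float
    ic_pct: float

    def __post_init__(self) -> None:
        for name, v in (("tc_pct", self.tc_pct), ("ic_pct", self.ic_pct)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0,100]")


@dataclass(frozen=True)
class IHCScore:
    patient_id: str
    tc_category: str  # TC0..TC3
    ic_category: str  # IC0..IC3
    tc_grade: Grade
    ic_grade: Grade
    tc_positive: bool
    ic_positive: bool


def _bin_level(pct: float, edges: tuple[float, ...]) -> int:
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage {pct} outside [0,100]")
    level = 0
    for edge in edges:  # lower bounds inclusive, half-open bins
        if pct >= edge:
            level += 1
    return level


def tc_category(tc_pct: float) -> str:
    return f"TC{_bin_level(tc_pct, TC_BIN_EDGES)}"


def ic_category(ic_pct: float) -> str:
    return f"IC{_bin_level(ic_pct, IC_BIN_EDGES)}"


def score_patient(readout: IHCReadout) -> IHCScore:
    """Score both compartments independently; positivity is any+."""
    tc_level = _bin_level(readout.tc_pct, TC_BIN_EDGES)
    ic_level = _bin_level(readout.ic_pct, IC_BIN_EDGES)
    return IHCScore(
        patient_id=readout.patient_id,
        tc_category=f"TC{tc_level}",
        ic_category=f"IC{ic_level}",
        tc_grade=_GRADES[tc_level],
        ic_grade=_GRADES[ic_level],
        tc_positive=tc_level > 0,
        ic_positive=ic_level > 0,
    )


def combined_grade(score: IHCScore) -> Grade:
    """Max of the two compartment grades (off the default analysis path)."""
    return _GRADES[max(_GRADES.index(score.tc_grade), _GRADES.index(score.ic_grade))]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def frequency_table(
    scores: Sequence[IHCScore],
    compartment: Literal["TC", "IC"] = "TC",
    n_categories: int = 4,
) -> dict:
    """Cohort percent frequencies of staining intensity.

    With ``n_categories=4`` the categories are negative/weak/moderate/strong;
    with 2 they collapse to negative vs positive (any+). Percentages are
    rounded half-up to integer percent; raw counts are also returned.
    """
    if not scores:
        raise ValueError("empty cohort")
    if n_categories not in (2, 4):
        raise ValueError("n_categories must be 2 or 4")
    grades = [s.tc_grade if compartment == "TC" else s.ic_grade for s in scores]
    n = len(grades)
    if n_categories == 4:
        labels: tuple[str, ...] = _GRADES
        counts = {g: grades.count(g) for g in labels}
    else:
        labels = ("negative", "positive")
        neg = grades.count("negative")
        counts = {"negative": neg, "positive": n - neg}
    return {
        "compartment": compartment,
        "n": n,
        "counts": counts,
        "percent": {k: round_half_up(100.0 * c / n) for k, c in counts.items()},
        "proportion": {k: c / n for k, c in counts.items()},
    }
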