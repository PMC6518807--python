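"""Combined TMB x PD-L1 biomarker classes and overlap summaries.

Dichotomized TMB (High vs Low/Moderate) crossed with PD-L1 TC positivity
(any+) yields four mutually exclusive classes: LM_neg, LM_pos, H_pos and
H_neg. Survival reporting typically shows the first three; H_neg patients
exist and are assigned explicitly, with a flag to exclude them from plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .pdl1 import round_half_up
from .tmb import TMBBinary

CombinedClass = Literal["LM_neg", "LM_pos", "H_pos", "H_neg"]
COMBINED_CLASSES: tuple[CombinedClass, ...] = ("LM_neg", "LM_pos", "H_pos", "H_neg")


@dataclass(frozen=True)
class StratumAssignment:
    patient_id: str
    tmb_binary: TMBBinary
    pdl1_positive: bool
    combined_class: CombinedClass

    def __post_init__(self) -> None:
        if self.combined_class != combine(self.tmb_binary, self.pdl1_positive):
            raise ValueError("combined_class inconsistent with its inputs")


def combine(tmb_binary: TMBBinary, pdl1_positive: bool) -> CombinedClass:
    if tmb_binary == "High":
        return "H_pos" if pdl1_positive else "H_neg"
    if tmb_binary == "Low/Moderate":
        return "LM_pos" if pdl1_positive else "LM_neg"
    raise ValueError(f"unknown TMB binary class {tmb_binary!r}")


def assign(patient_id: str, tmb_binary: TMBBinary, pdl1_positive: bool) -> StratumAssignment:
    return StratumAssignment(
        patient_id=patient_id,
        tmb_binary=tmb_binary,
        pdl1_positive=pdl1_positive,
        combined_class=combine(tmb_binary, pdl1_positive),
    )


def overlap_summary(
    assignments: Sequence[StratumAssignment],
    total_n: Optional[int] = None,
) -> dict:
    """Venn counts of PD-L1 positivity vs TMB-high within a subgroup.

    Returns mutually exclusive counts {pdl1_only, tmb_high_only, both,
    neither} summing to the subgroup size, with percentages (half-up) over
    the subgroup and, when ``total_n`` is given, over the total cohort —
    both normalizations, since overlap figures are quoted either way.
    """
    if not assignments:
        raise ValueError("empty subgroup")
    n = len(assignments)
    counts = {
        "pdl1_only": sum(a.combined_class == "LM_pos" for a in assignments),
        "tmb_high_only": sum(a.combined_class == "H_neg" for a in assignments),
        "both": sum(a.combined_class == "H_pos" for a in assignments),
        "neither": sum(a.combined_class == "LM_neg" for a in assignments),
    }
    out = {
        "n": n,
        "counts": counts,
        "percent": {k: round_half_up(100.0 * c / n) for k, c in counts.items()},
    }
    if total_n is not None:
        if total_n < n:
            raise ValueError("total_n smaller than subgroup size")
        out["percent_of_total"] = {
            k: round_half_up(100.0 * c / total_n) for k, c in counts.items()
        }
        out["total_n"] = total_n
    return out
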