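"""Tumor mutational burden: per-patient quantification and cohort cutoffs.

TMB is the number of retained somatic coding mutations (substitutions and
indels; synonymous included by default) divided by the panel's coding
territory in megabases. The cohort is trichotomized data-adaptively:
high cutoff = median + SD, low cutoff = median - SD/2 (floored at zero),
with boundary rules High iff TMB >= high cutoff and Low iff TMB < low
cutoff. A dichotomized view collapses Low and Moderate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .filtering import VariantRecord
from .panel import PanelDefinition

TMBClass = Literal["Low", "Moderate", "High"]
TMBBinary = Literal["Low/Moderate", "High"]


@dataclass(frozen=True)
class TMBResult:
    patient_id: str
    mutation_count: int
    territory_mb: float
    tmb: float  # mutations per Mb == mutation_count / territory_mb exactly
    tmb_class: TMBClass | None = None


@dataclass(frozen=True)
class TMBCutoffs:
    low_cutoff: float
    high_cutoff: float
    median: float
    sd: float
    method_tag: str = "median+SD / median-SD/2"

    def __post_init__(self) -> None:
        if self.low_cutoff > self.high_cutoff:
            raise ValueError("low cutoff exceeds high cutoff")


def compute_tmb(
    filtered_variants: Sequence[VariantRecord] | int,
    panel: PanelDefinition,
    patient_id: str = "",
) -> TMBResult:
    """Mutations per megabase for one patient's retained variant set.

    Accepts either the retained variant list or a pre-computed count (each
    retained alt allele counts once). Class is left unset; see
    :func:`classify_tmb`.
    """
    territory = panel.territory_mb
    if territory <= 0:
        raise ValueError("panel territory must be positive")
    count = filtered_variants if isinstance(filtered_variants, int) else len(filtered_variants)
    if count < 0:
        raise ValueError("mutation count cannot be negative")
    return TMBResult(
        patient_id=patient_id,
        mutation_count=count,
        territory_mb=territory,
        tmb=count / territory,
    )


def derive_cutoffs(tmb_values: Iterable[float], ddof: int = 1) -> TMBCutoffs:
    """Cohort cutoffs from pooled TMB values (both histologies together).

    SD is the sample standard deviation (``ddof=1``) by default; population
    SD is available for sensitivity analysis. The low cutoff is floored at
    zero since TMB is nonnegative.
    """
    values = np.asarray(list(tmb_values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 TMB values to derive cutoffs")
    median = float(np.median(values))
    sd = float(np.std(values, ddof=ddof))
    return TMBCutoffs(
        low_cutoff=max(0.0, median - sd / 2.0),
        high_cutoff=median + sd,
        median=median,
        sd=sd,
    )


def classify_tmb(tmb: float, cutoffs: TMBCutoffs) -> TMBClass:
    """High iff tmb >= high cutoff; Low iff tmb < low cutoff; else Moderate."""
    if tmb >= cutoffs.high_cutoff:
        return "High"
    if tmb < cutoffs.low_cutoff:
        return "Low"
    return "Moderate"


def dichotomize_tmb(tmb_class: TMBClass) -> TMBBinary:
    if tmb_class == "High":
        return "High"
    if tmb_class in ("Low", "Moderate"):
        return "Low/Moderate"
    raise ValueError(f"unknown TMB class {tmb_class!r}")
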