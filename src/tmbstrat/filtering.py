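"""Paired tumor/normal somatic filtering.

The filter chain reproduces a targeted-panel somatic calling scheme:
per-sample coverage minima (8x normal, 6x tumor), a one-sided exact test on
the 2x2 allele-count table (tumor vs normal x ref vs alt) at p <= 0.05,
a strand-bias rule (the majority-strand fraction of tumor alt reads must be
< 0.90), restriction to coding on-panel sites, and germline/benign
exclusions driven by annotation fields: population-database observation
count >= 2, a known-germline flag, a somatic-germline zygosity call, and a
deleteriousness score < 0.452 marking benign missense changes.

Every filter is evaluated for every variant (no short-circuit) so the audit
trail lists all failed rules, in the fixed order: coverage_normal,
coverage_tumor, not_somatic_p, strand_bias, noncoding, popdb_germline,
dbsnp_germline, zygosity_germline, benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field
from scipy.stats import fisher_exact

from .panel import PanelDefinition

Consequence = Literal[
    "synonymous", "missense", "nonsense", "frameshift_indel", "inframe_indel", "noncoding"
]
CODING_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "nonsense", "frameshift_indel", "inframe_indel"}
)
Zygosity = Literal["somatic", "germline", "ambiguous"]


@dataclass(frozen=True)
class VariantRecord:
    """One candidate mutation with paired count evidence and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int
    alt_fwd: int
    alt_rev: int
    consequence: Consequence
    popdb_count: int = 0
    known_germline: bool = False
    zygosity_call: Zygosity = "ambiguous"
    deleterious_score: Optional[float] = None  # defined for missense only
    strand_missing: bool = False  # strand counts absent in the source VCF

    def __post_init__(self) -> None:
        counts = (
            self.tumor_ref,
            self.tumor_alt,
            self.normal_ref,
            self.normal_alt,
            self.alt_fwd,
            self.alt_rev,
            self.popdb_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in variant {self.key}")
        if not self.strand_missing and self.alt_fwd + self.alt_rev != self.tumor_alt:
            raise ValueError(
                f"strand counts {self.alt_fwd}+{self.alt_rev} != tumor_alt "
                f"{self.tumor_alt} for {self.key}"
            )
        if self.deleterious_score is not None and not 0.0 <= self.deleterious_score <= 1.0:
            raise ValueError("deleterious_score outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt


class FilterConfig(BaseModel):
    """Thresholds of the somatic filter chain (defaults as published)."""

    min_normal_depth: int = Field(default=8, gt=0)
    min_tumor_depth: int = Field(default=6, gt=0)
    somatic_p_threshold: float = Field(default=0.05, gt=0, le=1)
    somatic_p_inclusive: bool = True  # call when p <= threshold
    somatic_test_alternative: Literal["greater", "two-sided"] = "greater"
    strand_bias_max: float = Field(default=0.90, gt=0, le=1)
    strand_unassessable_pass: bool = False  # zero alt strand evidence
    popdb_max_count: int = Field(default=1, ge=0)  # exclude counts >= 2
    benign_score_threshold: float = Field(default=0.452, ge=0, le=1)
    count_synonymous_for_tmb: bool = True


@dataclass(frozen=True)
class FilterVerdict:
    kept: bool
    reasons: tuple[str, ...]
    somatic_p: Optional[float] = None
    strand_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must hold exactly when no filter failed")


def somatic_p(
    tumor_ref: int,
    tumor_alt: int,
    normal_ref: int,
    normal_alt: int,
    alternative: str = "greater",
) -> float:
    """One-sided exact test that the tumor alt fraction exceeds the normal's.

    The 2x2 table is (tumor, normal) x (alt, ref); under ``greater`` the
    p-value is the hypergeometric upper tail at the observed tumor alt count.
    """
    if tumor_ref + tumor_alt == 0 or normal_ref + normal_alt == 0:
        raise ValueError("zero-depth sample: site is uncallable")
    table = [[tumor_alt, tumor_ref], [normal_alt, normal_ref]]
    return float(fisher_exact(table, alternative=alternative)[1])


def strand_bias_fraction(alt_fwd: int, alt_rev: int) -> float:
    """Fraction of tumor alt reads on the majority strand."""
    total = alt_fwd + alt_rev
    if total == 0:
        raise ValueError("no alt-supporting reads: strand bias unassessable")
    return max(alt_fwd, alt_rev) / total


def apply_filters(
    variant: VariantRecord,
    config: FilterConfig,
    panel: PanelDefinition,
) -> FilterVerdict:
    """Evaluate the full filter chain on one variant.

    All rules run regardless of earlier failures so ``reasons`` is complete.
    A zero-depth sample fails its coverage rule and additionally marks the
    somatic test as failed (the site is uncallable, hence never called).
    """
    reasons: list[str] = []

    if variant.normal_depth < config.min_normal_depth:
        reasons.append("coverage_normal")
    if variant.tumor_depth < config.min_tumor_depth:
        reasons.append("coverage_tumor")

    p: Optional[float] = None
    if variant.tumor_depth == 0 or variant.normal_depth == 0:
        reasons.append("not_somatic_p")
    else:
        p = somatic_p(
            variant.tumor_ref,
            variant.tumor_alt,
            variant.normal_ref,
            variant.normal_alt,
            alternative=config.somatic_test_alternative,
        )
        called = p <= config.somatic_p_threshold if config.somatic_p_inclusive else p < config.somatic_p_threshold
        if not called:
            reasons.append("not_somatic_p")

    frac: Optional[float] = None
    if variant.tumor_alt == 0 or variant.strand_missing:
        if not config.strand_unassessable_pass:
            reasons.append("strand_bias")
    else:
        frac = strand_bias_fraction(variant.alt_fwd, variant.alt_rev)
        if not frac < config.strand_bias_max:
            reasons.append("strand_bias")

    if variant.consequence not in CODING_CONSEQUENCES or not panel.contains(
        variant.chrom, variant.pos
    ):
        reasons.append("noncoding")
    elif variant.consequence == "synonymous" and not config.count_synonymous_for_tmb:
        reasons.append("synonymous")

    if variant.popdb_count > config.popdb_max_count:
        reasons.append("popdb_germline")
    if variant.known_germline:
        reasons.append("dbsnp_germline")
    if variant.zygosity_call == "germline":
        reasons.append("zygosity_germline")
    # benign rule applies only where the score is defined (missense)
    if (
        variant.consequence == "missense"
        and variant.deleterious_score is not None
        and variant.deleterious_score < config.benign_score_threshold
    ):
        reasons.append("benign")

    return FilterVerdict(
        kept=not reasons, reasons=tuple(reasons), somatic_p=p, strand_fraction=frac
    )


def filter_cohort(
    variants_by_patient: Mapping[str, Sequence[VariantRecord]],
    config: FilterConfig,
    panel: PanelDefinition,
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Filter every patient's candidate set; return retained lists + audit log.

    The audit log has one row per (patient, variant) with the verdict,
    failed-rule tags, somatic p and strand fraction. Counts are conserved:
    log rows = input variants; kept + dropped = input.
    """
    retained: dict[str, list[VariantRecord]] = {}
    rows = []
    for patient, variants in variants_by_patient.items():
        seen = set()
        kept_list = []
        for v in variants:
            if v.key in seen:
                raise ValueError(f"duplicate variant {v.key} for patient {patient}")
            seen.add(v.key)
            verdict = apply_filters(v, config, panel)
            if verdict.kept:
                kept_list.append(v)
            rows.append(
                {
                    "patient": patient,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "kept": verdict.kept,
                    "reasons": ";".join(verdict.reasons),
                    "somatic_p": verdict.somatic_p,
                    "strand_fraction": verdict.strand_fraction,
                }
            )
        retained[patient] = kept_list
    log = pd.DataFrame(
        rows,
        columns=[
            "patient", "chrom", "pos", "ref", "alt",
            "kept", "reasons", "somatic_p", "strand_fraction",
        ],
    )
    return retained, log
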