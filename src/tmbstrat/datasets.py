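"""Reference NSCLC cohort summary counts (ADC n=136, SQCC n=51).

Patient-level data for the reference cohort are not available; what is
available are its published summary tables. These counts serve as inputs
for consistency checks: per-allele driver-mutation counts, and the
PD-L1 TC/IC staining-intensity counts per histology. Four-category counts
are the unique integer vectors consistent with the published rounded
percent frequencies and the published group sizes.
"""

from __future__ import annotations

ADC_N = 136
SQCC_N = 51

# per-allele driver mutation subject counts (ADC + SQCC combined totals are
# reported per gene; per-allele counts are for the EGFR/KRAS-mutant subjects)
EGFR_ALLELE_COUNTS = {"L858R": 33, "exon19del": 25}
KRAS_ALLELE_COUNTS = {
    "A146V": 2, "A146X": 1, "G12A": 1, "G12C": 3,
    "G12D": 2, "G12V": 6, "G13D": 1, "Q61L": 1,
}

# four-category staining counts (negative, weak, moderate, strong)
PDL1_COUNTS = {
    "ADC": {"TC": (86, 14, 9, 27), "IC": (88, 14, 7, 27)},
    "SQCC": {"TC": (23, 7, 7, 14), "IC": (22, 15, 2, 12)},
}

# representative staining percentages per category, used to reconstruct
# per-patient readouts from category counts (any value inside the category's
# bin yields the same category)
TC_REPRESENTATIVE_PCT = (0.0, 2.0, 20.0, 60.0)
IC_REPRESENTATIVE_PCT = (0.0, 2.0, 7.0, 30.0)

# TC positivity cross-tabulated by sex within the ADC group
# rows: male, female; columns: TC negative, TC any+
ADC_SEX_BY_TC = ((45, 41), (41, 9))


def reconstruct_readout_pcts(histology: str, compartment: str) -> list[float]:
    """Expand category counts into per-patient representative percentages."""
    counts = PDL1_COUNTS[histology][compartment]
    reps = TC_REPRESENTATIVE_PCT if compartment == "TC" else IC_REPRESENTATIVE_PCT
    out: list[float] = []
    for count, pct in zip(counts, reps):
        out.extend([pct] * count)
    return out
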