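"""Synthetic NSCLC cohort generator with known ground truth.

Emulates the three inputs of the pipeline — a capture panel, per-patient
paired tumor/normal variant evidence with annotation fields, and a clinical
table with IHC readouts and overall survival — so that every downstream
stage is testable without real data.

The generative model: per-patient TMB is log-normal (median 8 mutations/Mb
by default, matching a targeted-panel NSCLC cohort); candidate variants are
a somatic/germline mixture where somatic variants carry tumor-only alt
evidence and germline variants carry matched allele fractions plus
population-database counts >= 2 (with a configurable leakage fraction);
sequencing depths are negative-binomial; a configurable fraction of
variants gets artifactually skewed strand counts; PD-L1 TC/IC percentages
are drawn from per-histology category mixtures with uniform within-bin
percentages; and survival is exponential with a hazard per combined
TMB x PD-L1 class, administratively censored at a configurable rate.
Covariate marginals (age, sex, smoking, stage, driver mutations) follow the
published ADC/SQCC cohort characteristics; they are cosmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .filtering import VariantRecord
from .panel import PanelDefinition, generate_panel
from .pdl1 import IHCReadout, score_patient
from .stratify import COMBINED_CLASSES, StratumAssignment, assign
from .tmb import classify_tmb, derive_cutoffs, dichotomize_tmb

LN2 = math.log(2.0)

# half-open percentage bins of the TC and IC ladders (upper bin closed at 100)
_TC_BINS = ((0.0, 1.0), (1.0, 5.0), (5.0, 50.0), (50.0, 100.0))
_IC_BINS = ((0.0, 1.0), (1.0, 5.0), (5.0, 10.0), (10.0, 100.0))

_BASES = np.array(list("ACGT"))


class DepthModel(BaseModel):
    """Negative-binomial read-depth model (mean + overdispersion shape)."""

    tumor_mean: float = Field(default=300.0, gt=0)
    normal_mean: float = Field(default=150.0, gt=0)
    dispersion: float = Field(default=10.0, gt=0)  # NB shape k; var = m + m^2/k

    def draw(self, rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        k = self.dispersion
        return rng.negative_binomial(k, k / (k + mean), size=size)


def _weights4(v: Sequence[float]) -> list[float]:
    if len(v) != 4:
        raise ValueError("need 4 category weights")
    if any(w < 0 for w in v):
        raise ValueError("weights must be nonnegative")
    s = sum(v)
    if not math.isclose(s, 1.0, abs_tol=1e-6):
        raise ValueError(f"weights must sum to 1, got {s}")
    return [float(w) for w in v]


class PDL1Model(BaseModel):
    """Mixture weights over the four TC/IC categories, per histology.

    Defaults reproduce the published ADC/SQCC four-category frequencies.
    Within a category the percentage is uniform over the category's bin.
    """

    adc_tc: list[float] = [0.63, 0.10, 0.07, 0.20]
    adc_ic: list[float] = [0.65, 0.10, 0.05, 0.20]
    sqcc_tc: list[float] = [0.45, 0.14, 0.14, 0.27]
    sqcc_ic: list[float] = [0.43, 0.29, 0.04, 0.24]

    @field_validator("adc_tc", "adc_ic", "sqcc_tc", "sqcc_ic")
    @classmethod
    def _check(cls, v: Sequence[float]) -> list[float]:
        w = list(v)
        s = sum(w)
        if s <= 0:
            raise ValueError("weights must have positive sum")
        return _weights4([x / s for x in w])

    def draw_pct(
        self, rng: np.random.Generator, histology: str, compartment: str
    ) -> float:
        weights = getattr(self, f"{histology.lower()}_{compartment.lower()}")
        bins = _TC_BINS if compartment == "TC" else _IC_BINS
        cat = int(rng.choice(4, p=weights))
        lo, hi = bins[cat]
        return float(lo + (hi - lo) * rng.random())


class HazardModel(BaseModel):
    """Exponential hazard per combined class, events/month.

    Defaults plant median OS of 32 months for responders (LM_neg) and
    6-8.5 months for the other classes, the separation the pipeline is
    meant to recover.
    """

    rates: dict[str, float] = {
        "LM_neg": LN2 / 32.0,
        "LM_pos": LN2 / 8.5,
        "H_pos": LN2 / 6.0,
        "H_neg": LN2 / 8.5,
    }

    @field_validator("rates")
    @classmethod
    def _check(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COMBINED_CLASSES)
        if unknown:
            raise ValueError(f"unknown combined classes {sorted(unknown)}")
        if any(r <= 0 for r in v.values()):
            raise ValueError("hazard rates must be strictly positive")
        return v

    def true_median_os(self) -> dict[str, float]:
        return {k: LN2 / r for k, r in self.rates.items()}


class CohortConfig(BaseModel):
    """Full configuration of the synthetic cohort."""

    n_patients: int = Field(default=187, ge=1)
    adc_fraction: float = Field(default=136 / 187, ge=0, le=1)
    tmb_log_median: float = 8.0  # mutations/Mb; lognormal median
    tmb_log_sigma: float = Field(default=0.8, gt=0)
    somatic_fraction: float = Field(default=0.5, ge=0, le=1)
    depth_model: DepthModel = DepthModel()
    strand_bias_rate: float = Field(default=0.02, ge=0, le=1)
    pdl1_model: PDL1Model = PDL1Model()
    hazard_model: HazardModel = HazardModel()
    censor_rate: float = Field(default=0.15, ge=0, le=1)
    panel_intervals: int = Field(default=150, ge=1)
    territory_mb: float = Field(default=1.4, gt=0)
    # annotation-field behaviour of the mixture
    germline_popdb_leak_rate: float = Field(default=0.1, ge=0, le=1)
    germline_dbsnp_rate: float = Field(default=0.8, ge=0, le=1)
    germline_zygosity_rate: float = Field(default=0.9, ge=0, le=1)
    somatic_benign_score_rate: float = Field(default=0.05, ge=0, le=1)
    consequence_weights: dict[str, float] = {
        "synonymous": 0.25,
        "missense": 0.55,
        "nonsense": 0.05,
        "frameshift_indel": 0.05,
        "inframe_indel": 0.03,
        "noncoding": 0.07,
    }
    seed: int = Field(default=0, ge=0, lt=2**31)

    @field_validator("consequence_weights")
    @classmethod
    def _check_weights(cls, v: dict[str, float]) -> dict[str, float]:
        s = sum(v.values())
        if not math.isclose(s, 1.0, abs_tol=1e-6):
            raise ValueError(f"consequence weights must sum to 1, got {s}")
        if any(w < 0 for w in v.values()):
            raise ValueError("negative consequence weight")
        return v


@dataclass
class SyntheticCohort:
    """Generated inputs plus the ground truth that produced them."""

    config: CohortConfig
    panel: PanelDefinition
    variants: dict[str, list[VariantRecord]]
    variant_labels: pd.DataFrame  # patient, chrom, pos, ref, alt, is_somatic
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame  # patient, true_tmb, true classes
    true_median_os: dict[str, float]


def _draw_positions(
    panel: PanelDefinition, rng: np.random.Generator, n: int
) -> list[tuple[str, int]]:
    """Distinct 1-based positions uniform over the panel territory."""
    iv = panel.intervals
    lengths = (iv["end"] - iv["start"]).to_numpy()
    probs = lengths / lengths.sum()
    out: list[tuple[str, int]] = []
    used: set[tuple[str, int]] = set()
    while len(out) < n:
        idx = int(rng.choice(len(iv), p=probs))
        row = iv.iloc[idx]
        pos = int(row["start"]) + int(rng.integers(0, int(row["end"] - row["start"]))) + 1
        key = (str(row["chrom"]), pos)
        if key not in used:
            used.add(key)
            out.append(key)
    return out


def generate_variants(
    panel: PanelDefinition,
    config: CohortConfig,
    patient_id: str,
    target_tmb: float,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], list[bool], float]:
    """Simulate one patient's candidate variants with truth labels.

    ``target_tmb`` sets the expected somatic coding density; the realized
    true TMB (returned third) is the count of truly somatic coding variants
    divided by territory, exactly.
    """
    if len(panel.intervals) == 0:
        raise ValueError("empty panel")
    territory = panel.territory_mb
    cons_names = list(config.consequence_weights)
    cons_probs = np.array([config.consequence_weights[c] for c in cons_names])
    coding_frac = 1.0 - config.consequence_weights.get("noncoding", 0.0)
    sf = config.somatic_fraction
    mean_somatic = target_tmb * territory / coding_frac
    mu = mean_somatic / sf if sf > 0 else mean_somatic
    n_cand = int(rng.poisson(mu))
    if n_cand == 0:
        return [], [], 0.0

    positions = _draw_positions(panel, rng, n_cand)
    dm = config.depth_model
    tumor_depths = dm.draw(rng, dm.tumor_mean, n_cand)
    normal_depths = dm.draw(rng, dm.normal_mean, n_cand)

    records: list[VariantRecord] = []
    labels: list[bool] = []
    n_somatic_coding = 0
    for i in range(n_cand):
        somatic = bool(rng.random() < sf) if sf < 1 else True
        if sf == 0:
            somatic = False
        chrom, pos = positions[i]
        consequence = cons_names[int(rng.choice(len(cons_names), p=cons_probs))]
        if consequence in ("frameshift_indel", "inframe_indel"):
            ref = "".join(rng.choice(_BASES, size=int(rng.integers(2, 5))))
            alt = ref[0]
        else:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            ref, alt = str(ref), str(alt)

        dp_t = int(tumor_depths[i])
        dp_n = int(normal_depths[i])
        if somatic:
            vaf_t = 0.1 + 0.5 * rng.random()
            vaf_n = 0.001
        else:
            hom = rng.random() < 0.2
            vaf_t = vaf_n = 1.0 if hom else 0.5
        t_alt = int(rng.binomial(dp_t, vaf_t)) if dp_t > 0 else 0
        n_alt = int(rng.binomial(dp_n, vaf_n)) if dp_n > 0 else 0

        p_strand = 0.98 if rng.random() < config.strand_bias_rate else 0.5
        fwd = int(rng.binomial(t_alt, p_strand)) if t_alt > 0 else 0

        if somatic:
            popdb = 0 if rng.random() < 0.98 else 1
            dbsnp = bool(rng.random() < 0.005)
            zyg = "somatic" if rng.random() < 0.9 else "ambiguous"
        else:
            if rng.random() < config.germline_popdb_leak_rate:
                popdb = int(rng.integers(0, 2))
            else:
                popdb = 2 + int(rng.poisson(30))
            dbsnp = bool(rng.random() < config.germline_dbsnp_rate)
            zyg = "germline" if rng.random() < config.germline_zygosity_rate else "ambiguous"

        score: Optional[float] = None
        if consequence == "missense":
            if somatic:
                benign = rng.random() < config.somatic_benign_score_rate
            else:
                benign = rng.random() < 0.8
            lo, hi = (0.0, 0.452) if benign else (0.452, 1.0)
            score = float(lo + (hi - lo) * rng.random())

        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                tumor_ref=dp_t - t_alt,
                tumor_alt=t_alt,
                normal_ref=dp_n - n_alt,
                normal_alt=n_alt,
                alt_fwd=fwd,
                alt_rev=t_alt - fwd,
                consequence=consequence,
                popdb_count=popdb,
                known_germline=dbsnp,
                zygosity_call=zyg,
                deleterious_score=score,
            )
        )
        labels.append(somatic)
        if somatic and consequence != "noncoding":
            n_somatic_coding += 1
    return records, labels, n_somatic_coding / territory


def generate_clinical(
    config: CohortConfig,
    strata: Sequence[StratumAssignment],
    histology: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical covariates and exponential survival per combined class.

    One stratum per patient; survival time is exponential with the
    stratum's hazard rate, and a ``censor_rate`` fraction is
    administratively censored uniformly before the death time.
    """
    if len(strata) != len(histology):
        raise ValueError("need one histology per stratum")
    rates = config.hazard_model.rates
    rows = []
    for s, h in zip(strata, histology):
        if s.combined_class not in rates:
            raise ValueError(f"unknown stratum {s.combined_class!r}")
        rate = rates[s.combined_class]
        t = float(rng.exponential(1.0 / rate))
        if rng.random() < config.censor_rate:
            t, event = t * float(rng.random()), 0
        else:
            event = 1
        adc = h == "ADC"
        age = int(np.clip(round(rng.normal(58 if adc else 60, 10)), 29, 85))
        sex = "male" if rng.random() < (0.63 if adc else 0.78) else "female"
        smoking = "smoker" if rng.random() < (0.20 if adc else 0.29) else "never"
        stage = "IIIB" if rng.random() < (0.40 if adc else 0.41) else "IV"
        u = rng.random()
        if adc:
            mutation = "EGFR" if u < 0.43 else ("KRAS" if u < 0.55 else "Other")
        else:
            mutation = "EGFR" if u < 0.04 else ("KRAS" if u < 0.08 else "Other")
        rows.append(
            {
                "patient_id": s.patient_id,
                "histology": h,
                "age": age,
                "sex": sex,
                "smoking": smoking,
                "stage": stage,
                "mutation_status": mutation,
                "os_months": t,
                "os_event": event,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    panel = generate_panel(
        config.panel_intervals, config.territory_mb, seed=int(rng.integers(2**31))
    )
    n = config.n_patients
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    histology = ["ADC" if rng.random() < config.adc_fraction else "SQCC" for _ in range(n)]
    target_tmb = np.exp(
        rng.normal(math.log(config.tmb_log_median), config.tmb_log_sigma, size=n)
    )

    variants: dict[str, list[VariantRecord]] = {}
    label_rows = []
    true_tmb = np.empty(n)
    for i, pid in enumerate(patient_ids):
        recs, labels, tt = generate_variants(panel, config, pid, float(target_tmb[i]), rng)
        variants[pid] = recs
        true_tmb[i] = tt
        for v, lab in zip(recs, labels):
            label_rows.append(
                {"patient": pid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                 "alt": v.alt, "is_somatic": lab}
            )

    # IHC readouts
    tc_pct = [config.pdl1_model.draw_pct(rng, h, "TC") for h in histology]
    ic_pct = [config.pdl1_model.draw_pct(rng, h, "IC") for h in histology]
    scores = [
        score_patient(IHCReadout(pid, tc, ic))
        for pid, tc, ic in zip(patient_ids, tc_pct, ic_pct)
    ]

    # true combined class from the true TMB values against median+SD cutoffs
    # derived on the truth itself
    if n >= 2:
        true_cut = derive_cutoffs(true_tmb)
        true_class = [classify_tmb(v, true_cut) for v in true_tmb]
    else:
        true_class = ["Moderate"] * n
    strata = [
        assign(pid, dichotomize_tmb(c), s.tc_positive)
        for pid, c, s in zip(patient_ids, true_class, scores)
    ]

    clinical = generate_clinical(config, strata, histology, rng)
    clinical["tc_pct"] = tc_pct
    clinical["ic_pct"] = ic_pct

    ground_truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_tmb": true_tmb,
            "true_tmb_class": true_class,
            "true_pdl1_tc_positive": [s.tc_positive for s in scores],
            "true_combined_class": [s.combined_class for s in strata],
        }
    )
    return SyntheticCohort(
        config=config,
        panel=panel,
        variants=variants,
        variant_labels=pd.DataFrame(
            label_rows,
            columns=["patient", "chrom", "pos", "ref", "alt", "is_somatic"],
        ),
        clinical=clinical,
        ground_truth=ground_truth,
        true_median_os=config.hazard_model.true_median_os(),
    )
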