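"""Readers and writers for the pipeline's file formats.

Formats: panel BED (0-based half-open), per-patient VCF v4.2 with paired
tumor/normal counts in FORMAT fields and annotations in INFO, clinical CSV,
TSV audit/result tables, and JSON summaries. Every tabular output embeds
the run seed and a config hash in a leading comment line so that identical
config + seed reproduces outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .filtering import FilterConfig, VariantRecord
from .panel import PanelDefinition, merge_intervals

logger = logging.getLogger("tmbstrat")

CLINICAL_COLUMNS = (
    "patient_id", "histology", "age", "sex", "smoking", "stage",
    "mutation_status", "tc_pct", "ic_pct", "os_months", "os_event",
)
_CATEGORY_VOCAB = {
    "histology": {"ADC", "SQCC"},
    "sex": {"male", "female"},
    "smoking": {"smoker", "never"},
    "stage": {"IIIB", "IV"},
    "mutation_status": {"EGFR", "KRAS", "Other"},
}


def config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(seed: Optional[int], cfg_hash: Optional[str]) -> str:
    return f"# tmbstrat seed={seed} config={cfg_hash}\n"


# --------------------------------------------------------------------- panel

def read_panel(path: str | Path) -> PanelDefinition:
    """Read a BED file (3+ columns); sort and merge overlapping intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: interval end <= start")
            rows.append((chrom, start, end))
    if not rows:
        raise ValueError(f"{path}: empty panel")
    raw = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    merged = merge_intervals(raw)
    if len(merged) < len(raw):
        warnings.warn(f"{path}: merged {len(raw) - len(merged)} overlapping interval(s)")
    return PanelDefinition(merged)


def write_panel(panel: PanelDefinition, path: str | Path,
                seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(seed, cfg_hash))
        for r in panel.intervals.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ----------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=POPDB,Number=1,Type=Integer,Description="Population-database observation count">
##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Known germline variant">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Somatic-germline zygosity call">
##INFO=<ID=PP2,Number=1,Type=Float,Description="Deleteriousness score in [0,1]">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference-supporting reads">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alt-supporting reads">
##FORMAT=<ID=SAF,Number=A,Type=Integer,Description="Alt-supporting reads, forward strand">
##FORMAT=<ID=SAR,Number=A,Type=Integer,Description="Alt-supporting reads, reverse strand">
"""


def write_variants(
    variants: Sequence[VariantRecord],
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    """Write one patient's candidate variants as VCF v4.2 (TUMOR, NORMAL)."""
    contigs = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"##tmbstrat_seed={seed}\n##tmbstrat_config={cfg_hash}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = [f"CSQ={v.consequence}", f"POPDB={v.popdb_count}", f"ZYG={v.zygosity_call}"]
            if v.known_germline:
                info.append("DBSNP")
            if v.deleterious_score is not None:
                info.append(f"PP2={v.deleterious_score:.6g}")
            tumor = f"{v.tumor_depth}:{v.tumor_ref}:{v.tumor_alt}:{v.alt_fwd}:{v.alt_rev}"
            normal = f"{v.normal_depth}:{v.normal_ref}:{v.normal_alt}:.:."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{';'.join(info)}\tDP:RO:AO:SAF:SAR\t{tumor}\t{normal}\n"
            )


def read_variants(
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[VariantRecord]:
    """Read candidate variants from VCF v4.2; multiallelic sites are split.

    Missing optional annotations default to permissive values (POPDB 0, no
    DBSNP flag, zygosity ambiguous, no deleteriousness score) with a
    warning; missing strand counts mark the variant strand-unassessable.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (tumor_sample, normal_sample):
        if s not in samples:
            raise ValueError(f"{path}: sample column {s!r} not found (have {samples})")
    ti = samples.index(tumor_sample)
    ni = samples.index(normal_sample)

    warned: set[str] = set()

    def warn_once(key: str, msg: str) -> None:
        if key not in warned:
            warned.add(key)
            warnings.warn(f"{path}: {msg}")

    def fmt(variant, key):
        try:
            arr = variant.format(key)
        except KeyError:
            return None
        return arr

    records: list[VariantRecord] = []
    for var in vcf:
        rd = fmt(var, "RO")
        ad = fmt(var, "AO")
        adf = fmt(var, "SAF")
        adr = fmt(var, "SAR")
        if rd is None or ad is None:
            raise ValueError(f"{path}: FORMAT fields RO and AO are required")
        csq = var.INFO.get("CSQ")
        if csq is None:
            warn_once("CSQ", "missing CSQ; defaulting to missense")
            csq = "missense"
        popdb = var.INFO.get("POPDB")
        if popdb is None:
            warn_once("POPDB", "missing POPDB; defaulting to 0")
            popdb = 0
        zyg = var.INFO.get("ZYG")
        if zyg is None:
            warn_once("ZYG", "missing ZYG; defaulting to ambiguous")
            zyg = "ambiguous"
        pp2 = var.INFO.get("PP2")
        dbsnp = bool(var.INFO.get("DBSNP"))
        for alt_idx, alt in enumerate(var.ALT):
            t_alt = int(ad[ti][alt_idx])
            strand_missing = adf is None or adr is None or adf[ti][alt_idx] < 0 or adr[ti][alt_idx] < 0
            if strand_missing:
                warn_once("SAF", "missing strand counts; strand bias unassessable")
                fwd, rev = 0, 0
            else:
                fwd, rev = int(adf[ti][alt_idx]), int(adr[ti][alt_idx])
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    tumor_ref=int(rd[ti][0]),
                    tumor_alt=t_alt,
                    normal_ref=int(rd[ni][0]),
                    normal_alt=int(ad[ni][alt_idx]),
                    alt_fwd=fwd,
                    alt_rev=rev,
                    consequence=csq,
                    popdb_count=int(popdb),
                    known_germline=dbsnp,
                    zygosity_call=zyg,
                    deleterious_score=float(pp2) if pp2 is not None else None,
                    strand_missing=bool(strand_missing),
                )
            )
    return records


# ------------------------------------------------------------------ clinical

def write_clinical(df: pd.DataFrame, path: str | Path,
                   seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(seed, cfg_hash))
        df.to_csv(fh, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical table (schema in CLINICAL_COLUMNS)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    for col, vocab in _CATEGORY_VOCAB.items():
        bad = set(df[col].unique()) - vocab
        if bad:
            raise ValueError(f"{path}: unknown {col} value(s) {sorted(bad)}")
    if (df["os_months"] < 0).any():
        raise ValueError(f"{path}: negative os_months")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError(f"{path}: os_event must be 0 or 1")
    if (df["age"] < 0).any():
        raise ValueError(f"{path}: negative age")
    for col in ("tc_pct", "ic_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValueError(f"{path}: {col} outside [0,100]")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


# -------------------------------------------------------------- table/bundle

def write_table(df: pd.DataFrame, path: str | Path,
                seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> None:
    """TSV with the reproducibility stamp."""
    with open(path, "w") as fh:
        fh.write(_stamp(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return "not_reached"
    return obj


def write_json(obj: dict, path: str | Path,
               seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> None:
    payload = dict(_jsonable(obj))
    payload.setdefault("_meta", {})
    payload["_meta"].update({"seed": seed, "config": cfg_hash})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_cohort(cohort, out_dir: str | Path) -> dict:
    """Write a synthetic cohort to disk; returns the manifest."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed
    h = config_hash(cohort.config)
    write_panel(cohort.panel, out / "panel.bed", seed, h)
    for pid, recs in cohort.variants.items():
        write_variants(recs, out / "vcf" / f"{pid}.vcf", seed, h)
    write_clinical(cohort.clinical, out / "clinical.csv", seed, h)
    write_table(cohort.ground_truth, out / "ground_truth.tsv", seed, h)
    write_table(cohort.variant_labels, out / "variant_labels.tsv", seed, h)
    manifest = {
        "seed": seed,
        "config_hash": h,
        "config": cohort.config.model_dump(mode="json"),
        "panel": "panel.bed",
        "clinical": "clinical.csv",
        "ground_truth": "ground_truth.tsv",
        "variant_labels": "variant_labels.tsv",
        "vcf": {pid: f"vcf/{pid}.vcf" for pid in sorted(cohort.variants)},
        "true_median_os": cohort.true_median_os,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


class RunConfig(BaseModel):
    """End-to-end run configuration for the CLI."""

    panel_bed: Optional[str] = None
    vcf_dir: Optional[str] = None
    clinical_csv: Optional[str] = None
    out_dir: str = "tmbstrat_out"
    seed: int = 0
    log_level: str = "INFO"
    filter: FilterConfig = FilterConfig()
    dunn_adjustment: str = "none"
    include_h_neg_in_survival: bool = False
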