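"""Readers and writers for the pipeline's file formats.

Formats: a sites VCF (GT only) carrying rs429358/rs7412/rs439401 calls,
TSV manifest/dosage/duplicate-pair/truth tables, TSV reports, and a JSON run
summary. VCF records are matched by ID, not position, so genome-build
coordinates are irrelevant; REF/ALT orientation is validated strictly
against the pinned allele definitions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .errors import (
    AlleleMismatchError,
    DuplicateSampleIdError,
    HeaderMismatchError,
    MissingVariantError,
)
from .genotypes import APOE_LABELS, VARIANTS
from .simulate import Dataset

log = logging.getLogger("apoeqc")

#: cosmetic GRCh38 coordinates for the emitted VCF; matching is by ID.
_POSITIONS = {"rs429358": 44908684, "rs7412": 44908822, "rs439401": 44906745}

MANIFEST_COLUMNS = (
    ["sample_id", "subject_id", "cohort", "dx", "age", "sex"]
    + [f"PC{k+1}" for k in range(5)]
    + ["provided_apoe", "source_flags"]
)
DOSAGE_COLUMNS = ["sample_id", "variant", "dosage", "r2"]
DUP_COLUMNS = ["sample_id_a", "sample_id_b"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (YAML-serialisable)."""

    vcf: str
    manifest: str
    dosages: str
    duplicates: str
    out_prefix: str = "apoeqc"
    r2_min: float = 0.8
    min_age: float = 60.0
    approach: int = 2
    seed: int = 0
    discordant_policy: str = "exclude"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    """Read per-sample ALT counts for the three pinned variants.

    Returns a frame with sample_id plus one column per variant (-1 missing).
    Swapped REF/ALT raises AlleleMismatchError; an absent variant raises
    MissingVariantError.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    calls: Dict[str, np.ndarray] = {}
    for rec in vcf:
        rid = rec.ID
        if rid not in VARIANTS:
            continue
        ref, alt = VARIANTS[rid]
        if rec.REF != ref or list(rec.ALT) != [alt]:
            raise AlleleMismatchError(
                f"{rid}: expected {ref}>{alt}, VCF has {rec.REF}>{','.join(rec.ALT)}"
            )
        # gts012: 0/1/2 = ALT count, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=np.int64)
        calls[rid] = np.where(gt == 3, -1, gt)
    missing = set(VARIANTS) - set(calls)
    if missing:
        raise MissingVariantError(f"variants absent from VCF: {sorted(missing)}")
    out = pd.DataFrame({"sample_id": samples})
    for rid in VARIANTS:
        out[rid] = calls[rid]
    return out


def write_sites_vcf(vcf_calls: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal VCF 4.2 sites file with GT calls (-1 -> ./.)."""
    sample_ids = vcf_calls["sample_id"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        "##source=apoeqc",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=19>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for rid, (ref, alt) in VARIANTS.items():
        counts = vcf_calls[rid].astype(int).tolist()
        gts = "\t".join(gt_str[c] for c in counts)
        lines.append(f"19\t{_POSITIONS[rid]}\t{rid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _check_header(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise HeaderMismatchError(f"{what}: missing columns {missing}")


def parse_apoe_token(token: str) -> str:
    """Parse 'e2/e3'-style tokens, order-insensitively; '' for unparseable."""
    if not isinstance(token, str) or not token.strip():
        return ""
    parts = sorted(p.strip().lower() for p in token.strip().split("/"))
    label = "/".join(parts)
    if label not in APOE_LABELS:
        log.warning("unparseable provided APOE token %r treated as missing", token)
        return ""
    return label


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    _check_header(df, MANIFEST_COLUMNS, "manifest")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateSampleIdError(f"duplicate sample ids in manifest: {dups[:5]}")
    df["provided_apoe"] = df["provided_apoe"].fillna("").map(parse_apoe_token)
    return df


def read_dosages(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _check_header(df, DOSAGE_COLUMNS, "dosages")
    bad = ~df["dosage"].between(0.0, 2.0) | ~df["r2"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} dosage rows outside dosage [0,2] / r2 [0,1]"
        )
    return df


def read_duplicates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_header(df, DUP_COLUMNS, "duplicates")
    return df


def write_dataset(ds: Dataset, prefix: str | Path) -> Dict[str, Path]:
    """Write a generated dataset to ``<prefix>.{vcf,manifest,dosages,dups,truth}``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".sites.vcf"),
        "manifest": prefix.with_suffix(".manifest.tsv"),
        "dosages": prefix.with_suffix(".dosages.tsv"),
        "duplicates": prefix.with_suffix(".dups.tsv"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    write_sites_vcf(ds.vcf_calls, paths["vcf"])
    ds.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    ds.dosages.to_csv(paths["dosages"], sep="\t", index=False)
    ds.dup_pairs.to_csv(paths["duplicates"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_dataset_files(
    vcf: str | Path, manifest: str | Path, dosages: str | Path, duplicates: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the four pipeline inputs; manifest order defines sample order."""
    man = read_manifest(manifest)
    calls = read_sites_vcf(vcf)
    dos = read_dosages(dosages)
    dup = read_duplicates(duplicates)
    return man, calls, dos, dup


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def fmt_pct(x: float) -> str:
    """Percentage to two decimals: 0.059071 -> '5.91 %'."""
    return "NA" if not np.isfinite(x) else f"{100.0 * x:.2f} %"


def fmt_or_ci(or_: float, lo: float, hi: float) -> str:
    if not np.isfinite(or_):
        return "NA"
    return f"{or_:.2f} ({lo:.2f}, {hi:.2f})"


def fmt_p(p: float) -> str:
    """P in scientific notation: 1.64e-07 -> '1.64E-07'."""
    return "NA" if not np.isfinite(p) else f"{p:.2E}"


def format_association_report(results: pd.DataFrame) -> pd.DataFrame:
    """Human-readable table in the carrier/MAF/OR/CI/P column convention."""
    out = pd.DataFrame()
    if "approach" in results.columns:
        out["approach"] = results["approach"]
    out["stratum"] = results["stratum"]
    out["model"] = results["model"]
    out["CN_carriers"] = [
        f"{c} / {n} ({fmt_pct(c / n if n else float('nan'))})"
        for c, n in zip(results["carriers_CN"], results["n_CN"])
    ]
    out["AD_carriers"] = [
        f"{c} / {n} ({fmt_pct(c / n if n else float('nan'))})"
        for c, n in zip(results["carriers_AD"], results["n_AD"])
    ]
    out["CN_AD_MAF"] = [
        f"{fmt_pct(m1)} - {fmt_pct(m2)}"
        for m1, m2 in zip(results["maf_CN"], results["maf_AD"])
    ]
    out["OR_95CI"] = [
        fmt_or_ci(o, lo, hi)
        for o, lo, hi in zip(results["OR"], results["CI95_low"], results["CI95_high"])
    ]
    out["P"] = [fmt_p(p) for p in results["P"]]
    return out


def write_reports(
    results: pd.DataFrame,
    ledger: pd.DataFrame,
    prefix: str | Path,
    config: Optional[RunConfig] = None,
) -> Dict[str, Path]:
    """Write the association TSV, exclusion-ledger TSV, and JSON summary.

    Output is deterministic: fixed column order, fixed rounding, sorted rows.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": prefix.with_suffix(".associations.tsv"),
        "ledger": prefix.with_suffix(".exclusions.tsv"),
        "summary": prefix.with_suffix(".summary.json"),
    }
    format_association_report(results).to_csv(paths["associations"], sep="\t", index=False)
    ledger.to_csv(paths["ledger"], sep="\t", index=False)
    summary = {
        "config": asdict(config) if config else None,
        "exclusions": {r.reason: int(r.n) for r in ledger.itertuples()},
        "n_strata": int(len(results)),
        "significant_strata": sorted(
            results.loc[results["P"] < 0.05, "stratum"].tolist()
        ),
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
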