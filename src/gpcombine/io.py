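"""Readers and writers for bull tables, genotype matrices and reports.

Bull tables are UTF-8 CSV with a header: fixed columns
``bull_id, population, birth_year, sire_id`` followed by one
``drp_<trait>, edc_<trait>, rel_<trait>`` triplet per trait. Genotypes
travel as a TSV matrix (bull_id + one 0/1/2 column per marker) or as a
biallelic-SNP VCF. Reports are CSV rounded the way evaluation summaries
are printed (2 decimals, half-even by default, configurable).
"""

from __future__ import annotations

import decimal
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import BullRecord, GenotypeMatrix, TraitObservation, ValidationReport

logger = logging.getLogger("gpcombine")

_FIXED_COLS = ["bull_id", "population", "birth_year", "sire_id"]


def read_bull_table(path) -> list[BullRecord]:
    """Parse a bull CSV into records, enforcing all invariants.

    Unknown sire ids are retained (the flag is resolved downstream against
    the reference set); malformed rows raise with the offending line.
    """
    df = pd.read_csv(path, dtype={"bull_id": str, "sire_id": str})
    for col in _FIXED_COLS:
        if col not in df.columns:
            raise ValueError(f"bull table {path} lacks required column {col!r}")
    traits = sorted(
        c[len("drp_"):] for c in df.columns if c.startswith("drp_")
    )
    for t in traits:
        for prefix in ("edc_", "rel_"):
            if prefix + t not in df.columns:
                raise ValueError(f"trait {t!r} lacks column {prefix + t!r}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            sire = row["sire_id"]
            sire = None if pd.isna(sire) or sire == "" else str(sire)
            obs = {}
            for t in traits:
                drp = row[f"drp_{t}"]
                if pd.isna(drp):
                    continue
                obs[t] = TraitObservation(
                    drp=float(drp),
                    edc=float(row[f"edc_{t}"]),
                    rel_drp=float(row[f"rel_{t}"]),
                )
            records.append(
                BullRecord(
                    bull_id=str(row["bull_id"]),
                    population=str(row["population"]),
                    birth_year=int(row["birth_year"]),
                    sire_id=sire,
                    traits=obs,
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"bull table {path} line {line}: {e}") from e
    if not records:
        logger.warning("bull table %s is empty (header only)", path)
    known = {r.bull_id for r in records}
    n_unknown = sum(1 for r in records if r.sire_id is not None and r.sire_id not in known)
    if n_unknown:
        logger.info("%d bulls have sires absent from the table", n_unknown)
    return records


def write_bull_table(records: list[BullRecord], path) -> None:
    traits = sorted({t for r in records for t in r.traits})
    rows = []
    for r in records:
        row = {
            "bull_id": r.bull_id,
            "population": r.population,
            "birth_year": r.birth_year,
            "sire_id": r.sire_id if r.sire_id is not None else "",
        }
        for t in traits:
            o = r.traits.get(t)
            row[f"drp_{t}"] = o.drp if o else np.nan
            row[f"edc_{t}"] = o.edc if o else np.nan
            row[f"rel_{t}"] = o.rel_drp if o else np.nan
        rows.append(row)
    cols = _FIXED_COLS + [f"{p}_{t}" for t in traits for p in ("drp", "edc", "rel")]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_genotypes(path, dialect: str = "tsv_matrix") -> GenotypeMatrix:
    """Load genotypes from a TSV dosage matrix or a biallelic-SNP VCF.

    Monomorphic markers are dropped with a logged count; missing
    genotypes are an error (imputation is out of scope); multiallelic
    VCF records are skipped with a warning.
    """
    if dialect == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", dtype={"bull_id": str})
        if "bull_id" not in df.columns:
            raise ValueError(f"genotype TSV {path} lacks a bull_id column")
        marker_ids = [c for c in df.columns if c != "bull_id"]
        dosages = df[marker_ids].to_numpy()
        if np.isnan(dosages.astype(float)).any():
            raise ValueError("missing genotypes are not allowed (imputation is out of scope)")
        bull_ids = df["bull_id"].to_numpy()
    elif dialect == "vcf":
        bull_ids, marker_ids, dosages = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    dosages = np.asarray(dosages)
    freq = dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("dropped %d monomorphic marker(s)", n_mono)
    return GenotypeMatrix(
        bull_ids=bull_ids,
        dosages=dosages[:, poly],
        marker_ids=np.asarray(marker_ids, dtype=object)[poly],
    )


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    bull_ids = np.asarray(vcf.samples, dtype=object)
    marker_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic record at %s:%d", var.CHROM, var.POS)
            continue
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = missing under gts012
        if (gt == 3).any():
            raise ValueError(
                f"missing genotype at {var.CHROM}:{var.POS} "
                "(imputation is out of scope)"
            )
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(gt.astype(np.int8))
    if not rows:
        raise ValueError(f"VCF {path} contains no usable biallelic SNPs")
    return bull_ids, marker_ids, np.column_stack(rows)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, columns=list(geno.marker_ids))
    df.insert(0, "bull_id", geno.bull_ids)
    df.to_csv(path, sep="\t", index=False)


_ROUNDING = {
    "half_even": decimal.ROUND_HALF_EVEN,
    "half_up": decimal.ROUND_HALF_UP,
    "half_down": decimal.ROUND_HALF_DOWN,
}


def round_decimal(x: float, ndigits: int = 2, mode: str = "half_even") -> float:
    """Decimal rounding of a float at the printed precision.

    Binary-float round() misbehaves exactly at the half; evaluation
    tables are printed at 2 decimals, so the half matters.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=_ROUNDING[mode])
    return float(d)


def write_validation_report(
    report: ValidationReport, path, ndigits: int = 2, rounding: str = "half_even"
) -> pd.DataFrame:
    """Write a validation report as CSV with table-style rounding."""
    if len(report) == 0:
        raise ValueError("cannot write an empty validation report")
    df = report.to_frame().copy()
    for col in ("rel_pi", "rel_gbv", "b0", "b0_sigma", "b1", "gain"):
        df[col] = [round_decimal(v, ndigits, rounding) for v in df[col]]
    df.to_csv(path, index=False, float_format=f"%.{ndigits}f")
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
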