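"""Readers and writers for genotype, phenotype, weight and result tables,
plus run configuration.

Genotypes come either from a VCF (biallelic SNVs, GT or DS fields; ALT is
the counted/effect allele) or from a dosage TSV (header row of snp ids,
first column subject_id) with an optional SNP-metadata sidecar TSV.
Missing genotypes are mean-imputed per SNP (the column mean, i.e. twice the
effect-allele frequency) and the count logged, so the subject set stays
constant across score variants.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, PhenotypeTable, SnpMeta, ValidationError, WeightTable

logger = logging.getLogger("grsmr")

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_weights",
    "write_weights",
    "load_config",
    "DEFAULT_CONFIG",
]

#: Analysis thresholds; every value can be overridden from the config file.
DEFAULT_CONFIG = {
    "maf_min": 0.005,        # exclude MAF strictly below 0.5%
    "info_min": 0.4,         # exclude imputation INFO strictly below 0.4
    "r2_threshold": 0.05,    # LD pruning r^2 cut
    "gwas_p": 5e-8,          # genome-wide significance tier for the restricted score
    "internal_p": 0.05,      # in-sample significance for the exposure-selected score
    "weighting": "weighted",
    "n_boot": 1000,          # weighted-median bootstrap replicates
    "seed": 0,
}


def _meta_from_column(snp_id: str, col: np.ndarray, effect: str = "A",
                      other: str = "B", chrom: str = "0", pos: int = 0,
                      info: Optional[float] = None) -> SnpMeta:
    p = float(np.mean(col)) / 2.0
    return SnpMeta(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=effect,
                   other_allele=other, maf=min(p, 1.0 - p), info=info)


def _impute_missing(dosages: np.ndarray, snp_ids: list[str]) -> np.ndarray:
    """Replace missing dosages by the per-SNP column mean (2 x allele freq)."""
    miss = np.isnan(dosages)
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, dosages), axis=0)
        col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
        dosages = np.where(miss, col_mean[None, :], dosages)
        for j, cnt in enumerate(miss.sum(axis=0)):
            if cnt:
                logger.info("imputed %d missing genotypes at %s to column mean %.4f",
                            cnt, snp_ids[j], col_mean[j])
    return dosages


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib errors are opaque
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    subject_ids = list(vcf.samples)
    cols, metas = [], []
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            raise ValidationError(
                f"{path} record {line_no} ({v.ID or v.POS}): multi-allelic records "
                "are not supported"
            )
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            col = np.empty(len(subject_ids))
            for i, gt in enumerate(v.genotypes):  # [allele0, allele1, phased]
                a = [x for x in gt[:-1] if x >= 0]
                col[i] = float(sum(a)) if len(a) == 2 else np.nan
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        info = v.INFO.get("INFO")
        if info is None:
            info = v.INFO.get("R2")
        cols.append(col)
        observed = col[~np.isnan(col)]
        p = float(observed.mean() / 2.0) if observed.size else 0.0
        metas.append(SnpMeta(
            snp_id=snp_id, chrom=str(v.CHROM), pos=int(v.POS),
            effect_allele=v.ALT[0], other_allele=v.REF,
            maf=min(p, 1.0 - p), info=None if info is None else float(info),
        ))
    if not cols:
        raise ValidationError(f"{path}: no variant records")
    dosages = _impute_missing(np.column_stack(cols), [m.snp_id for m in metas])
    return GenotypeMatrix(dosages, metas, subject_ids)


def _read_tsv_dosage(path: Path, snp_meta: Optional[Path]) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValidationError(f"cannot parse dosage TSV {path}: {exc}") from exc
    if df.columns[0] != "subject_id":
        raise ValidationError(f"{path}: first column must be 'subject_id'")
    subject_ids = df["subject_id"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    dosages = df[snp_ids].to_numpy(dtype=float)
    finite = dosages[~np.isnan(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        bad = np.unravel_index(
            np.nanargmax(np.abs(dosages - 1.0)), dosages.shape
        )
        raise ValidationError(
            f"{path}: dosage {dosages[bad]:g} outside [0, 2] "
            f"(subject {subject_ids[bad[0]]}, snp {snp_ids[bad[1]]})"
        )
    dosages = _impute_missing(dosages, snp_ids)
    if snp_meta is not None:
        meta_df = pd.read_csv(snp_meta, sep="\t").set_index("snp_id")
        metas = []
        for j, sid in enumerate(snp_ids):
            if sid not in meta_df.index:
                raise ValidationError(f"{snp_meta}: no metadata for {sid}")
            row = meta_df.loc[sid]
            info = row.get("info")
            metas.append(SnpMeta(
                snp_id=sid, chrom=str(row["chrom"]), pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]), maf=float(row["maf"]),
                info=None if pd.isna(info) else float(info),
            ))
    else:
        metas = [_meta_from_column(sid, dosages[:, j], pos=j + 1)
                 for j, sid in enumerate(snp_ids)]
    return GenotypeMatrix(dosages, metas, subject_ids)


def read_genotypes(path, format: str = "tsv_dosage",
                   snp_meta=None) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``tsv_dosage`` input.

    Dosage columns count the effect allele (the VCF ALT allele).  Phasing
    is ignored; missing genotypes are mean-imputed and logged.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv_dosage":
        return _read_tsv_dosage(path, None if snp_meta is None else Path(snp_meta))
    raise ValidationError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write dosages and SNP metadata as two TSVs: {prefix}.dosages.tsv and
    {prefix}.snps.tsv.  Round-trips hard-call input exactly."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dos_path = prefix.with_suffix(".dosages.tsv")
    meta_path = prefix.with_suffix(".snps.tsv")
    df = pd.DataFrame(g.dosages, columns=g.snp_ids)
    df.insert(0, "subject_id", g.subject_ids)
    df.to_csv(dos_path, sep="\t", index=False, float_format="%.17g")
    meta = pd.DataFrame([
        {
            "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
            "effect_allele": s.effect_allele, "other_allele": s.other_allele,
            "maf": s.maf, "info": s.info,
        }
        for s in g.snps
    ])
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.17g")
    return dos_path, meta_path


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV with columns subject_id, apn, dr (+ covariates).

    Log-standardization of adiponectin (apn_z) happens on construction;
    non-positive adiponectin or a dr value outside {0, 1, NA} is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"cannot parse phenotype CSV {path}: {exc}") from exc
    if "apn" in df.columns and "apn_raw" not in df.columns:
        df = df.rename(columns={"apn": "apn_raw"})
    return PhenotypeTable(df)


def write_phenotypes(ph: PhenotypeTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ph.frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_weights(path) -> WeightTable:
    """Read an external SNP weight table (TSV: snp_id, effect_allele, weight,
    source_p, source_tier)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    return WeightTable(pd.read_csv(path, sep="\t"))


def write_weights(wt: WeightTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wt.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def load_config(path) -> dict:
    """Load a YAML config and fill threshold defaults.

    Raises before any computation when a known key has an unusable value.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    for key in ("maf_min", "info_min", "r2_threshold", "gwas_p", "internal_p"):
        v = cfg[key]
        if not isinstance(v, (int, float)) or not (0 <= float(v) <= 1):
            raise ValidationError(f"config key {key}={v!r} must be a fraction in [0, 1]")
    if "simulate" not in cfg and ("genotypes" not in cfg or "phenotypes" not in cfg):
        raise ValidationError(
            "config must name input files (genotypes, phenotypes) or a simulate block"
        )
    return cfg
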