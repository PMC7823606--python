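"""Instrument selection and genetic-risk-score machinery.

LD pruning keeps, within each correlated cluster, the variant explaining
the most exposure variance; the surviving variants are combined into
weighted (or unweighted) allele scores used as composite instruments, with
score-level association and strength diagnostics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    GenotypeMatrix,
    GrsResult,
    GrsSpec,
    PhenotypeTable,
    SnpAssoc,
    ValidationError,
    WeightTable,
    Z_95,
)
from .qc_assoc import logistic_fit, ols_assoc, SeparationError

__all__ = [
    "ld_prune",
    "harmonize_weights",
    "build_grs",
    "grs_exposure_assoc",
    "grs_outcome_assoc",
    "select_grs_snps",
]


def ld_prune(g: GenotypeMatrix, exposure_assoc: Sequence[SnpAssoc],
             r2_threshold: float = 0.05) -> list[str]:
    """Greedy LD pruning on dosage correlations.

    Variants are ranked by exposure variance explained (descending, snp_id
    ascending on ties) and accepted iff their squared Pearson correlation
    with every already-kept variant is strictly below ``r2_threshold``.
    Variants lacking an exposure estimate rank last (r2 treated as 0).
    Returns kept snp_ids in genotype-matrix order.
    """
    r2_by_id = {a.snp_id: (a.r2 if a.r2 is not None else 0.0) for a in exposure_assoc}
    order = sorted(
        range(g.n_snps),
        key=lambda j: (-r2_by_id.get(g.snps[j].snp_id, 0.0), g.snps[j].snp_id),
    )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(g.dosages, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr))
    ld = corr ** 2
    kept: list[int] = []
    for j in order:
        if all(ld[j, k] < r2_threshold for k in kept):
            kept.append(j)
    kept_set = set(kept)
    return [s.snp_id for j, s in enumerate(g.snps) if j in kept_set]


def harmonize_weights(g: GenotypeMatrix, weights: WeightTable
                      ) -> tuple[GenotypeMatrix, GrsSpec, dict[str, str]]:
    """Align external weights to the genotype effect alleles.

    When the weight table's effect allele matches the genotype's other
    allele, the dosage column is flipped (2 - d) and the flip logged; when
    neither allele matches, the SNP is dropped with a warning entry.
    Returns the harmonized genotype subset, a GrsSpec over it, and the log.
    """
    meta = {s.snp_id: s for s in g.snps}
    log: dict[str, str] = {}
    keep_ids, flip_ids, w = [], [], []
    for row in weights.frame.itertuples(index=False):
        s = meta.get(row.snp_id)
        if s is None:
            log[row.snp_id] = "dropped: not in genotype matrix"
            continue
        if row.effect_allele == s.effect_allele:
            keep_ids.append(row.snp_id)
            w.append(row.weight)
        elif row.effect_allele == s.other_allele:
            keep_ids.append(row.snp_id)
            flip_ids.append(row.snp_id)
            w.append(row.weight)
            log[row.snp_id] = "flipped: weight effect allele matched other allele"
        else:
            log[row.snp_id] = (
                f"dropped: allele {row.effect_allele} matches neither "
                f"{s.effect_allele}/{s.other_allele}"
            )
    harmonized = g.subset(keep_ids).flipped(flip_ids)
    spec = GrsSpec(name="harmonized", snp_ids=keep_ids, weights=np.asarray(w))
    return harmonized, spec, log


def select_grs_snps(spec_name: str, rule: str, snp_ids: Sequence[str],
                    weights: np.ndarray, weight_table: Optional[WeightTable] = None,
                    exposure_assoc: Optional[Sequence[SnpAssoc]] = None,
                    gwas_p: float = 5e-8, internal_p: float = 0.05) -> GrsSpec:
    """Restrict a candidate SNP set by one of the three selection rules.

    ``all`` keeps everything; ``gwas_significant`` keeps SNPs whose source
    study reached p < gwas_p; ``internally_significant`` keeps SNPs with
    in-sample exposure p < internal_p.
    """
    ids = list(snp_ids)
    w = np.asarray(weights, dtype=float)
    if rule == "all":
        mask = np.ones(len(ids), bool)
    elif rule == "gwas_significant":
        if weight_table is None:
            raise ValidationError("gwas_significant rule needs a weight table")
        src = weight_table.frame.set_index("snp_id")["source_p"]
        mask = np.array([sid in src.index and src[sid] < gwas_p for sid in ids])
    elif rule == "internally_significant":
        if exposure_assoc is None:
            raise ValidationError("internally_significant rule needs exposure associations")
        pmap = {a.snp_id: a.p_exposure for a in exposure_assoc}
        mask = np.array([
            pmap.get(sid) is not None and pmap[sid] < internal_p for sid in ids
        ])
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    return GrsSpec(
        name=spec_name,
        snp_ids=[sid for sid, m in zip(ids, mask) if m],
        weights=w[mask],
        selection_rule=rule,
    )


def build_grs(g: GenotypeMatrix, spec: GrsSpec,
              weighting: str = "weighted") -> GrsResult:
    """Per-subject allele score, standardized to SD units.

    raw_i = sum_j w_j * dosage_ij (w_j = 1 under ``unweighted``); the
    returned scores_z are standardized with the sample SD, so any common
    rescaling of the weights leaves them unchanged.
    """
    if weighting not in ("weighted", "unweighted"):
        raise ValidationError("weighting must be 'weighted' or 'unweighted'")
    if not spec.snp_ids:
        raise ValidationError(f"GRS {spec.name}: empty SNP set")
    sub = g.subset(spec.snp_ids)
    w = spec.weights if weighting == "weighted" else np.ones(len(spec.snp_ids))
    raw = sub.dosages @ w
    sd = np.std(raw, ddof=1)
    if sd == 0:
        raise ValidationError(f"GRS {spec.name}: degenerate (constant) score")
    return GrsResult(spec=spec, scores_z=(raw - raw.mean()) / sd)


def grs_exposure_assoc(grs: GrsResult, ph: PhenotypeTable) -> GrsResult:
    """Fill the score's exposure-leg diagnostics: OLS of apn_z on scores_z.

    beta is SD log-adiponectin per SD of the score, with 95% CI
    beta +/- 1.959964 se, and F/R2 as for single-SNP instruments.
    """
    y = ph.apn_z
    ok = ~np.isnan(y)
    beta, se, p, r2 = ols_assoc(grs.scores_z[ok], y[ok])
    grs.beta_apn, grs.se, grs.p, grs.r2 = beta, se, p, r2
    grs.ci95 = (beta - Z_95 * se, beta + Z_95 * se)
    grs.f_stat = (beta / se) ** 2
    return grs


def grs_outcome_assoc(grs: GrsResult, ph: PhenotypeTable
                      ) -> tuple[float, float, float]:
    """Logistic regression of retinopathy on the standardized score.

    Returns (log-OR per SD of the score, Wald SE, two-sided p).  Separation
    and single-class outcomes raise.
    """
    y = ph.dr
    ok = ~np.isnan(y)
    y = y[ok]
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class")
    x = grs.scores_z[ok]
    try:
        coef, se = logistic_fit(np.column_stack([np.ones(len(y)), x]), y)
    except SeparationError:
        raise
    z = coef[1] / se[1]
    return float(coef[1]), float(se[1]), float(2.0 * stats.norm.sf(abs(z)))
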