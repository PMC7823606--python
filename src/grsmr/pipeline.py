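"""End-to-end pipeline: data in (or simulated), QC, associations, scores,
causal estimates, confounder scan, report.

Every filter decision is written to ``run.log`` with counts, and all result
tables are TSV at full precision; the human-readable report rounds to two
decimals.  Given a fixed seed the outputs are byte-identical across runs
(no timestamps are written).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .datatypes import GrsResult, MrEstimate, PowerInput, ValidationError
from .instruments import (
    build_grs,
    grs_exposure_assoc,
    grs_outcome_assoc,
    harmonize_weights,
    ld_prune,
    select_grs_snps,
)
from .mr import confounder_scan, grs_two_stage, ivw, mr_egger, mr_power, weighted_median
from .qc_assoc import apply_variant_qc, merge_assoc, snp_exposure_assoc, snp_outcome_assoc
from .simulate import SimConfig, simulate_cohort, table1_preset, weight_table_from_truth

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "assoc", "grs", "mr", "report")

#: Confounder-scan traits, in reporting order (sex handled as binary).
SCAN_TRAITS = ("sex", "sbp", "dbp", "glucose", "hba1c", "tg", "hdl", "ldl", "bmi")


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    if block.get("preset", None) == "table1" or not block:
        return table1_preset(
            seed=seed,
            pleiotropy=block.get("pleiotropy", "none"),
            causal_beta=float(block.get("causal_beta", 0.61)),
        )
    kwargs = dict(block)
    kwargs.pop("preset", None)
    kwargs["seed"] = seed
    return SimConfig(**kwargs)


def _estimate_row(instrument: str, est: MrEstimate) -> dict:
    return {
        "instrument": instrument,
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci95_lo": est.ci95[0],
        "ci95_hi": est.ci95[1],
        "ci90_lo": est.ci90[0],
        "ci90_hi": est.ci90[1],
        "p": est.p,
        "or": est.or_,
    }


def run_pipeline(cfg: dict, out_dir, stage: str = "report",
                 seed: Optional[int] = None) -> dict:
    """Run the pipeline through ``stage`` and write result files to out_dir.

    Returns a dict of in-memory results (genotypes, associations, GRS
    results, MR estimate table, ...) for programmatic use.  ``seed``
    overrides the config seed.
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def flush_log() -> None:
        (out_dir / "run.log").write_text("".join(line + "\n" for line in log_lines))

    log(f"seed={seed}")
    for key in ("maf_min", "info_min", "r2_threshold", "gwas_p", "internal_p"):
        log(f"threshold {key}={cfg[key]:g}")

    results: dict = {"seed": seed}

    # --- inputs -----------------------------------------------------------
    truth = None
    if "simulate" in cfg:
        sim_cfg = _sim_config_from_block(cfg["simulate"] or {}, seed)
        g, ph, truth = simulate_cohort(sim_cfg)
        weights = weight_table_from_truth(g, truth)
        gio.write_genotypes(g, out_dir / "cohort")
        gio.write_phenotypes(ph, out_dir / "phenotypes.csv")
        gio.write_weights(weights, out_dir / "weights.tsv")
        log(f"simulated cohort: n={g.n_subjects} subjects, m={g.n_snps} SNPs, "
            f"cases={int(np.nansum(ph.dr))}")
        results["truth"] = truth
    else:
        g = gio.read_genotypes(cfg["genotypes"], format=cfg.get("genotype_format", "tsv_dosage"),
                               snp_meta=cfg.get("snp_meta"))
        ph = gio.read_phenotypes(cfg["phenotypes"])
        weights = gio.read_weights(cfg["weights"]) if "weights" in cfg else None
        log(f"read cohort: n={g.n_subjects} subjects, m={g.n_snps} SNPs")
    results.update(genotypes=g, phenotypes=ph, weights=weights)
    if stage == "simulate":
        flush_log()
        return results

    # --- QC + per-SNP associations ---------------------------------------
    g_qc, qc_report = apply_variant_qc(g, maf_min=cfg["maf_min"], info_min=cfg["info_min"])
    log(f"variant QC: {qc_report.n_input} in, {qc_report.n_fail_maf} failed MAF, "
        f"{qc_report.n_fail_info} failed INFO, {qc_report.n_pass} pass")
    for sid, why in qc_report.reasons.items():
        log(f"  excluded {sid}: {why}")
    exp_assoc = snp_exposure_assoc(g_qc, ph, model=cfg.get("exposure_model", "base"),
                                   covariate_names=cfg.get("covariate_names", ()))
    out_assoc = snp_outcome_assoc(g_qc, ph)
    assoc = merge_assoc(exp_assoc, out_assoc)
    allele = {s.snp_id: s.effect_allele for s in g_qc.snps}
    assoc_df = pd.DataFrame([
        {
            "snp_id": a.snp_id, "effect_allele": allele[a.snp_id],
            "beta_exp": a.beta_exposure, "se_exp": a.se_exposure, "p_exp": a.p_exposure,
            "beta_out": a.beta_outcome, "se_out": a.se_outcome, "p_out": a.p_outcome,
            "n": a.n_used, "F": a.f_stat, "R2": a.r2,
            "qc_flag": a.reason_absent or "ok",
        }
        for a in assoc
    ])
    assoc_df.to_csv(out_dir / "associations.tsv", sep="\t", index=False,
                    float_format="%.17g")
    results.update(qc_report=qc_report, assoc=assoc, genotypes_qc=g_qc)
    if stage == "assoc":
        flush_log()
        return results

    # --- harmonization, LD pruning, scores --------------------------------
    if weights is not None:
        g_h, h_spec, h_log = harmonize_weights(g_qc, weights)
        for sid, why in h_log.items():
            log(f"  harmonization {sid}: {why}")
        log(f"harmonized {len(h_spec.snp_ids)} of {len(weights.frame)} weighted SNPs")
    else:
        # internal weights: in-sample exposure effects (overfitting caveat
        # documented; acceptable for simulation smoke runs only)
        usable = [a for a in assoc if a.beta_exposure is not None]
        g_h = g_qc.subset([a.snp_id for a in usable])
        from .datatypes import GrsSpec
        h_spec = GrsSpec(name="internal", snp_ids=[a.snp_id for a in usable],
                         weights=np.array([a.beta_exposure for a in usable]))
        log("no external weight table; using in-sample exposure effects as weights")

    pruned_ids = ld_prune(g_h, assoc, r2_threshold=cfg["r2_threshold"])
    log(f"LD pruning (r2 < {cfg['r2_threshold']:g}): kept {len(pruned_ids)} of "
        f"{g_h.n_snps} SNPs")
    keep_mask = [sid in set(pruned_ids) for sid in h_spec.snp_ids]
    base_ids = [sid for sid, k in zip(h_spec.snp_ids, keep_mask) if k]
    base_w = h_spec.weights[np.asarray(keep_mask, bool)]

    grs_defs = {
        "grs_all": "all",
        "grs_limited": "gwas_significant",
        "grs_apn": "internally_significant",
    }
    grs_results: dict[str, GrsResult] = {}
    grs_out_legs: dict[str, tuple[float, float, float]] = {}
    rows = []
    for name, rule in grs_defs.items():
        spec = select_grs_snps(name, rule, base_ids, base_w,
                               weight_table=weights, exposure_assoc=assoc,
                               gwas_p=cfg["gwas_p"], internal_p=cfg["internal_p"])
        if not spec.snp_ids:
            log(f"GRS {name}: no SNPs selected under rule {rule}; skipped")
            continue
        grs = build_grs(g_h, spec, weighting=cfg.get("weighting", "weighted"))
        grs = grs_exposure_assoc(grs, ph)
        bo, so, po = grs_outcome_assoc(grs, ph)
        grs_results[name] = grs
        grs_out_legs[name] = (bo, so, po)
        log(f"GRS {name}: {len(spec.snp_ids)} SNPs (rule {rule}), "
            f"F={grs.f_stat:.2f}, R2={grs.r2:.4f}")
        rows.append({
            "grs": name, "rule": rule, "n_snps": len(spec.snp_ids),
            "beta_apn": grs.beta_apn, "se": grs.se, "p": grs.p,
            "ci95_lo": grs.ci95[0], "ci95_hi": grs.ci95[1],
            "F": grs.f_stat, "R2": grs.r2,
            "beta_out": bo, "se_out": so, "p_out": po,
        })
    pd.DataFrame(rows).to_csv(out_dir / "grs_diagnostics.tsv", sep="\t",
                              index=False, float_format="%.17g")
    scores = pd.DataFrame({"subject_id": g.subject_ids})
    for name, grs in grs_results.items():
        scores[name] = grs.scores_z
    scores.to_csv(out_dir / "grs_scores.tsv", sep="\t", index=False,
                  float_format="%.17g")
    results.update(grs=grs_results, grs_out_legs=grs_out_legs, pruned_ids=pruned_ids)
    if stage == "grs":
        flush_log()
        return results

    # --- MR estimation -----------------------------------------------------
    by_id = {a.snp_id: a for a in assoc}
    est_rows = []
    for name, grs in grs_results.items():
        usable = [by_id[sid] for sid in grs.spec.snp_ids
                  if by_id[sid].beta_exposure not in (None, 0)
                  and by_id[sid].beta_outcome is not None]
        est_rows.append(_estimate_row(name, grs_two_stage(grs, grs_out_legs[name][:2])))
        snp_set = f"{name}_snps"
        if usable:
            est_rows.append(_estimate_row(snp_set, ivw(usable)))
        if len(usable) >= 3:
            slope, intercept = mr_egger(usable)
            est_rows.append(_estimate_row(snp_set, slope))
            est_rows.append(_estimate_row(snp_set, intercept))
            est_rows.append(_estimate_row(
                snp_set, weighted_median(usable, n_boot=int(cfg.get("n_boot", 1000)),
                                         seed=seed)))
    est_df = pd.DataFrame(est_rows)
    est_df.to_csv(out_dir / "mr_estimates.tsv", sep="\t", index=False,
                  float_format="%.17g")

    scan_rows = []
    traits = [t for t in SCAN_TRAITS if t in ph.frame.columns]
    for name, grs in grs_results.items():
        for trait, (b, s, p) in confounder_scan(grs, ph, traits).items():
            scan_rows.append({"grs": name, "trait": trait, "beta": b, "se": s, "p": p})
    pd.DataFrame(scan_rows).to_csv(out_dir / "confounders.tsv", sep="\t",
                                   index=False, float_format="%.17g")
    results.update(mr_estimates=est_df, confounders=pd.DataFrame(scan_rows))
    if stage == "mr":
        flush_log()
        return results

    # --- report ------------------------------------------------------------
    case_fraction = float(np.nanmean(ph.dr))
    lines = ["Causal effect of adiponectin on diabetic retinopathy (log-OR per SD)",
             ""]
    lines.append(f"{'instrument':<18}{'method':<18}{'k':>4}{'beta':>8}"
                 f"{'95% CI':>18}{'90% CI':>18}{'p':>10}")
    for row in est_rows:
        lines.append(
            f"{row['instrument']:<18}{row['method']:<18}{row['n_snps']:>4}"
            f"{row['beta']:>8.2f}"
            f"{'(%.2f, %.2f)' % (row['ci95_lo'], row['ci95_hi']):>18}"
            f"{'(%.2f, %.2f)' % (row['ci90_lo'], row['ci90_hi']):>18}"
            f"{row['p']:>10.3f}"
        )
    lines.append("")
    for name, grs in grs_results.items():
        power = mr_power(PowerInput(
            n=ph.n_subjects, r2_xz=max(grs.r2, 1e-12),
            or_per_sd=float(np.exp(abs(est_df.loc[
                (est_df.instrument == name) & (est_df.method == "grs_two_stage"),
                "beta"].iloc[0]))),
            case_fraction=case_fraction,
        ))
        lines.append(f"power ({name}, alpha=0.05, two-sided): {100 * power:.0f}%")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    flush_log()
    return results
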