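"""Repeatable simulation studies over the synthetic cohort generator.

Each function runs the full per-SNP pipeline (simulate -> association legs
-> estimator) across many seeded replicate cohorts and summarizes operating
characteristics: estimator bias and CI coverage, type-I error, pleiotropy
detection power, instrument-strength calibration, and empirical power.
These drive both the test suite and the results-reproduction script.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .datatypes import SnpAssoc
from .instruments import build_grs, grs_exposure_assoc, grs_outcome_assoc
from .datatypes import GrsSpec
from .mr import grs_two_stage, ivw, mr_egger, weighted_median
from .qc_assoc import merge_assoc, snp_exposure_assoc, snp_outcome_assoc
from .simulate import SimConfig, effects_for_variance, simulate_cohort

__all__ = [
    "simulate_ratio_cohort",
    "ivw_recovery",
    "egger_detection_rate",
    "median_vs_ivw_bias",
    "strength_calibration",
    "empirical_grs_power",
]

N_SUBJECTS = 1251          # emulated study size
PREVALENCE = 438.0 / 1251.0


def _spread_seed(base: int, rep: int, stream: int) -> int:
    """Distinct sub-seed per (replicate, stream), kept below 2**31."""
    return int((base * 1_000_003 + rep * 7919 + stream * 104_729) % (2 ** 31 - 1))


def simulate_ratio_cohort(
    seed: int,
    n_snps: int,
    total_r2: float,
    causal_beta: float,
    pleiotropy: Union[str, Sequence[float]] = "none",
    per_snp_r2: Optional[Sequence[float]] = None,
    n_subjects: int = N_SUBJECTS,
    gamma: float = 0.0,
    delta: float = 0.0,
) -> list[SnpAssoc]:
    """One replicate cohort's usable two-leg association summaries.

    Allele frequencies are drawn uniform on (0.1, 0.4) from a seed-derived
    stream; per-SNP exposure variance is split equally unless given.
    """
    rng = np.random.default_rng(_spread_seed(seed, 0, 1))
    mafs = rng.uniform(0.1, 0.4, n_snps)
    v = (np.full(n_snps, total_r2 / n_snps) if per_snp_r2 is None
         else np.asarray(per_snp_r2, dtype=float))
    cfg = SimConfig(
        n_subjects=n_subjects, n_snps=n_snps, mafs=mafs,
        snp_effects=effects_for_variance(mafs, v), causal_beta=causal_beta,
        confounder_loading_exposure=gamma, confounder_loading_outcome=delta,
        pleiotropy=list(pleiotropy) if not isinstance(pleiotropy, str) else pleiotropy,
        baseline_prevalence=PREVALENCE, seed=_spread_seed(seed, 0, 2),
    )
    g, ph, _ = simulate_cohort(cfg)
    assoc = merge_assoc(snp_exposure_assoc(g, ph), snp_outcome_assoc(g, ph))
    return [a for a in assoc
            if a.beta_exposure not in (None, 0.0) and a.beta_outcome is not None]


def ivw_recovery(causal_beta: float, n_rep: int = 500, n_snps: int = 20,
                 total_r2: float = 0.05, base_seed: int = 0) -> dict:
    """IVW operating characteristics across replicate cohorts with valid
    instruments (no pleiotropy, no confounding): mean estimate, empirical
    SD, 95% CI coverage of the conditional log-OR, and rejection rate of
    the causal null at alpha = 0.05."""
    betas, covered, rejected = [], [], []
    for r in range(n_rep):
        usable = simulate_ratio_cohort(base_seed + r, n_snps, total_r2, causal_beta)
        est = ivw(usable)
        betas.append(est.beta)
        covered.append(est.ci95[0] <= causal_beta <= est.ci95[1])
        rejected.append(est.p < 0.05)
    betas = np.asarray(betas)
    return {
        "mean": float(betas.mean()),
        "sd": float(betas.std(ddof=1)),
        "coverage": float(np.mean(covered)),
        "rejection": float(np.mean(rejected)),
        "n_rep": n_rep,
    }


def egger_detection_rate(pleiotropy: str, n_rep: int = 500, n_snps: int = 16,
                         total_r2: float = 0.034, base_seed: int = 0) -> float:
    """Fraction of replicates in which the Egger intercept rejects at
    alpha = 0.05 under the named pleiotropy regime (causal effect 0)."""
    rej = []
    for r in range(n_rep):
        usable = simulate_ratio_cohort(base_seed + r, n_snps, total_r2, 0.0,
                                       pleiotropy=pleiotropy)
        _, intercept = mr_egger(usable)
        rej.append(intercept.p < 0.05)
    return float(np.mean(rej))


def median_vs_ivw_bias(n_rep: int = 300, base_seed: int = 0,
                       invalid_effect: float = 0.2) -> tuple[float, float]:
    """Mean bias of the weighted median vs IVW when half the SNPs carry a
    directional direct effect but the valid half, being stronger
    instruments, holds the majority of inverse-variance weight.  True
    causal effect is 0, so the mean estimate is the bias."""
    wm, fe = [], []
    per_snp_r2 = np.r_[np.full(10, 0.005), np.full(10, 0.0015)]  # valid first
    d = list(np.r_[np.zeros(10), np.full(10, invalid_effect)])
    for r in range(n_rep):
        usable = simulate_ratio_cohort(base_seed + r, 20, per_snp_r2.sum(), 0.0,
                                       pleiotropy=d, per_snp_r2=per_snp_r2)
        wm.append(weighted_median(usable, n_boot=100,
                                  seed=_spread_seed(base_seed, r, 3)).beta)
        fe.append(ivw(usable).beta)
    return float(np.mean(wm)), float(np.mean(fe))


def strength_calibration(r2_true: float = 0.018, n_rep: int = 200,
                         n_subjects: int = N_SUBJECTS, base_seed: int = 0) -> float:
    """Mean single-SNP F statistic across replicates at a fixed true
    variance explained; compares against (n-2) R2 / (1 - R2)."""
    fs = []
    for r in range(n_rep):
        usable = simulate_ratio_cohort(base_seed + r, 1, r2_true, 0.0,
                                       n_subjects=n_subjects)
        fs.append(usable[0].f_stat)
    return float(np.mean(fs))


def empirical_grs_power(causal_beta: float = 0.61, total_r2: float = 0.052,
                        n_snps: int = 10, n_rep: int = 2000,
                        base_seed: int = 0) -> float:
    """Empirical rejection rate of the score-based two-stage test across
    full-pipeline replicates (simulate -> build score with true weights ->
    two-stage Wald test at alpha = 0.05)."""
    rej = []
    for r in range(n_rep):
        rng = np.random.default_rng(_spread_seed(base_seed, r, 4))
        mafs = rng.uniform(0.1, 0.4, n_snps)
        eff = effects_for_variance(mafs, np.full(n_snps, total_r2 / n_snps))
        cfg = SimConfig(
            n_subjects=N_SUBJECTS, n_snps=n_snps, mafs=mafs, snp_effects=eff,
            causal_beta=causal_beta, baseline_prevalence=PREVALENCE,
            seed=_spread_seed(base_seed, r, 5),
        )
        g, ph, truth = simulate_cohort(cfg)
        spec = GrsSpec(name="sim", snp_ids=g.snp_ids, weights=truth.snp_effects)
        grs = grs_exposure_assoc(build_grs(g, spec), ph)
        bo, so, _ = grs_outcome_assoc(grs, ph)
        rej.append(grs_two_stage(grs, (bo, so)).p < 0.05)
    return float(np.mean(rej))
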