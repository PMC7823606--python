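"""Synthetic diabetic cohorts with known causal structure.

The generator realizes the two-equation structure every stage of the MR
pipeline assumes:

    ln-APN* = sum_j a_j (G_j - 2 p_j) + gamma * U + eps,   var(ln-APN*) = 1
    DR      ~ Bernoulli( logit^-1( a0 + beta_c * apn_z + delta * U + sum_j d_j G_j ) )

with G_j additive effect-allele dosages in Hardy-Weinberg proportions,
optional within-block linkage disequilibrium via a Gaussian copula on the
latent haplotypes, a latent confounder U shared by exposure, outcome and
the risk-factor covariates, and optional direct (pleiotropic) SNP effects
d_j on the outcome.  The intercept a0 is solved so the realized disease
prevalence matches a target.  Ground truth is returned alongside the data
so parameter recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, ndtri

from .datatypes import COVARIATE_NAMES, GenotypeMatrix, PhenotypeTable, SnpMeta, WeightTable
from .datatypes import ValidationError

import pandas as pd

__all__ = [
    "LdBlock",
    "CovariateSpec",
    "SimConfig",
    "TruthRecord",
    "simulate_cohort",
    "table1_preset",
    "effects_for_variance",
    "draw_mafs",
    "weight_table_from_truth",
    "PLEIOTROPY_PRESETS",
]


@dataclass(frozen=True)
class LdBlock:
    """A run of consecutive SNPs sharing latent haplotype correlation rho."""

    size: int
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("LD block size must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            # negative equicorrelation is not positive-definite in general
            raise ValidationError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class CovariateSpec:
    """Target mean/SD for one covariate and its loading on the confounder U.

    ``binary`` covariates (sex) are drawn Bernoulli with success probability
    ``mean``; the loading shifts the logit.
    """

    mean: float
    sd: float = 1.0
    loading: float = 0.0
    binary: bool = False


#: Named direct-effect regimes for the Egger intercept machinery.  Values are
#: (mu_d, sd_d) of the per-allele direct log-OR on the outcome; instrument
#: strength and direct effects are drawn independently (InSIDE holds).  The
#: directional mean is sized so that average pleiotropy is detectable by the
#: Egger intercept test at the emulated design (n ~ 1250, 16 weak
#: instruments): with per-SNP F near 4, sign-orientation noise dilutes the
#: intercept, so a clearly detectable regime needs a direct effect of the
#: same order as the per-allele outcome-association SE (~0.1), times ~3.
PLEIOTROPY_PRESETS = {
    "none": (0.0, 0.0),
    "balanced": (0.0, 0.08),
    "directional": (0.3, 0.05),
}


@dataclass
class SimConfig:
    """Full description of one synthetic cohort.

    ``snp_effects`` are per-effect-allele effects a_j on SD log-adiponectin;
    ``causal_beta`` is the estimand (log-OR of retinopathy per SD of
    log-adiponectin); ``confounder_loading_exposure``/``_outcome`` are gamma
    and delta above.  ``pleiotropy`` is either an explicit per-SNP vector of
    direct log-OR effects, or the name of a preset regime.  ``mafs`` may pin
    effect-allele frequencies explicitly; otherwise they are drawn uniform
    over ``maf_range``.
    """

    n_subjects: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.45)
    mafs: Optional[Sequence[float]] = None
    ld_blocks: Optional[list[LdBlock]] = None
    snp_effects: Optional[Sequence[float]] = None
    confounder_loading_exposure: float = 0.0
    causal_beta: float = 0.0
    confounder_loading_outcome: float = 0.0
    pleiotropy: Union[str, Sequence[float]] = "none"
    baseline_prevalence: float = 0.35
    covariate_spec: dict[str, CovariateSpec] = field(default_factory=dict)
    apn_log_mean: float = 2.85
    apn_log_sd: float = 0.88
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValidationError("baseline_prevalence must lie in (0, 1)")
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValidationError("n_subjects and n_snps must be positive")
        if self.ld_blocks is not None:
            if sum(b.size for b in self.ld_blocks) != self.n_snps:
                raise ValidationError("LD block sizes must sum to n_snps")
        if isinstance(self.pleiotropy, str) and self.pleiotropy not in PLEIOTROPY_PRESETS:
            raise ValidationError(f"unknown pleiotropy preset {self.pleiotropy!r}")


@dataclass
class TruthRecord:
    """Ground truth realized for one simulated cohort (parameter-recovery oracle)."""

    snp_effects: np.ndarray
    pleiotropy: np.ndarray
    gamma: float
    delta: float
    causal_beta: float
    r2_true: float
    alpha0: float
    seed: int


def draw_mafs(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Effect-allele frequencies: explicit if pinned, else uniform over the range."""
    if cfg.mafs is not None:
        mafs = np.asarray(cfg.mafs, dtype=float)
        if mafs.shape != (cfg.n_snps,):
            raise ValidationError("mafs length must equal n_snps")
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValidationError("mafs must lie in (0, 0.5]")
        return mafs
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return rng.uniform(*cfg.maf_range, size=cfg.n_snps)


def effects_for_variance(mafs: Sequence[float], variances: Sequence[float]) -> np.ndarray:
    """Per-allele effects a_j such that each SNP contributes the requested
    fraction of unit exposure variance under Hardy-Weinberg (var(G_j)=2p(1-p))."""
    p = np.asarray(mafs, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(v < 0) or v.sum() >= 1.0:
        raise ValidationError("per-SNP variance contributions must be >=0 and sum < 1")
    return np.sqrt(v / (2.0 * p * (1.0 - p)))


def _draw_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                    blocks: Optional[list[LdBlock]]) -> np.ndarray:
    """Dosages 0/1/2 by thresholding correlated latent normals at the
    Hardy-Weinberg quantile, two haplotype draws per subject."""
    m = len(mafs)
    if blocks is None:
        blocks = [LdBlock(size=m, rho=0.0)] if m else []
    thresh = ndtri(mafs)  # latent < thresh  <=>  effect allele present
    dosage = np.empty((n, m))
    j = 0
    for b in blocks:
        sl = slice(j, j + b.size)
        if b.rho == 0.0:
            z = rng.standard_normal((2, n, b.size))
        else:
            shared = rng.standard_normal((2, n, 1))
            z = np.sqrt(b.rho) * shared + np.sqrt(1.0 - b.rho) * rng.standard_normal(
                (2, n, b.size)
            )
        alleles = z < thresh[sl]
        dosage[:, sl] = alleles.sum(axis=0)
        j += b.size
    return dosage


def _solve_intercept(lp: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection for a0 on [-20, 20] so mean(expit(a0 + lp)) hits the target
    prevalence in expectation over the realized linear predictors."""
    lo, hi = -20.0, 20.0
    f = lambda a: float(np.mean(expit(a + lp))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError("prevalence target unreachable within [-20, 20]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < tol:
            return mid
    raise ValidationError("intercept bisection failed to converge")


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Draw one cohort (genotypes, phenotypes, ground truth) from ``cfg``.

    The exposure's systematic part (genetics + confounder) is measured on the
    realized sample and the residual noise sized so the latent log-exposure
    has unit variance; a systematic variance >= 1 is an infeasible config.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = draw_mafs(cfg, rng)
    n, m = cfg.n_subjects, cfg.n_snps

    dosage = _draw_genotypes(rng, n, mafs, cfg.ld_blocks)

    a = (np.zeros(m) if cfg.snp_effects is None
         else np.asarray(cfg.snp_effects, dtype=float))
    if a.shape != (m,):
        raise ValidationError("snp_effects length must equal n_snps")
    if isinstance(cfg.pleiotropy, str):
        mu_d, sd_d = PLEIOTROPY_PRESETS[cfg.pleiotropy]
        d = mu_d + sd_d * rng.standard_normal(m) if (mu_d or sd_d) else np.zeros(m)
    else:
        d = np.asarray(cfg.pleiotropy, dtype=float)
        if d.shape != (m,):
            raise ValidationError("pleiotropy vector length must equal n_snps")

    gamma = cfg.confounder_loading_exposure
    delta = cfg.confounder_loading_outcome
    u = rng.standard_normal(n)

    centered = dosage - 2.0 * mafs
    eta_g = centered @ a
    eta = eta_g + gamma * u
    var_sys = float(np.var(eta, ddof=1)) if n > 1 else 0.0
    if var_sys >= 1.0:
        raise ValidationError(
            f"systematic exposure variance {var_sys:.3f} >= 1; infeasible config"
        )
    ln_apn = eta + np.sqrt(1.0 - var_sys) * rng.standard_normal(n)
    r2_true = float(np.var(eta_g, ddof=1) / np.var(ln_apn, ddof=1)) if n > 1 else 0.0

    apn_raw = np.exp(cfg.apn_log_mean + cfg.apn_log_sd * ln_apn)
    apn_z = (ln_apn - ln_apn.mean()) / np.std(ln_apn, ddof=1)

    lp = cfg.causal_beta * apn_z + delta * u + dosage @ d
    alpha0 = _solve_intercept(lp, cfg.baseline_prevalence)
    dr = rng.binomial(1, expit(alpha0 + lp))

    subject_ids = [f"S{i:06d}" for i in range(n)]
    data = {"subject_id": subject_ids, "apn_raw": apn_raw, "dr": dr}
    for name, spec in cfg.covariate_spec.items():
        if spec.binary:
            pr = expit(ndtri(np.clip(spec.mean, 1e-9, 1 - 1e-9)) + spec.loading * u)
            data[name] = rng.binomial(1, pr)
        else:
            resid = np.sqrt(max(0.0, 1.0 - spec.loading ** 2))
            data[name] = spec.mean + spec.sd * (
                spec.loading * u + resid * rng.standard_normal(n)
            )

    snps = [
        SnpMeta(
            snp_id=f"rs{j + 1:05d}",
            chrom=str(1 + j % 22),
            pos=10_000 + 1_000 * j,
            effect_allele="A",
            other_allele="G",
            maf=float(min(mafs[j], 1.0 - mafs[j])),
        )
        for j in range(m)
    ]
    g = GenotypeMatrix(dosage, snps, subject_ids)
    ph = PhenotypeTable(pd.DataFrame(data))
    truth = TruthRecord(
        snp_effects=a, pleiotropy=d, gamma=gamma, delta=delta,
        causal_beta=cfg.causal_beta, r2_true=r2_true, alpha0=alpha0, seed=cfg.seed,
    )
    return g, ph, truth


# Demographics of a Taiwanese type-2-diabetes cohort (no-retinopathy column):
# mean, SD, loading on the shared confounder U.  Loadings are moderate and
# sign-plausible (adiposity/glycemia load positively on U, HDL negatively);
# they emulate confounded risk factors, not a calibration to any dataset.
_TABLE1_COVARIATES = {
    "sex": CovariateSpec(mean=0.431, binary=True),
    "age": CovariateSpec(mean=59.43, sd=11.84, loading=0.15),
    "sbp": CovariateSpec(mean=130.67, sd=18.22, loading=0.25),
    "dbp": CovariateSpec(mean=75.82, sd=11.77, loading=0.25),
    "bmi": CovariateSpec(mean=26.54, sd=4.32, loading=0.30),
    "glucose": CovariateSpec(mean=134.15, sd=48.72, loading=0.30),
    "hba1c": CovariateSpec(mean=7.27, sd=1.40, loading=0.30),
    "tg": CovariateSpec(mean=166.65, sd=141.86, loading=0.25),
    "hdl": CovariateSpec(mean=47.36, sd=20.03, loading=-0.25),
    "ldl": CovariateSpec(mean=112.68, sd=36.43, loading=0.15),
}


def table1_preset(seed: int = 0, pleiotropy: str = "none",
                  causal_beta: float = 0.61) -> SimConfig:
    """A cohort emulating the study design this pipeline targets: 1251
    diabetic subjects, 35% retinopathy prevalence (438/1251), 47 candidate
    SNPs of which one is a strong instrument (~1.9% of exposure variance,
    F near 24) and the rest individually weak, ~5% of exposure variance
    explained by the full SNP set, moderate latent confounding, and a
    moderate causal log-OR.  A plausible emulation, not a calibration.
    """
    n_snps = 47
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.05, 0.45, size=n_snps)
    # one strong instrument + 46 weak ones sharing the remaining variance
    variances = np.full(n_snps, 0.033 / 46.0)
    variances[0] = 0.019
    effects = effects_for_variance(mafs, variances)
    return SimConfig(
        n_subjects=1251,
        n_snps=n_snps,
        mafs=mafs,
        snp_effects=effects,
        confounder_loading_exposure=0.30,
        causal_beta=causal_beta,
        confounder_loading_outcome=0.30,
        pleiotropy=pleiotropy,
        baseline_prevalence=438.0 / 1251.0,
        covariate_spec=dict(_TABLE1_COVARIATES),
        seed=seed,
    )


def weight_table_from_truth(g: GenotypeMatrix, truth: TruthRecord,
                            n_gwas_tier: int = 16) -> WeightTable:
    """External-style weight table derived from simulation ground truth.

    Plays the role of published summary statistics: true per-allele effects
    as weights, with the ``n_gwas_tier`` largest-effect SNPs tagged as
    genome-wide significant (the restricted-score tier).
    """
    order = np.argsort(-np.abs(truth.snp_effects))
    tier = np.array(["other"] * g.n_snps, dtype=object)
    tier[order[:n_gwas_tier]] = "gwas_genomewide"
    source_p = np.where(tier == "gwas_genomewide", 1e-9, 1e-3)
    frame = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "effect_allele": [s.effect_allele for s in g.snps],
            "weight": truth.snp_effects,
            "source_p": source_p,
            "source_tier": tier,
        }
    )
    return WeightTable(frame)
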