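"""Core containers for the MR pipeline.

The pipeline moves individual-level data (genotype dosages, phenotypes)
through per-SNP association summaries into instrument-level causal
estimates.  Each container validates its own invariants on construction so
that downstream code can assume them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpMeta",
    "GenotypeMatrix",
    "PhenotypeTable",
    "WeightTable",
    "SnpAssoc",
    "QcReport",
    "GrsSpec",
    "GrsResult",
    "MrEstimate",
    "PowerInput",
    "ValidationError",
    "COVARIATE_NAMES",
    "Z_95",
    "Z_90",
]

# Conventional two-sided normal quantiles used for all reported intervals.
Z_95 = 1.959964
Z_90 = 1.644854

#: Risk-factor covariates carried by a phenotype table (sex handled as 0/1).
COVARIATE_NAMES = (
    "sex", "age", "sbp", "dbp", "bmi", "glucose", "hba1c", "tg", "hdl", "ldl",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates a stated invariant."""


@dataclass(frozen=True)
class SnpMeta:
    """Per-variant metadata: alleles, minor-allele frequency, imputation INFO.

    ``effect_allele`` is the counted allele of the dosage column; ``maf`` is
    the minor-allele frequency (in [0, 0.5] by definition); ``info`` is the
    post-imputation quality score, absent for directly genotyped variants.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    info: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.snp_id}: effect and other allele are identical"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")
        if self.info is not None and not (0.0 <= self.info <= 1.0):
            raise ValidationError(f"{self.snp_id}: INFO {self.info} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """n_subjects x n_snps additive dosage matrix with per-SNP metadata.

    Dosages count copies of each SNP's effect allele and live in [0, 2].
    """

    dosages: np.ndarray
    snps: list[SnpMeta]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length does not match dosage rows")
        if len(self.snps) != m:
            raise ValidationError("snps length does not match dosage columns")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValidationError("duplicate snp ids")
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValidationError("dosage outside [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from the dosage columns."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the given order; unknown ids raise."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise ValidationError(f"SNPs absent from genotype matrix: {missing}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            snps=[self.snps[i] for i in cols],
            subject_ids=list(self.subject_ids),
        )

    def flipped(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Return a copy with the listed SNPs recoded to the opposite allele
        (dosage -> 2 - dosage, alleles swapped)."""
        flip = set(snp_ids)
        dos = self.dosages.copy()
        snps = []
        for j, s in enumerate(self.snps):
            if s.snp_id in flip:
                dos[:, j] = 2.0 - dos[:, j]
                snps.append(
                    dataclasses.replace(
                        s, effect_allele=s.other_allele, other_allele=s.effect_allele
                    )
                )
            else:
                snps.append(s)
        return GenotypeMatrix(dos, snps, list(self.subject_ids))


class PhenotypeTable:
    """Per-subject exposure (plasma adiponectin), outcome (retinopathy status)
    and risk-factor covariates.

    The exposure used by every analysis is ``apn_z``: natural-log adiponectin
    standardized to mean 0, variance 1 (sample SD, n-1 denominator) over
    subjects with a non-missing measurement.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"subject_id", "apn_raw", "dr"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        if frame["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject ids in phenotype table")
        apn = frame["apn_raw"].to_numpy(dtype=float)
        ok = ~np.isnan(apn)
        if np.any(apn[ok] <= 0):
            raise ValidationError("adiponectin must be positive (pg/mL scale)")
        dr = frame["dr"].to_numpy()
        dr_ok = pd.Series(dr).dropna()
        if not set(np.unique(dr_ok.astype(float))) <= {0.0, 1.0}:
            raise ValidationError("dr status must be 0, 1 or missing")
        frame = frame.copy()
        if "apn_z" not in frame.columns:
            ln = np.full_like(apn, np.nan)
            ln[ok] = np.log(apn[ok])
            sd = np.std(ln[ok], ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValidationError("zero variance exposure")
            frame["apn_z"] = (ln - np.nanmean(ln[ok])) / sd
        self.frame = frame

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].astype(str).tolist()

    @property
    def apn_z(self) -> np.ndarray:
        return self.frame["apn_z"].to_numpy(dtype=float)

    @property
    def dr(self) -> np.ndarray:
        return self.frame["dr"].to_numpy(dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise ValidationError(f"unknown covariate {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)


@dataclass
class WeightTable:
    """External per-allele effects on log-adiponectin used as GRS weights.

    ``source_tier`` marks whether the source association reached genome-wide
    significance (p < 5e-8), the criterion for the restricted score.
    """

    frame: pd.DataFrame  # snp_id, effect_allele, weight, source_p, source_tier

    def __post_init__(self) -> None:
        req = {"snp_id", "effect_allele", "weight", "source_p", "source_tier"}
        missing = req - set(self.frame.columns)
        if missing:
            raise ValidationError(f"weight table missing columns: {sorted(missing)}")
        w = self.frame["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite GRS weight")
        p = self.frame["source_p"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValidationError("source p-values must lie in (0, 1]")


@dataclass
class SnpAssoc:
    """Per-SNP association summaries for the exposure and outcome legs.

    ``beta_exposure`` is SD of log-adiponectin per effect allele (linear
    model); ``beta_outcome`` is the log odds ratio of retinopathy per effect
    allele (logistic model).  ``f_stat`` and ``r2`` diagnose instrument
    strength on the exposure leg.
    """

    snp_id: str
    beta_exposure: Optional[float] = None
    se_exposure: Optional[float] = None
    p_exposure: Optional[float] = None
    beta_outcome: Optional[float] = None
    se_outcome: Optional[float] = None
    p_outcome: Optional[float] = None
    n_used: Optional[int] = None
    f_stat: Optional[float] = None
    r2: Optional[float] = None
    reason_absent: Optional[str] = None

    def __post_init__(self) -> None:
        for se in (self.se_exposure, self.se_outcome):
            if se is not None and se <= 0:
                raise ValidationError(f"{self.snp_id}: non-positive SE")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"{self.snp_id}: R2 outside [0, 1]")


@dataclass
class QcReport:
    """Counts and per-SNP reasons from the variant QC step.

    A SNP failing both filters is counted once, as a MAF failure.
    """

    n_input: int
    n_fail_maf: int
    n_fail_info: int
    n_pass: int
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_fail_maf + self.n_fail_info + self.n_pass:
            raise ValidationError("QC counts do not partition the input")


@dataclass
class GrsSpec:
    """A named genetic risk score: SNP set, aligned per-allele weights, and
    the rule that selected the set."""

    name: str
    snp_ids: list[str]
    weights: np.ndarray
    selection_rule: str = "all"  # all | gwas_significant | internally_significant

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError(f"GRS {self.name}: duplicate snp ids")
        if len(self.snp_ids) != len(self.weights):
            raise ValidationError(f"GRS {self.name}: weights misaligned")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError(f"GRS {self.name}: non-finite weight")


@dataclass
class GrsResult:
    """A built score plus its exposure-leg diagnostics.

    ``scores_z`` is the per-subject score standardized to SD units, so
    ``beta_apn`` reads as SD log-adiponectin per SD of the score.
    """

    spec: GrsSpec
    scores_z: np.ndarray
    beta_apn: Optional[float] = None
    se: Optional[float] = None
    p: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    f_stat: Optional[float] = None
    r2: Optional[float] = None


class MrEstimate:
    """A method-tagged causal estimate on the log-OR-per-SD-exposure scale.

    Confidence intervals, the two-sided p-value and the odds ratio are all
    derived from (beta, se) under a normal approximation, except that a
    caller may supply its own p (e.g. a t-based Egger p-value).
    """

    __slots__ = ("method", "beta", "se", "ci95", "ci90", "p", "or_", "n_snps")

    METHODS = {
        "wald", "ivw", "grs_two_stage", "egger_slope", "egger_intercept",
        "weighted_median",
    }

    def __init__(self, method: str, beta: float, se: float, n_snps: int,
                 p: Optional[float] = None):
        if method not in self.METHODS:
            raise ValidationError(f"unknown MR method {method!r}")
        if se < 0 or not np.isfinite(se):
            raise ValidationError("SE must be finite and non-negative")
        self.method = method
        self.beta = float(beta)
        self.se = float(se)
        self.n_snps = int(n_snps)
        self.ci95 = (self.beta - Z_95 * self.se, self.beta + Z_95 * self.se)
        self.ci90 = (self.beta - Z_90 * self.se, self.beta + Z_90 * self.se)
        if p is not None:
            self.p = float(p)
        elif se == 0:
            self.p = 0.0 if beta != 0 else 1.0
        else:
            self.p = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        self.or_ = math.exp(self.beta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MrEstimate({self.method}, beta={self.beta:.4f}, se={self.se:.4f}, "
            f"p={self.p:.3g}, n_snps={self.n_snps})"
        )


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the asymptotic binary-outcome MR power approximation."""

    n: int
    r2_xz: float
    or_per_sd: float
    case_fraction: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("r2_xz", "case_fraction", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValidationError("or_per_sd must be positive")
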