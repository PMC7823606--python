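"""Variant QC and per-SNP association estimation.

Exposure leg: ordinary least squares of standardized log-adiponectin on the
additive dosage (optionally with covariates).  Outcome leg: logistic
regression of retinopathy status on the dosage, fit by Newton/IRLS to a
score-norm tolerance of 1e-8 (50 iterations max); a coefficient escaping
|beta| > 20 during iteration is flagged as separation and the estimate
marked absent.  Instrument strength uses the single-predictor identities
F = (beta/se)^2 and R2 = F / (F + n - 2).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .datatypes import GenotypeMatrix, PhenotypeTable, QcReport, SnpAssoc, ValidationError

__all__ = [
    "apply_variant_qc",
    "snp_exposure_assoc",
    "snp_outcome_assoc",
    "instrument_strength",
    "ols_assoc",
    "logistic_fit",
    "SeparationError",
]


class SeparationError(RuntimeError):
    """Quasi-complete separation detected during logistic iteration."""


def apply_variant_qc(g: GenotypeMatrix, maf_min: float = 0.005,
                     info_min: float = 0.4) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants with MAF < maf_min, or with INFO present and < info_min.

    Exclusion is strictly below threshold (a variant exactly at the cut is
    kept).  Variants without an INFO score pass the INFO test (directly
    genotyped).  A variant failing both filters is reported once, as a MAF
    failure.  An empty result is allowed and flagged in the report.
    """
    keep, reasons = [], {}
    n_maf = n_info = 0
    for j, s in enumerate(g.snps):
        if s.maf < maf_min:
            n_maf += 1
            reasons[s.snp_id] = f"maf {s.maf:.4g} < {maf_min:g}"
        elif s.info is not None and s.info < info_min:
            n_info += 1
            reasons[s.snp_id] = f"info {s.info:.4g} < {info_min:g}"
        else:
            keep.append(j)
    report = QcReport(
        n_input=g.n_snps, n_fail_maf=n_maf, n_fail_info=n_info,
        n_pass=len(keep), reasons=reasons,
    )
    filtered = GenotypeMatrix(
        g.dosages[:, keep], [g.snps[j] for j in keep], list(g.subject_ids)
    )
    return filtered, report


def ols_assoc(x: np.ndarray, y: np.ndarray,
              covariates: Optional[np.ndarray] = None) -> tuple[float, float, float, float]:
    """OLS of y on x (plus optional covariate columns), intercept included.

    Returns (beta_x, se_x, p_x, partial_r2_x).  Without covariates the
    partial R2 is the squared Pearson correlation.  p is two-sided from the
    t distribution with n - k - 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is None:
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = xc @ xc
        if sxx == 0:
            raise ValidationError("degenerate (constant) predictor")
        beta = (xc @ yc) / sxx
        resid = yc - beta * xc
        df = n - 2
        sigma2 = (resid @ resid) / df
        se = np.sqrt(sigma2 / sxx)
        syy = yc @ yc
        r2 = (xc @ yc) ** 2 / (sxx * syy) if syy > 0 else 0.0
    else:
        X = np.column_stack([np.ones(n), x, covariates])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("singular design matrix") from exc
        coef = XtX_inv @ (X.T @ y)
        resid = y - X @ coef
        df = n - X.shape[1]
        sigma2 = (resid @ resid) / df
        beta = coef[1]
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        # partial R2 of the dosage term: t^2 / (t^2 + df)
        t2 = (beta / se) ** 2
        r2 = t2 / (t2 + df)
    if se == 0:
        p = 0.0 if beta != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(beta / se), df)
    return float(beta), float(se), float(p), float(min(r2, 1.0))


def logistic_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    X must include its intercept column.  Converged when the score norm
    drops below ``tol``; raises SeparationError when any coefficient
    escapes |beta| > 20 while iterating (quasi-complete separation), and
    RuntimeError when 50 iterations pass without convergence.
    Returns (coefficients, standard errors from the observed information).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            break
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.any(np.abs(beta) > 20):
            raise SeparationError("coefficient diverged (|beta| > 20)")
    else:
        raise RuntimeError("logistic IRLS failed to converge in 50 iterations")
    mu = expit(X @ beta)
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def _aligned(g: GenotypeMatrix, ph: PhenotypeTable) -> None:
    if g.subject_ids != ph.subject_ids:
        raise ValidationError("genotype and phenotype subject ids do not align")


def snp_exposure_assoc(g: GenotypeMatrix, ph: PhenotypeTable,
                       covariate_names: Sequence[str] = (),
                       model: str = "base") -> list[SnpAssoc]:
    """Per-SNP additive-model regression of apn_z on dosage.

    ``model='base'`` is unadjusted; ``model='adjusted'`` adds the named
    covariates.  Monomorphic SNPs are returned with the estimate absent and
    a reason recorded.
    """
    if model not in ("base", "adjusted"):
        raise ValidationError("model must be 'base' or 'adjusted'")
    _aligned(g, ph)
    y = ph.apn_z
    ok = ~np.isnan(y)
    covs = None
    if model == "adjusted":
        covs = np.column_stack([ph.covariate(c) for c in covariate_names])
        ok &= ~np.isnan(covs).any(axis=1)
    n_used = int(ok.sum())
    k = 0 if covs is None else covs.shape[1]
    if n_used < 10 + k:
        raise ValidationError(f"too few complete observations (n={n_used})")
    if np.std(y[ok], ddof=1) == 0:
        raise ValidationError("zero variance exposure")
    out = []
    for j, s in enumerate(g.snps):
        x = g.dosages[ok, j]
        if np.ptp(x) == 0:
            out.append(SnpAssoc(snp_id=s.snp_id, n_used=n_used,
                                reason_absent="monomorphic"))
            continue
        beta, se, p, r2 = ols_assoc(x, y[ok], None if covs is None else covs[ok])
        f = (beta / se) ** 2 if se > 0 else np.inf
        out.append(SnpAssoc(snp_id=s.snp_id, beta_exposure=beta, se_exposure=se,
                            p_exposure=p, n_used=n_used, f_stat=float(f), r2=r2))
    return out


def snp_outcome_assoc(g: GenotypeMatrix, ph: PhenotypeTable) -> list[SnpAssoc]:
    """Per-SNP logistic regression of retinopathy status on dosage.

    Returns log-OR per effect allele with Wald SE and two-sided normal p.
    Requires at least 5 subjects in each outcome class.  Separation marks
    the estimate absent rather than failing the run.
    """
    _aligned(g, ph)
    y = ph.dr
    ok = ~np.isnan(y)
    y = y[ok]
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 < 5 or n1 < 5:
        raise ValidationError(
            f"need >= 5 subjects per outcome class (got {n0} controls, {n1} cases)"
        )
    ones = np.ones(len(y))
    out = []
    for j, s in enumerate(g.snps):
        x = g.dosages[ok, j]
        if np.ptp(x) == 0:
            out.append(SnpAssoc(snp_id=s.snp_id, n_used=len(y),
                                reason_absent="monomorphic"))
            continue
        try:
            coef, se = logistic_fit(np.column_stack([ones, x]), y)
        except SeparationError as exc:
            out.append(SnpAssoc(snp_id=s.snp_id, n_used=len(y),
                                reason_absent=f"separation: {exc}"))
            continue
        z = coef[1] / se[1]
        out.append(SnpAssoc(
            snp_id=s.snp_id, beta_outcome=float(coef[1]), se_outcome=float(se[1]),
            p_outcome=float(2.0 * stats.norm.sf(abs(z))), n_used=len(y),
        ))
    return out


def merge_assoc(exposure: list[SnpAssoc], outcome: list[SnpAssoc]) -> list[SnpAssoc]:
    """Join exposure- and outcome-leg summaries on snp_id (outer on exposure)."""
    by_id = {a.snp_id: a for a in outcome}
    merged = []
    for e in exposure:
        o = by_id.get(e.snp_id)
        if o is None:
            merged.append(e)
            continue
        reason = e.reason_absent or o.reason_absent
        merged.append(dataclasses.replace(
            e, beta_outcome=o.beta_outcome, se_outcome=o.se_outcome,
            p_outcome=o.p_outcome, reason_absent=reason,
        ))
    return merged


def instrument_strength(sa: SnpAssoc, n: int) -> tuple[float, float, bool]:
    """F-statistic, variance explained, and the conventional strength call.

    F = (beta/se)^2; R2 = F/(F + n - 2); strong means strictly F > 10
    (F = 10 exactly is classified weak).
    """
    if sa.beta_exposure is None or sa.se_exposure is None:
        raise ValidationError(f"{sa.snp_id}: exposure estimate absent")
    f = (sa.beta_exposure / sa.se_exposure) ** 2
    r2 = f / (f + n - 2)
    return float(f), float(r2), bool(f > 10.0)
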