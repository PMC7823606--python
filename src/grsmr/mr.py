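"""Causal estimation and sensitivity analysis.

All estimates are on the scale of log odds of retinopathy per SD increase
in genetically determined log-adiponectin.  The single-instrument Wald
ratio is the outcome association divided by the exposure association;
multiple instruments are combined by fixed-effect inverse-variance
weighting, with MR-Egger regression (free intercept = average directional
pleiotropy) and the weighted-median estimator as sensitivity analyses.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    GrsResult,
    MrEstimate,
    PhenotypeTable,
    PowerInput,
    SnpAssoc,
    ValidationError,
    Z_95,
)
from .qc_assoc import logistic_fit, ols_assoc

__all__ = [
    "wald_ratio",
    "ivw",
    "grs_two_stage",
    "mr_egger",
    "weighted_median",
    "confounder_scan",
    "mr_power",
]


def _require_legs(sa: SnpAssoc) -> None:
    if sa.beta_exposure is None or sa.beta_outcome is None:
        raise ValidationError(f"{sa.snp_id}: both legs required for a ratio")
    if sa.beta_exposure == 0:
        raise ValidationError(f"{sa.snp_id}: zero exposure effect, ratio undefined")


def wald_ratio(sa: SnpAssoc, second_order: bool = False) -> MrEstimate:
    """Single-instrument causal estimate: beta_outcome / beta_exposure.

    First-order delta-method SE is se_outcome/|beta_exposure|; the
    second-order form adds the exposure leg's uncertainty,
    sqrt(se_o^2/b_e^2 + b_o^2 se_e^2 / b_e^4).
    """
    _require_legs(sa)
    be, bo = sa.beta_exposure, sa.beta_outcome
    beta = bo / be
    if second_order:
        if sa.se_exposure is None:
            raise ValidationError(f"{sa.snp_id}: second-order SE needs se_exposure")
        se = math.sqrt(sa.se_outcome ** 2 / be ** 2
                       + bo ** 2 * sa.se_exposure ** 2 / be ** 4)
    else:
        se = sa.se_outcome / abs(be)
    return MrEstimate("wald", beta, se, n_snps=1)


def _ratios(estimates: Sequence[SnpAssoc]) -> tuple[np.ndarray, np.ndarray]:
    betas, ses = [], []
    for sa in estimates:
        _require_legs(sa)
        betas.append(sa.beta_outcome / sa.beta_exposure)
        ses.append(sa.se_outcome / abs(sa.beta_exposure))
    return np.asarray(betas), np.asarray(ses)


def ivw(estimates: Sequence[SnpAssoc], random_effects: bool = False) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    Weights are 1/se_i^2 of each first-order ratio.  With
    ``random_effects`` the SE is inflated multiplicatively by
    max(1, sqrt(Q/(k-1))), Q being Cochran's heterogeneity statistic.
    """
    if not estimates:
        raise ValidationError("IVW needs at least one usable ratio")
    b, s = _ratios(estimates)
    w = 1.0 / s ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    k = len(b)
    if random_effects and k > 1:
        q = float(np.sum(w * (b - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (k - 1)))
    return MrEstimate("ivw", beta, se, n_snps=k)


def grs_two_stage(exp_leg: GrsResult, out_leg: tuple[float, float],
                  include_exposure_uncertainty: bool = False) -> MrEstimate:
    """Causal estimate with a risk score as the single composite instrument.

    beta = (log-OR per SD score) / (SD exposure per SD score); first-order
    delta SE by default, optionally including the exposure leg's variance.
    """
    if exp_leg.beta_apn is None:
        raise ValidationError("exposure leg not fitted; run grs_exposure_assoc first")
    if exp_leg.beta_apn == 0:
        raise ValidationError("zero exposure-leg coefficient, ratio undefined")
    bo, so = out_leg
    be = exp_leg.beta_apn
    beta = bo / be
    if include_exposure_uncertainty:
        se = math.sqrt(so ** 2 / be ** 2 + bo ** 2 * exp_leg.se ** 2 / be ** 4)
    else:
        se = so / abs(be)
    return MrEstimate("grs_two_stage", beta, se,
                      n_snps=len(exp_leg.spec.snp_ids))


def mr_egger(estimates: Sequence[SnpAssoc],
             force_zero_intercept: bool = False
             ) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger: weighted regression of outcome effects on exposure effects
    with a free intercept.

    Each SNP is oriented so its exposure effect is positive (both legs'
    signs flipped when negative; exactly-zero exposure effects are
    excluded).  Weights are 1/se_outcome^2.  SEs carry a multiplicative
    overdispersion factor max(1, sqrt(weighted RSS/(k-2))) and p-values use
    the t distribution with k-2 df.  The slope estimates the causal effect;
    the intercept, the average directional pleiotropy.  The
    ``force_zero_intercept`` mode drops the intercept (then the slope is
    algebraically the IVW estimate; internal cross-check only).
    """
    usable = [sa for sa in estimates
              if sa.beta_exposure not in (None, 0) and sa.beta_outcome is not None]
    if len(usable) < 3:
        raise ValidationError("MR-Egger needs at least 3 instruments")
    be = np.array([sa.beta_exposure for sa in usable])
    bo = np.array([sa.beta_outcome for sa in usable])
    so = np.array([sa.se_outcome for sa in usable])
    flip = np.sign(be)
    be, bo = be * flip, bo * flip
    w = 1.0 / so ** 2
    k = len(be)

    if force_zero_intercept:
        slope = float(np.sum(w * be * bo) / np.sum(w * be ** 2))
        se = float(1.0 / math.sqrt(np.sum(w * be ** 2)))
        return (MrEstimate("egger_slope", slope, se, n_snps=k),
                MrEstimate("egger_intercept", 0.0, 0.0, n_snps=k, p=1.0))

    X = np.column_stack([np.ones(k), be])
    XtWX = (X * w[:, None]).T @ X
    try:
        cov_unscaled = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("degenerate exposure effects in Egger fit") from exc
    coef = cov_unscaled @ ((X * w[:, None]).T @ bo)
    resid = bo - X @ coef
    df = k - 2
    scale = max(1.0, math.sqrt(float(np.sum(w * resid ** 2)) / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    p = 2.0 * stats.t.sf(np.abs(coef / ses), df) if df > 0 else np.array([np.nan] * 2)
    slope = MrEstimate("egger_slope", coef[1], ses[1], n_snps=k, p=float(p[1]))
    intercept = MrEstimate("egger_intercept", coef[0], ses[0], n_snps=k, p=float(p[0]))
    return slope, intercept


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: order the ratios, place each at
    standardized cumulative weight (cumsum(w) - w/2)/sum(w), and linearly
    interpolate across 0.5."""
    order = np.argsort(b)
    b, w = b[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def weighted_median(estimates: Sequence[SnpAssoc], n_boot: int = 1000,
                    seed: int = 0) -> MrEstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Consistent when instruments carrying at least half the inverse-variance
    weight are valid.  The SE is the SD of the estimate over ``n_boot``
    replicates in which both legs are resampled from their fitted normals
    and ratios and weights recomputed.
    """
    if len(estimates) < 3:
        raise ValidationError("weighted median needs at least 3 instruments")
    b, s = _ratios(estimates)
    w = 1.0 / s ** 2
    point = _weighted_median_point(b, w)

    be = np.array([sa.beta_exposure for sa in estimates])
    se_e = np.array([sa.se_exposure for sa in estimates])
    bo = np.array([sa.beta_outcome for sa in estimates])
    se_o = np.array([sa.se_outcome for sa in estimates])
    rng = np.random.default_rng(seed)
    k = len(estimates)
    be_b = be + se_e * rng.standard_normal((n_boot, k))
    bo_b = bo + se_o * rng.standard_normal((n_boot, k))
    be_b = np.where(be_b == 0, 1e-300, be_b)
    ratios = bo_b / be_b
    weights = (be_b / se_o) ** 2
    boots = np.fromiter(
        (_weighted_median_point(ratios[i], weights[i]) for i in range(n_boot)),
        dtype=float, count=n_boot,
    )
    se = float(np.std(boots, ddof=1))
    return MrEstimate("weighted_median", point, se, n_snps=k)


def confounder_scan(grs: GrsResult, ph: PhenotypeTable,
                    traits: Sequence[str]) -> dict[str, tuple[float, float, float]]:
    """Association of the score with each candidate confounding trait.

    Continuous traits: OLS of the trait on scores_z.  Sex: logistic
    regression.  p-values are unadjusted two-sided, reported as-is with no
    multiplicity correction.  Returns {trait: (beta, se, p)}.
    """
    out = {}
    for trait in traits:
        y = ph.covariate(trait)  # raises on unknown trait
        ok = ~np.isnan(y)
        x = grs.scores_z[ok]
        yv = y[ok]
        if trait == "sex":
            coef, se = logistic_fit(np.column_stack([np.ones(len(yv)), x]), yv)
            z = coef[1] / se[1]
            out[trait] = (float(coef[1]), float(se[1]),
                          float(2.0 * stats.norm.sf(abs(z))))
        else:
            beta, se, p, _ = ols_assoc(x, yv)
            out[trait] = (beta, se, p)
    return out


def mr_power(pi: PowerInput) -> float:
    """Asymptotic power of the MR test with a binary outcome.

    power = Phi( sqrt(n * R2_xz * cf * (1 - cf)) * |ln OR| - z_{1-alpha/2} ),
    one published approximation among several; a null OR of 1 returns the
    alpha/2 tail, and power tends to 1 as n grows for any OR != 1.
    """
    z_crit = stats.norm.ppf(1.0 - pi.alpha / 2.0)
    ncp = math.sqrt(pi.n * pi.r2_xz * pi.case_fraction * (1.0 - pi.case_fraction))
    return float(stats.norm.cdf(ncp * abs(math.log(pi.or_per_sd)) - z_crit))
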