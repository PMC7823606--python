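"""Variant QC and association legs, cross-checked against statsmodels
oracles and closed-form identities."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import genotypes_from_array, make_snp, phenotypes_from_arrays
from grsmr.datatypes import GenotypeMatrix, SnpAssoc, ValidationError
from grsmr.qc_assoc import (
    apply_variant_qc,
    instrument_strength,
    logistic_fit,
    merge_assoc,
    ols_assoc,
    snp_exposure_assoc,
    snp_outcome_assoc,
)


class TestVariantQc:
    def test_maf_threshold_is_strict_below(self):
        mafs = [0.004, 0.005, 0.3, 0.49, 0.001]
        g = genotypes_from_array(np.ones((12, 5)), mafs=mafs)
        kept, report = apply_variant_qc(g, maf_min=0.005)
        assert report.n_pass == 3 and report.n_fail_maf == 2
        assert kept.snp_ids == ["rs002", "rs003", "rs004"]

    def test_info_threshold_applies_when_present(self):
        g = genotypes_from_array(np.ones((12, 2)), mafs=[0.3, 0.3],
                                 infos=[0.39, None])
        kept, report = apply_variant_qc(g)
        assert report.n_fail_info == 1 and kept.snp_ids == ["rs002"]

    def test_fail_both_counted_as_maf(self):
        g = genotypes_from_array(np.ones((12, 1)), mafs=[0.001], infos=[0.1])
        _, report = apply_variant_qc(g)
        assert report.n_fail_maf == 1 and report.n_fail_info == 0

    def test_no_thresholds_is_identity(self):
        g = genotypes_from_array(np.ones((12, 3)), mafs=[0.1, 0.2, 0.3])
        kept, report = apply_variant_qc(g, maf_min=0.0)
        assert kept.snp_ids == g.snp_ids and report.n_pass == 3

    def test_idempotent(self, rng):
        mafs = list(rng.uniform(0.001, 0.5, 8))
        g = genotypes_from_array(np.ones((12, 8)), mafs=mafs)
        once, _ = apply_variant_qc(g)
        twice, rep2 = apply_variant_qc(once)
        assert once.snp_ids == twice.snp_ids
        assert rep2.n_fail_maf == rep2.n_fail_info == 0


class TestExposureAssoc:
    def test_perfect_fit(self, rng):
        d = rng.binomial(2, 0.3, 200).astype(float)
        z = (d - d.mean()) / d.std(ddof=1)
        apn = np.exp(z)  # ln(apn) standardized == standardized dosage
        ph = phenotypes_from_arrays(apn, np.zeros(200))
        (a,) = snp_exposure_assoc(genotypes_from_array(d[:, None]), ph)
        assert a.r2 == pytest.approx(1.0, abs=1e-12)
        assert a.beta_exposure * d.std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        assert a.p_exposure < 1e-100

    def test_matches_statsmodels_base_and_adjusted(self, small_cohort):
        g, ph = small_cohort
        age = np.linspace(40, 70, g.n_subjects)
        ph.frame["age"] = age
        base = snp_exposure_assoc(g, ph)
        adj = snp_exposure_assoc(g, ph, covariate_names=["age"], model="adjusted")
        for j in range(g.n_snps):
            X = sm.add_constant(g.dosages[:, j])
            fit = sm.OLS(ph.apn_z, X).fit()
            assert base[j].beta_exposure == pytest.approx(fit.params[1], rel=1e-9)
            assert base[j].se_exposure == pytest.approx(fit.bse[1], rel=1e-9)
            assert base[j].p_exposure == pytest.approx(fit.pvalues[1], rel=1e-6)
            Xa = sm.add_constant(np.column_stack([g.dosages[:, j], age]))
            fita = sm.OLS(ph.apn_z, Xa).fit()
            assert adj[j].beta_exposure == pytest.approx(fita.params[1], rel=1e-9)
            assert adj[j].se_exposure == pytest.approx(fita.bse[1], rel=1e-9)

    def test_monomorphic_snp_marked_absent(self):
        d = np.column_stack([np.full(50, 2.0), np.r_[np.zeros(25), np.ones(25)]])
        ph = phenotypes_from_arrays(np.exp(np.linspace(-1, 1, 50)), np.zeros(50))
        out = snp_exposure_assoc(genotypes_from_array(d), ph)
        assert out[0].reason_absent == "monomorphic"
        assert out[1].beta_exposure is not None

    def test_permutation_null_p_uniform(self, rng):
        """Under permuted dosages, exposure p-values are U(0,1)."""
        n = 1000
        d = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal(n)
        ph = phenotypes_from_arrays(np.exp(y), np.zeros(n))
        ps = []
        for _ in range(300):
            perm = rng.permutation(d)
            (a,) = snp_exposure_assoc(genotypes_from_array(perm[:, None]), ph)
            ps.append(a.p_exposure)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestOutcomeAssoc:
    def test_matches_statsmodels_logit_small_n(self, rng):
        n = 100
        d = rng.binomial(2, 0.4, n).astype(float)
        y = rng.binomial(1, 0.4, n).astype(float)
        ph = phenotypes_from_arrays(np.exp(rng.standard_normal(n)), y)
        (a,) = snp_outcome_assoc(genotypes_from_array(d[:, None]), ph)
        fit = sm.Logit(y, sm.add_constant(d)).fit(disp=0)
        assert a.beta_outcome == pytest.approx(fit.params[1], abs=1e-6)
        assert a.se_outcome == pytest.approx(fit.bse[1], abs=1e-6)

    def test_two_by_two_log_odds_ratio_closed_form(self):
        # carriers vs non-carriers: counts a=30 b=20 (carrier), c=25 d=45
        x = np.r_[np.ones(50), np.zeros(70)]
        y = np.r_[np.ones(30), np.zeros(20), np.ones(25), np.zeros(45)]
        ph = phenotypes_from_arrays(np.exp(np.random.default_rng(0).standard_normal(120)), y)
        (a,) = snp_outcome_assoc(genotypes_from_array(x[:, None]), ph)
        assert a.beta_outcome == pytest.approx(np.log(30 * 45 / (20 * 25)), abs=1e-6)

    def test_single_class_outcome_refused(self):
        ph = phenotypes_from_arrays(np.exp(np.linspace(-1, 1, 30)), np.zeros(30))
        g = genotypes_from_array(np.random.default_rng(1).binomial(2, 0.3, (30, 1)).astype(float))
        with pytest.raises(ValidationError, match="outcome class"):
            snp_outcome_assoc(g, ph)

    def test_separation_marked_absent(self):
        x = np.r_[np.zeros(20), np.full(20, 2.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        ph = phenotypes_from_arrays(np.exp(np.linspace(-1, 1, 40)), y)
        (a,) = snp_outcome_assoc(genotypes_from_array(x[:, None]), ph)
        assert a.beta_outcome is None
        assert "separation" in a.reason_absent

    def test_null_type_i_error_calibrated(self, rng):
        rejections = []
        for _ in range(200):
            n = 500
            d = rng.binomial(2, 0.3, n).astype(float)
            y = rng.binomial(1, 0.35, n).astype(float)
            ph = phenotypes_from_arrays(np.exp(rng.standard_normal(n)), y)
            (a,) = snp_outcome_assoc(genotypes_from_array(d[:, None]), ph)
            rejections.append(a.p_outcome < 0.05)
        assert 0.02 <= np.mean(rejections) <= 0.09


class TestInstrumentStrength:
    def test_arithmetic(self):
        sa = SnpAssoc(snp_id="rs1", beta_exposure=0.1, se_exposure=0.05)
        f, r2, strong = instrument_strength(sa, n=1000)
        assert f == pytest.approx(4.0)
        assert r2 == pytest.approx(4.0 / (4.0 + 998))
        assert not strong

    def test_strong_instrument_regime(self):
        sa = SnpAssoc(snp_id="rs1", beta_exposure=0.489898, se_exposure=0.1002)
        f, _, strong = instrument_strength(sa, n=1251)
        assert f == pytest.approx(23.9, abs=0.1) and strong

    def test_boundary_comparison_is_strict(self):
        # F equal to the threshold classifies weak; (beta/se)^2 = 9 exactly
        sa = SnpAssoc(snp_id="rs1", beta_exposure=0.3, se_exposure=0.1)
        f, _, strong = instrument_strength(sa, n=500)
        assert f == pytest.approx(9.0, abs=1e-12) and not strong
        near = SnpAssoc(snp_id="rs2", beta_exposure=np.sqrt(10), se_exposure=1.0)
        f2, _, strong2 = instrument_strength(near, n=500)
        assert strong2 == (f2 > 10.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_f_r2_t_consistency_property(seed):
    """On random small instances: F = (beta/se)^2, R2 = F/(F+n-2), and the
    t-based p all agree with a from-scratch OLS fit."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 50))
    x = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    if np.ptp(x) == 0:
        return
    y = 0.2 * x + rng.standard_normal(n)
    beta, se, p, r2 = ols_assoc(x, y)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    assert beta == pytest.approx(coef[1], rel=1e-8, abs=1e-10)
    assert se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-8)
    f = (beta / se) ** 2
    assert r2 == pytest.approx(f / (f + n - 2), abs=1e-8)
    assert p == pytest.approx(2 * stats.t.sf(np.sqrt(f), n - 2), rel=1e-8)


def test_merge_assoc_joins_on_snp_id():
    e = [SnpAssoc(snp_id="rs1", beta_exposure=0.1, se_exposure=0.05)]
    o = [SnpAssoc(snp_id="rs1", beta_outcome=0.2, se_outcome=0.1)]
    (m,) = merge_assoc(e, o)
    assert m.beta_exposure == 0.1 and m.beta_outcome == 0.2
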