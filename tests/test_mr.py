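"""Causal estimators: Wald ratio, IVW, two-stage score estimate, MR-Egger,
weighted median, confounder scan and power, against hand computations,
algebraic identities and Monte-Carlo oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import genotypes_from_array, phenotypes_from_arrays
from grsmr.datatypes import (
    GrsSpec,
    MrEstimate,
    PowerInput,
    SnpAssoc,
    ValidationError,
)
from grsmr.instruments import build_grs, grs_exposure_assoc
from grsmr.mr import (
    confounder_scan,
    grs_two_stage,
    ivw,
    mr_egger,
    mr_power,
    wald_ratio,
    weighted_median,
)


def sa(snp_id="rs1", be=0.1, se_e=0.05, bo=0.05, se_o=0.1):
    return SnpAssoc(snp_id=snp_id, beta_exposure=be, se_exposure=se_e,
                    beta_outcome=bo, se_outcome=se_o)


class TestMrEstimateContracts:
    def test_ci_arithmetic_and_or(self):
        est = MrEstimate("ivw", beta=0.61, se=0.2645, n_snps=47)
        lo95, hi95 = est.ci95
        lo90, hi90 = est.ci90
        assert lo95 == pytest.approx(0.61 - 1.959964 * 0.2645, abs=1e-9)
        assert hi90 == pytest.approx(0.61 + 1.644854 * 0.2645, abs=1e-9)
        assert lo95 < lo90 < hi90 < hi95  # 95% strictly contains 90%
        assert est.or_ == pytest.approx(np.exp(0.61), rel=1e-12)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(sa(be=0.5, bo=0.3, se_o=0.1))
        assert est.beta == pytest.approx(0.6)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_maps_to_or_one(self):
        est = wald_ratio(sa(be=0.5, bo=0.0, se_o=0.1))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_zero_exposure_beta_is_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            wald_ratio(sa(be=0.0))

    def test_second_order_se_against_monte_carlo(self, rng):
        be, se_e, bo, se_o = 0.5, 0.05, 0.3, 0.1
        est = wald_ratio(sa(be=be, se_e=se_e, bo=bo, se_o=se_o), second_order=True)
        draws = (bo + se_o * rng.standard_normal(10 ** 6)) / \
                (be + se_e * rng.standard_normal(10 ** 6))
        assert est.se == pytest.approx(np.std(draws), rel=0.02)
        assert est.se == pytest.approx(
            np.sqrt(se_o ** 2 / be ** 2 + bo ** 2 * se_e ** 2 / be ** 4), rel=1e-12)


class TestIvw:
    def test_single_snp_reduces_to_wald(self):
        one = sa(be=0.4, bo=0.24, se_o=0.12)
        assert ivw([one]).beta == pytest.approx(wald_ratio(one).beta, rel=1e-12)
        assert ivw([one]).se == pytest.approx(wald_ratio(one).se, rel=1e-12)

    def test_hand_computed_average(self):
        ests = [sa("rs1", be=1.0, bo=0.4, se_o=0.2),
                sa("rs2", be=1.0, bo=0.8, se_o=0.2)]
        est = ivw(ests)
        assert est.beta == pytest.approx(0.6)
        assert est.se == pytest.approx(0.2 / np.sqrt(2), abs=1e-4)

    def test_equals_zero_intercept_wls_slope(self, rng):
        ests = [sa(f"rs{i}", be=rng.uniform(0.05, 0.3), bo=rng.normal(0, 0.1),
                   se_o=rng.uniform(0.05, 0.2)) for i in range(20)]
        est = ivw(ests)
        be = np.array([e.beta_exposure for e in ests])
        bo = np.array([e.beta_outcome for e in ests])
        so = np.array([e.se_outcome for e in ests])
        fit = sm.WLS(bo, be[:, None], weights=1 / so ** 2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-9)

    def test_random_effects_never_shrinks_se(self, rng):
        ests = [sa(f"rs{i}", be=0.2, bo=rng.normal(0, 0.5), se_o=0.05)
                for i in range(10)]
        assert ivw(ests, random_effects=True).se >= ivw(ests).se

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            ivw([])


class TestGrsTwoStage:
    def _exp_leg(self, rng, beta=1.0):
        d = rng.binomial(2, 0.3, 500).astype(float)
        g = genotypes_from_array(d[:, None])
        grs = build_grs(g, GrsSpec("one", ["rs001"], [1.0]))
        apn = np.exp(beta * grs.scores_z + 0.1 * rng.standard_normal(500))
        ph = phenotypes_from_arrays(apn, rng.binomial(1, 0.35, 500))
        return grs_exposure_assoc(grs, ph)

    def test_published_scale_arithmetic(self):
        from grsmr.datatypes import GrsResult

        grs = GrsSpec("apn", ["rs1"], [1.0])
        leg = GrsResult(spec=grs, scores_z=np.zeros(3), beta_apn=0.09, se=0.015)
        est = grs_two_stage(leg, (0.0549, 0.03))
        assert est.beta == pytest.approx(0.61, abs=1e-9)
        assert est.se == pytest.approx(0.03 / 0.09, rel=1e-12)

    def test_unit_exposure_leg_is_identity(self, rng):
        leg = self._exp_leg(rng)
        leg.beta_apn = 1.0
        est = grs_two_stage(leg, (0.3, 0.1))
        assert est.beta == pytest.approx(0.3) and est.se == pytest.approx(0.1)

    def test_null_type_i_error(self):
        from grsmr.experiments import empirical_grs_power

        rate = empirical_grs_power(causal_beta=0.0, n_rep=300, base_seed=5)
        assert 0.02 <= rate <= 0.09


class TestMrEgger:
    def test_exact_line_recovered(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        ests = [sa(f"rs{i}", be=b, se_e=0.01, bo=0.1 + 0.5 * b, se_o=0.1)
                for i, b in enumerate(be)]
        slope, intercept = mr_egger(ests)
        assert slope.beta == pytest.approx(0.5, abs=1e-9)
        assert intercept.beta == pytest.approx(0.1, abs=1e-9)

    def test_zero_intercept_mode_equals_ivw(self, rng):
        ests = [sa(f"rs{i}", be=rng.uniform(0.05, 0.3), bo=rng.normal(0, 0.2),
                   se_o=rng.uniform(0.05, 0.2)) for i in range(15)]
        slope, _ = mr_egger(ests, force_zero_intercept=True)
        assert slope.beta == pytest.approx(ivw(ests).beta, abs=1e-9)

    def test_orientation_invariance_to_allele_coding(self):
        """Flipping an instrument's effect allele (both legs change sign)
        leaves the Egger fit unchanged."""
        ests = [sa("rs1", be=0.2, bo=0.10, se_o=0.1),
                sa("rs2", be=0.1, bo=0.04, se_o=0.1),
                sa("rs3", be=0.3, bo=0.18, se_o=0.1)]
        flipped = [sa("rs1", be=-0.2, bo=-0.10, se_o=0.1)] + ests[1:]
        s1, i1 = mr_egger(ests)
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValidationError, match="3"):
            mr_egger([sa("rs1"), sa("rs2")])


class TestWeightedMedian:
    def test_equal_weight_interpolated_median(self):
        ests = [sa("rs1", be=1.0, bo=0.1, se_o=0.1),
                sa("rs2", be=1.0, bo=0.2, se_o=0.1),
                sa("rs3", be=1.0, bo=0.9, se_o=0.1)]
        est = weighted_median(ests, n_boot=50, seed=0)
        # cumulative standardized weights (1/6, 3/6, 5/6); 0.5 hits 0.2 exactly
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_majority_weight_snp_dominates(self):
        ests = [sa("rs1", be=1.0, bo=0.5, se_o=0.02),   # ~86% of weight
                sa("rs2", be=1.0, bo=-0.3, se_o=0.1),
                sa("rs3", be=1.0, bo=0.9, se_o=0.1)]
        est = weighted_median(ests, n_boot=50, seed=0)
        assert abs(est.beta - 0.5) < 0.1

    def test_bootstrap_is_seed_deterministic(self):
        ests = [sa(f"rs{i}", be=0.2 + 0.05 * i, bo=0.05 * i, se_o=0.1)
                for i in range(5)]
        a = weighted_median(ests, n_boot=200, seed=42)
        b = weighted_median(ests, n_boot=200, seed=42)
        assert a.se == b.se


class TestConfounderScan:
    def test_trait_copied_from_score_is_detected(self, rng):
        d = rng.binomial(2, 0.3, (300, 2)).astype(float)
        g = genotypes_from_array(d)
        grs = build_grs(g, GrsSpec("s", g.snp_ids, [0.2, 0.1]))
        ph = phenotypes_from_arrays(
            np.exp(rng.standard_normal(300)), rng.binomial(1, 0.35, 300),
            hdl=grs.scores_z.copy(), sex=rng.binomial(1, 0.45, 300),
        )
        res = confounder_scan(grs, ph, ["hdl", "sex"])
        assert res["hdl"][2] < 1e-100
        assert res["sex"][2] > 1e-4  # independent binary trait

    def test_unknown_trait_rejected(self, rng, small_cohort):
        g, ph = small_cohort
        grs = build_grs(g, GrsSpec("s", g.snp_ids, np.ones(g.n_snps)))
        with pytest.raises(ValidationError, match="unknown covariate"):
            confounder_scan(grs, ph, ["not_a_trait"])

    def test_null_traits_calibrated(self, rng):
        hits, total = 0, 0
        for s in range(40):
            local = np.random.default_rng(s)
            d = local.binomial(2, 0.3, (400, 2)).astype(float)
            g = genotypes_from_array(d)
            grs = build_grs(g, GrsSpec("s", g.snp_ids, [0.2, 0.1]))
            traits = {f"t{i}": local.standard_normal(400) for i in range(5)}
            ph = phenotypes_from_arrays(
                np.exp(local.standard_normal(400)),
                local.binomial(1, 0.35, 400), **traits)
            res = confounder_scan(grs, ph, list(traits))
            hits += sum(p < 0.05 for _, _, p in res.values())
            total += len(traits)
        assert 0.02 < hits / total < 0.09


class TestPower:
    def test_null_or_gives_alpha_tail(self):
        p = mr_power(PowerInput(n=1251, r2_xz=0.05, or_per_sd=1.0,
                                case_fraction=0.35))
        assert p == pytest.approx(0.025, abs=1e-3)

    def test_power_tends_to_one_with_n(self):
        p = mr_power(PowerInput(n=10 ** 7, r2_xz=0.05, or_per_sd=1.1,
                                case_fraction=0.35))
        assert p > 0.999

    def test_formula_tracks_full_pipeline_simulation(self):
        """The asymptotic formula is checked against the empirical rejection
        rate of the score-based test at the emulated design.  The formula
        targets the conditional OR; with a logistic outcome the realized
        two-stage estimate is attenuated (non-collapsibility), so the
        formula overstates power by a few points."""
        from grsmr.experiments import empirical_grs_power

        formula = mr_power(PowerInput(n=1251, r2_xz=0.052, or_per_sd=1.84,
                                      case_fraction=438 / 1251))
        assert formula == pytest.approx(0.650, abs=0.002)
        empirical = empirical_grs_power(causal_beta=np.log(1.84),
                                        total_r2=0.052, n_rep=600, base_seed=1)
        assert empirical > 0.5
        assert abs(formula - empirical) < 0.10
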