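"""Logistic association fits: closed-form oracle, coding symmetries,
genotype-category models and the KCNQ1 mutual adjustment."""

import numpy as np
import pandas as pd
import pytest

from transrep.association import (
    build_design,
    fit_logistic,
    kcnq1_coadjusted_assoc,
    quartile_codes,
    snp_dosage_assoc,
    snp_genotype_assoc,
)
from transrep.cohort_io import AnalysisConfig, Cohort, Panel, VariantDef
from transrep.exceptions import DataError, RankError, SeparationError

from conftest import make_panel, make_spec, toy_cohort

NOCOV = AnalysisConfig(covariates=())


def two_by_two_design(case_exposed, case_unexposed, ctrl_exposed, ctrl_unexposed):
    x = np.concatenate(
        [
            np.ones(case_exposed),
            np.zeros(case_unexposed),
            np.ones(ctrl_exposed),
            np.zeros(ctrl_unexposed),
        ]
    )
    y = np.concatenate(
        [np.ones(case_exposed + case_unexposed), np.zeros(ctrl_exposed + ctrl_unexposed)]
    )
    return np.column_stack([np.ones_like(x), x]), y


class TestFitLogistic:
    def test_saturated_fit_equals_cross_product_ratio(self):
        """No-covariate logistic OR is the 2x2 cross-product ratio."""
        X, y = two_by_two_design(30, 70, 20, 80)
        fit = fit_logistic(X, y, ["const", "exposed"], ("exposed",))
        assert fit.term("exposed").or_ == pytest.approx((30 * 80) / (70 * 20), abs=1e-10)
        assert fit.converged

    def test_constant_predictor_raises_rank_error(self):
        X = np.column_stack([np.ones(40), np.ones(40)])
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(RankError, match="collinear"):
            fit_logistic(X, y, ["const", "flat"], ("flat",))

    def test_single_class_outcome_rejected(self):
        X, _ = two_by_two_design(5, 5, 5, 5)
        with pytest.raises(DataError, match="both cases and controls"):
            fit_logistic(X, np.ones(20), ["const", "exposed"])

    def test_separation_detected(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()  # exposure perfectly predicts outcome
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(SeparationError):
            fit_logistic(X, y, ["const", "exposed"], ("exposed",))

    def test_ci_brackets_or(self, effect_cohort):
        fit = snp_dosage_assoc(effect_cohort, "rs001", "PopA", NOCOV)
        t = fit.primary
        assert t.ci_low < t.or_ < t.ci_high


class TestDosageModel:
    def test_allele_flip_negates_beta_and_keeps_p(self, effect_cohort):
        fit = snp_dosage_assoc(effect_cohort, "rs002", "PopA", NOCOV)
        flipped = effect_cohort.subjects.copy()
        flipped["rs002"] = 2.0 - flipped["rs002"]
        fit_f = snp_dosage_assoc(
            Cohort(panel=effect_cohort.panel, subjects=flipped), "rs002", "PopA", NOCOV
        )
        assert fit_f.primary.beta == pytest.approx(-fit.primary.beta, abs=1e-8)
        assert fit_f.primary.wald_p == pytest.approx(fit.primary.wald_p, rel=1e-8)

    def test_monomorphic_snp_not_estimable(self, small_panel):
        rows = [{"case": i % 2, "rs001": 0.0, "rs002": 1, "rs003": i % 3}
                for i in range(60)]
        cohort = toy_cohort(small_panel, rows)
        fit = snp_dosage_assoc(cohort, "rs001", config=NOCOV)
        assert not fit.estimable and "monomorphic" in fit.reason

    def test_recovers_generative_effect(self, effect_cohort):
        for rsid in effect_cohort.panel.rsids:
            t = snp_dosage_assoc(effect_cohort, rsid, "PopA").primary
            assert abs(t.beta - np.log(1.5)) < 3.2 * t.se

    def test_independent_covariate_leaves_beta_stable(self, effect_cohort):
        bare = snp_dosage_assoc(effect_cohort, "rs001", "PopA", NOCOV).primary
        adjusted = snp_dosage_assoc(
            effect_cohort, "rs001", "PopA", AnalysisConfig(covariates=("age", "bmi", "sex"))
        ).primary
        # age/bmi/sex are independent of genotype here: no confounding shift
        assert abs(adjusted.beta - bare.beta) < 3 * abs(adjusted.se - bare.se) + 0.05


@pytest.fixture(scope="module")
def mult_cohort():
    panel = make_panel(1)
    spec = make_spec(panel, strata_names=("PopA",), n_cases=2500, n_controls=2500,
                     raf=0.4, or_gen=1.4, missing_rate=0.0, seed=31)
    from transrep.synthetic import simulate_study

    return simulate_study(spec, panel, seed=31)


class TestGenotypeModel:

    def test_hom_or_consistent_with_squared_het_or(self, mult_cohort):
        fit = snp_genotype_assoc(mult_cohort, "rs001", "PopA", NOCOV)
        het = fit.term("rs001_het")
        hom = fit.term("rs001_hom")
        # multiplicative truth: beta_hom = 2 * beta_het
        assert abs(hom.beta - 2 * het.beta) < 3 * np.hypot(hom.se, 2 * het.se)

    def test_dosage_beta_between_zero_and_hom_beta(self, mult_cohort):
        hom = snp_genotype_assoc(mult_cohort, "rs001", "PopA", NOCOV).term("rs001_hom")
        dos = snp_dosage_assoc(mult_cohort, "rs001", "PopA", NOCOV).primary
        assert 0.0 < dos.beta < hom.beta

    def test_empty_reference_class_not_estimable(self, small_panel):
        rows = [{"case": i % 2, "rs001": 1.0, "rs002": i % 2 + 1, "rs003": 1}
                for i in range(40)]
        cohort = toy_cohort(small_panel, rows)
        fit = snp_genotype_assoc(cohort, "rs001", config=NOCOV)
        assert not fit.estimable and "non-carrier" in fit.reason


class TestKCNQ1CoAdjustment:
    @staticmethod
    def _pair_panel():
        return Panel(
            [
                VariantDef("rs2237895", "11", "KCNQ1", "C", 1.11),
                VariantDef("rs2237897", "11", "KCNQ1", "C", 1.21),
            ]
        )

    def test_independent_snps_match_single_fits(self):
        panel = self._pair_panel()
        spec = make_spec(panel, strata_names=("PopA",), n_cases=2000, n_controls=2000,
                         raf=0.4, or_gen=1.2, missing_rate=0.0, seed=13)
        from transrep.synthetic import simulate_study

        cohort = simulate_study(spec, panel, seed=13)
        co = kcnq1_coadjusted_assoc(cohort, "PopA", NOCOV)
        for rsid in panel.rsids:
            single = snp_dosage_assoc(cohort, rsid, "PopA", NOCOV).primary
            assert co[rsid].primary.beta == pytest.approx(single.beta, abs=3 * single.se)

    def test_correlated_pair_inflates_se(self):
        panel = self._pair_panel()
        spec = make_spec(panel, strata_names=("PopA",), n_cases=2000, n_controls=2000,
                         raf=0.4, or_gen=1.2, missing_rate=0.0, kcnq1_ld_r=0.8, seed=14)
        from transrep.synthetic import simulate_study

        cohort = simulate_study(spec, panel, seed=14)
        co = kcnq1_coadjusted_assoc(cohort, "PopA", NOCOV)
        single = snp_dosage_assoc(cohort, "rs2237895", "PopA", NOCOV).primary
        assert co["rs2237895"].primary.se > 1.3 * single.se

    def test_near_collinear_pair_surfaces_rank_error(self, small_panel):
        rows = [{"case": i % 2, "rs001": float(i % 3), "rs002": float(i % 3), "rs003": 1}
                for i in range(60)]
        cohort = toy_cohort(small_panel, rows)
        with pytest.raises(RankError, match="collinear"):
            kcnq1_coadjusted_assoc(cohort, config=NOCOV, rsids=("rs001", "rs002"))


class TestDesignMatrix:
    def test_quartile_codes_tie_to_lower(self):
        x = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])
        codes = quartile_codes(x)
        # 3 equals the 75% cutpoint -> stays in the lower quartile
        assert list(codes) == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_complete_case_on_model_variables(self, small_panel):
        rows = [{"case": i % 2, "rs001": np.nan if i < 4 else 1.0, "rs002": 1, "rs003": 0}
                for i in range(20)]
        cohort = toy_cohort(small_panel, rows)
        X, y, names = build_design(cohort.subjects, {"rs001": cohort.subjects["rs001"]})
        assert len(y) == 16 and X.shape[0] == 16

    def test_requesting_absent_covariate_fails_loudly(self, small_cohort):
        with pytest.raises(DataError, match="education"):
            build_design(
                small_cohort.subjects,
                {"rs001": small_cohort.subjects["rs001"]},
                covariates=("age", "bmi", "sex", "education"),
            )
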