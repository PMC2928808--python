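"""Aggregate risk score: imputation arithmetic, association, quartiles and
the weighted/unweighted correlation."""

import numpy as np
import pandas as pd
import pytest

from transrep import studydata
from transrep.cohort_io import AnalysisConfig
from transrep.exceptions import DataError, ParameterError
from transrep.score import (
    ScoreConfig,
    compute_scores,
    expected_mean_score,
    quartile_assoc,
    score_assoc,
    score_correlation,
)
from transrep.synthetic import simulate_population, simulate_study

from conftest import make_panel, make_spec, toy_cohort

NOCOV = AnalysisConfig(covariates=())


class TestComputeScores:
    def test_missing_snp_contributes_twice_the_stratum_raf(self, small_panel):
        # observed rs001 dosages of the other 3 subjects: 1,0,1 -> RAF 1/3... use 4 with RAF 0.25
        rows = [
            {"case": 1, "rs001": np.nan, "rs002": 2, "rs003": 1},
            {"case": 0, "rs001": 1, "rs002": 0, "rs003": 1},
            {"case": 1, "rs001": 0, "rs002": 1, "rs003": 0},
            {"case": 0, "rs001": 0.0, "rs002": 2, "rs003": 2},
            {"case": 1, "rs001": 1.0, "rs002": 1, "rs003": 1},
        ]
        cohort = toy_cohort(small_panel, rows)
        result = compute_scores(cohort, ScoreConfig(include=tuple(small_panel.rsids)))
        # observed rs001: 1,0,0,1 -> RAF 0.25 -> imputed contribution 0.5
        assert result.raf_table.loc["PopA", "rs001"] == pytest.approx(0.25)
        assert result.scores[0] == pytest.approx(0.5 + 2 + 1)

    def test_complete_data_unweighted_scores_are_integer_sums(self, effect_cohort):
        result = compute_scores(effect_cohort, ScoreConfig(include=tuple(effect_cohort.panel.rsids)))
        expected = effect_cohort.subjects[effect_cohort.panel.rsids].sum(axis=1)
        assert np.array_equal(result.scores.to_numpy(), expected.to_numpy())
        assert np.allclose(result.scores % 1, 0)
        assert result.scores.between(0, 2 * len(effect_cohort.panel)).all()

    def test_imputation_is_exactly_mean_preserving(self, small_cohort):
        """Stratum mean of imputed scores equals 2 * sum of stratum RAFs."""
        result = compute_scores(small_cohort, ScoreConfig(include=tuple(small_cohort.panel.rsids)))
        for stratum in small_cohort.strata():
            idx = small_cohort.subjects["ethnicity"] == stratum
            expected = 2.0 * result.raf_table.loc[stratum].sum()
            assert result.scores[idx].mean() == pytest.approx(expected, abs=1e-9)

    def test_complete_case_mode_leaves_nan(self, small_cohort):
        result = compute_scores(
            small_cohort,
            ScoreConfig(include=tuple(small_cohort.panel.rsids), imputation="complete_case"),
        )
        has_missing = small_cohort.subjects[small_cohort.panel.rsids].isna().any(axis=1)
        assert result.scores[has_missing].isna().all()
        assert result.scores[~has_missing].notna().all()

    def test_all_missing_snp_in_stratum_raises(self, small_panel):
        rows = [{"case": i % 2, "rs001": np.nan, "rs002": 1, "rs003": 1} for i in range(6)]
        with pytest.raises(DataError, match="rs001"):
            compute_scores(toy_cohort(small_panel, rows), ScoreConfig(include=tuple(small_panel.rsids)))


class TestExpectedMeanScore:
    def test_half_frequency_panel_gives_snp_count(self):
        assert expected_mean_score([0.5] * 18) == pytest.approx(18.0)

    def test_raf_bounds_enforced(self):
        with pytest.raises(ParameterError):
            expected_mean_score([0.5, 1.2])

    def test_simulated_stratum_mean_matches_reconstruction(self):
        """A prospective draw at the published European-American RAFs has
        mean score 2*sum(RAF) within Monte-Carlo error."""
        panel = studydata.default_panel()
        rafs = studydata.raf_table()["EuropeanAmerican"]
        from transrep.synthetic import SimulationSpec, StratumSpec

        spec = SimulationSpec(
            strata=[
                StratumSpec("EuropeanAmerican", 100, 100,
                            raf=rafs.to_dict(),
                            or_gen={r: 1.0 for r in panel.rsids})
            ],
            missing_rate=0.0,
            seed=2,
        )
        pool = simulate_population(spec, spec.strata[0], 6000, np.random.default_rng(2))
        score = pool[panel.score_rsids].sum(axis=1)
        expected = expected_mean_score(rafs[panel.score_rsids])
        assert expected == pytest.approx(18.78, abs=1e-9)
        assert abs(score.mean() - expected) < 3 * score.std() / np.sqrt(len(score))


class TestScoreAssoc:
    def test_shift_invariance(self, effect_cohort):
        result = compute_scores(effect_cohort, ScoreConfig(include=tuple(effect_cohort.panel.rsids)))
        fit = score_assoc(effect_cohort, result, "PopA", NOCOV)
        shifted = result
        shifted.scores = result.scores + 7.0
        fit_shift = score_assoc(effect_cohort, shifted, "PopA", NOCOV)
        assert fit_shift.primary.beta == pytest.approx(fit.primary.beta, abs=1e-9)

    def test_effect_cohort_score_or_positive(self, effect_cohort):
        result = compute_scores(effect_cohort, ScoreConfig(include=tuple(effect_cohort.panel.rsids)))
        t = score_assoc(effect_cohort, result, "PopA").primary
        assert t.or_ > 1.2 and t.wald_p < 1e-6  # three OR-1.5 SNPs


class TestQuartiles:
    def _uniform_cohort(self, small_panel):
        rows = []
        for score_val in range(1, 9):
            for i in range(40):
                rows.append(
                    {"case": i % 2, "rs001": 1, "rs002": 1, "rs003": 1, "score": score_val}
                )
        return toy_cohort(small_panel, rows)

    def test_balanced_case_fraction_gives_null_quartile_ors(self, small_panel):
        cohort = self._uniform_cohort(small_panel)
        result = compute_scores(cohort, ScoreConfig(include=tuple(small_panel.rsids)))
        result.scores = cohort.subjects["score"].astype(float)
        fit = quartile_assoc(cohort, result, "PopA", NOCOV)
        for q in (2, 3, 4):
            assert abs(fit.term(f"score_q{q}").beta) < 1e-6

    def test_boundary_tie_goes_to_lower_quartile(self, small_cohort):
        result = compute_scores(small_cohort)
        stratum = small_cohort.strata()[0]
        idx = small_cohort.subjects["ethnicity"] == stratum
        scores = result.scores[idx]
        cut = np.quantile(scores, [0.25, 0.5, 0.75])
        on_cut = scores[np.isclose(scores, cut[1])]
        if len(on_cut):  # deterministic for the fixed seed
            assert (result.quartiles[on_cut.index] == 2).all()

    def test_degenerate_distribution_rejected(self, small_panel):
        rows = [{"case": i % 2, "rs001": 1, "rs002": 1, "rs003": 1} for i in range(40)]
        cohort = toy_cohort(small_panel, rows)
        result = compute_scores(cohort, ScoreConfig(include=tuple(small_panel.rsids)))
        with pytest.raises(DataError, match="distinct"):
            quartile_assoc(cohort, result, "PopA", NOCOV)

    def test_monotone_quartile_trend_under_additive_risk(self):
        panel = make_panel(8)
        spec = make_spec(panel, strata_names=("PopA",), n_cases=1500, n_controls=1500,
                         raf=0.4, or_gen=1.25, missing_rate=0.0, seed=19)
        cohort = simulate_study(spec, panel, seed=19)
        result = compute_scores(cohort, ScoreConfig(include=tuple(panel.rsids)))
        fit = quartile_assoc(cohort, result, "PopA")
        b2, b4 = fit.term("score_q2").beta, fit.term("score_q4").beta
        assert b4 > b2 and fit.term("score_q4").or_ > 1.3


class TestScoreCorrelation:
    def test_equal_weights_give_exact_unity(self, small_cohort):
        cfg_u = ScoreConfig(include=tuple(small_cohort.panel.rsids))
        u = compute_scores(small_cohort, cfg_u).scores
        assert score_correlation(u, 3.0 * u) == pytest.approx(1.0, abs=1e-12)

    def test_weighted_vs_unweighted_correlation_matches_theory(self):
        """The weighted and unweighted scores are strongly correlated in
        every stratum, and the empirical Pearson r matches the theoretical
        plug-in value sum(w v)/sqrt(sum(v) sum(w^2 v)) with v = 2p(1-p)."""
        from transrep.synthetic import SimulationSpec

        panel = studydata.default_panel()
        weights = pd.Series(panel.published_weights())[panel.score_rsids]
        rafs = studydata.raf_table()

        spec = SimulationSpec.from_study(seed=23)
        for s in spec.strata:  # scale down for speed
            s.n_cases = max(s.n_cases // 4, 100)
            s.n_controls = max(s.n_controls // 4, 100)
        cohort = simulate_study(spec, seed=23)
        u = compute_scores(cohort, ScoreConfig(weighting="unweighted")).scores
        w = compute_scores(cohort, ScoreConfig(weighting="log_published_or")).scores
        for stratum in cohort.strata():
            idx = cohort.subjects["ethnicity"] == stratum
            v = 2 * rafs.loc[panel.score_rsids, stratum] * (1 - rafs.loc[panel.score_rsids, stratum])
            theory = (weights * v).sum() / np.sqrt(v.sum() * (weights**2 * v).sum())
            r = score_correlation(u[idx], w[idx])
            assert r >= 0.8
            assert r == pytest.approx(theory, abs=0.05)

    def test_zero_variance_rejected(self):
        s = pd.Series([3.0, 3.0, 3.0])
        with pytest.raises(DataError, match="zero variance"):
            score_correlation(s, pd.Series([1.0, 2.0, 3.0]))

    def test_dominant_negative_weight_breaks_correlation(self, small_cohort):
        cfg = ScoreConfig(include=tuple(small_cohort.panel.rsids))
        u = compute_scores(small_cohort, cfg).scores
        dosages = small_cohort.subjects[small_cohort.panel.rsids].fillna(0.0)
        w = dosages @ np.array([-10.0, 1.0, 1.0])
        r = score_correlation(u, w)
        assert np.isfinite(r) and r < 0.5
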