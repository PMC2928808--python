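"""Aggregate genetic risk score.

The score is the per-subject sum of risk-allele dosages over the included
SNPs (by default all panel SNPs flagged ``in_score`` — the FTO variant is
excluded), either unweighted or with each allele weighted by the log of
its published odds ratio.  A missing genotype contributes the ethnic mean
allele count, twice the stratum risk-allele frequency computed from the
analysis sample (cases + controls), which keeps the imputation exactly
mean-preserving.  Downstream: per-allele logistic association of the
score, ethnic-specific quartile analysis (quartile 1 referent, boundary
ties to the lower quartile), and the Pearson correlation between the
unweighted and weighted scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AnalysisConfig, FitResult, build_design, fit_logistic
from .cohort_io import Cohort
from .exceptions import DataError, ParameterError


@dataclass
class ScoreConfig:
    """Configuration of the aggregate score."""

    include: tuple[str, ...] | None = None  # None -> panel's in_score SNPs
    weighting: str = "unweighted"  # or "log_published_or"
    imputation: str = "ethnic_2raf"  # or "complete_case"
    quartile_reference: str = "combined"  # or "controls"

    def __post_init__(self) -> None:
        if self.weighting not in ("unweighted", "log_published_or"):
            raise ParameterError(f"unknown weighting {self.weighting!r}")
        if self.imputation not in ("ethnic_2raf", "complete_case"):
            raise ParameterError(f"unknown imputation {self.imputation!r}")
        if self.quartile_reference not in ("combined", "controls"):
            raise ParameterError(f"unknown quartile reference {self.quartile_reference!r}")

    def included_rsids(self, cohort: Cohort) -> list[str]:
        rsids = list(self.include) if self.include is not None else cohort.panel.score_rsids
        if not rsids:
            raise ParameterError("score inclusion list is empty")
        unknown = [r for r in rsids if r not in cohort.panel]
        if unknown:
            raise ParameterError(f"score SNPs not in panel: {unknown}")
        return rsids

    def weights(self, cohort: Cohort, rsids: Sequence[str]) -> np.ndarray:
        if self.weighting == "unweighted":
            return np.ones(len(rsids))
        return np.array([np.log(cohort.panel[r].published_or) for r in rsids])


@dataclass
class ScoreResult:
    """Per-subject scores plus stratum-level summaries.

    ``scores`` and ``quartiles`` are indexed like ``cohort.subjects``;
    ``raf_table`` holds the stratum RAFs used for imputation; ``summary``
    is one row per stratum (and 'Pooled') with mean and range.
    """

    scores: pd.Series
    quartiles: pd.Series
    raf_table: pd.DataFrame
    summary: pd.DataFrame
    config: ScoreConfig = field(default_factory=ScoreConfig)


def _assign_quartiles(scores: pd.Series) -> pd.Series:
    cut = np.quantile(scores, [0.25, 0.5, 0.75])
    codes = (scores.to_numpy()[:, None] > cut[None, :]).sum(axis=1)
    return pd.Series(codes + 1, index=scores.index)  # 1..4, ties to lower


def compute_scores(cohort: Cohort, config: ScoreConfig | None = None) -> ScoreResult:
    """Compute the aggregate score for every subject.

    With ``ethnic_2raf`` imputation a missing dosage contributes
    ``2 x RAF`` of its SNP in the subject's stratum; with
    ``complete_case`` subjects with any missing included SNP get NaN.
    """
    cfg = config or ScoreConfig()
    rsids = cfg.included_rsids(cohort)
    w = cfg.weights(cohort, rsids)
    subjects = cohort.subjects
    dosages = subjects[rsids].astype(float)

    raf_rows = {}
    filled = dosages.copy()
    for stratum in cohort.strata():
        idx = subjects["ethnicity"] == stratum
        block = dosages[idx]
        observed = block.notna().sum()
        if (observed == 0).any():
            bad = observed.index[observed == 0].tolist()
            raise DataError(f"no observed genotypes for {bad} in stratum {stratum}")
        raf = block.mean() / 2.0  # cases + controls combined
        raf_rows[stratum] = raf
        if cfg.imputation == "ethnic_2raf":
            filled.loc[idx] = block.fillna(2.0 * raf)
    raf_table = pd.DataFrame(raf_rows).T

    if cfg.imputation == "complete_case":
        scores = dosages.to_numpy() @ w
        scores = pd.Series(scores, index=subjects.index)
        scores[dosages.isna().any(axis=1)] = np.nan
    else:
        scores = pd.Series(filled.to_numpy() @ w, index=subjects.index)

    quart = pd.Series(np.nan, index=subjects.index)
    rows = []
    for stratum in cohort.strata():
        idx = subjects.index[subjects["ethnicity"] == stratum]
        s = scores[idx].dropna()
        ref = s if cfg.quartile_reference == "combined" else s[subjects.loc[s.index, "case"] == 0]
        if s.nunique() >= 4:
            cut = np.quantile(ref, [0.25, 0.5, 0.75])
            quart[s.index] = (s.to_numpy()[:, None] > cut[None, :]).sum(axis=1) + 1
        rows.append((stratum, s.mean(), s.min(), s.max(), len(s)))
    all_s = scores.dropna()
    rows.append(("Pooled", all_s.mean(), all_s.min(), all_s.max(), len(all_s)))
    summary = pd.DataFrame(rows, columns=["stratum", "mean", "min", "max", "n"])
    return ScoreResult(scores=scores, quartiles=quart, raf_table=raf_table, summary=summary, config=cfg)


def expected_mean_score(rafs: Sequence[float] | pd.Series, weights: Sequence[float] | None = None) -> float:
    """Expected score under HWE: ``sum_j w_j * 2 * RAF_j`` (w = 1 when
    unweighted).  This reconstructs the published mean total risk-allele
    counts directly from the published allele frequencies."""
    rafs = np.asarray(rafs, dtype=float)
    if ((rafs < 0) | (rafs > 1)).any() or not np.isfinite(rafs).all():
        raise ParameterError("RAFs must lie in [0,1]")
    w = np.ones_like(rafs) if weights is None else np.asarray(weights, dtype=float)
    return float((w * 2.0 * rafs).sum())


def score_assoc(
    cohort: Cohort,
    result: ScoreResult,
    stratum: str | None = None,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Per-allele odds ratio of the aggregate score (logistic fit of case
    status on the score plus the configured adjusters)."""
    cfg = config or AnalysisConfig()
    df = cohort.subjects if stratum is None else cohort.stratum(stratum)
    pooled = stratum is None and df["ethnicity"].nunique() > 1
    X, y, names = build_design(
        df, {"risk_score": result.scores[df.index]}, cfg.covariates, include_ethnicity=pooled
    )
    return fit_logistic(X, y, names, primary_terms=("risk_score",), alpha=cfg.alpha)


def quartile_assoc(
    cohort: Cohort,
    result: ScoreResult,
    stratum: str | None = None,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Odds ratios for score quartiles Q2-Q4 versus Q1 within one stratum
    (quartiles are defined separately for each population)."""
    cfg = config or AnalysisConfig()
    df = cohort.subjects if stratum is None else cohort.stratum(stratum)
    scores = result.scores[df.index].dropna()
    if scores.nunique() < 4:
        raise DataError(
            f"score distribution in {stratum or 'pooled'} has "
            f"{scores.nunique()} distinct values; quartiles undefined"
        )
    # quartiles are always defined within each population separately
    quart = pd.Series(np.nan, index=df.index)
    for s in dict.fromkeys(df["ethnicity"]):
        idx = df.index[df["ethnicity"] == s]
        sc = result.scores[idx].dropna()
        cut = np.quantile(sc, [0.25, 0.5, 0.75])
        quart[sc.index] = (sc.to_numpy()[:, None] > cut[None, :]).sum(axis=1) + 1
    primary = {
        f"score_q{q}": (quart == q).astype(float).where(quart.notna())
        for q in (2, 3, 4)
    }
    pooled = stratum is None and df["ethnicity"].nunique() > 1
    X, y, names = build_design(df, primary, cfg.covariates, include_ethnicity=pooled)
    return fit_logistic(X, y, names, primary_terms=tuple(primary), alpha=cfg.alpha)


def score_correlation(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Pearson correlation between two score variants on shared subjects."""
    joined = pd.concat([scores_a, scores_b], axis=1, keys=["a", "b"]).dropna()
    if len(joined) < 2:
        raise DataError("need at least two subjects with both scores")
    if joined["a"].std() == 0 or joined["b"].std() == 0:
        raise DataError("correlation undefined: a score has zero variance")
    return float(stats.pearsonr(joined["a"], joined["b"]).statistic)


def score_summary_table(
    cohort: Cohort,
    result: ScoreResult,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Study-style summary: per-stratum (and pooled) mean/range of the
    score and the adjusted per-allele OR with 95% CI."""
    cfg = config or AnalysisConfig()
    rows = []
    for stratum in list(cohort.strata()) + [None]:
        label = stratum or "Pooled"
        srow = result.summary[result.summary["stratum"] == label].iloc[0]
        fit = score_assoc(cohort, result, stratum, cfg)
        t = fit.primary
        rows.append(
            (label, srow["mean"], srow["min"], srow["max"],
             t.or_, t.ci_low, t.ci_high, t.wald_p, fit.n_used)
        )
    return pd.DataFrame(
        rows,
        columns=["stratum", "mean_ra", "min_ra", "max_ra", "or", "ci_low", "ci_high", "p", "n"],
    )
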