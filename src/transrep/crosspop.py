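"""Cross-population evidence synthesis.

Given per-SNP association fits in one stratum (or pooled), counts how many
risk alleles trend in the reported direction (OR > 1) and how many reach
nominal significance, attaching exact binomial tail probabilities (null:
half of the alleles trend either way; a fraction ``alpha`` is nominally
significant by chance).  Between-stratum heterogeneity of the per-allele
log odds ratio is tested with Cochran's Q (chi-square, strata-1 df); a
SNP-by-ethnicity interaction likelihood-ratio test is available as an
alternative with the same degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    AnalysisConfig,
    FitResult,
    build_design,
    fit_logistic,
    likelihood_ratio_p,
    snp_dosage_assoc,
)
from .cohort_io import Cohort
from .exceptions import ParameterError


def binom_tail(k: int, n: int, p: float) -> float:
    """Exact upper-tail probability P(X >= k) under Binomial(n, p)."""
    if not 0 < p < 1:
        raise ParameterError(f"null probability must be in (0,1), got {p}")
    if k < 0 or n < 0 or k > n:
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


@dataclass(frozen=True)
class DirectionSummary:
    """Direction-consistency and nominal-significance counts for one
    stratum's per-SNP fits."""

    n_snps: int
    n_or_gt1: int
    n_nominal: int
    binom_p_direction: float
    binom_p_nominal: float
    alpha: float
    ties_at_1: int = 0


def direction_summary_from_values(
    ors: Sequence[float],
    pvals: Sequence[float],
    alpha: float = 0.05,
) -> DirectionSummary:
    """Direction summary from unrounded odds ratios and p-values.

    ORs exactly 1.0 count as "not > 1" but are tallied separately, since
    on unrounded estimates an exact tie indicates a degenerate fit.
    """
    ors = np.asarray(ors, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    n = len(ors)
    n_gt1 = int((ors > 1.0).sum())
    n_nom = int((pvals < alpha).sum())
    return DirectionSummary(
        n_snps=n,
        n_or_gt1=n_gt1,
        n_nominal=n_nom,
        binom_p_direction=binom_tail(n_gt1, n, 0.5),
        binom_p_nominal=binom_tail(n_nom, n, alpha),
        alpha=alpha,
        ties_at_1=int((ors == 1.0).sum()),
    )


def direction_summary(
    fits: Mapping[str, FitResult],
    alpha: float = 0.05,
) -> DirectionSummary:
    """Direction summary over per-SNP fits; non-estimable SNPs are excluded
    from the denominator with a warning."""
    dropped = [rsid for rsid, f in fits.items() if not f.estimable]
    if dropped:
        warnings.warn(f"excluding non-estimable SNPs from direction counts: {dropped}")
    kept = {rsid: f for rsid, f in fits.items() if f.estimable}
    return direction_summary_from_values(
        [f.primary.or_ for f in kept.values()],
        [f.primary.wald_p for f in kept.values()],
        alpha,
    )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across strata for one SNP."""

    q_stat: float
    df: int
    p_het: float
    n_strata: int


def cochran_q(log_ors: Sequence[float], ses: Sequence[float]) -> HeterogeneityResult:
    """Cochran's Q on per-stratum log odds ratios with inverse-variance
    weights; chi-square reference with (strata - 1) df."""
    theta = np.asarray(log_ors, dtype=float)
    se = np.asarray(ses, dtype=float)
    keep = np.isfinite(theta) & np.isfinite(se)
    theta, se = theta[keep], se[keep]
    if len(theta) < 2:
        raise ParameterError("heterogeneity test needs >= 2 estimable strata")
    if (se <= 0).any():
        raise ParameterError("all standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float((w * theta).sum() / w.sum())
    q = float((w * (theta - pooled) ** 2).sum())
    df = len(theta) - 1
    return HeterogeneityResult(q_stat=q, df=df, p_het=float(stats.chi2.sf(q, df)), n_strata=len(theta))


def snp_heterogeneity(
    cohort: Cohort,
    rsid: str,
    config: AnalysisConfig | None = None,
    method: str = "cochran_q",
) -> HeterogeneityResult:
    """Heterogeneity of one SNP's per-allele effect across ethnic strata.

    ``method='cochran_q'`` (default) uses the per-stratum dosage fits;
    ``method='interaction_lrt'`` compares pooled models with and without
    dosage-by-ethnicity interaction terms (same df)."""
    cfg = config or AnalysisConfig()
    strata = [s for s in cohort.strata()]
    if method == "cochran_q":
        fits = [snp_dosage_assoc(cohort, rsid, s, cfg) for s in strata]
        est = [f for f in fits if f.estimable]
        return cochran_q(
            [f.primary.beta for f in est], [f.primary.se for f in est]
        )
    if method != "interaction_lrt":
        raise ParameterError(f"unknown heterogeneity method {method!r}")
    df_all = cohort.subjects
    d = df_all[rsid]
    levels = list(dict.fromkeys(df_all["ethnicity"]))
    primary_red = {rsid: d}
    X0, y0, n0 = build_design(df_all, primary_red, cfg.covariates, include_ethnicity=True)
    reduced = fit_logistic(X0, y0, n0, primary_terms=(rsid,), alpha=cfg.alpha)
    primary_full = dict(primary_red)
    for lv in levels[1:]:
        primary_full[f"{rsid}:x:{lv}"] = d * (df_all["ethnicity"] == lv)
    X1, y1, n1 = build_design(df_all, primary_full, cfg.covariates, include_ethnicity=True)
    full = fit_logistic(X1, y1, n1, primary_terms=tuple(primary_full), alpha=cfg.alpha)
    df_test = len(levels) - 1
    stat = max(2 * (full.loglik - reduced.loglik), 0.0)
    return HeterogeneityResult(
        q_stat=float(stat),
        df=df_test,
        p_het=likelihood_ratio_p(full, reduced, df_test),
        n_strata=len(levels),
    )


def heterogeneity_table(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    method: str = "cochran_q",
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Per-SNP heterogeneity across strata, with a reported (never
    filtering) Bonferroni-adjusted column over the panel's tests."""
    from .exceptions import RankError, SeparationError

    rows = []
    for rsid in cohort.panel.rsids:
        try:
            het = snp_heterogeneity(cohort, rsid, config, method)
            rows.append((rsid, het.q_stat, het.df, het.p_het))
        except (ParameterError, RankError, SeparationError):
            rows.append((rsid, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["rsid", "q", "df", "p_het"])
    if bonferroni:
        out["p_het_bonferroni"] = np.minimum(out["p_het"] * len(out), 1.0)
    return out
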