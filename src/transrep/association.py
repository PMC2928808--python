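"""Per-SNP case-control logistic association.

Implements the study's analysis models: allele-dosage (per-allele odds
ratio) and genotype-category logistic regressions, ethnic-stratified or
pooled, adjusted for age (quartiles), BMI (quartiles), sex, and ethnicity
in pooled analyses, plus the mutual adjustment of the two KCNQ1 variants.
Quartile cutpoints are computed within the analysis sample (cases and
controls combined); single-SNP models are complete-case for that SNP.

Maximum-likelihood fitting is delegated to statsmodels (Newton-Raphson);
this module adds rank and separation diagnostics and packages estimates as
:class:`FitResult` (per-term log-odds, SE, OR with 95% CI, two-sided Wald
p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort_io import AnalysisConfig, Cohort
from .exceptions import DataError, RankError, SeparationError
from . import studydata

#: |log-odds| beyond which a fit is declared separated
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class TermEstimate:
    """One coefficient: log-odds scale plus the odds-ratio presentation."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    wald_p: float


@dataclass
class FitResult:
    """A fitted logistic model."""

    terms: dict[str, TermEstimate] = field(default_factory=dict)
    primary_terms: tuple[str, ...] = ()
    loglik: float = np.nan
    n_used: int = 0
    converged: bool = False
    estimable: bool = True
    reason: str | None = None

    @classmethod
    def not_estimable(cls, reason: str) -> "FitResult":
        return cls(estimable=False, reason=reason)

    def term(self, name: str) -> TermEstimate:
        return self.terms[name]

    @property
    def primary(self) -> TermEstimate:
        """The estimate of the first primary term (the SNP or score)."""
        if not self.estimable:
            raise DataError(f"model not estimable: {self.reason}")
        return self.terms[self.primary_terms[0]]


def quartile_codes(x: np.ndarray | pd.Series) -> np.ndarray:
    """Quartile index 0..3 within the sample; ties go to the lower quartile."""
    x = np.asarray(x, dtype=float)
    cut = np.quantile(x, [0.25, 0.5, 0.75])
    return (x[:, None] > cut[None, :]).sum(axis=1)


def _indicator_block(codes: np.ndarray, prefix: str, levels: list) -> tuple[np.ndarray, list[str]]:
    """Dummy columns for all levels after the first (reference)."""
    cols = [np.asarray(codes == lv, dtype=float) for lv in levels[1:]]
    names = [f"{prefix}_{lv}" for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(codes), 0))), names


def build_design(
    df: pd.DataFrame,
    primary: dict[str, np.ndarray | pd.Series],
    covariates: tuple[str, ...] = ("age", "bmi", "sex"),
    include_ethnicity: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, names) for a logistic fit.

    Complete-case on all model variables; quartile codings are computed on
    the retained rows (cases + controls combined).
    """
    prim = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in primary.items()}, index=df.index)
    extra = [c for c in ("education", "ancestry") if c in covariates]
    for c in extra:
        if c not in df.columns:
            raise DataError(f"covariate {c!r} requested but absent from the cohort")
    raw = [c for c in ("age", "bmi") if c in covariates] + extra
    mask = prim.notna().all(axis=1) & df[raw].notna().all(axis=1) if raw else prim.notna().all(axis=1)
    sub = df[mask]
    prim = prim[mask]

    blocks = [np.ones((len(sub), 1)), prim.to_numpy()]
    names = ["const"] + list(prim.columns)
    for cov in ("age", "bmi"):
        if cov in covariates:
            block, nm = _indicator_block(quartile_codes(sub[cov]), f"{cov}_q", [0, 1, 2, 3])
            blocks.append(block)
            names += nm
    if "sex" in covariates:
        blocks.append(np.asarray(sub["sex"] == "female", dtype=float)[:, None])
        names.append("sex_female")
    if include_ethnicity:
        levels = list(dict.fromkeys(sub["ethnicity"]))
        block, nm = _indicator_block(sub["ethnicity"].to_numpy(), "eth", levels)
        blocks.append(block)
        names += nm
    for c in extra:
        blocks.append(np.asarray(sub[c], dtype=float)[:, None])
        names.append(c)
    X = np.column_stack(blocks)
    y = sub["case"].to_numpy(dtype=float)
    return X, y, names


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    primary_terms: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> FitResult:
    """Maximum-likelihood logistic fit with rank and separation checks."""
    if len(np.unique(y)) < 2:
        raise DataError("outcome must contain both cases and controls")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the smallest singular directions
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]
        raise RankError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {[names[i] for i in bad]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except Exception as exc:  # statsmodels raises on singular Hessians
            raise SeparationError(f"logistic fit failed: {exc}") from None
    beta = np.asarray(res.params, dtype=float)
    if np.abs(beta).max() > SEPARATION_BETA:
        worst = names[int(np.abs(beta).argmax())]
        raise SeparationError(
            f"diverging coefficient for {worst!r} (|beta| > {SEPARATION_BETA}); "
            "complete or quasi-complete separation"
        )
    se = np.asarray(res.bse, dtype=float)
    z = norm.ppf(1 - alpha / 2)
    terms = {
        name: TermEstimate(
            beta=float(b),
            se=float(s_),
            or_=float(np.exp(b)),
            ci_low=float(np.exp(b - z * s_)),
            ci_high=float(np.exp(b + z * s_)),
            wald_p=float(2 * norm.sf(abs(b) / s_)) if s_ > 0 else np.nan,
        )
        for name, b, s_ in zip(names, beta, se)
    }
    return FitResult(
        terms=terms,
        primary_terms=primary_terms or tuple(n for n in names if n != "const"),
        loglik=float(res.llf),
        n_used=int(len(y)),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def _subset(cohort: Cohort, stratum: str | None) -> pd.DataFrame:
    return cohort.subjects if stratum is None else cohort.stratum(stratum)


def snp_dosage_assoc(
    cohort: Cohort,
    rsid: str,
    stratum: str | None = None,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Per-allele (dosage) odds ratio for one SNP, covariate adjusted.

    ``stratum=None`` is the pooled analysis with ethnicity indicators.
    Monomorphic SNPs yield a not-estimable result rather than an error.
    """
    cfg = config or AnalysisConfig()
    df = _subset(cohort, stratum)
    observed = df[rsid].dropna()
    if observed.nunique() < 2:
        return FitResult.not_estimable(f"{rsid} monomorphic in {stratum or 'pooled'}")
    pooled = stratum is None and df["ethnicity"].nunique() > 1
    X, y, names = build_design(df, {rsid: df[rsid]}, cfg.covariates, include_ethnicity=pooled)
    return fit_logistic(X, y, names, primary_terms=(rsid,), alpha=cfg.alpha)


def snp_genotype_assoc(
    cohort: Cohort,
    rsid: str,
    stratum: str | None = None,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Genotype-category model: heterozygote and homozygote ORs versus
    non-carriers of the risk allele.  If no homozygotes are observed, only
    the heterozygote term is fitted."""
    cfg = config or AnalysisConfig()
    df = _subset(cohort, stratum)
    d = df[rsid]
    counts = {g: int((d == g).sum()) for g in (0, 1, 2)}
    if counts[0] == 0:
        return FitResult.not_estimable(
            f"{rsid}: no non-carrier reference subjects in {stratum or 'pooled'}"
        )
    if counts[1] == 0 and counts[2] == 0:
        return FitResult.not_estimable(f"{rsid} monomorphic in {stratum or 'pooled'}")
    primary = {f"{rsid}_het": (d == 1).astype(float).where(d.notna())}
    if counts[2] > 0:
        primary[f"{rsid}_hom"] = (d == 2).astype(float).where(d.notna())
    pooled = stratum is None and df["ethnicity"].nunique() > 1
    X, y, names = build_design(df, primary, cfg.covariates, include_ethnicity=pooled)
    return fit_logistic(X, y, names, primary_terms=tuple(primary), alpha=cfg.alpha)


def kcnq1_coadjusted_assoc(
    cohort: Cohort,
    stratum: str | None = None,
    config: AnalysisConfig | None = None,
    rsids: tuple[str, str] = studydata.KCNQ1_RSIDS,
) -> dict[str, FitResult]:
    """Dosage ORs for the two linked KCNQ1 variants from one model holding
    both dosages (each adjusted for the other) plus the usual covariates."""
    cfg = config or AnalysisConfig()
    df = _subset(cohort, stratum)
    a, b = rsids
    both = df[[a, b]].dropna()
    r = np.corrcoef(both[a], both[b])[0, 1] if len(both) > 1 else np.nan
    if np.isfinite(r) and abs(r) > 0.99:
        raise RankError(f"dosages of {a} and {b} nearly collinear (r={r:.4f})")
    pooled = stratum is None and df["ethnicity"].nunique() > 1
    X, y, names = build_design(df, {a: df[a], b: df[b]}, cfg.covariates, include_ethnicity=pooled)
    fit = fit_logistic(X, y, names, primary_terms=rsids, alpha=cfg.alpha)
    out = {}
    for rsid in rsids:
        out[rsid] = FitResult(
            terms=fit.terms,
            primary_terms=(rsid,),
            loglik=fit.loglik,
            n_used=fit.n_used,
            converged=fit.converged,
        )
    return out


def likelihood_ratio_p(full: FitResult, reduced: FitResult, df: int) -> float:
    """Two-sided LRT p-value between nested fits."""
    stat = 2 * (full.loglik - reduced.loglik)
    return float(chi2.sf(max(stat, 0.0), df))


def association_table(
    cohort: Cohort,
    strata: list[str | None],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Dosage association of every panel SNP in each requested stratum
    (``None`` = pooled); one row per SNP x stratum."""
    cfg = config or AnalysisConfig()
    rows = []
    for stratum in strata:
        label = stratum or "Pooled"
        for rsid in cohort.panel.rsids:
            try:
                fit = snp_dosage_assoc(cohort, rsid, stratum, cfg)
            except (SeparationError, RankError) as exc:
                fit = FitResult.not_estimable(str(exc))
            if fit.estimable:
                t = fit.primary
                rows.append((rsid, label, t.beta, t.se, t.or_, t.ci_low, t.ci_high, t.wald_p, fit.n_used))
            else:
                rows.append((rsid, label) + (np.nan,) * 6 + (0,))
    return pd.DataFrame(
        rows,
        columns=["rsid", "stratum", "beta", "se", "or", "ci_low", "ci_high", "p", "n"],
    )
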