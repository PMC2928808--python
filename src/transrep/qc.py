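"""Genotype quality control: call rates, Hardy-Weinberg exact testing, and
subject/SNP exclusion rules.

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the p-value sums the probabilities of all heterozygote
counts no more probable than the observed one (two-sided by probability
ordering, no mid-p correction).  SNPs failing call-rate or control-HWE
thresholds are flagged in the report but never silently dropped; subjects
missing more than a threshold number of genotypes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .cohort_io import Cohort, QCThresholds
from .exceptions import ParameterError

# relative guard when comparing heterozygote-count probabilities: counts with
# probability <= (1 + GUARD) * observed probability enter the tail sum, making
# the probability-ordering rule robust to floating-point ties
_TIE_GUARD = 1e-10


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one SNP in one group of subjects."""

    n_hom_risk: int
    n_het: int
    n_hom_other: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_other) < 0:
            raise ParameterError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_other

    @classmethod
    def from_dosages(cls, dosages: pd.Series | np.ndarray) -> "GenotypeCounts":
        d = np.asarray(dosages, dtype=float)
        d = d[~np.isnan(d)]
        return cls(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))


class HWEResult(NamedTuple):
    p_value: float
    monomorphic: bool


def _log_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """Log probability of ``n_het`` heterozygotes given ``n_rare`` copies of
    the rarer allele among ``n`` diploid individuals (exact conditional
    distribution under HWE)."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (
        n_het * np.log(2)
        + gammaln(n + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_common + 1)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(counts: GenotypeCounts) -> HWEResult:
    """Exact conditional Hardy-Weinberg test.

    Returns p = 1.0 with a monomorphic flag when one allele is absent.
    """
    n = counts.total
    if n < 1:
        raise ParameterError("HWE test requires at least one genotype")
    n_risk = 2 * counts.n_hom_risk + counts.n_het
    n_other = 2 * counts.n_hom_other + counts.n_het
    if n_risk == 0 or n_other == 0:
        return HWEResult(1.0, True)
    n_rare = min(n_risk, n_other)
    # heterozygote counts share the parity of the rare-allele total
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array([_log_het_prob(int(h), n_rare, n) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, counts.n_het)]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_GUARD)].sum())
    return HWEResult(min(p, 1.0), False)


def hwe_chisq_test(counts: GenotypeCounts) -> HWEResult:
    """One-df chi-square alternative to the exact test."""
    n = counts.total
    if n < 1:
        raise ParameterError("HWE test requires at least one genotype")
    p_risk = (2 * counts.n_hom_risk + counts.n_het) / (2 * n)
    if p_risk in (0.0, 1.0):
        return HWEResult(1.0, True)
    expected = n * np.array([p_risk**2, 2 * p_risk * (1 - p_risk), (1 - p_risk) ** 2])
    observed = np.array([counts.n_hom_risk, counts.n_het, counts.n_hom_other])
    stat = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(float(chi2.sf(stat, 1)), False)


def call_rate(cohort: Cohort, rsid: str, stratum: str | None = None, cases: bool | None = None) -> float:
    """Fraction of non-missing genotypes for one SNP, optionally within one
    ethnicity stratum and/or case status."""
    if rsid not in cohort.panel:
        raise KeyError(f"unknown rsid {rsid!r}")
    sub = cohort.subjects
    if stratum is not None:
        sub = sub[sub["ethnicity"] == stratum]
    if cases is not None:
        sub = sub[sub["case"] == int(cases)]
    if sub.empty:
        raise ParameterError("empty group for call-rate computation")
    return float(sub[rsid].notna().mean())


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`.

    ``snp_table`` has one row per SNP x stratum x case-status with the call
    rate and (among controls) the exact HWE p-value; ``excluded_subjects``
    records each removed subject with its single primary reason.
    """

    snp_table: pd.DataFrame
    excluded_subjects: pd.DataFrame
    flagged: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_subjects)


def apply_qc(cohort: Cohort, thresholds: QCThresholds | None = None) -> tuple[Cohort, QCReport]:
    """Remove subjects missing more than ``max_missing_snps_per_subject``
    genotypes; compute the per-SNP call-rate/HWE report and flag (never
    drop) SNPs below ``min_call_rate`` or with control HWE p below
    ``hwe_flag_p``.  Idempotent."""
    th = thresholds or QCThresholds()
    n_missing = cohort.n_missing_per_subject()
    drop = n_missing > th.max_missing_snps_per_subject
    excluded = pd.DataFrame(
        {
            "subject_id": cohort.subjects.loc[drop, "subject_id"],
            "reason": [
                f"missing {int(m)} of {len(cohort.panel)} genotypes "
                f"(> {th.max_missing_snps_per_subject})"
                for m in n_missing[drop]
            ],
        }
    ).reset_index(drop=True)
    filtered = Cohort(panel=cohort.panel, subjects=cohort.subjects[~drop].reset_index(drop=True))

    rows = []
    flagged: list[str] = []
    for stratum in filtered.strata():
        sub = filtered.stratum(stratum)
        for status, label in ((1, "case"), (0, "control")):
            grp = sub[sub["case"] == status]
            if grp.empty:
                continue
            for rsid in filtered.panel.rsids:
                cr = float(grp[rsid].notna().mean())
                hwe_p = np.nan
                mono = False
                if label == "control":
                    res = hwe_exact_test(GenotypeCounts.from_dosages(grp[rsid]))
                    hwe_p, mono = res.p_value, res.monomorphic
                    if not mono and hwe_p < th.hwe_flag_p:
                        flagged.append(f"{rsid}/{stratum}: control HWE p={hwe_p:.3g} < {th.hwe_flag_p}")
                if cr < th.min_call_rate:
                    flagged.append(f"{rsid}/{stratum}/{label}: call rate {cr:.3f} < {th.min_call_rate}")
                rows.append((rsid, stratum, label, cr, hwe_p, mono))
    snp_table = pd.DataFrame(
        rows, columns=["rsid", "stratum", "group", "call_rate", "hwe_p", "monomorphic"]
    )
    return filtered, QCReport(snp_table=snp_table, excluded_subjects=excluded, flagged=flagged)
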