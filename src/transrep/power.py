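"""Analytic power for the per-allele (log-additive) association test.

Default method is the allele-counting normal approximation: the case
risk-allele frequency implied by the control frequency and the assumed
per-allele odds ratio is derived on the odds scale, the variance of the
log allele-count odds ratio comes from expected allele counts under HWE
(2N alleles per group), and two-sided power is

    power = Phi(-z_{a/2} + |ln OR| / SE) + Phi(-z_{a/2} - |ln OR| / SE).

A logistic-Wald variant computes the SE from the expected information of
the dosage model instead.  Both are cross-validated against simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_io import Panel
from .exceptions import ParameterError


@dataclass(frozen=True)
class PowerQuery:
    """One power computation: stratum sizes, control RAF, assumed OR, level."""

    n_cases: int
    n_controls: int
    raf: float
    or_: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("n_cases and n_controls must be >= 1")
        if not 0.0 < self.raf < 1.0:
            raise ParameterError(f"raf must be in (0,1), got {self.raf}")
        if self.or_ <= 0:
            raise ParameterError(f"or must be > 0, got {self.or_}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")


def case_allele_frequency(raf: float, or_: float) -> float:
    """Risk-allele frequency among cases implied by the control frequency
    and a per-allele odds ratio (odds multiplied by OR)."""
    odds = raf / (1.0 - raf) * or_
    return odds / (1.0 + odds)


def allelic_test_power(q: PowerQuery, method: str = "allele_count") -> float:
    """Two-sided power of the per-allele association test."""
    p0 = q.raf
    p1 = case_allele_frequency(p0, q.or_)
    if not 0.0 < p1 < 1.0:
        raise ParameterError(f"derived case allele frequency {p1} degenerate")
    if method == "allele_count":
        var = 1.0 / (2 * q.n_cases * p1 * (1 - p1)) + 1.0 / (2 * q.n_controls * p0 * (1 - p0))
    elif method == "logistic_wald":
        # expected information of the dosage coefficient under HWE genotypes
        var = _logistic_dosage_variance(q.n_cases, q.n_controls, p0, p1)
    else:
        raise ParameterError(f"unknown power method {method!r}")
    se = np.sqrt(var)
    z = norm.ppf(1 - q.alpha / 2)
    delta = abs(np.log(q.or_)) / se
    return float(norm.cdf(-z + delta) + norm.cdf(-z - delta))


def _logistic_dosage_variance(n_cases: int, n_controls: int, p0: float, p1: float) -> float:
    """Variance of the dosage log-OR from the expected inverse information
    of a case-control logistic fit with HWE genotype distributions."""
    d = np.array([0.0, 1.0, 2.0])
    g0 = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2])
    g1 = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1**2])
    n = n_cases + n_controls
    w = (n_controls * g0 + n_cases * g1) / n
    pr_case = n_cases * g1 / (n_controls * g0 + n_cases * g1)
    v = w * pr_case * (1 - pr_case)
    i00 = (v).sum()
    i01 = (v * d).sum()
    i11 = (v * d**2).sum()
    return float(1.0 / (n * (i11 - i01**2 / i00)))


def simulate_rejection_rate(
    q: PowerQuery,
    n_replicates: int = 2000,
    seed: int | np.random.Generator = 0,
    method: str = "allele_count",
) -> float:
    """Monte-Carlo oracle: empirical rejection rate of the per-allele test.

    ``allele_count`` draws the 2x2 allele table and applies the Wald test
    of the log allele-count odds ratio (vectorised over replicates);
    ``logistic`` simulates HWE dosages and fits the dosage logistic model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p1 = case_allele_frequency(q.raf, q.or_)
    z = norm.ppf(1 - q.alpha / 2)
    if method == "allele_count":
        a = rng.binomial(2 * q.n_cases, p1, n_replicates).astype(float)
        b = 2 * q.n_cases - a
        c = rng.binomial(2 * q.n_controls, q.raf, n_replicates).astype(float)
        d = 2 * q.n_controls - c
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        lor = np.log(a[ok] * d[ok] / (b[ok] * c[ok]))
        se = np.sqrt(1 / a[ok] + 1 / b[ok] + 1 / c[ok] + 1 / d[ok])
        return float((np.abs(lor) > z * se).mean())
    if method != "logistic":
        raise ParameterError(f"unknown oracle method {method!r}")
    from .association import fit_logistic  # local import to avoid cycle

    hits = 0
    used = 0
    for _ in range(n_replicates):
        d_case = rng.binomial(2, p1, q.n_cases)
        d_ctrl = rng.binomial(2, q.raf, q.n_controls)
        x = np.concatenate([d_case, d_ctrl]).astype(float)
        y = np.concatenate([np.ones(q.n_cases), np.zeros(q.n_controls)])
        X = np.column_stack([np.ones_like(x), x])
        try:
            fit = fit_logistic(X, y, ["const", "dosage"], ("dosage",), q.alpha)
        except Exception:
            continue
        used += 1
        hits += fit.term("dosage").wald_p < q.alpha
    if used == 0:
        raise ParameterError("no estimable replicates")
    return hits / used


def panel_power_table(
    panel: Panel,
    stratum_sizes: Mapping[str, tuple[int, int]],
    rafs: pd.DataFrame | Mapping[str, Mapping[str, float]],
    assumed_ors: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    method: str = "allele_count",
) -> pd.DataFrame:
    """Per-SNP power in each stratum plus a per-stratum mean row input.

    ``rafs``: rsid x stratum frequencies; ``assumed_ors``: per-SNP odds
    ratios (defaults to the panel's published ORs).  A ``Pooled`` column
    uses summed sizes with the pooled RAF column when present.
    """
    rafs = pd.DataFrame(rafs)
    ors = dict(assumed_ors) if assumed_ors is not None else {
        v.rsid: v.published_or for v in panel
    }
    missing = [r for r in panel.rsids if r not in ors]
    if missing:
        raise ParameterError(f"no assumed OR for SNPs: {missing}")
    sizes = dict(stratum_sizes)
    if "Pooled" in rafs.columns and "Pooled" not in sizes:
        sizes["Pooled"] = tuple(np.sum(list(stratum_sizes.values()), axis=0))
    rows = []
    for rsid in panel.rsids:
        row = {"rsid": rsid, "assumed_or": ors[rsid]}
        for stratum, (n_ca, n_co) in sizes.items():
            if stratum not in rafs.columns:
                continue
            raf = float(rafs.loc[rsid, stratum])
            if not 0.0 < raf < 1.0:  # monomorphic: power undefined
                row[stratum] = np.nan
                continue
            q = PowerQuery(n_ca, n_co, raf, float(ors[rsid]), alpha)
            row[stratum] = allelic_test_power(q, method=method)
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_row = {"rsid": "MEAN", "assumed_or": np.nan}
    for col in table.columns[2:]:
        mean_row[col] = table[col].mean()
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
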