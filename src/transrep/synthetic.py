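"""Synthetic multiethnic case-control cohorts.

Generates cohorts with the statistical structure the analysis assumes:

* genotypes drawn under Hardy-Weinberg equilibrium, ``dosage ~
  Binomial(2, RAF)`` independently across SNPs (optionally with linkage
  between the two KCNQ1 variants via a haplotype-frequency parameter);
* disease through a logistic model ``logit P(D) = b0 + sum_j d_j
  ln(OR_gen,j) + covariate terms`` with the intercept solved so the
  marginal prevalence matches a target;
* retrospective case-control sampling from the prospective pool with
  controls frequency-matched to cases on 5-year age bands;
* independent per-genotype missingness.

Defaults transcribe the published per-stratum risk-allele frequencies,
per-allele odds ratios and sample sizes of the multiethnic T2D study
(:mod:`transrep.studydata`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort_io import Cohort, Panel
from .exceptions import DataError, ParameterError
from . import studydata


@dataclass
class StratumSpec:
    """Generative parameters for one ethnicity stratum."""

    name: str
    n_cases: int
    n_controls: int
    raf: dict[str, float]
    or_gen: dict[str, float]
    age_mean: float = 59.0
    age_sd: float = 8.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.5
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError(f"{self.name}: n_cases and n_controls must be >= 1")
        for rsid, f in self.raf.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{self.name}: RAF for {rsid} outside [0,1]: {f}")
        for rsid, o in self.or_gen.items():
            if not o > 0:
                raise ParameterError(f"{self.name}: OR_gen for {rsid} must be > 0: {o}")


@dataclass
class SimulationSpec:
    """Full study design for the generator."""

    strata: list[StratumSpec]
    baseline_prevalence: float = 0.10
    missing_rate: float = 0.02
    age_match_band_years: int = 5
    age_range: tuple[float, float] = (45.0, 77.0)
    # covariate effects of the disease model, per quartile step / for women
    bmi_quartile_or: float = 1.5
    age_quartile_or: float = 1.1
    sex_or: float = 1.0
    kcnq1_ld_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ParameterError("baseline_prevalence must be in (0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0,1)")

    @classmethod
    def from_study(cls, seed: int = 0, **overrides) -> "SimulationSpec":
        """The packaged multiethnic T2D study design (published RAFs,
        per-allele ORs and stratum sizes as generative parameters)."""
        params = studydata.study_parameters()
        strata = [
            StratumSpec(
                name=name,
                n_cases=s["n_cases"],
                n_controls=s["n_controls"],
                raf=dict(s["raf"]),
                or_gen=dict(s["or_gen"]),
                age_mean=s["age_mean"],
                age_sd=s["age_sd"],
                bmi_mean=s["bmi_mean"],
                bmi_sd=s["bmi_sd"],
                female_fraction=s["female_fraction"],
            )
            for name, s in params["strata"].items()
        ]
        kwargs = dict(
            strata=strata,
            baseline_prevalence=params["baseline_prevalence"],
            missing_rate=params["missing_rate"],
            age_match_band_years=params["age_match_band_years"],
            age_range=tuple(params["age_range"]),
            bmi_quartile_or=params["bmi_quartile_or"],
            age_quartile_or=params["age_quartile_or"],
            sex_or=params["sex_or"],
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int = 0) -> "SimulationSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        strata = [
            StratumSpec(
                name=name,
                **{k: v for k, v in s.items() if k in {f.name for f in dataclasses.fields(StratumSpec)}},
            )
            for name, s in cfg.pop("strata").items()
        ]
        cfg.pop("pooled", None)
        if "age_range" in cfg:
            cfg["age_range"] = tuple(cfg["age_range"])
        cfg.setdefault("seed", seed)
        return cls(strata=strata, **cfg)

    def stratum(self, name: str) -> StratumSpec:
        for s in self.strata:
            if s.name == name:
                return s
        raise KeyError(name)


def _quartile_steps(x: np.ndarray) -> np.ndarray:
    """Quartile index 0..3 of each value within its own distribution;
    values tied with a cutpoint fall in the lower quartile."""
    cut = np.quantile(x, [0.25, 0.5, 0.75])
    return (x[:, None] > cut[None, :]).sum(axis=1)


def _solve_intercept(lp: np.ndarray, prevalence: float, tol: float = 1e-6) -> float:
    """Bisection for the intercept giving the target marginal prevalence."""
    lo, hi = -40.0, 20.0
    if not np.mean(expit(lo + lp)) < prevalence < np.mean(expit(hi + lp)):
        raise ParameterError(f"prevalence {prevalence} unattainable")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.mean(expit(mid + lp)) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _kcnq1_pair_dosages(n: int, p1: float, p2: float, r: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two linked KCNQ1 dosages from a two-locus haplotype model
    with allele frequencies ``p1, p2`` and haplotype correlation ``r``."""
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    h11 = np.clip(p1 * p2 + r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2)), lo, hi)
    probs = np.array([h11, p1 - h11, p2 - h11, 1 - p1 - p2 + h11])
    haps = rng.choice(4, size=(n, 2), p=probs / probs.sum())
    a1 = np.isin(haps, (0, 1)).sum(axis=1)  # haplotypes carrying allele at locus 1
    a2 = np.isin(haps, (0, 2)).sum(axis=1)
    return a1.astype(float), a2.astype(float)


def simulate_population(
    spec: SimulationSpec,
    stratum: StratumSpec,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a prospective pool of ``n`` individuals for one stratum.

    Returns a frame with ``ethnicity case sex age bmi`` plus one dosage
    column per SNP (no missingness yet; that is injected after sampling).
    """
    rsids = list(stratum.raf)
    age = np.clip(rng.normal(stratum.age_mean, stratum.age_sd, n), *spec.age_range)
    bmi = np.clip(rng.normal(stratum.bmi_mean, stratum.bmi_sd, n), 15.0, None)
    female = rng.random(n) < stratum.female_fraction

    dosages = np.column_stack([rng.binomial(2, stratum.raf[r], n) for r in rsids]).astype(float)
    if spec.kcnq1_ld_r != 0.0 and all(k in rsids for k in studydata.KCNQ1_RSIDS):
        i1, i2 = (rsids.index(k) for k in studydata.KCNQ1_RSIDS)
        dosages[:, i1], dosages[:, i2] = _kcnq1_pair_dosages(
            n, stratum.raf[rsids[i1]], stratum.raf[rsids[i2]], spec.kcnq1_ld_r, rng
        )

    log_ors = np.array([np.log(stratum.or_gen[r]) for r in rsids])
    lp = dosages @ log_ors
    lp += _quartile_steps(age) * np.log(spec.age_quartile_or)
    lp += _quartile_steps(bmi) * np.log(spec.bmi_quartile_or)
    lp += female * np.log(spec.sex_or)
    b0 = _solve_intercept(lp, spec.baseline_prevalence)
    case = rng.random(n) < expit(b0 + lp)

    frame = pd.DataFrame(
        {
            "ethnicity": stratum.name,
            "case": case.astype(int),
            "sex": np.where(female, "female", "male"),
            "age": age,
            "bmi": bmi,
        }
    )
    for j, rsid in enumerate(rsids):
        frame[rsid] = dosages[:, j]
    return frame


def sample_case_control(
    pool: pd.DataFrame,
    stratum: StratumSpec,
    band_years: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Retrospective sampling: all-or-random cases, controls frequency
    matched to the sampled cases on age bands (largest-remainder rounding)."""
    cases = pool[pool["case"] == 1]
    controls = pool[pool["case"] == 0]
    if len(cases) < stratum.n_cases:
        raise DataError(
            f"{stratum.name}: pool has {len(cases)} cases, need {stratum.n_cases}"
        )
    picked_cases = cases.iloc[rng.choice(len(cases), stratum.n_cases, replace=False)]

    band = (picked_cases["age"] // band_years).astype(int)
    band_counts = band.value_counts().sort_index()
    # largest-remainder allocation of controls across case age bands
    exact = band_counts / stratum.n_cases * stratum.n_controls
    target = np.floor(exact).astype(int)
    short = stratum.n_controls - int(target.sum())
    for b in (exact - target).sort_values(ascending=False).index[:short]:
        target[b] += 1

    ctrl_band = (controls["age"] // band_years).astype(int)
    chunks = []
    for b, want in target.items():
        if want == 0:
            continue
        avail = controls[ctrl_band == b]
        if len(avail) < want:
            raise DataError(
                f"{stratum.name}: age band [{b * band_years},{(b + 1) * band_years}) "
                f"has {len(avail)} eligible controls, need {want}"
            )
        chunks.append(avail.iloc[rng.choice(len(avail), want, replace=False)])
    out = pd.concat([picked_cases] + chunks, ignore_index=True)
    return out


def inject_missingness(cohort: Cohort, rate: float, seed: int | np.random.Generator) -> Cohort:
    """Independently set each genotype missing with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ParameterError(f"missing rate must be in [0,1), got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = cohort.subjects.copy()
    if rate > 0.0:
        block = subjects[cohort.panel.rsids].to_numpy(dtype=float)
        block[rng.random(block.shape) < rate] = np.nan
        subjects[cohort.panel.rsids] = block
    return Cohort(panel=cohort.panel, subjects=subjects)


def simulate_study(
    spec: SimulationSpec,
    panel: Panel | None = None,
    seed: int | np.random.Generator | None = None,
) -> Cohort:
    """Simulate the full case-control study: per-stratum pools, age-matched
    sampling, then genotype missingness.  Bit-reproducible for a fixed seed."""
    panel = panel or studydata.default_panel()
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    for stratum in spec.strata:
        need_cases = stratum.n_cases
        n_pool = int(1.4 * max(
            need_cases / spec.baseline_prevalence,
            stratum.n_controls / (1 - spec.baseline_prevalence),
        )) + 200
        for attempt in range(4):
            pool = simulate_population(spec, stratum, n_pool, rng)
            try:
                parts.append(
                    sample_case_control(pool, stratum, spec.age_match_band_years, rng)
                )
                break
            except DataError:
                if attempt == 3:
                    raise
                n_pool *= 2
    subjects = pd.concat(parts, ignore_index=True)
    subjects.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(subjects))])
    cohort = Cohort(panel=panel, subjects=subjects[
        ["subject_id", "ethnicity", "case", "sex", "age", "bmi"] + panel.rsids
    ])
    return inject_missingness(cohort, spec.missing_rate, rng)
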