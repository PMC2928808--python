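"""Data model and tabular I/O for SNP panels and case-control cohorts.

A *panel* defines the SNPs under study (risk allele, per-allele published
odds ratio, score-inclusion flag).  A *cohort* couples a panel with one row
per subject: identifiers, ethnicity, case status, covariates, and one
risk-allele dosage column per SNP coded 0/1/2 (count of risk alleles on the
forward strand) with NaN for a failed genotype.  Files are plain TSV with
``NA`` (case-insensitive) as the missing sentinel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: Default ethnicity labels of the study design (extensible via AnalysisConfig).
DEFAULT_ETHNICITIES = (
    "EuropeanAmerican",
    "AfricanAmerican",
    "Latino",
    "JapaneseAmerican",
    "NativeHawaiian",
)

PANEL_COLUMNS = ["rsid", "chrom", "gene", "risk_allele", "published_or", "in_score"]
SUBJECT_COLUMNS = ["subject_id", "ethnicity", "case", "sex", "age", "bmi"]
OPTIONAL_SUBJECT_COLUMNS = ["education", "ancestry"]


@dataclass(frozen=True)
class VariantDef:
    """One SNP of the panel.

    ``published_or`` is the per-allele odds ratio reported by the discovery
    literature; its log is the weight of the weighted risk score.
    ``in_score`` marks membership in the default aggregate score (the FTO
    variant is excluded because its diabetes association is mediated by
    adiposity).
    """

    rsid: str
    chrom: str
    gene: str
    risk_allele: str
    published_or: float
    in_score: bool = True

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.risk_allele not in VALID_ALLELES:
            raise ValidationError(
                f"variant {self.rsid}: risk_allele {self.risk_allele!r} "
                f"is not one of A/C/G/T"
            )
        if not np.isfinite(self.published_or) or self.published_or <= 0:
            raise ValidationError(
                f"variant {self.rsid}: published_or must be > 0, "
                f"got {self.published_or!r}"
            )


class Panel:
    """Ordered collection of :class:`VariantDef` with unique rsids."""

    def __init__(self, variants: Iterable[VariantDef]):
        self.variants = list(variants)
        if not self.variants:
            raise ValidationError("empty panel")
        seen: set[str] = set()
        for v in self.variants:
            if v.rsid in seen:
                raise ValidationError(f"duplicate rsid in panel: {v.rsid}")
            seen.add(v.rsid)
        self._by_rsid = {v.rsid: v for v in self.variants}

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def score_rsids(self) -> list[str]:
        """SNPs included in the default aggregate risk score."""
        return [v.rsid for v in self.variants if v.in_score]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantDef]:
        return iter(self.variants)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __getitem__(self, rsid: str) -> VariantDef:
        return self._by_rsid[rsid]

    def published_weights(self) -> dict[str, float]:
        """Log published odds ratio per rsid (weights of the weighted score)."""
        return {v.rsid: float(np.log(v.published_or)) for v in self.variants}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v.rsid, v.chrom, v.gene, v.risk_allele, v.published_or, int(v.in_score))
                for v in self.variants
            ],
            columns=PANEL_COLUMNS,
        )


@dataclass
class SubjectRecord:
    """One subject: phenotype, covariates and per-SNP risk-allele dosages.

    ``dosages`` maps rsid -> 0.0/1.0/2.0 or NaN for a missing genotype.
    """

    subject_id: str
    ethnicity: str
    is_case: bool
    sex: str
    age_years: float
    bmi_kgm2: float
    education_le12yr: bool | None = None
    extra_covariates: dict[str, float] = field(default_factory=dict)
    dosages: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """A panel plus a subjects table (one row per subject).

    ``subjects`` columns: ``subject_id ethnicity case sex age bmi
    [education] [ancestry] <rsid...>``; dosage columns are floats in
    {0, 1, 2, NaN}.
    """

    panel: Panel
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in self.panel.rsids if r not in self.subjects.columns]
        if missing:
            raise ValidationError(f"cohort lacks dosage columns for: {missing}")
        for col in SUBJECT_COLUMNS:
            if col not in self.subjects.columns:
                raise ValidationError(f"cohort lacks required column {col!r}")
        dosed = self.subjects[self.panel.rsids].to_numpy(dtype=float)
        bad = ~(np.isnan(dosed) | np.isin(dosed, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage for subject {self.subjects['subject_id'].iloc[i]!r} at "
                f"{self.panel.rsids[j]} is {dosed[i, j]!r}; must be 0, 1, 2 or NA"
            )

    @property
    def n(self) -> int:
        return len(self.subjects)

    def strata(self) -> list[str]:
        """Ethnicity labels present, in first-appearance order."""
        return list(dict.fromkeys(self.subjects["ethnicity"]))

    def stratum(self, name: str) -> pd.DataFrame:
        sub = self.subjects[self.subjects["ethnicity"] == name]
        if sub.empty:
            raise ValidationError(f"no subjects in stratum {name!r}")
        return sub

    def dosage_matrix(self, rsids: Sequence[str] | None = None) -> np.ndarray:
        return self.subjects[list(rsids or self.panel.rsids)].to_numpy(dtype=float)

    def n_missing_per_subject(self) -> pd.Series:
        return self.subjects[self.panel.rsids].isna().sum(axis=1)

    def iter_records(self) -> Iterator[SubjectRecord]:
        opt = [c for c in OPTIONAL_SUBJECT_COLUMNS if c in self.subjects.columns]
        for _, row in self.subjects.iterrows():
            edu = row["education"] if "education" in opt and pd.notna(row.get("education")) else None
            extra = {c: row[c] for c in opt if c != "education" and pd.notna(row[c])}
            yield SubjectRecord(
                subject_id=str(row["subject_id"]),
                ethnicity=str(row["ethnicity"]),
                is_case=bool(row["case"]),
                sex=str(row["sex"]),
                age_years=float(row["age"]),
                bmi_kgm2=float(row["bmi"]),
                education_le12yr=None if edu is None else bool(edu),
                extra_covariates=extra,
                dosages={r: float(row[r]) for r in self.panel.rsids},
            )


@dataclass
class QCThresholds:
    """Cutoffs of the genotype quality-control stage."""

    max_missing_snps_per_subject: int = 5
    min_call_rate: float = 0.95
    hwe_flag_p: float = 0.01


@dataclass
class AnalysisConfig:
    """Run-wide knobs shared by the analysis stages."""

    alpha: float = 0.05
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "bmi", "sex")
    qc: QCThresholds = field(default_factory=QCThresholds)
    ethnicities: tuple[str, ...] = DEFAULT_ETHNICITIES
    output_dir: str = "transrep_output"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "AnalysisConfig":
        qc = QCThresholds(**cfg.get("qc", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"qc"}
        kwargs = {k: v for k, v in cfg.items() if k in known}
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        if "ethnicities" in kwargs:
            kwargs["ethnicities"] = tuple(kwargs["ethnicities"])
        return cls(qc=qc, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers

def read_panel(path: str | Path) -> Panel:
    """Read a panel TSV (columns ``rsid chrom gene risk_allele published_or
    in_score``) preserving row order."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty panel file") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing panel columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: empty panel")
    variants = []
    for i, row in df.iterrows():
        try:
            variants.append(
                VariantDef(
                    rsid=row["rsid"],
                    chrom=str(row["chrom"]),
                    gene=str(row["gene"]),
                    risk_allele=str(row["risk_allele"]),
                    published_or=float(row["published_or"]),
                    in_score=str(row["in_score"]).strip().lower() in ("1", "true", "yes"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return Panel(variants)


def write_panel(panel: Panel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_cohort(
    path: str | Path,
    panel: Panel,
    ethnicities: Sequence[str] | None = None,
) -> Cohort:
    """Read a cohort TSV against ``panel``.

    Dosage columns must match the panel rsids exactly; values outside
    {0,1,2,NA} and ethnicity labels outside ``ethnicities`` (when given)
    are validation errors.  No row is ever silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, na_values=["NA", "na", "Na", "nA"], keep_default_na=False)
    required = SUBJECT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing subject columns {missing}")
    file_rsids = [c for c in df.columns if c not in SUBJECT_COLUMNS + OPTIONAL_SUBJECT_COLUMNS]
    if set(file_rsids) != set(panel.rsids):
        extra = sorted(set(file_rsids) - set(panel.rsids))
        absent = sorted(set(panel.rsids) - set(file_rsids))
        raise ValidationError(
            f"{path}: dosage columns do not match panel "
            f"(unexpected: {extra}, absent: {absent})"
        )
    if ethnicities is not None:
        unknown = sorted(set(df["ethnicity"]) - set(ethnicities))
        if unknown:
            raise ValidationError(f"{path}: unknown ethnicity labels {unknown}")
    for rsid in panel.rsids:
        try:
            df[rsid] = pd.to_numeric(df[rsid])
        except (ValueError, TypeError):
            raise ValidationError(f"{path}: non-numeric dosage in column {rsid}") from None
    df["case"] = df["case"].astype(int)
    if not df["case"].isin((0, 1)).all():
        raise ValidationError(f"{path}: 'case' must be 0 or 1")
    return Cohort(panel=panel, subjects=df.reset_index(drop=True))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort TSV (missing dosages as ``NA``); lossless round-trip."""
    df = cohort.subjects.copy()
    for rsid in cohort.panel.rsids:
        df[rsid] = df[rsid].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def flip_dosage(dosages: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Recode dosages to the opposite allele (d -> 2 - d), keeping NaN.

    The single place allele/strand orientation is handled: downstream
    statistics only ever see counts of the panel's risk allele.
    """
    return 2.0 - dosages


def write_results_table(results: pd.DataFrame, path: str | Path, sidecar: Mapping | None = None) -> None:
    """Write a results table as TSV with full float precision plus an
    optional JSON summary sidecar at ``<path>.json``."""
    results.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=float))
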