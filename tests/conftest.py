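"""Shared fixtures: small panels and synthetic cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transrep.cohort_io import Cohort, Panel, VariantDef
from transrep.synthetic import SimulationSpec, StratumSpec, simulate_study


def make_panel(n_snps: int = 3, ors: list[float] | None = None) -> Panel:
    ors = ors or [1.3] * n_snps
    return Panel(
        [
            VariantDef(
                rsid=f"rs{i + 1:03d}",
                chrom=str(i + 1),
                gene=f"GENE{i + 1}",
                risk_allele="ACGT"[i % 4],
                published_or=ors[i],
            )
            for i in range(n_snps)
        ]
    )


def make_spec(
    panel: Panel,
    strata_names=("PopA", "PopB"),
    n_cases: int = 150,
    n_controls: int = 150,
    raf: float = 0.3,
    or_gen: float = 1.0,
    **kwargs,
) -> SimulationSpec:
    strata = [
        StratumSpec(
            name=name,
            n_cases=n_cases,
            n_controls=n_controls,
            raf={r: raf for r in panel.rsids},
            or_gen={r: or_gen for r in panel.rsids},
        )
        for name in strata_names
    ]
    return SimulationSpec(strata=strata, **kwargs)


def toy_cohort(panel: Panel, rows: list[dict]) -> Cohort:
    """Cohort from explicit row dictionaries; absent dosages become NaN."""
    frame = pd.DataFrame(rows)
    for rsid in panel.rsids:
        if rsid not in frame.columns:
            frame[rsid] = np.nan
        frame[rsid] = frame[rsid].astype(float)
    if "subject_id" not in frame.columns:
        frame.insert(0, "subject_id", [f"T{i:03d}" for i in range(len(frame))])
    for col, default in (("ethnicity", "PopA"), ("sex", "female"), ("age", 60.0), ("bmi", 26.0)):
        if col not in frame.columns:
            frame[col] = default
    return Cohort(panel=panel, subjects=frame)


@pytest.fixture(scope="session")
def small_panel() -> Panel:
    return make_panel(3)


@pytest.fixture(scope="session")
def small_cohort(small_panel) -> Cohort:
    """Two-stratum null cohort (OR 1) with 2% missingness, 150/150 each."""
    spec = make_spec(small_panel, missing_rate=0.02, seed=11)
    return simulate_study(spec, small_panel, seed=11)


@pytest.fixture(scope="session")
def effect_cohort(small_panel) -> Cohort:
    """Single-stratum cohort with a real effect (OR 1.5), complete data."""
    spec = make_spec(
        small_panel,
        strata_names=("PopA",),
        n_cases=900,
        n_controls=900,
        or_gen=1.5,
        missing_rate=0.0,
        seed=7,
    )
    return simulate_study(spec, small_panel, seed=7)
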