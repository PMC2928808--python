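"""Packaged study parameters: the 19-SNP T2D panel and the published
per-stratum summary data (risk-allele frequencies, per-allele odds ratios,
sample sizes, covariate distributions) of the multiethnic case-control
study the synthetic cohorts emulate.

Everything here is loaded from two plain-text files shipped with the
package (``data/mec_t2d_panel.tsv`` and ``data/mec_t2d_study.yaml``), so a
user can copy and edit them to model a different study.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

from .cohort_io import Panel, read_panel

#: rsid of the FTO variant excluded from the default risk score.
FTO_RSID = "rs8050136"

#: The two KCNQ1 variants analysed with mutual adjustment.
KCNQ1_RSIDS = ("rs2237895", "rs2237897")

#: Centering constant of the published risk-distribution model
#: (mean total risk alleles among all controls).
STUDY_CENTER_RA = 18.5


def _data_path(name: str):
    return resources.files("transrep.data").joinpath(name)


@lru_cache(maxsize=1)
def study_parameters() -> dict:
    """Parsed study-parameter mapping (see the YAML for the schema)."""
    with resources.as_file(_data_path("mec_t2d_study.yaml")) as p:
        return yaml.safe_load(p.read_text())


@lru_cache(maxsize=1)
def default_panel() -> Panel:
    """The 19-SNP panel with published per-allele odds ratios."""
    with resources.as_file(_data_path("mec_t2d_panel.tsv")) as p:
        return read_panel(p)


def ethnicities() -> list[str]:
    return list(study_parameters()["strata"])


def stratum_sizes() -> dict[str, tuple[int, int]]:
    """(n_cases, n_controls) per ethnicity."""
    return {
        name: (s["n_cases"], s["n_controls"])
        for name, s in study_parameters()["strata"].items()
    }


def raf_table() -> pd.DataFrame:
    """Published risk-allele frequencies, rsid x (ethnicity + 'Pooled')."""
    params = study_parameters()
    cols = {name: s["raf"] for name, s in params["strata"].items()}
    cols["Pooled"] = params["pooled"]["raf"]
    return pd.DataFrame(cols).loc[default_panel().rsids]


def or_table() -> pd.DataFrame:
    """Published per-allele odds ratios, rsid x (ethnicity + 'Pooled')."""
    params = study_parameters()
    cols = {name: s["or_gen"] for name, s in params["strata"].items()}
    cols["Pooled"] = params["pooled"]["or"]
    return pd.DataFrame(cols).loc[default_panel().rsids]
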