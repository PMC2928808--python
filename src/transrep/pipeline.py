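"""End-to-end orchestration: simulate/load -> QC -> per-SNP association ->
direction consistency & heterogeneity -> risk score -> risk distributions
-> power, with per-stage logging, deterministic outputs under a fixed
seed, and a manifest of digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, studydata
from .association import association_table
from .cohort_io import (
    AnalysisConfig,
    Cohort,
    read_cohort,
    read_panel,
    write_cohort,
    write_results_table,
)
from .crosspop import direction_summary_from_values, heterogeneity_table
from .exceptions import TransrepError
from .power import panel_power_table
from .qc import apply_qc
from .riskdist import build_distribution, compare_distributions, smooth_distribution
from .score import ScoreConfig, compute_scores, score_assoc, score_summary_table
from .synthetic import SimulationSpec, simulate_study

log = logging.getLogger("transrep")


@dataclass
class RunManifest:
    """Provenance record: identical config + seed => identical digests."""

    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: Mapping, out_dir: str | Path) -> RunManifest:
    """Run every stage and write the report bundle under ``out_dir``.

    ``config`` keys: ``seed``, ``alpha``, ``covariates``, ``qc``,
    ``score``, and either ``simulate: true`` (packaged study design,
    optionally scaled by ``simulate_scale``) / ``simulate_spec: <yaml>``
    or ``cohort: <tsv>`` (+ ``panel: <tsv>``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cfg = AnalysisConfig.from_mapping(config)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=seed,
        version=__version__,
    )

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        for p in paths:
            manifest.outputs[p.name] = _digest(p)
        log.info("stage %s done in %.1fs", stage, manifest.stage_seconds[stage])

    # ----- input stage -------------------------------------------------
    t0 = time.perf_counter()
    if config.get("cohort"):
        panel = read_panel(config["panel"]) if config.get("panel") else studydata.default_panel()
        cohort = read_cohort(config["cohort"], panel)
        log.info("loaded cohort: %d subjects, %d SNPs", cohort.n, len(panel))
    elif config.get("simulate") or config.get("simulate_spec"):
        if config.get("simulate_spec"):
            spec = SimulationSpec.from_yaml(config["simulate_spec"], seed=seed)
        else:
            spec = SimulationSpec.from_study(seed=seed)
        scale = float(config.get("simulate_scale", 1.0))
        if scale != 1.0:
            for s in spec.strata:
                s.n_cases = max(int(s.n_cases * scale), 20)
                s.n_controls = max(int(s.n_controls * scale), 20)
        panel = studydata.default_panel()
        cohort = simulate_study(spec, panel, seed)
        sim_path = out / "cohort.tsv"
        write_cohort(cohort, sim_path)
        log.info("simulated cohort: %d subjects across %d strata", cohort.n, len(spec.strata))
    else:
        raise TransrepError("config must provide 'cohort' or 'simulate'/'simulate_spec'")
    record("input", t0)

    # ----- QC -----------------------------------------------------------
    t0 = time.perf_counter()
    cohort, qc_report = apply_qc(cohort, cfg.qc)
    qc_path = out / "qc_report.tsv"
    write_results_table(
        qc_report.snp_table,
        qc_path,
        sidecar={
            "n_excluded_subjects": qc_report.n_excluded,
            "flags": qc_report.flagged,
        },
    )
    log.info("QC: removed %d subjects, %d flags; %d subjects remain",
             qc_report.n_excluded, len(qc_report.flagged), cohort.n)
    record("qc", t0, qc_path)

    # ----- per-SNP association -----------------------------------------
    t0 = time.perf_counter()
    strata = list(cohort.strata())
    assoc = association_table(cohort, strata + [None], cfg)
    assoc_path = out / "association.tsv"
    write_results_table(assoc, assoc_path)
    record("association", t0, assoc_path)

    # ----- direction consistency / heterogeneity ------------------------
    t0 = time.perf_counter()
    consistency = {}
    for label in strata + ["Pooled"]:
        sub = assoc[(assoc["stratum"] == label) & assoc["or"].notna()]
        consistency[label] = dataclasses.asdict(
            direction_summary_from_values(sub["or"], sub["p"], cfg.alpha)
        )
    cons_path = out / "direction_summary.json"
    cons_path.write_text(json.dumps(consistency, indent=2))
    het = heterogeneity_table(cohort, cfg)
    het_path = out / "heterogeneity.tsv"
    write_results_table(het, het_path)
    record("consistency_het", t0, cons_path, het_path)

    # ----- risk score ----------------------------------------------------
    t0 = time.perf_counter()
    score_cfg = ScoreConfig(**config.get("score", {}))
    scored = compute_scores(cohort, score_cfg)
    score_path = out / "score_summary.tsv"
    write_results_table(score_summary_table(cohort, scored, cfg), score_path)
    record("score", t0, score_path)

    # ----- risk distributions -------------------------------------------
    t0 = time.perf_counter()
    controls = cohort.subjects["case"] == 0
    center = float(scored.scores[controls].mean())
    dists = {}
    plot_rows = []
    for stratum in strata:
        fit = score_assoc(cohort, scored, stratum, cfg)
        mask = controls & (cohort.subjects["ethnicity"] == stratum)
        dist = build_distribution(scored.scores[mask], fit.primary.or_, center, stratum)
        dists[stratum] = dist
        x, dens = smooth_distribution(dist)
        plot_rows.append(pd.DataFrame({"population": stratum, "logrr": x, "density": dens}))
    ref = strata[0]
    comparisons = {
        s: dataclasses.asdict(compare_distributions(dists[s], dists[ref]))
        for s in strata if s != ref
    }
    dist_path = out / "risk_distributions.tsv"
    write_results_table(
        pd.concat(
            [
                pd.DataFrame(
                    {
                        "population": s,
                        "allele_count": d.support,
                        "rel_freq": d.rel_freq,
                        "logrr": d.logrr_grid,
                    }
                )
                for s, d in dists.items()
            ],
            ignore_index=True,
        ),
        dist_path,
        sidecar={"center": center, "comparisons_vs_" + ref: comparisons},
    )
    plot_path = out / "risk_distribution_curves.csv"
    pd.concat(plot_rows, ignore_index=True).to_csv(plot_path, index=False, float_format="%.6g")
    record("risk_distribution", t0, dist_path, plot_path)

    # ----- power ---------------------------------------------------------
    t0 = time.perf_counter()
    sizes = {
        s: (
            int((cohort.stratum(s)["case"] == 1).sum()),
            int((cohort.stratum(s)["case"] == 0).sum()),
        )
        for s in strata
    }
    rafs = pd.DataFrame(
        {s: cohort.stratum(s)[cohort.panel.rsids].mean() / 2.0 for s in strata}
    )
    power_path = out / "power_table.tsv"
    write_results_table(
        panel_power_table(cohort.panel, sizes, rafs, alpha=cfg.alpha), power_path
    )
    record("power", t0, power_path)

    manifest.to_json(out / "manifest.json")
    return manifest


def load_run_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise TransrepError(f"{path}: run config must be a mapping")
    return cfg
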