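"""End-to-end orchestration: catalog -> screen -> activation -> classification
-> IHC -> signature/GSEA on a single seeded configuration.

The demo mode generates the whole study synthetically and exercises every
stage; alternatively, paths to a normal panel, a tumour matrix and a clinical
table can be supplied. Each run writes versioned, deterministic JSON/TSV
reports (config, seed and software version embedded; no timestamps) into a
fresh ``run_NNNN`` directory, so re-running never silently overwrites.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .activation import call_activations, derive_activation_threshold
from .biomarker_screen import ScreenCriteria, run_screen
from .errors import ConfigurationError, InputError
from .io_formats import (
    NormalTissuePanel,
    TumorCohort,
    read_clinical_table,
    read_expression_matrix,
    read_ihc_table,
    read_tissue_labels,
    write_clinical_table,
    write_expression_matrix,
    write_ihc_table,
    write_json_report,
    write_tissue_labels,
)
from .ihc_scoring import ihc_cohort_analysis
from .panel_classifier import (
    derive_clinical_covariates,
    multivariate_analysis,
    score_panel,
    stratified_survival_analysis,
    subgroup_analysis,
)
from .signature import (
    differential_expression,
    gsea_enrichment,
    select_signature_genes,
)
from .io_formats import GeneSet
from .synthetic_data import SimConfig, simulate_ihc_table, simulate_study
from .tissue_catalog import TissueCriteria, select_tissue_predominant_silent_genes


@dataclass
class PipelineConfig:
    """One config for the whole discovery pipeline."""

    sim: Optional[SimConfig] = None
    panel_matrix_path: Optional[str] = None
    tissue_labels_path: Optional[str] = None
    tumor_matrix_path: Optional[str] = None
    clinical_path: Optional[str] = None
    ihc_path: Optional[str] = None
    tissue_criteria: TissueCriteria = field(default_factory=TissueCriteria)
    screen_criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    activation_strategy: str = "background_based"
    activation_multiplier: float = 2.0
    panel_genes: Optional[tuple] = None    # None -> top selected genes
    panel_size: int = 3
    run_subgroups: bool = True
    run_multivariate: bool = True
    run_signature: bool = True
    gsea_permutations: int = 500
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        has_paths = all(
            p is not None
            for p in (
                self.panel_matrix_path,
                self.tissue_labels_path,
                self.tumor_matrix_path,
                self.clinical_path,
            )
        )
        if self.sim is None and not has_paths:
            raise ConfigurationError(
                "either a simulation config or all input paths must be provided"
            )
        if self.activation_strategy not in ("background_based", "interval_midpoint", "fixed_percentile"):
            raise ConfigurationError(f"unknown activation_strategy {self.activation_strategy!r}")
        return self

    def to_dict(self) -> dict:
        return {
            "sim": None if self.sim is None else self.sim.to_dict(),
            "paths": {
                "panel_matrix": self.panel_matrix_path,
                "tissue_labels": self.tissue_labels_path,
                "tumor_matrix": self.tumor_matrix_path,
                "clinical": self.clinical_path,
                "ihc": self.ihc_path,
            },
            "tissue_criteria": self.tissue_criteria.to_dict(),
            "screen_criteria": self.screen_criteria.to_dict(),
            "activation_strategy": self.activation_strategy,
            "activation_multiplier": self.activation_multiplier,
            "panel_genes": None if self.panel_genes is None else list(self.panel_genes),
            "panel_size": self.panel_size,
            "run_subgroups": self.run_subgroups,
            "run_multivariate": self.run_multivariate,
            "run_signature": self.run_signature,
            "gsea_permutations": self.gsea_permutations,
            "seed": self.seed,
            "version": __version__,
        }


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small fully-synthetic configuration exercising every stage."""
    sim = SimConfig(
        n_genes=300,
        n_tissue_specific=40,
        n_ectopic_candidates=40,
        n_true_prognostic=3,
        n_patients=300,
        seed=seed,
    )
    return PipelineConfig(sim=sim, seed=seed, gsea_permutations=500)


def _next_run_dir(out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 1
    while (out_dir / f"run_{n:04d}").exists():
        n += 1
    run_dir = out_dir / f"run_{n:04d}"
    run_dir.mkdir()
    return run_dir


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the enabled stages in order; returns the versioned run directory."""
    config.validate()
    run_dir = _next_run_dir(Path(out_dir))
    log_lines: list[str] = []
    t0 = _time.perf_counter()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{_time.perf_counter() - t0:8.2f}s] {stage}: {msg}")

    meta = {"config": config.to_dict(), "version": __version__, "seed": config.seed}
    write_json_report(meta, run_dir / "config.json")

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.sim is not None:
        panel, cohort, ihc, truth = simulate_study(config.sim)
        write_expression_matrix(panel.expression, run_dir / "normal_panel.tsv")
        write_tissue_labels(
            panel.tissue_of_sample, panel.germline_tissues, run_dir / "tissues.tsv"
        )
        write_expression_matrix(cohort.expression, run_dir / "tumor_matrix.tsv")
        write_clinical_table(cohort.clinical, run_dir / "clinical.tsv")
        write_ihc_table(ihc, run_dir / "ihc.tsv")
        write_json_report(truth.to_dict(), run_dir / "truth.json")
        log("simulate", f"{cohort.expression.values.shape} tumour matrix, "
            f"{panel.expression.values.shape} normal panel")
    else:
        matrix = read_expression_matrix(config.panel_matrix_path)
        labels, germ = read_tissue_labels(config.tissue_labels_path)
        panel = NormalTissuePanel(matrix, labels, germ)
        cohort = TumorCohort(
            read_expression_matrix(config.tumor_matrix_path),
            read_clinical_table(config.clinical_path),
        )
        ihc = read_ihc_table(config.ihc_path) if config.ihc_path else None
        log("load", "inputs read from disk")

    # --- tissue catalog ---------------------------------------------------
    candidates, profiles = select_tissue_predominant_silent_genes(
        panel, config.tissue_criteria
    )
    write_json_report(
        {
            "criteria": config.tissue_criteria.to_dict(),
            "selected": candidates,
            "n_genes_tested": len(profiles),
            "profiles": {g: profiles[g].to_dict() for g in candidates},
        },
        run_dir / "catalog.json",
    )
    log("catalog", f"{len(candidates)} tissue-predominant silent genes")
    if not candidates:
        raise InputError("tissue catalog selected no candidate genes")

    # --- biomarker screen -------------------------------------------------
    screenable = [g for g in candidates if g in cohort.expression.values.index]
    screen = run_screen(cohort, screenable, config.screen_criteria)
    write_json_report(screen.to_dict(include_scans=False), run_dir / "screen.json")
    log("screen", f"{len(screen.selected_genes)} of {screen.n_candidates} genes selected")

    # --- panel choice and activation calls --------------------------------
    if config.panel_genes is not None:
        panel_genes = list(config.panel_genes)
        missing = [g for g in panel_genes if g not in screenable]
        if missing:
            raise InputError(f"configured panel genes not among candidates: {missing}")
    else:
        panel_genes = screen.selected_genes[: config.panel_size]
    if not panel_genes:
        raise InputError("no panel genes available (screen selected nothing)")

    screen_by_gene = {r.gene_id: r for r in screen.results}
    rules = {}
    for g in panel_genes:
        rules[g] = derive_activation_threshold(
            g,
            strategy=config.activation_strategy,
            profile=profiles.get(g),
            scan=screen_by_gene[g].scan if g in screen_by_gene else None,
            percentile=60.0,
            multiplier=config.activation_multiplier,
        )
    activations = call_activations(cohort, rules)
    act_out = activations.calls.copy()
    act_out.index.name = "gene_id"
    act_out.to_csv(run_dir / "activations.tsv", sep="\t", lineterminator="\n")
    log("activate", f"panel {panel_genes}")

    # --- classification ---------------------------------------------------
    scores = score_panel(activations, panel_genes)
    strat = stratified_survival_analysis(scores, cohort.clinical)
    classification: dict = {
        "panel_genes": panel_genes,
        "rules": {g: rules[g].to_dict() for g in panel_genes},
        "stratification": strat.to_dict(),
    }
    covariates = derive_clinical_covariates(cohort.clinical)
    if config.run_subgroups:
        subgroups = {}
        for by in ("stage_class", "hpv", "site_class"):
            try:
                per_level = subgroup_analysis(scores, covariates, cohort.clinical, by)
            except InputError as exc:
                subgroups[by] = {"skipped": str(exc)}
                continue
            subgroups[by] = {
                level: {
                    "flags": d["flags"],
                    "report": None if d["report"] is None else d["report"].to_dict(),
                }
                for level, d in per_level.items()
            }
        classification["subgroups"] = subgroups
    if config.run_multivariate:
        mv = multivariate_analysis(
            scores, covariates, cohort.clinical, ("age", "gender", "stage_class")
        )
        classification["multivariate"] = mv.to_dict()
    write_json_report(classification, run_dir / "classification.json")
    log("classify", f"risk groups {dict(scores['risk_group'].value_counts())}")

    # --- IHC --------------------------------------------------------------
    if ihc is not None and set(ihc["marker"]) >= {"AREG", "CCNA1", "DDX20"}:
        ihc_res = ihc_cohort_analysis(ihc, cohort.clinical)
        write_json_report(
            {
                "panel_report": ihc_res["panel_report"].to_dict(),
                "per_marker_logrank": ihc_res["per_marker_logrank"],
                "ccna1_rule": ihc_res["ccna1_rule"],
            },
            run_dir / "ihc_report.json",
        )
        log("ihc", "IHC cohort analysed")

    # --- signature + GSEA -------------------------------------------------
    if config.run_signature:
        groups = pd.Series(
            ["positive" if r == "poor" else "negative" for r in scores["risk_group"]],
            index=scores.index,
        )
        counts = groups.value_counts()
        if {"positive", "negative"} <= set(counts.index) and counts.min() >= 2:
            de = differential_expression(cohort.expression.values, groups)
            de.to_csv(run_dir / "de_table.tsv", sep="\t", lineterminator="\n")
            sets = select_signature_genes(de)
            gsea_results = []
            ranking = de["log_ratio"]
            for name, members in (("signature_up", sets.up), ("signature_down", sets.down)):
                if members and len(members) < len(ranking):
                    gs = GeneSet(name=name, description="derived signature", genes=tuple(sorted(members)))
                    gsea_results.append(
                        gsea_enrichment(
                            ranking, gs,
                            n_permutations=config.gsea_permutations,
                            seed=config.seed,
                        ).to_dict()
                    )
            write_json_report(
                {"signature": sets.to_dict(), "gsea": gsea_results},
                run_dir / "signature.json",
            )
            log("signature", f"{len(sets.up)} up / {len(sets.down)} down genes")
        else:
            log("signature", "skipped: a DE group has fewer than 2 patients")

    with open(run_dir / "log.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return run_dir
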