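"""End-to-end pipeline orchestration: simulate → filter → quantify → select → enrich.

Every stage persists its table under the output directory, and the run is
summarized in a JSON :class:`RunReport` with per-stage record counts and
wall-clock times.  Identical config + seed gives byte-identical tables
(wall-clock fields excluded).  A stage failure aborts the run with the
failing stage named and leaves a ``<run>.partial`` marker next to the
outputs already written.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrich as enrich_mod
from . import io as io_mod
from .fdr import compute_fdr, filter_fdr
from .quantify import aggregate_proteins, build_reporter_matrix, peptide_ratios, quantile_normalize
from .select import SelectionThresholds, select_deps
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger("iquantdep")


@dataclass
class PipelineConfig:
    """Resolved parameters for a full pipeline run.

    Defaults are the study's printed analysis settings: PSM FDR < 0.01,
    raw p < 0.1, at least 2 nonredundant peptides, 90th-percentile
    fold-change cutoffs, enrichment at p < 0.1 with >= 3 overlapping DEPs.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    fdr_threshold: float = 0.01
    normalize: str = "joint"
    enrich_p_cut: float = 0.1
    min_overlap: int = 3
    celltype_p_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        thr = SelectionThresholds(**raw.pop("thresholds", {}))
        return cls(simulation=sim, thresholds=thr, **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Per-stage record counts and timings for one pipeline run."""

    seed: int
    config: dict
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Run all stages on a freshly simulated dataset and persist everything."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial_marker = out / "run.partial"
    partial_marker.write_text("run in progress\n")

    report = RunReport(
        seed=config.simulation.seed,
        config=config.resolved(),
        version=__version__,
    )
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        psms, truth, collection = generate_dataset(config.simulation)
        io_mod.write_psm_tsv(psms, out / "psms.tsv")
        io_mod.write_truth(truth, out / "truth.tsv")
        io_mod.write_gmt(collection, out / "gene_sets.gmt")
        report.counts["psms_simulated"] = len(psms)
        report.counts["proteins_simulated"] = len(truth)
        report.timings_s[stage] = time.perf_counter() - t0
        logger.info("simulate: %d PSMs, %d proteins", len(psms), len(truth))

        stage = "filter"
        t0 = time.perf_counter()
        annotated = compute_fdr(psms)
        passed = filter_fdr(annotated, config.fdr_threshold)
        io_mod.write_psm_tsv(passed, out / "psms.passed.tsv")
        report.counts["psms_passed_fdr"] = len(passed)
        report.timings_s[stage] = time.perf_counter() - t0
        logger.info("filter: %d/%d PSMs at FDR < %g",
                    len(passed), len(psms), config.fdr_threshold)

        stage = "quantify"
        t0 = time.perf_counter()
        matrix = build_reporter_matrix(passed)
        matrix = quantile_normalize(matrix, mode=config.normalize)
        ratios = peptide_ratios(matrix)
        proteins = aggregate_proteins(ratios)
        io_mod.write_protein_ratios(proteins, out / "protein_ratios.tsv")
        report.counts["peptides_quantified"] = int(matrix.shape[0])
        report.counts["proteins_quantified"] = int(proteins["protein"].nunique())
        report.timings_s[stage] = time.perf_counter() - t0
        logger.info("quantify: %d proteins from %d peptides",
                    report.counts["proteins_quantified"], matrix.shape[0])

        stage = "deps"
        t0 = time.perf_counter()
        deps = select_deps(proteins, config.thresholds)
        io_mod.write_dep_table(deps, out / "deps.tsv")
        report.counts["deps_1day"] = int(deps["is_dep_1day"].sum())
        report.counts["deps_2month"] = int(deps["is_dep_2month"].sum())
        report.counts["deps_2m_over_1d"] = int(deps["is_dep_2m_over_1d"].sum())
        report.counts["fc_cutoff_1day"] = deps.attrs["fc_cutoff_1day"]
        report.counts["fc_cutoff_2month"] = deps.attrs["fc_cutoff_2month"]
        report.counts["norm_fc_cutoff"] = deps.attrs["norm_fc_cutoff"]
        report.timings_s[stage] = time.perf_counter() - t0
        logger.info("deps: %d / %d / %d (1 day / 2 month / 2m over 1d)",
                    report.counts["deps_1day"], report.counts["deps_2month"],
                    report.counts["deps_2m_over_1d"])

        stage = "enrich"
        t0 = time.perf_counter()
        markers = collection.subset(enrich_mod.MARKER_SET_NAMES)
        func_names = [n for n in collection.names()
                      if n not in enrich_mod.MARKER_SET_NAMES]
        results = []
        if func_names:
            functional = enrich_mod.enrich_sets(
                deps, collection.subset(func_names),
                p_cut=config.enrich_p_cut, min_overlap=config.min_overlap,
            )
            io_mod.write_enrichment(functional, out / "enrichment.tsv")
            results.append(functional)
            report.counts["enrichment_passes"] = int(functional["passes"].sum())
        profile = enrich_mod.cell_type_profile(
            deps, markers, p_cut=config.celltype_p_cut)
        io_mod.write_enrichment(profile, out / "cell_type_profile.tsv")
        report.counts["celltype_passes"] = int(profile["passes"].sum())
        report.timings_s[stage] = time.perf_counter() - t0
        logger.info("enrich: %d cell-type rows pass p < %g",
                    report.counts["celltype_passes"], config.celltype_p_cut)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    partial_marker.unlink()
    io_mod.write_json_report(report.to_dict(), out / "report.json")
    return report
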