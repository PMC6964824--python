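"""End-to-end pipeline runner and the summary matrix of significant alterations.

Stages run in dependency order: motif scan -> classification -> {mutation
enrichment, Ti/Tv, signatures, methylation, CNA} -> summary. A stage whose
inputs are missing or that fails is recorded and the independent stages still
run; the summary marks it with a dash. All stage defaults equal the study
constants (score fraction 0.80, per-patient minimum 5, delta-beta and CNA
thresholds 0.2, 10,000 bootstrap iterations, 180 kb gene radius) and every
run is fully determined by the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import (cna_analysis, io_formats, methylation_analysis, motif_engine,
               mutation_analysis, signature_refit)

logger = logging.getLogger("boundaryalt")


@dataclass
class PipelineConfig:
    """Input paths and per-stage parameters for one cohort run."""

    fasta: str
    boundaries: str
    peaks: str
    mutations: str | None = None
    probes: str | None = None
    segments: str | None = None
    tss: str | None = None
    pfm: str | None = None            # JASPAR PFM; synthetic model if None
    catalog: str | None = None        # signature catalogue TSV
    cancer_type: str = "cohort"

    min_fraction: float = 0.80
    min_count: int = 5
    delta_beta_threshold: float = 0.2
    cna_threshold: float = 0.2
    cna_percentile: int = 50
    bootstrap_iterations: int = 10_000
    radius: int = 180_000
    alpha: float = 0.05
    seed: int = 0
    enrichment_method: str = "gof"    # "gof" | "homogeneity"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the config's inputs allow; return the result bundle.

    The bundle maps stage names to their result objects, plus ``errors``
    (stage -> message), ``log`` (parameters and input checksums) and
    ``summary`` (the per-analysis significance matrix).
    """
    results: dict = {"errors": {}, "log": {"config": config.to_dict(),
                                           "checksums": {}}}
    for name in ("fasta", "boundaries", "peaks", "mutations", "probes",
                 "segments", "tss", "pfm", "catalog"):
        path = getattr(config, name)
        if path and Path(path).exists():
            results["log"]["checksums"][name] = _checksum(path)

    # --- scan + classify ---------------------------------------------------
    genome = io_formats.read_fasta(config.fasta)
    if config.pfm:
        model = motif_engine.build_motif_model(
            io_formats.read_jaspar_pfm(config.pfm))
    else:
        from .synthetic_data import synthetic_ctcf_model
        model = synthetic_ctcf_model()
    sites = motif_engine.scan_genome(genome, model, config.min_fraction,
                                     dedup=True)
    boundaries = io_formats.read_bed(config.boundaries, "boundary")
    peaks = io_formats.read_bed(config.peaks, "peak")
    motif_engine.classify_sites(sites, peaks, boundaries)
    results["sites"] = sites
    results["class_summary"] = motif_engine.summarize_classes(sites)
    logger.info("scanned %d sites: %s", len(sites), results["class_summary"])

    mutations = None
    if config.mutations:
        mutations, n_rejected = io_formats.read_mutations(config.mutations)
        results["log"]["mutations_rejected"] = n_rejected

    # --- mutation enrichment + Ti/Tv --------------------------------------
    if mutations is not None:
        try:
            contingency = mutation_analysis.count_per_patient(
                mutations, sites, min_count=config.min_count)
            q = mutation_analysis.expected_in_fraction(sites)
            results["mutation_contingency"] = contingency
            results["mutation"] = mutation_analysis.mutation_enrichment_test(
                contingency, expected_fraction=q,
                method=config.enrichment_method)
        except (ValueError, KeyError) as exc:
            results["errors"]["mutation"] = str(exc)
        try:
            table, test = mutation_analysis.titv_table(mutations, sites)
            results["titv_table"] = table
            results["titv"] = test
        except ValueError as exc:
            results["errors"]["titv"] = str(exc)
        if config.tss:
            try:
                tss = io_formats.read_bed(config.tss, "tss")
                results["near_genes"] = mutation_analysis.genes_near_mutated_sites(
                    mutations, sites, tss, radius=config.radius)
            except (ValueError, io_formats.ParseError) as exc:
                results["errors"]["near_genes"] = str(exc)

    # --- signatures --------------------------------------------------------
    if mutations is not None and config.catalog:
        try:
            catalog = signature_refit.read_catalog(config.catalog)
            whole = signature_refit.build_spectrum(mutations, genome)
            coll, _ = mutation_analysis._active_site_index(
                s for s in sites if s.in_boundary)
            subset = [m for m in mutations
                      if mutation_analysis.sites_hit_by(m, coll)]
            sub_spec = signature_refit.build_spectrum(subset, genome)
            exp_whole = signature_refit.refit_exposures(whole, catalog)
            exp_sub = signature_refit.refit_exposures(sub_spec, catalog)
            results["signatures"] = exp_sub
            results["signatures_whole"] = exp_whole
            results["signature_diff"] = signature_refit.compare_exposures(
                exp_sub, exp_whole)
        except ValueError as exc:
            results["errors"]["signatures"] = str(exc)

    # --- methylation -------------------------------------------------------
    if config.probes:
        try:
            probes, rej = io_formats.read_probes(config.probes)
            results["log"]["probes_rejected"] = rej
            assignments = methylation_analysis.assign_probes(probes, sites)
            d_in, d_off = methylation_analysis.deltas_by_class(assignments)
            results["methylation"] = methylation_analysis.bootstrap_group_test(
                d_in, d_off, n_iterations=config.bootstrap_iterations,
                seed=config.seed)
        except (ValueError, io_formats.ParseError) as exc:
            results["errors"]["methylation"] = str(exc)

    # --- CNA ---------------------------------------------------------------
    if config.segments:
        try:
            segments, rej = io_formats.read_segments(config.segments)
            results["log"]["segments_rejected"] = rej
            mutated = cna_analysis.filter_mutated_segments(
                segments, threshold=config.cna_threshold)
            strata = cna_analysis.stratify_segments(mutated)
            group = strata.groups.get(config.cna_percentile, mutated)
            contingency, test = cna_analysis.cna_contingency_test(
                group, sites, method=config.enrichment_method)
            results["cna_contingency"] = contingency
            results["cna"] = test
            results["cna_median_size"] = strata.cutoffs.get(50)
        except ValueError as exc:
            results["errors"]["cna"] = str(exc)

    results["summary"] = build_summary({config.cancer_type: results},
                                       alpha=config.alpha)
    return results


def _cell(stage: str, res, alpha: float) -> str:
    if res is None:
        return "-"
    if stage == "methylation":
        direction = "+" if res.observed_mean_in > res.observed_mean_off else "-"
        if res.empirical_p < alpha or res.empirical_p > 1.0 - alpha:
            return f"Y({direction})"
        return "N"
    return "Y" if res.p_value < alpha else "N"


def build_summary(results_by_cancer: Mapping[str, Mapping], alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Significance matrix: one row per cancer, one column per analysis.

    Cells are Y (p strictly below alpha), N, or "-" when the stage did not
    run; methylation cells carry the direction sign, Y(+) for
    hyper-methylation and Y(-) for hypo-methylation (one-tailed empirical p
    near 0 or 1 respectively).
    """
    rows = {}
    for cancer, res in results_by_cancer.items():
        rows[cancer] = {
            "mutation": _cell("mutation", res.get("mutation"), alpha),
            "methylation": _cell("methylation", res.get("methylation"), alpha),
            "cna": _cell("cna", res.get("cna"), alpha),
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["mutation", "methylation", "cna"])
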