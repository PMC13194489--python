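"""End-to-end orchestration: one config in, a reproducible report bundle out.

A run covers up to five stages — genome/variant simulation (or loading
real inputs), variant annotation, genome-wide mutation statistics,
structure comparison, expression and phenotype analysis — and emits one
TSV/CSV per report plus a manifest (config hash, seed, version) that
suffices to reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import delta_delta_ct, write_expression_csv
from .genome import AnnotatedGenome
from .mutstats import (
    comparison_summary,
    detect_hotspots,
    find_large_gaps,
    genome_reduction,
    mutational_background,
    write_hotspot_tsv,
    write_summary_tsv,
)
from .phenotype import GrowthCurve, fit_growth_rate, fold_change_rates, write_rates_csv
from .simulate import (
    EvolutionScenario,
    alignment_blocks_from_deletions,
    evolve_lineage,
    generate_ancestral_genome,
    generate_ct_table,
    generate_growth_curves,
    generate_structure_pair,
)
from .structure import comparison_report, write_model_pdb, write_ss_string
from .variants import (
    aggregate_gene_profiles,
    annotate_variants,
    read_snippy_tsv,
    read_vcf,
    write_annotated_tsv,
    write_vcf,
)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Each stage block is either a synthetic-scenario mapping or (for the
    genomic stage) a mapping of real input paths {fasta, gff3, vcf|snippy};
    exactly one of the two per stage.
    """

    seed: int = 0
    output_dir: str = "geoevo_out"
    hotspot_factor: float = 3.0
    background_denominator: str = "cds"
    min_gap: int = 1000
    alpha: float = 0.05
    scenario: dict | None = None
    inputs: dict | None = None
    structure: dict | None = None
    expression: dict | None = None
    phenotype: dict | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError(
                "configure exactly one of a synthetic scenario or real inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "seed", "output_dir", "hotspot_factor", "background_denominator",
            "min_gap", "alpha", "scenario", "inputs", "structure",
            "expression", "phenotype")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns {report name: path or value}.

    Identical config + seed gives a byte-identical bundle (the manifest
    carries no timestamps).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    parent, variants, truth = _genomic_inputs(config, out, bundle)
    annotated = annotate_variants(parent, variants)
    write_annotated_tsv(out / "annotated_variants.tsv", annotated)
    bundle["annotated_variants"] = str(out / "annotated_variants.tsv")

    descendant = bundle.pop("_descendant", None)
    summary = comparison_summary(
        parent, descendant or parent, annotated,
        comparison="descendant vs parent",
        hotspot_factor=config.hotspot_factor,
        background_denominator=config.background_denominator)
    write_summary_tsv(out / "comparison_summary.tsv", [summary])
    bundle["comparison_summary"] = str(out / "comparison_summary.tsv")

    profiles = aggregate_gene_profiles(annotated, parent)
    denom_kb = (parent.coding_length if config.background_denominator == "cds"
                else len(parent.sequence)) / 1000.0
    background = mutational_background(profiles, denom_kb)
    hotspots = detect_hotspots(profiles, background, config.hotspot_factor)
    write_hotspot_tsv(out / "hotspots.tsv", hotspots)
    bundle["hotspots"] = str(out / "hotspots.tsv")

    _write_gene_changes(out, profiles)
    bundle["gene_changes"] = str(out / "gene_changes.tsv")

    if descendant is not None:
        bundle["genome_reduction_percent"] = genome_reduction(
            len(parent.sequence), len(descendant.sequence))
    if truth is not None and truth.deleted_intervals:
        blocks = alignment_blocks_from_deletions(
            truth.deleted_intervals, len(parent.sequence))
        gaps = find_large_gaps(blocks, config.min_gap)
        pd.DataFrame([{"ref_start": g.ref_start, "ref_end": g.ref_end,
                       "length": g.length} for g in gaps],
                     columns=["ref_start", "ref_end", "length"]).to_csv(
            out / "large_gaps.tsv", sep="\t", index=False)
        bundle["large_gaps"] = str(out / "large_gaps.tsv")

    if config.structure is not None:
        _structure_stage(config, out, bundle)
    if config.expression is not None:
        _expression_stage(config, out, bundle)
    if config.phenotype is not None:
        _phenotype_stage(config, out, bundle)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps({k: v for k, v in config.to_dict().items()
                        if k != "output_dir"},  # location is not an input
                       sort_keys=True).encode()).hexdigest(),
        "reports": sorted(k for k in bundle if isinstance(bundle[k], str)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = str(out / "manifest.json")
    return bundle


def _genomic_inputs(config, out, bundle):
    if config.scenario is not None:
        scenario = EvolutionScenario(**{**config.scenario, "seed": config.seed})
        parent = generate_ancestral_genome(scenario)
        descendant, variants, truth = evolve_lineage(parent, scenario)
        parent.write_fasta(out / "ancestor.fasta")
        parent.write_gff3(out / "ancestor.gff3")
        descendant.write_fasta(out / "descendant.fasta")
        descendant.write_gff3(out / "descendant.gff3")
        write_vcf(out / "variants.vcf", parent, variants)
        truth.write_tsv(out / "truth.tsv")
        bundle.update(ancestor=str(out / "ancestor.fasta"),
                      variants=str(out / "variants.vcf"),
                      truth=str(out / "truth.tsv"))
        bundle["_descendant"] = descendant
        return parent, variants, truth
    paths = config.inputs
    parent = AnnotatedGenome.read(paths["fasta"], paths["gff3"])
    if "vcf" in paths:
        variants = read_vcf(paths["vcf"])
    elif "snippy" in paths:
        variants = read_snippy_tsv(paths["snippy"])
    else:
        raise ValueError("real inputs need a 'vcf' or 'snippy' variant table")
    return parent, variants, None


def _write_gene_changes(out, profiles):
    rows = [{"locus_id": p.locus_id, "gene_length": p.gene_length,
             "n_total": p.n_total, "n_functional": p.n_functional,
             "n_category_changes": p.n_category_changes, "n_lof": p.n_lof}
            for p in profiles]
    pd.DataFrame(rows).to_csv(out / "gene_changes.tsv", sep="\t", index=False)


def _structure_stage(config, out, bundle):
    params = dict(config.structure)
    model_a, model_b = generate_structure_pair(
        seed=config.seed, **params)
    write_model_pdb(model_a, out / "model_a.pdb")
    write_model_pdb(model_b, out / "model_b.pdb")
    write_ss_string(model_a.ss_string, out / "model_a.ss")
    write_ss_string(model_b.ss_string, out / "model_b.ss")
    report = comparison_report(model_a, model_b)
    pd.DataFrame([{"statistic": k, "value": v} for k, v in report.items()]) \
        .to_csv(out / "structure_comparison.tsv", sep="\t", index=False)
    bundle["structure_comparison"] = str(out / "structure_comparison.tsv")


def _expression_stage(config, out, bundle):
    params = dict(config.expression)
    housekeeping = params.pop("housekeeping_gene", "recA")
    reference = params.pop("reference_strain", None)
    folds = {tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
             for k, v in params.pop("true_folds", {}).items()}
    table = generate_ct_table(true_folds=folds, seed=config.seed,
                              housekeeping_gene=housekeeping, **params)
    table.to_csv(out / "ct_table.csv", index=False)
    result = delta_delta_ct(table, housekeeping,
                            reference or params["strains"][0])
    write_expression_csv(result, out / "expression.csv")
    bundle["expression"] = str(out / "expression.csv")


def _phenotype_stage(config, out, bundle):
    params = dict(config.phenotype)
    table = generate_growth_curves(seed=config.seed, **params)
    table.to_csv(out / "growth_curves.csv", index=False)
    curves = [GrowthCurve(strain, acc, int(rep), g.time.to_numpy(),
                          g.value.to_numpy(), unit)
              for (strain, acc, rep, unit), g in table.groupby(
                  ["strain", "acceptor", "replicate", "unit"], sort=True)]
    estimates = [fit_growth_rate(c) for c in curves]
    write_rates_csv(estimates, out / "growth_rates.csv")
    bundle["phenotype"] = str(out / "growth_rates.csv")
    bundle["rate_estimates"] = estimates
    return estimates
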