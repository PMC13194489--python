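"""Mutation-census statistics against enumeration oracles and planted truth."""

import math

import numpy as np
import pytest

from geoevo import (
    AlignmentBlock,
    VariantRecord,
    comparison_summary,
    detect_hotspots,
    find_large_gaps,
    genome_dnds,
    genome_reduction,
    lof_fraction,
    mutated_fraction,
    mutational_background,
    ng_site_counts,
    ts_tv,
)
from geoevo.mutstats import genome_site_totals, read_alignment_blocks
from geoevo.simulate import EvolutionScenario, evolve_lineage, generate_ancestral_genome
from geoevo.variants import (
    CODON_TO_AA,
    SENSE_CODONS,
    GeneMutationProfile,
    annotate_variants,
)

BASES = "ACGT"


def enumerate_site_counts(codon):
    """Brute-force Nei-Gojobori sites: fraction of the 9 neighbors synonymous."""
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:  # stop is never equal
                syn += 1 / 3
    return syn, 3.0 - syn


# ------------------------------------------------------------------- Ts/Tv


def test_ts_tv_counting():
    mk = lambda pairs: [VariantRecord(i + 1, r, a) for i, (r, a) in enumerate(pairs)]
    assert ts_tv(mk([("A", "G"), ("G", "A"), ("C", "T"), ("A", "C")])) == 3.0
    assert ts_tv(mk([("A", "C")])) == 0.0
    assert math.isinf(ts_tv(mk([("A", "G")])))
    with pytest.raises(ValueError):
        ts_tv([VariantRecord(1, "AT", "A")])  # indels only: no SNPs


# ---------------------------------------------------------------- NG sites


@pytest.mark.parametrize(
    "codon, expected",
    [("TTT", (1 / 3, 8 / 3)), ("GGA", (1.0, 2.0)), ("ATG", (0.0, 3.0))],
)
def test_ng_site_counts_worked_examples(codon, expected):
    s, n = ng_site_counts(codon)
    assert s == pytest.approx(expected[0])
    assert n == pytest.approx(expected[1])


def test_ng_site_counts_match_enumeration_for_all_sense_codons():
    assert len(SENSE_CODONS) == 61
    for codon in SENSE_CODONS:
        s, n = ng_site_counts(codon)
        es, en = enumerate_site_counts(codon)
        assert s == pytest.approx(es), codon
        assert n == pytest.approx(en), codon
        assert s + n == pytest.approx(3.0)
    with pytest.raises(ValueError):
        ng_site_counts("TAA")


def test_genome_site_totals_equal_per_codon_enumeration(tiny_genome):
    S, N = genome_site_totals(tiny_genome)
    expected_S = expected_N = 0.0
    for f in tiny_genome.features:
        cds = f.cds_sequence(tiny_genome.sequence)
        for i in range(0, len(cds) - 3, 3):  # skip the terminal stop
            s, n = enumerate_site_counts(cds[i : i + 3])
            expected_S += s
            expected_N += n
    assert S == pytest.approx(expected_S)
    assert N == pytest.approx(expected_N)


# ------------------------------------------------------------------- dN/dS


def test_dnds_micro_example_matches_hand_computation(tiny_genome):
    """1 synonymous + 1 missense SNP: dN/dS = (1/N)/(1/S)."""
    variants = [VariantRecord(10, "A", "G"), VariantRecord(11, "C", "G")]
    annotated = annotate_variants(tiny_genome, variants)
    S, N = genome_site_totals(tiny_genome)
    assert genome_dnds(tiny_genome, annotated) == pytest.approx((1 / N) / (1 / S))


def test_dnds_degenerate_variant_sets(tiny_genome):
    syn_only = annotate_variants(tiny_genome, [VariantRecord(10, "A", "G")])
    assert genome_dnds(tiny_genome, syn_only) == 0.0
    nonsyn_only = annotate_variants(tiny_genome, [VariantRecord(11, "C", "G")])
    assert math.isnan(genome_dnds(tiny_genome, nonsyn_only))


# -------------------------------------------------- densities and hotspots


def test_mutational_background_arithmetic():
    profiles = [GeneMutationProfile("a", 1000, n_functional=41)]
    assert mutational_background(profiles, 3336.0) == pytest.approx(0.0123, abs=2e-4)
    assert mutational_background([], 100.0) == 0.0
    assert mutational_background(profiles, 200.0) == pytest.approx(
        2 * mutational_background(profiles, 400.0))
    with pytest.raises(ValueError):
        mutational_background(profiles, 0.0)


def test_hotspot_rule_and_properties():
    bg = 0.01  # per kb
    cold = GeneMutationProfile("cold", 1000, n_functional=0)
    hot = GeneMutationProfile("hot", 1000, n_functional=1)  # density 1.0/kb
    assert detect_hotspots([cold, hot], bg, factor=3) == [hot]
    # monotonicity: adding a functional SNP never removes a hotspot
    hotter = GeneMutationProfile("hot", 1000, n_functional=2)
    assert hotter in detect_hotspots([cold, hotter], bg, factor=3)
    # scale invariance: rescaling lengths and counts together changes nothing
    scaled = [GeneMutationProfile("cold", 10000, n_functional=0),
              GeneMutationProfile("hot", 10000, n_functional=10)]
    assert [p.locus_id for p in detect_hotspots(scaled, bg, factor=3)] == ["hot"]
    with pytest.raises(ValueError):
        detect_hotspots([GeneMutationProfile("bad", 0, n_functional=1)], bg)


def test_lof_fraction_bounds():
    mk = lambda lof, func: [GeneMutationProfile("g", 300, n_functional=func,
                                                n_lof=lof)]
    assert lof_fraction(mk(6, 41)) == pytest.approx(14.6, abs=0.05)
    assert lof_fraction(mk(0, 10)) == 0.0
    assert lof_fraction(mk(10, 10)) == 100.0
    assert math.isnan(lof_fraction(mk(0, 0)))


def test_genome_reduction_and_census_percentages():
    assert genome_reduction(3_814_128, 3_726_411) == pytest.approx(2.3, abs=0.05)
    assert genome_reduction(3_726_411, 3_714_300) == pytest.approx(0.32, abs=0.01)
    assert genome_reduction(100, 100) == 0.0
    assert genome_reduction(100, 110) == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        genome_reduction(0, 10)
    assert mutated_fraction(74, 274) == pytest.approx(27.0, abs=0.05)
    assert mutated_fraction(23, 77) == pytest.approx(30.0, abs=0.15)


# -------------------------------------------------------------- large gaps


def test_find_large_gaps_basics(tmp_path):
    whole = [AlignmentBlock(1, 1000, 1, 1000)]
    assert find_large_gaps(whole, min_gap=50, ref_length=1000) == []
    blocks = [AlignmentBlock(1, 100, 1, 100), AlignmentBlock(201, 300, 101, 200)]
    (gap,) = find_large_gaps(blocks, min_gap=50)
    assert (gap.ref_start, gap.ref_end, gap.length) == (101, 200, 100)
    assert (gap.left_query, gap.right_query) == (100, 101)
    assert find_large_gaps(blocks, min_gap=150) == []
    with pytest.raises(ValueError, match="overlap"):
        find_large_gaps([AlignmentBlock(1, 100, 1, 100),
                         AlignmentBlock(50, 200, 50, 200)])
    # coords-style TSV reader round-trip
    tsv = tmp_path / "blocks.tsv"
    tsv.write_text("ref_start\tref_end\tqry_start\tqry_end\torientation\n"
                   "1\t100\t1\t100\t+\n201\t300\t101\t200\t+\n")
    assert read_alignment_blocks(tsv) == blocks


# ------------------------------------------------------------- summary row


def test_comparison_summary_recovers_planted_regime(lineage, lt_like_scenario):
    parent, descendant, variants, truth = lineage
    annotated = annotate_variants(parent, variants)
    summary = comparison_summary(parent, descendant, annotated)
    assert summary.total_snps == lt_like_scenario.n_snps
    assert summary.n_functional == truth.n_functional
    assert summary.n_lof == truth.n_lof
    assert summary.lof_percent == pytest.approx(100 * truth.n_lof / truth.n_functional)
    assert summary.n_hotspots <= summary.n_genes_with_functional
    assert 0 <= summary.lof_percent <= 100
    assert summary.ts_tv == pytest.approx(
        truth.n_transitions / truth.n_transversions)
    # genome reduction equals the planted deletion load
    lost = sum(b - a + 1 for a, b in truth.deleted_intervals) + truth.n_indels
    assert len(parent.sequence) - len(descendant.sequence) == lost
    assert genome_reduction(len(parent.sequence), len(descendant.sequence)) == \
        pytest.approx(100 * lost / len(parent.sequence))


def test_comparison_summary_null_scenario():
    scenario = EvolutionScenario(n_genes=5, mean_gene_len=40, n_snps=0, seed=2)
    parent = generate_ancestral_genome(scenario)
    descendant, variants, _ = evolve_lineage(parent, scenario)
    assert variants == []
    summary = comparison_summary(parent, descendant, [])
    assert summary.total_snps == 0 and summary.n_functional == 0
    assert math.isnan(summary.ts_tv) and math.isnan(summary.lof_percent)
    assert summary.dnds == 0.0  # no substitutions at all
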