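"""Variant-effect classification against exhaustive translate-and-compare."""

import numpy as np
import pytest

from geoevo import (
    AnnotatedGenome,
    CDSFeature,
    VariantRecord,
    aa_category,
    aggregate_gene_profiles,
    classify_variant,
)
from geoevo.genome import revcomp
from geoevo.variants import (
    AA_CATEGORIES,
    CODON_TO_AA,
    SENSE_CODONS,
    START_CODONS,
    annotate_variants,
    read_snippy_tsv,
    read_vcf,
    write_annotated_tsv,
    write_vcf,
)

BASES = "ACGT"


def translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def oracle_effect(cds: str, local_pos: int, alt_base: str) -> str:
    """Independent full-CDS translate-and-compare classification of a SNP."""
    alt_cds = cds[:local_pos] + alt_base + cds[local_pos + 1 :]
    if local_pos < 3:  # start codon
        return "synonymous" if alt_cds[:3] in START_CODONS else "start_loss"
    ref_prot, alt_prot = translate(cds), translate(alt_cds)
    if ref_prot == alt_prot:
        return "synonymous"
    ref_stop = ref_prot.index("*") if "*" in ref_prot else len(ref_prot)
    alt_stop = alt_prot.index("*") if "*" in alt_prot else len(alt_prot)
    if alt_stop < ref_stop:
        return "nonsense"
    if alt_stop > ref_stop:
        return "stop_loss"
    return "missense"


# ---------------------------------------------------------------- categories


def test_aa_categories_cover_all_twenty_residues_once():
    assert len(AA_CATEGORIES) == 20
    assert aa_category("D") == "negative"
    assert aa_category("K") == "positive"
    assert aa_category("P") == "special"
    assert aa_category("A") == "nonpolar-aliphatic"
    # the proline-to-alanine substitution crosses categories
    assert aa_category("P") != aa_category("A")
    with pytest.raises(ValueError):
        aa_category("X")


# ------------------------------------------------------------ worked examples


@pytest.mark.parametrize(
    "pos, ref, alt, effect, functional",
    [
        (10, "A", "G", "synonymous", False),  # GGA->GGG, Gly degeneracy
        (11, "C", "G", "missense", True),     # CCT->GCT, Pro->Ala
        (16, "G", "A", "nonsense", True),     # TGG->TGA
        (19, "A", "C", "stop_loss", True),    # TAA->TAC
        (18, "A", "G", "synonymous", False),  # TAA->TGA, stop retained
        (6, "T", "C", "start_loss", True),    # ATG->ACG
        (5, "A", "G", "synonymous", False),   # ATG->GTG, alternative start
        (2, "T", "A", "intergenic", False),
    ],
)
def test_plus_strand_effects(tiny_genome, pos, ref, alt, effect, functional):
    av = classify_variant(tiny_genome, VariantRecord(pos, ref, alt))
    assert av.effect == effect
    assert av.is_functional == functional


def test_proline_to_alanine_is_category_change(tiny_genome):
    av = classify_variant(tiny_genome, VariantRecord(11, "C", "G"))
    assert (av.ref_aa, av.alt_aa) == ("P", "A")
    assert av.is_category_change


def test_minus_strand_codon_extraction(tiny_genome):
    # G_MINUS codon AAA -> GAA is Lys->Glu; forward-strand alleles are complements
    av = classify_variant(tiny_genome, VariantRecord(32, "T", "C"))
    assert (av.locus_id, av.effect) == ("G_MINUS", "missense")
    assert (av.ref_aa, av.alt_aa) == ("K", "E")
    assert av.is_category_change  # positive -> negative


def test_indels_in_and_out_of_cds(tiny_genome):
    fs = classify_variant(tiny_genome, VariantRecord(9, "GA", "G"))
    assert fs.effect == "frameshift" and fs.is_lof
    inframe = classify_variant(tiny_genome, VariantRecord(9, "GACC", "G"))
    assert inframe.effect == "inframe_indel" and not inframe.is_lof
    inter = classify_variant(tiny_genome, VariantRecord(1, "TT", "T"))
    assert inter.effect == "intergenic"


def test_reference_mismatch_and_out_of_range_raise(tiny_genome):
    with pytest.raises(ValueError, match="mismatch"):
        classify_variant(tiny_genome, VariantRecord(10, "C", "G"))
    with pytest.raises(ValueError, match="outside"):
        classify_variant(tiny_genome, VariantRecord(999, "A", "G"))


# ----------------------------------------------------------- exhaustive oracle


def test_all_tgg_substitutions_match_genetic_code():
    """All 9 single-base changes of TGG: 7 missense + 2 nonsense."""
    seq = "ATG" + "TGG" + "TAA"
    genome = AnnotatedGenome("t", seq, [CDSFeature("g", 1, 9, "+")])
    effects = []
    for i in range(3, 6):
        for b in BASES:
            if b == seq[i]:
                continue
            effects.append(classify_variant(
                genome, VariantRecord(i + 1, seq[i], b)).effect)
    assert sorted(effects).count("missense") == 7
    assert sorted(effects).count("nonsense") == 2


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classification_matches_translate_oracle(strand):
    """Every substitution of 300 random codons agrees with the oracle, both strands."""
    rng = np.random.default_rng(42)
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=300)]
    cds = "ATG" + "".join(codons) + "TAA"
    seq = "AC" + (cds if strand == "+" else revcomp(cds)) + "GT"
    genome = AnnotatedGenome("o", seq, [CDSFeature("g", 3, 2 + len(cds), strand)])
    f = genome.features[0]
    for local in range(len(cds)):
        pos = f.start + local if strand == "+" else f.end - local
        ref_cds = cds[local]
        ref_fwd = ref_cds if strand == "+" else revcomp(ref_cds)
        for b in BASES:
            if b == ref_cds:
                continue
            alt_fwd = b if strand == "+" else revcomp(b)
            got = classify_variant(genome, VariantRecord(pos, ref_fwd, alt_fwd))
            assert got.effect == oracle_effect(cds, local, b), (local, b)


def test_strand_symmetry_of_classification():
    """A minus-strand call equals the call on the reverse-complemented construction."""
    rng = np.random.default_rng(7)
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=50)]
    cds = "ATG" + "".join(codons) + "TGA"
    fwd = AnnotatedGenome("f", cds, [CDSFeature("g", 1, len(cds), "+")])
    rev = AnnotatedGenome("r", revcomp(cds), [CDSFeature("g", 1, len(cds), "-")])
    for local in rng.integers(len(cds), size=120):
        local = int(local)
        ref = cds[local]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        a = classify_variant(fwd, VariantRecord(local + 1, ref, alt))
        b = classify_variant(
            rev, VariantRecord(len(cds) - local, revcomp(ref), revcomp(alt)))
        assert a.effect == b.effect
        assert (a.ref_aa, a.alt_aa) == (b.ref_aa, b.alt_aa)


# ------------------------------------------------------------------ aggregation


def test_effect_partition_and_profile_counts(lineage):
    """Each variant gets exactly one class; per-gene tallies are consistent."""
    parent, _, variants, _ = lineage
    annotated = annotate_variants(parent, variants)
    assert len(annotated) == len(variants)  # no CDS overlap in the simulation
    profiles = aggregate_gene_profiles(annotated, parent)
    in_genes = [av for av in annotated if av.locus_id is not None]
    assert sum(p.n_total for p in profiles) == len(in_genes)
    for p in profiles:
        assert p.n_functional + p.n_synonymous == p.n_total
        assert p.n_lof <= p.n_functional


def test_aggregate_empty_and_counting(tiny_genome):
    assert aggregate_gene_profiles([], tiny_genome) == []
    variants = [VariantRecord(11, "C", "G"), VariantRecord(16, "G", "A"),
                VariantRecord(10, "A", "G")]
    profiles = aggregate_gene_profiles(
        annotate_variants(tiny_genome, variants), tiny_genome)
    (p,) = profiles
    assert (p.n_total, p.n_functional, p.n_synonymous, p.n_lof) == (3, 2, 1, 1)


# -------------------------------------------------------------------------- IO


def test_vcf_and_snippy_round_trip(tmp_path, tiny_genome):
    variants = [VariantRecord(10, "A", "G"), VariantRecord(9, "GA", "G"),
                VariantRecord(32, "T", "C")]
    vcf = tmp_path / "v.vcf"
    write_vcf(vcf, tiny_genome, variants)
    assert sorted(read_vcf(vcf), key=lambda v: v.position) == sorted(
        variants, key=lambda v: v.position)

    snippy = tmp_path / "v.tab"
    snippy.write_text("CHROM\tPOS\tTYPE\tREF\tALT\n"
                      "tiny\t10\tsnp\tA\tG\ntiny\t32\tsnp\tT\tC\n")
    recs = read_snippy_tsv(snippy)
    assert recs == [VariantRecord(10, "A", "G"), VariantRecord(32, "T", "C")]

    out = tmp_path / "ann.tsv"
    write_annotated_tsv(out, annotate_variants(tiny_genome, variants))
    assert "missense" in out.read_text()
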