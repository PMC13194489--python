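"""Variant-effect annotation against an annotated bacterial genome.

Each variant is classified into exactly one effect class (synonymous,
missense, nonsense, start_loss, stop_loss, frameshift, inframe_indel or
intergenic) by strand-aware codon lookup under the bacterial/archaeal
translation table (NCBI table 11; alternative initiation codons at an
annotated start are read as Met).  "Functional" means any coding change
that alters the protein product; LOF (loss of function) is the
nonsense + frameshift + start-loss subset, following the convention of
standard prokaryotic effect annotators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .genome import AnnotatedGenome, CDSFeature, revcomp

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid; '*' for stop codons
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE11.stop_codons})

START_CODONS = frozenset(_TABLE11.start_codons)
STOP_CODONS = frozenset(_TABLE11.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

#: physicochemical classes used to score amino-acid category changes
AA_CATEGORIES: dict[str, str] = {
    **{aa: "nonpolar-aliphatic" for aa in "AVLIM"},
    **{aa: "aromatic" for aa in "FYW"},
    **{aa: "polar-uncharged" for aa in "STNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "CGP"},
}

EFFECT_CLASSES = (
    "synonymous", "missense", "nonsense", "start_loss", "stop_loss",
    "frameshift", "inframe_indel", "intergenic",
)

FUNCTIONAL_EFFECTS = frozenset(EFFECT_CLASSES) - {"synonymous", "intergenic"}
LOF_EFFECTS = frozenset({"nonsense", "frameshift", "start_loss"})


def aa_category(aa: str) -> str:
    """Physicochemical category of a standard residue.

    Six classes: nonpolar-aliphatic (AVLIM), aromatic (FYW), polar-uncharged
    (STNQ), positive (KRH), negative (DE) and special (CGP, the
    conformationally/chemically atypical residues).  A proline-to-alanine
    substitution is therefore a category change.
    """
    try:
        return AA_CATEGORIES[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


@dataclass(frozen=True)
class VariantRecord:
    """One variant in VCF convention: 1-based, alleles on the forward strand.

    Indels are anchored (e.g. REF=AC, ALT=A for a 1-bp deletion).
    """

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"allele must be nonempty uppercase ACGT: {allele!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def type(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele):
            return "SNP" if len(self.ref_allele) == 1 else "MNP"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_snp(self) -> bool:
        return self.type == "SNP"

    @property
    def is_transition(self) -> bool:
        return self.is_snp and {self.ref_allele, self.alt_allele} in ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True)
class AnnotatedVariant:
    """A VariantRecord joined to its gene, codon context and effect class."""

    variant: VariantRecord
    locus_id: str | None  # None = intergenic
    effect: str
    codon_index: int | None = None  # 0-based codon within the CDS
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_functional(self) -> bool:
        return self.effect in FUNCTIONAL_EFFECTS

    @property
    def is_lof(self) -> bool:
        return self.effect in LOF_EFFECTS

    @property
    def is_category_change(self) -> bool:
        """True for missense changes crossing physicochemical categories."""
        if self.effect != "missense":
            return False
        return aa_category(self.ref_aa) != aa_category(self.alt_aa)


@dataclass
class GeneMutationProfile:
    """Per-gene mutation tallies underlying hotspot detection."""

    locus_id: str
    gene_length: int  # bp
    n_total: int = 0
    n_synonymous: int = 0
    n_functional: int = 0
    n_lof: int = 0
    n_category_changes: int = 0

    @property
    def functional_density(self) -> float:
        """Functional variants per kb of gene."""
        if self.gene_length <= 0:
            raise ValueError(f"{self.locus_id}: non-positive gene length")
        return self.n_functional / (self.gene_length / 1000.0)


# --------------------------------------------------------------- classification


def _check_reference(genome: AnnotatedGenome, v: VariantRecord) -> None:
    if v.position > len(genome.sequence):
        raise ValueError(f"position {v.position} outside sequence of length {len(genome)}")
    end = v.position + len(v.ref_allele) - 1
    observed = genome.sequence[v.position - 1 : end]
    if observed != v.ref_allele:
        raise ValueError(
            f"reference mismatch at {v.position}: genome has {observed!r}, "
            f"variant claims {v.ref_allele!r}"
        )


def _classify_in_cds(genome: AnnotatedGenome, v: VariantRecord,
                     f: CDSFeature) -> AnnotatedVariant:
    if v.length_change != 0:
        effect = "inframe_indel" if v.length_change % 3 == 0 else "frameshift"
        return AnnotatedVariant(v, f.locus_id, effect)

    cds = f.cds_sequence(genome.sequence)
    n_codons = len(cds) // 3

    # map the substituted reference span into CDS-local coordinates
    if f.strand == "+":
        local_start = v.position - f.start
        ref_local, alt_local = v.ref_allele, v.alt_allele
    else:
        # last substituted base maps to the smallest local coordinate
        local_start = f.end - (v.position + len(v.ref_allele) - 1)
        ref_local, alt_local = revcomp(v.ref_allele), revcomp(v.alt_allele)

    local_end = local_start + len(ref_local) - 1
    first_codon = local_start // 3
    last_codon = local_end // 3

    ref_seg = cds[first_codon * 3 : (last_codon + 1) * 3]
    offset = local_start - first_codon * 3
    alt_seg = ref_seg[:offset] + alt_local + ref_seg[offset + len(ref_local):]
    if ref_seg[:offset] + ref_local + ref_seg[offset + len(ref_local):] != ref_seg:
        raise AssertionError("internal codon bookkeeping error")

    ref_aas = "".join(CODON_TO_AA[ref_seg[i : i + 3]] for i in range(0, len(ref_seg), 3))
    alt_aas = "".join(CODON_TO_AA[alt_seg[i : i + 3]] for i in range(0, len(alt_seg), 3))

    ref_codon = ref_seg[:3] if first_codon == last_codon else ref_seg
    alt_codon = alt_seg[:3] if first_codon == last_codon else alt_seg

    common = dict(codon_index=first_codon, ref_codon=ref_codon, alt_codon=alt_codon,
                  ref_aa=ref_aas, alt_aa=alt_aas)

    if first_codon == 0:
        # annotated start codon: alternative initiators (GTG/TTG...) read as Met
        if alt_codon in START_CODONS:
            return AnnotatedVariant(v, f.locus_id, "synonymous",
                                    **{**common, "ref_aa": "M", "alt_aa": "M"})
        return AnnotatedVariant(v, f.locus_id, "start_loss",
                                **{**common, "ref_aa": "M"})
    if "*" in ref_aas:  # touches the annotated stop codon
        if "*" not in alt_aas:
            effect = "stop_loss"
        elif alt_aas.index("*") < ref_aas.index("*"):
            effect = "nonsense"
        elif alt_aas == ref_aas:
            effect = "synonymous"
        else:
            effect = "missense"  # stop retained, an upstream residue changed
        return AnnotatedVariant(v, f.locus_id, effect, **common)
    if "*" in alt_aas:
        return AnnotatedVariant(v, f.locus_id, "nonsense", **common)
    if ref_aas == alt_aas:
        return AnnotatedVariant(v, f.locus_id, "synonymous", **common)
    return AnnotatedVariant(v, f.locus_id, "missense", **common)


def classify_variant(genome: AnnotatedGenome, v: VariantRecord,
                     feature: CDSFeature | None = None) -> AnnotatedVariant:
    """Classify one variant into exactly one effect class.

    If ``feature`` is given the variant is classified against that CDS;
    otherwise against the first overlapping CDS (use
    :func:`classify_variant_all_loci` when CDS overlap matters).
    Raises on coordinate or reference-allele inconsistency.
    """
    _check_reference(genome, v)
    if feature is None:
        hits = genome.features_at(v.position)
        if not hits:
            return AnnotatedVariant(v, None, "intergenic")
        feature = hits[0]
    elif not feature.contains(v.position):
        raise ValueError(f"variant at {v.position} outside {feature.locus_id}")
    return _classify_in_cds(genome, v, feature)


def classify_variant_all_loci(genome: AnnotatedGenome,
                              v: VariantRecord) -> list[AnnotatedVariant]:
    """One AnnotatedVariant per overlapping CDS (or a single intergenic call)."""
    _check_reference(genome, v)
    hits = genome.features_at(v.position)
    if not hits:
        return [AnnotatedVariant(v, None, "intergenic")]
    return [_classify_in_cds(genome, v, f) for f in hits]


def annotate_variants(genome: AnnotatedGenome,
                      variants: list[VariantRecord]) -> list[AnnotatedVariant]:
    """Classify a variant list; overlapping CDS yield one record per locus."""
    out: list[AnnotatedVariant] = []
    for v in variants:
        out.extend(classify_variant_all_loci(genome, v))
    return out


def aggregate_gene_profiles(annotated: list[AnnotatedVariant],
                            genome: AnnotatedGenome,
                            include_zero: bool = False) -> list[GeneMutationProfile]:
    """Collapse annotated variants into per-gene mutation profiles.

    Returns one profile per locus carrying at least one variant, plus
    zero-count profiles for every annotated gene when ``include_zero``.
    """
    known = {f.locus_id: f for f in genome.features}
    profiles: dict[str, GeneMutationProfile] = {}
    if include_zero:
        for f in genome.features:
            profiles[f.locus_id] = GeneMutationProfile(f.locus_id, f.length)
    for av in annotated:
        if av.locus_id is None:
            continue
        if av.locus_id not in known:
            raise ValueError(f"variant references unknown locus {av.locus_id}")
        p = profiles.setdefault(
            av.locus_id, GeneMutationProfile(av.locus_id, known[av.locus_id].length))
        p.n_total += 1
        if av.effect == "synonymous":
            p.n_synonymous += 1
        if av.is_functional:
            p.n_functional += 1
        if av.is_lof:
            p.n_lof += 1
        if av.is_category_change:
            p.n_category_changes += 1
    return sorted(profiles.values(), key=lambda p: p.locus_id)


# ------------------------------------------------------------------------- I/O


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNPs/indels from a (plain-text or bgzipped) VCF 4.x file."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            for alt in rec.alts or ():
                out.append(VariantRecord(rec.pos, rec.ref.upper(), alt.upper()))
    return out


def write_vcf(path: str | Path, genome: AnnotatedGenome,
              variants: list[VariantRecord]) -> None:
    """Write a minimal VCF 4.2 with the genome as the single contig."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome.sequence)}>\n")
        fh.write("##source=geoevo\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.position):
            fh.write(f"{genome.id}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\tPASS\t.\n")


def read_snippy_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a Snippy-style tab file (CHROM, POS, TYPE, REF, ALT[, EFFECT...])."""
    df = pd.read_csv(path, sep="\t")
    required = {"POS", "REF", "ALT"}
    if not required <= set(df.columns):
        raise ValueError(f"Snippy table must contain columns {sorted(required)}")
    return [VariantRecord(int(r.POS), str(r.REF).upper(), str(r.ALT).upper())
            for r in df.itertuples()]


def write_annotated_tsv(path: str | Path, annotated: list[AnnotatedVariant]) -> None:
    rows = []
    for av in annotated:
        rows.append({
            "position": av.variant.position,
            "ref": av.variant.ref_allele,
            "alt": av.variant.alt_allele,
            "type": av.variant.type,
            "locus_id": av.locus_id or "intergenic",
            "effect": av.effect,
            "codon_index": av.codon_index,
            "ref_codon": av.ref_codon,
            "alt_codon": av.alt_codon,
            "ref_aa": av.ref_aa,
            "alt_aa": av.alt_aa,
            "is_functional": av.is_functional,
            "is_lof": av.is_lof,
            "is_category_change": av.is_category_change,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
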