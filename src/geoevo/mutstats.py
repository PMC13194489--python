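"""Genome-wide mutation statistics for an evolved-vs-parent genome pair.

Implements the census statistics used to summarize clonal divergence in
experimental-evolution resequencing: SNP tallies, transition/transversion
ratio, genome-wide dN/dS by Nei–Gojobori (equal-pathway) site counting,
functional-SNP background density, mutational-hotspot detection at a
configurable fold-over-background threshold, loss-of-function fractions,
genome-size reduction, and large alignment-gap detection.

dN/dS here is the single-pair census estimator

    dN/dS = (Nd / N) / (Sd / S)

with N and S the nonsynonymous/synonymous site totals summed over every
reference CDS codon and Nd, Sd the observed substitution counts.  No
multiple-hit correction is applied by default: at the divergences this
package targets (1e-5..1e-3 substitutions per site) the Jukes–Cantor
correction is far below counting noise.  A corrected variant is available
via ``jukes_cantor=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd

from .genome import AnnotatedGenome
from .variants import (
    CODON_TO_AA,
    STOP_CODONS,
    AnnotatedVariant,
    GeneMutationProfile,
)

_BASES = "ACGT"


# ------------------------------------------------------------------- Ts/Tv


def ts_tv(variants: list) -> float:
    """Transition/transversion ratio over the SNPs in a variant list.

    Transitions are A<->G and C<->T.  Indels are ignored.  Returns
    ``math.inf`` when there are transitions but no transversions.
    """
    snps = [v for v in _as_records(variants) if v.is_snp]
    if not snps:
        raise ValueError("no SNPs to compute Ts/Tv from")
    ts = sum(1 for v in snps if v.is_transition)
    tv = len(snps) - ts
    if tv == 0:
        return math.inf
    return ts / tv


def _as_records(variants):
    return [v.variant if isinstance(v, AnnotatedVariant) else v for v in variants]


# ----------------------------------------------------- Nei–Gojobori sites


@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts for a sense codon.

    Each codon position contributes (number of synonymous single-base
    changes at that position)/3 synonymous sites; mutations to stop codons
    count as nonsynonymous.  The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        n_syn = sum(
            1
            for b in _BASES
            if b != codon[i] and CODON_TO_AA[codon[:i] + b + codon[i + 1:]] == aa
        )
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def genome_site_totals(genome: AnnotatedGenome) -> tuple[float, float]:
    """(S, N): Nei–Gojobori site totals over all sense codons of all CDS."""
    S = N = 0.0
    for f in genome.features:
        cds = f.cds_sequence(genome.sequence)
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in STOP_CODONS:
                continue  # terminal stop codon carries no sense sites
            s, n = ng_site_counts(codon)
            S += s
            N += n
    return S, N


def genome_dnds(genome: AnnotatedGenome, annotated: list[AnnotatedVariant],
                jukes_cantor: bool = False) -> float:
    """Genome-wide dN/dS from classified SNPs against the reference CDS set.

    Counts only single-base substitutions inside CDS: nonsynonymous =
    missense + nonsense + stop_loss + start_loss; synonymous = synonymous.
    Returns ``math.nan`` (undefined) when no synonymous substitution was
    observed, 0.0 when all substitutions are synonymous.
    """
    S, N = genome_site_totals(genome)
    if S == 0 or N == 0:
        raise ValueError("genome has no coding sites")
    Sd = Nd = 0
    seen = set()
    for av in annotated:
        if not av.variant.is_snp or av.locus_id is None:
            continue
        if av.variant.position in seen:  # overlapping CDS: count once
            continue
        seen.add(av.variant.position)
        if av.effect == "synonymous":
            Sd += 1
        elif av.effect in ("missense", "nonsense", "stop_loss", "start_loss"):
            Nd += 1
    if Sd == 0:
        return 0.0 if Nd == 0 else math.nan
    ps, pn = Sd / S, Nd / N
    if jukes_cantor:
        ps = -0.75 * math.log(1 - 4 * ps / 3)
        pn = -0.75 * math.log(1 - 4 * pn / 3)
    return pn / ps


# --------------------------------------------------- densities & hotspots


def mutational_background(profiles: list[GeneMutationProfile],
                          coding_length_kb: float) -> float:
    """Functional SNPs per kb of coding sequence (the genome background)."""
    if coding_length_kb <= 0:
        raise ValueError("coding length must be positive")
    return sum(p.n_functional for p in profiles) / coding_length_kb


def detect_hotspots(profiles: list[GeneMutationProfile],
                    background_density: float,
                    factor: float = 3.0) -> list[GeneMutationProfile]:
    """Genes whose functional-mutation density is >= factor x background.

    A gene qualifies when it carries at least one functional variant and
    its per-gene density (functional variants / gene kb) reaches
    ``factor * background_density``.  Returned sorted by density, descending.
    """
    if background_density < 0:
        raise ValueError("background density must be >= 0")
    hits = [
        p for p in profiles
        if p.n_functional >= 1
        and p.functional_density >= factor * background_density
    ]
    return sorted(hits, key=lambda p: p.functional_density, reverse=True)


def lof_fraction(profiles: list[GeneMutationProfile]) -> float:
    """Percent of functional mutations that are loss-of-function."""
    n_func = sum(p.n_functional for p in profiles)
    if n_func == 0:
        return math.nan
    return 100.0 * sum(p.n_lof for p in profiles) / n_func


def genome_reduction(size_parent: int, size_descendant: int) -> float:
    """Percent genome-size reduction from parent to descendant (negative = growth)."""
    if size_parent <= 0 or size_descendant <= 0:
        raise ValueError("genome sizes must be positive")
    return 100.0 * (size_parent - size_descendant) / size_parent


def mutated_fraction(n_mutated: int, n_total: int) -> float:
    """Percent of a gene census carrying mutations (e.g. 74 of 274 -> 27.0)."""
    if n_total <= 0:
        raise ValueError("census total must be positive")
    if not 0 <= n_mutated <= n_total:
        raise ValueError("mutated count outside [0, total]")
    return 100.0 * n_mutated / n_total


# ------------------------------------------------------------- large gaps


@dataclass(frozen=True)
class AlignmentBlock:
    """A colinear aligned block between reference and query (1-based, inclusive)."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    orientation: str = "+"

    def __post_init__(self):
        if self.ref_end < self.ref_start or self.qry_end < self.qry_start:
            raise ValueError("block ends must be >= starts")


@dataclass(frozen=True)
class Gap:
    """A reference interval absent from the query, with flanking query coords."""

    ref_start: int
    ref_end: int
    left_query: int | None  # query coordinate flanking the gap on the left
    right_query: int | None

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


def find_large_gaps(blocks: list[AlignmentBlock], min_gap: int = 1000,
                    ref_length: int | None = None) -> list[Gap]:
    """Reference intervals uncovered between consecutive alignment blocks.

    Blocks must be sorted by reference start and non-overlapping on the
    reference.  Terminal gaps (before the first / after the last block) are
    reported when ``ref_length`` is given.  The default 1 kb threshold marks
    "large" gaps of the kind produced by multi-gene deletions.
    """
    blocks = sorted(blocks, key=lambda b: b.ref_start)
    for a, b in zip(blocks, blocks[1:]):
        if b.ref_start <= a.ref_end:
            raise ValueError("alignment blocks overlap on the reference")
    gaps: list[Gap] = []
    if blocks and blocks[0].ref_start > 1:
        g = Gap(1, blocks[0].ref_start - 1, None, blocks[0].qry_start)
        if g.length >= min_gap:
            gaps.append(g)
    for a, b in zip(blocks, blocks[1:]):
        if b.ref_start - a.ref_end - 1 >= min_gap:
            gaps.append(Gap(a.ref_end + 1, b.ref_start - 1, a.qry_end, b.qry_start))
    if ref_length is not None and blocks and blocks[-1].ref_end < ref_length:
        g = Gap(blocks[-1].ref_end + 1, ref_length, blocks[-1].qry_end, None)
        if g.length >= min_gap:
            gaps.append(g)
    return gaps


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read a coords-style TSV (ref_start, ref_end, qry_start, qry_end, orientation)."""
    df = pd.read_csv(path, sep="\t")
    return [AlignmentBlock(int(r.ref_start), int(r.ref_end), int(r.qry_start),
                           int(r.qry_end), str(getattr(r, "orientation", "+")))
            for r in df.itertuples()]


# ------------------------------------------------------------ summary row


@dataclass
class ComparisonSummary:
    """One row of genome-wide mutation statistics for an evolved/parent pair."""

    comparison: str
    total_snps: int
    ts_tv: float
    dnds: float
    n_functional: int
    background_density: float  # functional SNPs per kb
    n_genes_with_functional: int
    n_hotspots: int
    n_lof: int
    lof_percent: float
    background_denominator: str = "cds"  # 'cds' or 'genome'

    COLUMNS = (
        "comparison", "total_snps", "ts_tv", "dnds", "n_functional",
        "background_density", "n_genes_with_functional", "n_hotspots",
        "n_lof", "lof_percent", "background_denominator",
    )

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def comparison_summary(genome_parent: AnnotatedGenome,
                       genome_descendant: AnnotatedGenome,
                       annotated: list[AnnotatedVariant],
                       comparison: str = "descendant vs parent",
                       hotspot_factor: float = 3.0,
                       background_denominator: str = "cds") -> ComparisonSummary:
    """Assemble all genome-wide mutation statistics for one pair.

    ``background_denominator`` selects the density denominator: total CDS
    length ('cds', default) or total genome length ('genome'); the choice is
    echoed in the output row.
    """
    from .variants import aggregate_gene_profiles

    snps = [av for av in annotated if av.variant.is_snp]
    # genome-wide totals: count each variant position once even when CDS overlap
    by_pos: dict[int, AnnotatedVariant] = {}
    for av in annotated:
        prev = by_pos.get(av.variant.position)
        if prev is None or (av.is_functional and not prev.is_functional):
            by_pos[av.variant.position] = av
    unique = list(by_pos.values())
    unique_snps = [av for av in unique if av.variant.is_snp]

    profiles = aggregate_gene_profiles(annotated, genome_parent)
    if background_denominator == "cds":
        denom_kb = genome_parent.coding_length / 1000.0
    elif background_denominator == "genome":
        denom_kb = len(genome_parent.sequence) / 1000.0
    else:
        raise ValueError("background_denominator must be 'cds' or 'genome'")

    n_functional = sum(1 for av in unique if av.is_functional)
    n_lof = sum(1 for av in unique if av.is_lof)
    background = n_functional / denom_kb
    hotspots = detect_hotspots(profiles, background, hotspot_factor)

    return ComparisonSummary(
        comparison=comparison,
        total_snps=len(unique_snps),
        ts_tv=ts_tv(unique_snps) if unique_snps else math.nan,
        dnds=genome_dnds(genome_parent, snps),
        n_functional=n_functional,
        background_density=background,
        n_genes_with_functional=sum(1 for p in profiles if p.n_functional > 0),
        n_hotspots=len(hotspots),
        n_lof=n_lof,
        lof_percent=100.0 * n_lof / n_functional if n_functional else math.nan,
        background_denominator=background_denominator,
    )


def write_summary_tsv(path: str | Path, summaries: list[ComparisonSummary]) -> None:
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(path, sep="\t", index=False)


def write_hotspot_tsv(path: str | Path, hotspots: list[GeneMutationProfile]) -> None:
    rows = [{"locus_id": p.locus_id, "gene_length": p.gene_length,
             "n_functional": p.n_functional, "n_lof": p.n_lof,
             "functional_density_per_kb": p.functional_density}
            for p in hotspots]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
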