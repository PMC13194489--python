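"""Annotated bacterial genome: nucleotide sequence plus CDS features.

This container is the coordinate frame for all variant-effect calls.
Coordinates follow the GFF3/VCF convention: 1-based, inclusive.  CDS
features carry a strand; sequence extraction is strand-resolved
(reverse-complemented for minus-strand genes).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CDSFeature:
    """A protein-coding feature on the genome (1-based inclusive span)."""

    locus_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"{self.locus_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_sequence(self, genome_sequence: str) -> str:
        """Coding-strand sequence (reverse-complemented for '-' features)."""
        s = genome_sequence[self.start - 1 : self.end]
        return revcomp(s) if self.strand == "-" else s


@dataclass
class AnnotatedGenome:
    """A genome sequence with non-splicing CDS annotations.

    Invariants enforced at construction: features lie within the sequence,
    CDS lengths are multiples of 3, locus ids are unique.
    """

    id: str
    sequence: str
    features: list[CDSFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        seen = set()
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"{f.locus_id} extends past sequence end")
            if f.length % 3 != 0:
                raise ValueError(f"{f.locus_id} length {f.length} not divisible by 3")
            if f.locus_id in seen:
                raise ValueError(f"duplicate locus id {f.locus_id}")
            seen.add(f.locus_id)
        self.features = sorted(self.features, key=lambda f: f.start)
        self._starts = [f.start for f in self.features]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coding_length(self) -> int:
        """Total CDS length in bp (overlaps, if any, counted once per locus)."""
        return sum(f.length for f in self.features)

    def feature_by_locus(self, locus_id: str) -> CDSFeature:
        for f in self.features:
            if f.locus_id == locus_id:
                return f
        raise KeyError(locus_id)

    def features_at(self, pos: int) -> list[CDSFeature]:
        """All CDS features overlapping a 1-based position."""
        # features sorted by start; only those starting at or before pos qualify
        i = bisect.bisect_right(self._starts, pos)
        return [f for f in self.features[:i] if f.end >= pos]

    def intergenic_intervals(self) -> list[tuple[int, int]]:
        """Maximal 1-based inclusive intervals not covered by any CDS."""
        out = []
        cursor = 1
        for f in self.features:
            if f.start > cursor:
                out.append((cursor, f.start - 1))
            cursor = max(cursor, f.end + 1)
        if cursor <= len(self.sequence):
            out.append((cursor, len(self.sequence)))
        return out

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.id, description="")
        SeqIO.write([rec], str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.id} 1 {len(self.sequence)}\n")
            for f in self.features:
                attrs = f"ID={f.locus_id};locus_tag={f.locus_id}"
                if f.product:
                    attrs += f";product={f.product}"
                fh.write(
                    f"{self.id}\tgeoevo\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
                )

    @classmethod
    def read(cls, fasta_path: str | Path, gff3_path: str | Path) -> "AnnotatedGenome":
        """Load a genome from FASTA plus a GFF3 of CDS features."""
        import gffutils

        recs = list(SeqIO.parse(str(fasta_path), "fasta"))
        if len(recs) != 1:
            raise ValueError("expected a single-sequence FASTA")
        rec = recs[0]
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        feats = []
        for f in db.features_of_type("CDS"):
            locus = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f.id])[0]
            product = (f.attributes.get("product") or [""])[0]
            feats.append(CDSFeature(locus, f.start, f.end, f.strand, product))
        return cls(rec.id, str(rec.seq), feats)
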