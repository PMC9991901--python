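"""Shared sequence and coordinate primitives.

All internal coordinates are 0-based half-open; GFF3 and VCF are converted
to/from 1-based at the I/O boundary only. Isoleucine and leucine are isobaric
and indistinguishable in standard shotgun MS, so every sequence-identity check
in the pipeline goes through :func:`collapse_il`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
START_CODON = "ATG"

VALID_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
_NT_RE = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IL = str.maketrans("I", "L")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_il(seq: str) -> str:
    """Collapse I onto L for MS-style sequence identity."""
    return seq.translate(_IL)


def is_peptide(seq: str) -> bool:
    return bool(_AA_RE.match(seq))


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string codon by codon.

    Stops become ``*``; any codon containing N becomes ``X`` (treated as a
    fragment break downstream). Trailing sub-codon bases are dropped.
    Raises ValueError on characters outside {A,C,G,T,N}.
    """
    if seq and not _NT_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def translate_three_frames(seq: str) -> list[list[tuple[str, int]]]:
    """Three-frame translation with ORF-fragment splitting.

    Returns, per frame 0/1/2, a list of ``(fragment, aa_offset)`` pairs where
    ``aa_offset`` is the fragment's amino-acid offset within the full frame
    translation. Stop codons and N-containing codons break fragments and are
    not part of any fragment; empty fragments are dropped. No minimum length
    is applied at this stage.
    """
    frames: list[list[tuple[str, int]]] = []
    for frame in range(3):
        aa = translate_nt(seq[frame:])
        fragments: list[tuple[str, int]] = []
        start = 0
        for m in re.finditer(r"[*X]", aa):
            if m.start() > start:
                fragments.append((aa[start : m.start()], start))
            start = m.end()
        if len(aa) > start:
            fragments.append((aa[start:], start))
        frames.append(fragments)
    return frames


Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """A transcript as a set of genomic exon blocks with splice-aware mapping.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic start;
    transcript order is ascending for ``+`` genes and descending for ``-``.
    UTR/CDS genomic intervals are optional (non-coding transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def extract(self, genome: dict[str, str]) -> str:
        """Spliced transcript sequence (reverse-complemented on minus strand)."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def to_genomic(self, t_start: int, t_end: int) -> list[Interval]:
        """Map a transcript-coordinate interval to genomic intervals.

        Result intervals are 0-based half-open, sorted by genomic position,
        and their lengths sum to ``t_end - t_start``.
        """
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise ValueError(
                f"transcript interval [{t_start},{t_end}) outside "
                f"[0,{self.spliced_length}) for {self.transcript_id}"
            )
        order = self.exons if self.strand == "+" else self.exons[::-1]
        out: list[Interval] = []
        off = 0
        for es, ee in order:
            length = ee - es
            a, b = max(t_start, off), min(t_end, off + length)
            if a < b:
                if self.strand == "+":
                    out.append((es + (a - off), es + (b - off)))
                else:
                    out.append((ee - (b - off), ee - (a - off)))
            off += length
        return sorted(out)

    def genomic_to_transcript(self, gpos: int) -> int:
        """Transcript coordinate of a genomic position (must lie in an exon)."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        off = 0
        for es, ee in order:
            if es <= gpos < ee:
                return off + (gpos - es if self.strand == "+" else ee - 1 - gpos)
            off += ee - es
        raise ValueError(f"position {gpos} not exonic in {self.transcript_id}")


@dataclass
class GeneModel:
    """A gene with one or more transcript structures on the toy genome."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel]

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))

    def overlaps(self, chrom: str, intervals: Iterable[Interval]) -> bool:
        if chrom != self.chrom:
            return False
        gs, ge = self.span
        return any(s < ge and gs < e for s, e in intervals)


IG_NAME_RE = re.compile(r"^IG[HKL]")


def is_ig_gene(gene: GeneModel) -> bool:
    """Immunoglobulin genes by biotype prefix or symbol convention."""
    return gene.biotype.startswith("IG_") or bool(IG_NAME_RE.match(gene.name))


@dataclass
class VariantRecord:
    """A somatic single-nucleotide variant (VCF-style, 1-based position)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    transcript_id: str | None = None
    consequence: str | None = None  # e.g. "missense", "synonymous", "non_coding"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")


def intervals_overlap(a: Iterable[Interval], b: Iterable[Interval]) -> bool:
    return any(s1 < e2 and s2 < e1 for s1, e1 in a for s2, e2 in b)


def intervals_contain(outer: list[Interval], inner: list[Interval]) -> bool:
    """True if every inner interval is covered by the union of outer intervals."""
    return all(
        any(os <= s and e <= oe for os, oe in outer) for s, e in inner
    )
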