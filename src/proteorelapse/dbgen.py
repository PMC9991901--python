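"""Proteogenomic search-space construction.

Builds the customized peptide database searched alongside the canonical
proteome: tryptic peptides from a three-frame translation of every expressed
transcript (TPM > 1), single-amino-acid-alteration (SAAA) peptides from
somatic SNVs, fusion-junction peptides from fusion transcripts, and
pseudo-reversed decoys. Peptide isoelectric points are predicted for
consistency checks against the observed isoelectric-focusing fraction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    TranscriptModel,
    VariantRecord,
    collapse_il,
    is_peptide,
    revcomp,
    translate_three_frames,
)

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 7
MAX_PEPTIDE_LEN = 40
MAX_MISSED_CLEAVAGES = 2

PEPTIDE_CLASSES = ("novel_candidate", "canonical", "saaa", "fusion", "decoy")

#: Bjellqvist pKa values used by the charge model: termini plus the seven
#: ionizable side chains. Fixed so predicted pI values are bit-reproducible.
PKA_BJELLQVIST: dict[str, float] = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class PeptideRecord:
    """One candidate peptide in the search space."""

    sequence: str
    pep_class: str  # one of PEPTIDE_CLASSES
    source_transcript_id: str | None = None
    frame: int = 0  # 0-2 transcript frames; 3-5 are reverse-strand frames
    offset: int = 0  # aa offset of the peptide start within the frame translation
    predicted_pi: float | None = None
    psm_count: int = 0
    sub_pos: int | None = None  # 1-based altered-residue position (SAAA only)
    junction: int | None = None  # junction nt offset (fusion only)

    def __post_init__(self) -> None:
        if not is_peptide(self.sequence):
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if self.pep_class not in PEPTIDE_CLASSES:
            raise ValueError(f"unknown peptide class {self.pep_class!r}")


# ------------------------------------------------------------ expression filter

def filter_expressed(expression: pd.Series, threshold: float = 1.0) -> set[str]:
    """Transcripts with TPM strictly greater than ``threshold``.

    The cutoff is a strict inequality: a transcript at exactly 1.0 TPM is
    excluded. Missing TPM values are an error naming the transcript.
    """
    missing = expression.index[expression.isna()].tolist()
    if missing:
        raise ValueError(f"missing TPM for transcripts: {missing}")
    return set(expression.index[expression > threshold])


# ------------------------------------------------------------ digestion

def digest_tryptic(
    fragment: str,
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[tuple[str, int]]:
    """In-silico tryptic digestion of a protein fragment.

    Cleaves C-terminal to K or R except when the next residue is P, emits all
    peptides with 0..max_missed missed cleavages, and keeps lengths within
    [min_len, max_len]. Returns ``(peptide, start_offset)`` pairs with the
    offset relative to the fragment start.
    """
    sites = [
        i + 1
        for i in range(len(fragment) - 1)
        if fragment[i] in "KR" and fragment[i + 1] != "P"
    ]
    bounds = [0, *sites, len(fragment)]
    out: list[tuple[str, int]] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            pep = fragment[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len:
                out.append((pep, bounds[i]))
    return out


# ------------------------------------------------------------ canonical subtraction

class CanonicalIndex:
    """I/L-collapsed substring index over a canonical proteome.

    Exact substring search against the concatenated proteome with separator
    sentinels; conservative and deterministic.
    """

    def __init__(self, proteins: dict[str, str]):
        if not proteins:
            warnings.warn("empty canonical proteome: nothing will be subtracted")
        self._haystack = "#" + "#".join(collapse_il(p) for p in proteins.values()) + "#"

    def __contains__(self, peptide: str) -> bool:
        return collapse_il(peptide) in self._haystack


# ------------------------------------------------------------ novel candidates

def build_novel_db(
    transcripts: dict[str, str],
    expression: pd.Series,
    canonical: dict[str, str],
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[PeptideRecord]:
    """Three-frame novel-candidate peptides from expressed transcripts.

    Every tryptic peptide from all three frames of every transcript with
    TPM > 1 is retained unless its I/L-collapsed sequence occurs as a
    substring of the I/L-collapsed canonical proteome. Source transcript,
    frame and amino-acid offset are preserved for genome mapping.
    """
    expressed = filter_expressed(expression.loc[list(transcripts)])
    index = CanonicalIndex(canonical)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for tid in sorted(expressed):
        seq = transcripts[tid]
        for frame, fragments in enumerate(translate_three_frames(seq)):
            for fragment, frag_off in fragments:
                for pep, pep_off in digest_tryptic(fragment, max_missed, min_len, max_len):
                    key = collapse_il(pep)
                    if key in seen or pep in index:
                        continue
                    seen.add(key)
                    records.append(
                        PeptideRecord(
                            sequence=pep,
                            pep_class="novel_candidate",
                            source_transcript_id=tid,
                            frame=frame,
                            offset=frag_off + pep_off,
                            predicted_pi=predict_pi(pep),
                        )
                    )
    return records


def build_canonical_db(
    canonical: dict[str, str],
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[PeptideRecord]:
    """Tryptic peptides of the canonical proteome (class=canonical)."""
    records = []
    seen: set[str] = set()
    for pid in sorted(canonical):
        for pep, off in digest_tryptic(canonical[pid], max_missed, min_len, max_len):
            key = collapse_il(pep)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                PeptideRecord(
                    sequence=pep,
                    pep_class="canonical",
                    source_transcript_id=pid,
                    offset=off,
                    predicted_pi=predict_pi(pep),
                )
            )
    return records


# ------------------------------------------------------------ SAAA peptides

SAAA_WINDOW_NT = 120  # covers any 40-aa tryptic peptide containing the variant


def make_saaa_peptides(
    variants: list[VariantRecord],
    transcripts: dict[str, str],
    tx_models: dict[str, TranscriptModel],
    canonical: dict[str, str],
    six_frame: bool = True,
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[PeptideRecord]:
    """Mutated peptides carrying single amino acid alterations.

    For each SNV inside a transcript the altered base is substituted, a
    ±120 nt window around the variant is translated in six frames (three if
    ``six_frame`` is False), digested, and peptides that contain the altered
    residue and are absent from the I/L-collapsed canonical proteome are
    emitted. The 1-based position of the altered residue within the peptide
    is recorded for downstream flanking-ion curation.
    """
    index = CanonicalIndex(canonical)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for var in variants:
        model = tx_models.get(var.transcript_id) if var.transcript_id else None
        if model is None:
            logger.info("SNV %s:%d outside any transcript; skipped", var.chrom, var.pos)
            continue
        try:
            tpos = model.genomic_to_transcript(var.pos - 1)
        except ValueError:
            logger.info("SNV %s:%d not exonic in %s; skipped", var.chrom, var.pos, var.transcript_id)
            continue
        seq = transcripts[model.transcript_id]
        alt_base = var.alt if model.strand == "+" else revcomp(var.alt)
        if seq[tpos] == alt_base:
            raise ValueError(f"variant {var} does not change transcript base")
        mutated = seq[:tpos] + alt_base + seq[tpos + 1 :]
        lo = max(0, tpos - SAAA_WINDOW_NT)
        hi = min(len(mutated), tpos + SAAA_WINDOW_NT + 1)
        window, var_off = mutated[lo:hi], tpos - lo
        strands = ((window, var_off, 0), (revcomp(window), len(window) - 1 - var_off, 3))
        if not six_frame:
            strands = strands[:1]
        for wseq, woff, frame_base in strands:
            for frame, fragments in enumerate(translate_three_frames(wseq)):
                if woff < frame:
                    continue
                var_aa_idx = (woff - frame) // 3  # aa index of the altered codon
                for fragment, frag_off in fragments:
                    for pep, pep_off in digest_tryptic(fragment, max_missed, min_len, max_len):
                        start = frag_off + pep_off
                        if not (start <= var_aa_idx < start + len(pep)):
                            continue
                        key = collapse_il(pep)
                        if key in seen or pep in index:
                            continue
                        seen.add(key)
                        records.append(
                            PeptideRecord(
                                sequence=pep,
                                pep_class="saaa",
                                source_transcript_id=model.transcript_id,
                                frame=frame_base + frame,
                                offset=start,
                                predicted_pi=predict_pi(pep),
                                sub_pos=var_aa_idx - start + 1,
                            )
                        )
    return records


# ------------------------------------------------------------ fusion peptides

def make_fusion_peptides(
    fusions: pd.DataFrame,
    canonical: dict[str, str],
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[PeptideRecord]:
    """Junction-spanning peptides from three-frame translated fusion transcripts.

    ``fusions`` columns: fusion_id, gene5, gene3, junction (nt offset of the
    breakpoint within ``sequence``), sequence. A peptide is kept only when its
    codon range crosses the junction and it is absent from the canonical
    proteome.
    """
    index = CanonicalIndex(canonical)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for row in fusions.itertuples():
        seq, junction = row.sequence, int(row.junction)
        if not (0 < junction < len(seq)):
            raise ValueError(f"junction {junction} outside fusion sequence {row.fusion_id}")
        for frame, fragments in enumerate(translate_three_frames(seq)):
            for fragment, frag_off in fragments:
                for pep, pep_off in digest_tryptic(fragment, max_missed, min_len, max_len):
                    start_aa = frag_off + pep_off
                    nt_start = frame + 3 * start_aa
                    nt_end = nt_start + 3 * len(pep)
                    if not (nt_start < junction < nt_end):
                        continue
                    key = collapse_il(pep)
                    if key in seen or pep in index:
                        continue
                    seen.add(key)
                    records.append(
                        PeptideRecord(
                            sequence=pep,
                            pep_class="fusion",
                            source_transcript_id=str(row.fusion_id),
                            frame=frame,
                            offset=start_aa,
                            predicted_pi=predict_pi(pep),
                            junction=junction,
                        )
                    )
    return records


# ------------------------------------------------------------ pI prediction

def peptide_charge(sequence: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Net charge of a peptide at a given pH (Henderson–Hasselbalch sum)."""
    pka = pka or PKA_BJELLQVIST
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for aa in _POSITIVE:
        charge += sequence.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        charge -= sequence.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def predict_pi(sequence: str, pka: dict[str, float] | None = None, tol: float = 1e-6) -> float:
    """Isoelectric point by bisection on the net-charge function.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; the returned pH satisfies |net charge| < 1e-4.
    """
    if not is_peptide(sequence):
        raise ValueError(f"invalid peptide {sequence!r}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peptide_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


OUT_OF_RANGE = -1


def assign_hirief_fraction(pi: float, boundaries: list[float]) -> int:
    """Index of the half-open pH bin [b_i, b_{i+1}) containing ``pi``.

    ``boundaries`` must be strictly increasing; a pI outside the strip range
    returns the OUT_OF_RANGE sentinel (-1).
    """
    b = np.asarray(boundaries, dtype=float)
    if len(b) < 2 or not np.all(np.diff(b) > 0):
        raise ValueError("fraction boundaries must be strictly increasing")
    if pi < b[0] or pi >= b[-1]:
        return OUT_OF_RANGE
    return int(np.searchsorted(b, pi, side="right") - 1)


DEFAULT_FRACTION_BOUNDARIES = [float(x) for x in range(3, 11)]  # 3-10 strip, 1 pH bins


# ------------------------------------------------------------ decoys

def generate_decoys(targets: list[PeptideRecord]) -> list[PeptideRecord]:
    """Pseudo-reversed decoys: reverse the sequence keeping the C-terminal
    residue fixed. Decoys colliding with any target sequence (I/L-collapsed)
    are discarded; each decoy inherits its target's class via ``decoy``
    records that mirror the source class in ``source_transcript_id`` prefix.
    """
    target_keys = {collapse_il(t.sequence) for t in targets}
    decoys: list[PeptideRecord] = []
    n_dropped = 0
    for t in targets:
        seq = t.sequence[:-1][::-1] + t.sequence[-1]
        if collapse_il(seq) in target_keys:
            n_dropped += 1
            continue
        decoys.append(
            PeptideRecord(
                sequence=seq,
                pep_class="decoy",
                source_transcript_id=f"decoy_{t.pep_class}|{t.source_transcript_id}",
                frame=t.frame,
                offset=t.offset,
                predicted_pi=predict_pi(seq),
            )
        )
    if n_dropped:
        logger.info("discarded %d palindromic decoys colliding with targets", n_dropped)
    return decoys


def decoy_source_class(record: PeptideRecord | str) -> str:
    """The target class a decoy record mirrors."""
    src = record if isinstance(record, str) else record.source_transcript_id
    return src.split("|", 1)[0].removeprefix("decoy_")


# ------------------------------------------------------------ database assembly

@dataclass
class SearchDatabase:
    """The full search space as a tidy table plus FASTA export."""

    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_records(cls, records: list[PeptideRecord]) -> "SearchDatabase":
        rows = [
            {
                "peptide_id": f"pep{i + 1:06d}",
                "sequence": r.sequence,
                "pep_class": r.pep_class,
                "transcript_id": r.source_transcript_id,
                "frame": r.frame,
                "offset": r.offset,
                "predicted_pi": round(r.predicted_pi, 4) if r.predicted_pi is not None else np.nan,
                "sub_pos": r.sub_pos if r.sub_pos is not None else -1,
                "junction": r.junction if r.junction is not None else -1,
            }
            for i, r in enumerate(records)
        ]
        return cls(pd.DataFrame(rows))

    def write(self, out_dir) -> None:
        from .io import ensure_dir, write_tsv

        out = ensure_dir(out_dir)
        write_tsv(self.peptides, out / "peptides.tsv")
        lines = []
        for row in self.peptides.itertuples():
            prefix = "decoy_" if row.pep_class == "decoy" else ""
            header = f"{prefix}{row.peptide_id}|{row.pep_class}|{row.transcript_id}|{row.frame}|{row.offset}"
            lines.append(f">{header}\n{row.sequence}")
        (out / "search_db.fasta").write_text("\n".join(lines) + "\n")


def build_search_database(
    transcripts: dict[str, str],
    expression: pd.Series,
    canonical: dict[str, str],
    variants: list[VariantRecord],
    fusions: pd.DataFrame,
    tx_models: dict[str, TranscriptModel],
    max_missed: int = MAX_MISSED_CLEAVAGES,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> SearchDatabase:
    """Assemble the complete target+decoy search space."""
    kw = dict(max_missed=max_missed, min_len=min_len, max_len=max_len)
    targets = (
        build_canonical_db(canonical, **kw)
        + build_novel_db(transcripts, expression, canonical, **kw)
        + make_saaa_peptides(variants, transcripts, tx_models, canonical, **kw)
        + make_fusion_peptides(fusions, canonical, **kw)
    )
    return SearchDatabase.from_records(targets + generate_decoys(targets))
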