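"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython, GFF3 parsing through gffutils (in-memory
sqlite), VCF reading through pysam. Everything tabular is plain TSV with a
single header line so that the whole cohort stays human-inspectable.
"""
from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Interval, TranscriptModel, VariantRecord


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- TSV

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.Series:
    """Expression table (transcript_id, tpm) as a Series indexed by transcript."""
    df = read_tsv(path)
    return df.set_index("transcript_id")["tpm"]


# ---------------------------------------------------------------- GFF3

_FEATURE_BY_SLOT = {
    "five_prime_UTR": "utr5",
    "CDS": "cds",
    "three_prime_UTR": "utr3",
}


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/UTR/CDS features, 1-based inclusive per GFF3."""
    lines = ["##gff-version 3"]

    def feat(chrom: str, ftype: str, iv: Interval, strand: str, attrs: str) -> str:
        return "\t".join(
            [chrom, "proteorelapse", ftype, str(iv[0] + 1), str(iv[1]), ".", strand, ".", attrs]
        )

    for g in genes:
        gs, ge = g.span
        lines.append(
            feat(g.chrom, "gene", (gs, ge), g.strand,
                 f"ID=gene:{g.gene_id};Name={g.name};biotype={g.biotype}")
        )
        for t in g.transcripts:
            ts, te = t.span
            lines.append(
                feat(g.chrom, "mRNA" if g.biotype == "protein_coding" else "transcript",
                     (ts, te), g.strand,
                     f"ID=transcript:{t.transcript_id};Parent=gene:{g.gene_id}")
            )
            for i, iv in enumerate(t.exons):
                lines.append(
                    feat(g.chrom, "exon", iv, g.strand,
                         f"ID=exon:{t.transcript_id}.{i};Parent=transcript:{t.transcript_id}")
                )
            for ftype, slot in _FEATURE_BY_SLOT.items():
                for i, iv in enumerate(getattr(t, slot)):
                    lines.append(
                        feat(g.chrom, ftype, iv, g.strand,
                             f"ID={slot}:{t.transcript_id}.{i};Parent=transcript:{t.transcript_id}")
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse an annotation back into gene models (coordinates to 0-based)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gene_id = gf.id.split(":", 1)[-1]
        transcripts = []
        for tf in db.children(gf, level=1):
            tid = tf.id.split(":", 1)[-1]
            slots: dict[str, list[Interval]] = {"exon": [], "utr5": [], "utr3": [], "cds": []}
            for cf in db.children(tf, level=1):
                slot = {"exon": "exon", **_FEATURE_BY_SLOT}.get(cf.featuretype)
                if slot:
                    slots[slot].append((cf.start - 1, cf.end))
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=gf.seqid,
                    strand=gf.strand,
                    exons=sorted(slots["exon"]),
                    utr5=sorted(slots["utr5"]),
                    cds=sorted(slots["cds"]),
                    utr3=sorted(slots["utr3"]),
                )
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                name=gf.attributes.get("Name", [gene_id])[0],
                chrom=gf.seqid,
                strand=gf.strand,
                biotype=gf.attributes.get("biotype", ["."])[0],
                transcripts=transcripts,
            )
        )
    return genes


# ---------------------------------------------------------------- transcript blocks

def write_transcript_blocks(models: list[TranscriptModel], path: str | Path) -> None:
    """Assembled-transcript alignments: one row per transcript, exon blocks
    encoded ``start-end;start-end`` in genomic order (0-based half-open)."""
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "blocks": ";".join(f"{s}-{e}" for s, e in t.exons),
        }
        for t in models
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_transcript_blocks(path: str | Path) -> dict[str, TranscriptModel]:
    out: dict[str, TranscriptModel] = {}
    for row in read_tsv(path).itertuples():
        exons = [
            (int(a), int(b))
            for a, b in (blk.split("-") for blk in row.blocks.split(";"))
        ]
        out[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            exons=exons,
        )
    return out


# ---------------------------------------------------------------- VCF

def write_vcf(variants: list[VariantRecord], contigs: dict[str, int], path: str | Path) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=TID,Number=1,Type=String,Description="Transcript id">')
    lines.append('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, v in enumerate(variants):
        info = []
        if v.transcript_id:
            info.append(f"TID={v.transcript_id}")
        if v.consequence:
            info.append(f"CSQ={v.consequence}")
        lines.append(
            f"{v.chrom}\t{v.pos}\tsnv{i + 1}\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + (";".join(info) or ".")
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    transcript_id=rec.info.get("TID"),
                    consequence=rec.info.get("CSQ"),
                )
            )
    return out


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    lines = [
        "\t".join([name, (descriptions or {}).get(name, "na"), *genes])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
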