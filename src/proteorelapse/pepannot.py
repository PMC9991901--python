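"""Genomic annotation of confident novel peptides.

Maps each peptide back to the genome through its source transcript (splice-
and strand-aware), classifies it into annotation categories (protein-coding
with UTR/intron/exon-variant subcategories, pseudogene, lincRNA, antisense,
intergenic, or overlapping when several genes/categories fit), summarizes
category frequencies, flags outlier samples per peptide, and tests paired
diagnosis-relapse abundance differences of novel peptides with the shared
empirical-Bayes moderated-t engine.
"""
from __future__ import annotations

import decimal
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    GeneModel,
    Interval,
    TranscriptModel,
    collapse_il,
    intervals_contain,
    intervals_overlap,
)
from .quantprot import moderated_t

logger = logging.getLogger(__name__)

CATEGORIES = ("protein_coding", "pseudogene", "lincRNA", "antisense", "intergenic", "overlapping")
SUBCATEGORIES = ("utr5", "utr3", "intronic", "exon_variant", "other")


def map_peptide_to_genome(
    sequence: str, frame: int, offset: int, model: TranscriptModel
) -> list[Interval]:
    """Genomic intervals of a peptide (0-based half-open, genomic order).

    The peptide occupies transcript nucleotides
    ``[frame + 3*offset, frame + 3*(offset + len))``; walking the exon blocks
    splits that range at splice junctions. Interval lengths always sum to
    three times the peptide length.
    """
    t_start = frame + 3 * offset
    return model.to_genomic(t_start, t_start + 3 * len(sequence))


@dataclass
class AnnotatedPeptide:
    sequence: str
    category: str
    subcategory: str | None  # non-null iff category == protein_coding
    gene_ids: list[str]
    intervals: list[Interval]
    chrom: str


def classify_peptide(
    sequence: str,
    chrom: str,
    intervals: list[Interval],
    genes: list[GeneModel],
) -> AnnotatedPeptide:
    """Assign the annotation category of a genome-mapped peptide.

    No overlapping gene -> intergenic; exactly one gene -> that gene's
    biotype (protein-coding genes get a subcategory); more than one distinct
    gene -> overlapping. For a single protein-coding gene: entirely within
    the annotated 5'/3'UTR -> utr5/utr3; entirely intronic (inside the gene
    span, no exon overlap) -> intronic; overlapping annotated CDS -> exon
    variant (the peptide cannot equal a canonical in-frame peptide, those
    were subtracted upstream); anything else -> other.
    """
    if not intervals:
        raise ValueError(f"peptide {sequence} has no genomic mapping")
    hits = [g for g in genes if g.overlaps(chrom, intervals)]
    if not hits:
        return AnnotatedPeptide(sequence, "intergenic", None, [], intervals, chrom)
    if len({g.gene_id for g in hits}) > 1:
        return AnnotatedPeptide(
            sequence, "overlapping", None, sorted(g.gene_id for g in hits), intervals, chrom
        )
    gene = hits[0]
    biotype = "protein_coding" if gene.biotype in ("protein_coding", "IG_V_gene") else gene.biotype
    if biotype != "protein_coding":
        category = biotype if biotype in CATEGORIES else "overlapping"
        return AnnotatedPeptide(sequence, category, None, [gene.gene_id], intervals, chrom)

    sub = "other"
    tx = gene.transcripts[0]
    exon_hit = intervals_overlap(tx.exons, intervals)
    if tx.utr5 and intervals_contain(tx.utr5, intervals):
        sub = "utr5"
    elif tx.utr3 and intervals_contain(tx.utr3, intervals):
        sub = "utr3"
    elif not exon_hit:
        sub = "intronic"
    elif tx.cds and intervals_overlap(tx.cds, intervals):
        sub = "exon_variant"
    return AnnotatedPeptide(sequence, "protein_coding", sub, [gene.gene_id], intervals, chrom)


def annotate_peptides(
    peptides: pd.DataFrame,
    provenance: pd.DataFrame,
    tx_models: dict[str, TranscriptModel],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Map and classify a table of confident peptides.

    ``provenance`` supplies (sequence, transcript_id, frame, offset); frames
    >= 3 (reverse-strand SAAA frames) and sequences without provenance are
    reported as unmapped.
    """
    prov = provenance.drop_duplicates("sequence").set_index("sequence")
    rows = []
    for seq in peptides["sequence"]:
        rec = {
            "sequence": seq, "category": "unmapped", "subcategory": ".",
            "gene_ids": ".", "chrom": ".", "intervals": ".",
        }
        if seq in prov.index:
            p = prov.loc[seq]
            model = tx_models.get(p["transcript_id"])
            if model is not None and int(p["frame"]) < 3:
                ivs = map_peptide_to_genome(seq, int(p["frame"]), int(p["offset"]), model)
                ann = classify_peptide(seq, model.chrom, ivs, genes)
                rec.update(
                    category=ann.category,
                    subcategory=ann.subcategory or ".",
                    gene_ids=";".join(ann.gene_ids) or ".",
                    chrom=ann.chrom,
                    intervals=";".join(f"{s}-{e}" for s, e in ann.intervals),
                )
        rows.append(rec)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ summaries

def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_annotation(annotated: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category and protein-coding subcategory frequency tables.

    Category percentages use all peptides as the denominator; subcategory
    percentages use only peptides annotated to solely one protein-coding
    gene. Percentages are rounded half-up to one decimal.
    """
    if annotated.empty:
        raise ValueError("no annotated peptides to summarize")
    total = len(annotated)
    cat_rows = []
    for cat in CATEGORIES:
        sub = annotated[annotated["category"] == cat]
        genes = {
            g for ids in sub["gene_ids"] if ids != "." for g in str(ids).split(";")
        } if cat != "overlapping" else set()
        cat_rows.append(
            {
                "category": cat,
                "n_peptides": len(sub),
                "pct": _round_half_up(100.0 * len(sub) / total),
                "n_genes": len(genes),
            }
        )
    pc = annotated[annotated["category"] == "protein_coding"]
    pc_total = max(1, len(pc))
    sub_rows = [
        {
            "subcategory": s,
            "n_peptides": int((pc["subcategory"] == s).sum()),
            "pct": _round_half_up(100.0 * (pc["subcategory"] == s).sum() / pc_total),
        }
        for s in SUBCATEGORIES
    ]
    return pd.DataFrame(cat_rows), pd.DataFrame(sub_rows)


def cohort_overlap(adult: set[str], pediatric: set[str]) -> dict[str, int]:
    """Set algebra over I/L-collapsed peptide sequences."""
    a = {collapse_il(s) for s in adult}
    p = {collapse_il(s) for s in pediatric}
    return {
        "n_adult": len(a),
        "n_pediatric": len(p),
        "n_intersection": len(a & p),
        "n_union": len(a | p),
    }


# ------------------------------------------------------------ outliers

def detect_outlier_samples(values: pd.Series, factor: float = 2.0) -> list[str]:
    """Samples whose linear-scale abundance exceeds ``factor`` times the
    third quartile of the peptide's values across all samples.

    Q3 uses linear interpolation on sorted order statistics (the common
    "type 7" quantile) and includes the candidate sample itself. Fewer than
    four observed samples yields no calls (with a warning).
    """
    obs = values.dropna()
    if len(obs) < 4:
        warnings.warn("fewer than 4 samples with quant values; no outlier calls")
        return []
    q3 = float(np.percentile(obs.to_numpy(dtype=float), 75))
    return sorted(obs.index[obs > factor * q3].tolist())


def outlier_table(quant: pd.DataFrame, factor: float = 2.0) -> pd.DataFrame:
    """Per-peptide outlier calls over a peptide x sample linear-scale matrix."""
    rows = []
    for pep, values in quant.iterrows():
        obs = values.dropna()
        if len(obs) < 4:
            continue
        q3 = float(np.percentile(obs.to_numpy(dtype=float), 75))
        for sample in sorted(obs.index[obs > factor * q3]):
            rows.append({"peptide": pep, "sample": sample, "value": obs[sample], "q3": q3})
    return pd.DataFrame(rows, columns=["peptide", "sample", "value", "q3"])


# ------------------------------------------------------------ peptide quant + diff

def peptide_sample_matrix(psms: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Peptide-level log2 ratios to the reference pool, per sample.

    Per PSM the channel intensity is divided by the reference-pool channel
    and log2-transformed; per peptide and sample the median over PSMs is
    taken. Decoy PSMs never contribute.
    """
    targets = psms[~psms["is_decoy"]].dropna(subset=["intensity_refpool"])
    cols = [f"intensity_{s}" for s in sample_ids]
    ratios = np.log2(
        targets[cols].to_numpy(dtype=float)
        / targets["intensity_refpool"].to_numpy(dtype=float)[:, None]
    )
    df = pd.DataFrame(ratios, columns=sample_ids, index=targets.index)
    df["sequence"] = targets["sequence"].to_numpy()
    return df.groupby("sequence").median()


def diff_novel_peptides(
    pep_matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    psm_counts: pd.Series,
    min_psms: int = 2,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Paired diagnosis-relapse differential abundance of novel peptides.

    Keeps peptides with ``psm_count >= min_psms`` (more than one PSM by
    default) that are quantified in every pair, computes paired differences
    relapse - diagnosis on the log2 scale, and applies the empirical-Bayes
    moderated one-sample t with BH adjustment. Peptides missing in any pair
    are excluded and logged.
    """
    eligible = psm_counts[psm_counts >= min_psms].index
    mat = pep_matrix.loc[pep_matrix.index.intersection(eligible)]
    d_cols = pairs["diagnosis"].tolist()
    r_cols = pairs["relapse"].tolist()
    diffs = mat[r_cols].to_numpy(dtype=float) - mat[d_cols].to_numpy(dtype=float)
    complete = ~np.isnan(diffs).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("excluded %d peptides missing in >=1 pair", n_dropped)
    result = moderated_t(
        pd.DataFrame(diffs[complete], index=mat.index[complete]), prior_df=prior_df
    )
    return result.rename(columns={"gene": "sequence"})
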