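"""Confident novel/SAAA/fusion peptide identification.

Implements class-specific target-decoy FDR with q-value monotonization and
the downstream curation chain: confidence filtering, post-search canonical
subtraction, immunoglobulin-gene removal, a simplified flanking-ion check
for substituted residues, and an optional predicted-pI vs observed-fraction
consistency filter. Each stage only removes peptides; stage-by-stage counts
are logged to a filter table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dbgen import CanonicalIndex, DEFAULT_FRACTION_BOUNDARIES
from .models import GeneModel, TranscriptModel, is_ig_gene

logger = logging.getLogger(__name__)

FDR_CLASSES = ("novel_candidate", "saaa", "fusion")


# ------------------------------------------------------------ FDR

def class_fdr(psms: pd.DataFrame) -> pd.Series:
    """q-value per PSM for one peptide class.

    For a score threshold s the FDR estimate is
    ``#decoys >= s / max(1, #targets >= s)``; the q-value is the running
    minimum of this estimate over decreasing thresholds, clipped to [0, 1].
    Ties in score rank decoys above targets (pessimistic). The result is
    aligned to the input index and invariant under input reordering.
    """
    if psms.empty:
        return pd.Series(dtype=float)
    score = psms["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(score)):
        raise ValueError("non-finite PSM scores")
    decoy = psms["is_decoy"].to_numpy(dtype=bool)
    # sort by descending score; decoys first at equal score
    order = np.lexsort((~decoy, -score))
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    fdr = d_cum / np.maximum(1, t_cum)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=psms.index, name="q_value")


def apply_confidence_filter(
    psms: pd.DataFrame, q_threshold: float = 0.01, count_all_psms: bool = False
) -> pd.DataFrame:
    """Unique target peptides whose best q-value beats the threshold.

    ``psm_count`` counts confident PSMs only (those passing the threshold)
    unless ``count_all_psms`` is set, in which case all PSMs of a retained
    peptide are counted.
    """
    targets = psms[~psms["is_decoy"]]
    if targets.empty:
        return pd.DataFrame(columns=["sequence", "pep_class", "min_q", "psm_count"])
    grp = targets.groupby("sequence", sort=True)
    min_q = grp["q_value"].min()
    keep = min_q[min_q < q_threshold]
    if count_all_psms:
        counts = grp.size()
    else:
        counts = targets[targets["q_value"] < q_threshold].groupby("sequence").size()
    out = pd.DataFrame(
        {
            "sequence": keep.index,
            "pep_class": grp["pep_class"].first().loc[keep.index].to_numpy(),
            "min_q": keep.to_numpy(),
            "psm_count": counts.reindex(keep.index).fillna(0).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


# ------------------------------------------------------------ curation stages

def subtract_canonical_post(
    peptides: pd.DataFrame, extended_canonical: dict[str, str]
) -> tuple[pd.DataFrame, int]:
    """Drop peptides with an I/L-collapsed substring match in the extended
    reference collection; returns (kept, n_removed)."""
    index = CanonicalIndex(extended_canonical)
    mask = peptides["sequence"].map(lambda s: s not in index)
    removed = int((~mask).sum())
    if removed:
        logger.info("canonical subtraction removed %d peptides", removed)
    return peptides[mask].reset_index(drop=True), removed


def peptide_genomic_intervals(
    sequence_len: int, frame: int, offset: int, model: TranscriptModel
) -> list[tuple[int, int]]:
    """Genomic intervals of a peptide from its transcript/frame/offset."""
    t_start = frame + 3 * offset
    return model.to_genomic(t_start, t_start + 3 * sequence_len)


def drop_ig_peptides(
    peptides: pd.DataFrame,
    genes: list[GeneModel],
    tx_models: dict[str, TranscriptModel],
    provenance: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Remove peptides whose genomic span overlaps an immunoglobulin gene.

    ``provenance`` maps sequences to (transcript_id, frame, offset) from the
    search database. Peptides without a mappable transcript are kept.
    """
    ig_genes = [g for g in genes if is_ig_gene(g)]
    if not ig_genes or peptides.empty:
        return peptides.reset_index(drop=True), 0
    prov = provenance.drop_duplicates("sequence").set_index("sequence")
    keep_mask = []
    for seq in peptides["sequence"]:
        hit = False
        if seq in prov.index:
            row = prov.loc[seq]
            model = tx_models.get(row["transcript_id"])
            if model is not None and int(row["frame"]) < 3:
                ivs = peptide_genomic_intervals(len(seq), int(row["frame"]), int(row["offset"]), model)
                hit = any(g.overlaps(model.chrom, ivs) for g in ig_genes)
        keep_mask.append(not hit)
    kept = peptides[np.array(keep_mask)].reset_index(drop=True)
    return kept, int(len(peptides) - len(kept))


def curate_saaa(sequence: str, sub_pos: int, matched_sites: set[int]) -> bool:
    """Simplified flanking-ion rule for a substituted residue.

    Pass iff the fragment evidence contains a matched b/y ion on each side of
    the altered residue at 1-based position ``sub_pos``: one ion with
    cleavage site ``sub_pos - 1`` and one with site ``sub_pos``. Substitutions
    at either peptide terminus require only the single definable flanking ion.
    """
    n = len(sequence)
    if not 1 <= sub_pos <= n:
        raise ValueError(f"substituted position {sub_pos} outside peptide of length {n}")
    if any(not 1 <= s <= n - 1 for s in matched_sites):
        raise ValueError("matched ion cleavage sites out of bounds")
    left_ok = sub_pos == 1 or (sub_pos - 1) in matched_sites
    right_ok = sub_pos == n or sub_pos in matched_sites
    return left_ok and right_ok


def pi_consistency_filter(
    peptides: pd.DataFrame,
    psms: pd.DataFrame,
    predicted_pi: pd.Series,
    boundaries: list[float] | None = None,
    tolerance: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Keep peptides with >=1 supporting PSM whose observed isoelectric-
    focusing fraction midpoint is within ``tolerance`` pH of the predicted pI.

    The first and last fractions of the strip are open-ended: they collect
    every peptide focusing beyond the pH range, so a predicted pI outside the
    strip on the matching side counts as distance zero.
    """
    if not np.isfinite(tolerance):
        return peptides.reset_index(drop=True), 0
    b = np.asarray(boundaries or DEFAULT_FRACTION_BOUNDARIES, dtype=float)
    mids = 0.5 * (b[:-1] + b[1:])

    def distance(pi: float, f: int) -> float:
        if f == 0 and pi < mids[0]:
            return 0.0
        if f == len(mids) - 1 and pi > mids[-1]:
            return 0.0
        return abs(pi - mids[f])

    frac = psms[["sequence", "fraction"]].dropna()
    keep = []
    for seq in peptides["sequence"]:
        pi = predicted_pi.get(seq, np.nan)
        obs = frac.loc[frac["sequence"] == seq, "fraction"].astype(int)
        ok = bool(len(obs)) and np.isfinite(pi) and any(
            0 <= f < len(mids) and distance(pi, f) <= tolerance for f in obs
        )
        keep.append(ok)
    kept = peptides[np.array(keep, dtype=bool)].reset_index(drop=True)
    return kept, int(len(peptides) - len(kept))


# ------------------------------------------------------------ full chain

@dataclass
class FilterChainResult:
    confident: dict[str, pd.DataFrame]  # class -> peptide table
    log: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_filter_chain(
    psms: pd.DataFrame,
    extended_canonical: dict[str, str],
    genes: list[GeneModel] | None = None,
    tx_models: dict[str, TranscriptModel] | None = None,
    provenance: pd.DataFrame | None = None,
    fragments: pd.DataFrame | None = None,
    q_threshold: float = 0.01,
    pi_tolerance: float = 1.0,
    boundaries: list[float] | None = None,
    classes: tuple[str, ...] = FDR_CLASSES,
    count_all_psms: bool = False,
) -> FilterChainResult:
    """Fixed-order curation pipeline per peptide class.

    class FDR -> confidence filter -> canonical subtraction -> IG removal ->
    (SAAA flanking-ion curation) -> (pI consistency). Decoys of a class are
    identified by the ``pep_class`` column value ``decoy`` plus the mirrored
    class recorded at decoy generation; here the PSM table carries the decoy
    flag and the target class directly.
    """
    log_rows = []
    confident: dict[str, pd.DataFrame] = {}
    frag_idx = None
    if fragments is not None and not fragments.empty:
        frag_idx = fragments.set_index("sequence")

    for cls in classes:
        sub = psms[(psms["pep_class"] == cls) | (psms["is_decoy"] & psms["target_class"].eq(cls))]
        sub = sub.copy()
        if sub.empty:
            confident[cls] = pd.DataFrame(columns=["sequence", "pep_class", "min_q", "psm_count"])
            continue
        sub["q_value"] = class_fdr(sub)
        peps = apply_confidence_filter(sub, q_threshold, count_all_psms=count_all_psms)
        log_rows.append({"pep_class": cls, "stage": "confidence", "peptides_out": len(peps), "removed": -1})

        peps, n_canon = subtract_canonical_post(peps, extended_canonical)
        log_rows.append({"pep_class": cls, "stage": "canonical_subtraction", "peptides_out": len(peps), "removed": n_canon})

        if genes is not None and tx_models is not None and provenance is not None:
            peps, n_ig = drop_ig_peptides(peps, genes, tx_models, provenance)
            log_rows.append({"pep_class": cls, "stage": "ig_removal", "peptides_out": len(peps), "removed": n_ig})

        if cls == "saaa" and frag_idx is not None and not peps.empty:
            prov = provenance.drop_duplicates("sequence").set_index("sequence") if provenance is not None else None
            keep = []
            for seq in peps["sequence"]:
                if seq not in frag_idx.index:
                    keep.append(False)
                    continue
                row = frag_idx.loc[seq]
                sites = {int(s) for s in str(row["matched_sites"]).split(";") if s}
                keep.append(curate_saaa(seq, int(row["sub_pos"]), sites))
            n_before = len(peps)
            peps = peps[np.array(keep, dtype=bool)].reset_index(drop=True)
            log_rows.append({"pep_class": cls, "stage": "saaa_curation", "peptides_out": len(peps), "removed": n_before - len(peps)})

        if np.isfinite(pi_tolerance):
            pi_map = pd.Series(dtype=float)
            if provenance is not None and "predicted_pi" in provenance.columns:
                pi_map = provenance.drop_duplicates("sequence").set_index("sequence")["predicted_pi"]
            peps, n_pi = pi_consistency_filter(
                peps, psms[psms["pep_class"] == cls], pi_map, boundaries, pi_tolerance
            )
            log_rows.append({"pep_class": cls, "stage": "pi_consistency", "peptides_out": len(peps), "removed": n_pi})

        confident[cls] = peps

    return FilterChainResult(confident=confident, log=pd.DataFrame(log_rows))


def attach_target_class(psms: pd.DataFrame, peptides: pd.DataFrame) -> pd.DataFrame:
    """Annotate each PSM with the class its decoy mirrors (targets keep their
    own class), using the search-database provenance."""
    from .dbgen import decoy_source_class

    psms = psms.copy()
    decoy_src = peptides.set_index("peptide_id")["transcript_id"]

    def target_class(row):
        if not row.is_decoy:
            return row.pep_class
        return decoy_source_class(str(decoy_src.get(row.peptide_id, "decoy_unknown|")))

    psms["target_class"] = [target_class(r) for r in psms.itertuples()]
    return psms
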