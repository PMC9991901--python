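"""End-to-end pipeline orchestration.

Runs the enabled stages in their fixed order — synth, dbgen, identify,
annotate, quant — each stage reading its inputs from the files the previous
stage wrote, so the report is always recomputable from the stage outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dbgen, identfilter, pepannot, quantprot, synthio
from .io import (
    ensure_dir,
    read_expression,
    read_fasta,
    read_gff3,
    read_gmt,
    read_transcript_blocks,
    read_tsv,
    read_vcf,
    write_tsv,
)

logger = logging.getLogger(__name__)

STAGES = ("synth", "dbgen", "identify", "annotate", "quant")
_STAGE_DEPS = {
    "dbgen": ("synth",),
    "identify": ("synth", "dbgen"),
    "annotate": ("synth", "dbgen", "identify"),
    "quant": ("synth",),
}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fdr: float = 0.01
    alpha: float = 0.05
    tpm: float = 1.0
    missed: int = 2
    min_len: int = 7
    max_len: int = 40
    pi_tolerance: float = 1.0
    enrich_fdr: float = 0.01
    enrich_min_score: float = 3.0
    synth: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            missing = set(_STAGE_DEPS.get(stage, ())) - set(self.stages)
            if missing:
                raise ValueError(f"stage {stage!r} requires {sorted(missing)}")
        if not (0 < self.fdr <= 1 and 0 < self.alpha <= 1):
            raise ValueError("fdr and alpha must be in (0, 1]")
        if self.tpm < 0 or self.missed < 0 or self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid digestion/expression thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _load_reference(out: Path):
    genes = read_gff3(out / "annotation.gff3")
    tx_models = read_transcript_blocks(out / "transcript_blocks.tsv")
    # enrich mapped transcripts with UTR/CDS structure from the annotation
    for g in genes:
        for t in g.transcripts:
            if t.transcript_id in tx_models:
                tx_models[t.transcript_id] = t
    return genes, tx_models


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the summary report."""
    config.validate()
    out = ensure_dir(config.out_dir)
    report: dict = {"seed": config.seed, "thresholds": {
        "fdr": config.fdr, "alpha": config.alpha, "tpm": config.tpm,
        "missed_cleavages": config.missed, "peptide_length": [config.min_len, config.max_len],
        "pi_tolerance": config.pi_tolerance,
        "enrichment": {"fdr": config.enrich_fdr, "min_score": config.enrich_min_score},
    }, "stages": {}}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s", stage)
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, out)
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _stage_synth(config: PipelineConfig, out: Path) -> dict:
    synth_cfg = synthio.SynthConfig(**{"seed": config.seed, **config.synth})
    cohort = synthio.generate_cohort(synth_cfg, out)
    return {
        "n_transcripts": len(cohort.reference.transcripts),
        "n_genes": len(cohort.reference.genes),
        "n_samples": len(cohort.samples),
        "n_variants": len(cohort.variants),
        "n_peptides": int(len(cohort.peptides)),
        "n_psms": int(len(cohort.psms)),
    }


def _stage_dbgen(config: PipelineConfig, out: Path) -> dict:
    transcripts = read_fasta(out / "transcripts.fa")
    expression = read_expression(out / "expression.tsv")
    canonical = read_fasta(out / "canonical.fa")
    variants = read_vcf(out / "somatic.vcf")
    fusions = read_tsv(out / "fusions.tsv")
    _genes, tx_models = _load_reference(out)
    db = dbgen.build_search_database(
        transcripts, expression, canonical, variants, fusions, tx_models,
        max_missed=config.missed, min_len=config.min_len, max_len=config.max_len,
    )
    db.write(out)
    counts = db.peptides["pep_class"].value_counts().to_dict()
    return {"peptides_per_class": {k: int(v) for k, v in counts.items()}}


def _stage_identify(config: PipelineConfig, out: Path) -> dict:
    psms = read_tsv(out / "psms.tsv")
    peptides = read_tsv(out / "peptides.tsv")
    canonical = read_fasta(out / "canonical.fa")
    fragments = read_tsv(out / "fragments.tsv")
    genes, tx_models = _load_reference(out)
    psms = identfilter.attach_target_class(psms, peptides)
    result = identfilter.run_filter_chain(
        psms, canonical, genes=genes, tx_models=tx_models, provenance=peptides,
        fragments=fragments, q_threshold=config.fdr, pi_tolerance=config.pi_tolerance,
    )
    names = {"novel_candidate": "novel_confident", "saaa": "saaa_confident",
             "fusion": "fusion_confident"}
    counts = {}
    for cls, stem in names.items():
        table = result.confident.get(cls, pd.DataFrame())
        write_tsv(table, out / f"{stem}.tsv")
        counts[cls] = int(len(table))
    write_tsv(result.log, out / "filter_log.tsv")
    return {"confident_peptides": counts}


def _stage_annotate(config: PipelineConfig, out: Path) -> dict:
    confident = read_tsv(out / "novel_confident.tsv")
    peptides = read_tsv(out / "peptides.tsv")
    psms = read_tsv(out / "psms.tsv")
    samples = read_tsv(out / "samples.tsv")
    genes, tx_models = _load_reference(out)

    annotated = pepannot.annotate_peptides(confident, peptides, tx_models, genes)
    write_tsv(annotated, out / "annotated_peptides.tsv")
    summary: dict = {}
    if len(annotated):
        cat, sub = pepannot.summarize_annotation(annotated)
        write_tsv(cat, out / "category_summary.tsv")
        write_tsv(sub, out / "subcategory_summary.tsv")
        summary["categories"] = dict(zip(cat["category"], cat["n_peptides"].astype(int)))

    conf_seqs = set(confident["sequence"])
    by_cohort = {
        cohort: set(psms.loc[(psms["cohort"] == cohort) & ~psms["is_decoy"], "sequence"])
        & conf_seqs
        for cohort in ("adult", "pediatric")
    }
    summary["cohort_overlap"] = pepannot.cohort_overlap(
        by_cohort["adult"], by_cohort["pediatric"]
    )

    sample_ids = samples["sample_id"].tolist()
    pep_matrix = pepannot.peptide_sample_matrix(psms, sample_ids)
    pep_matrix = pep_matrix.loc[pep_matrix.index.intersection(conf_seqs)]
    outliers_all = []
    diffs_all = []
    for cohort in ("adult", "pediatric"):
        cohort_samples = samples.loc[samples["cohort"] == cohort, "sample_id"].tolist()
        cohort_seqs = pep_matrix.index.intersection(by_cohort[cohort])
        linear = np.exp2(pep_matrix.loc[cohort_seqs, cohort_samples])
        table = pepannot.outlier_table(linear)
        table.insert(0, "cohort", cohort)
        outliers_all.append(table)

        pairs = synthio.paired_samples(samples, cohort)
        cohort_psms = psms[(psms["cohort"] == cohort) & ~psms["is_decoy"]]
        psm_counts = cohort_psms.groupby("sequence").size()
        if len(pairs) >= 2 and len(cohort_seqs):
            diff = pepannot.diff_novel_peptides(
                pep_matrix.loc[cohort_seqs], pairs, psm_counts
            )
            diff.insert(0, "cohort", cohort)
            diffs_all.append(diff)
    outliers = pd.concat(outliers_all, ignore_index=True) if outliers_all else pd.DataFrame()
    write_tsv(outliers, out / "outliers.tsv")
    novel_diff = pd.concat(diffs_all, ignore_index=True) if diffs_all else pd.DataFrame()
    write_tsv(novel_diff, out / "novel_diff.tsv")
    summary["n_outlier_calls"] = int(len(outliers))
    if len(novel_diff):
        summary["n_significant_novel"] = int((novel_diff["p_value"] < config.alpha).sum())
    return summary


def _stage_quant(config: PipelineConfig, out: Path) -> dict:
    quant = read_tsv(out / "quant.tsv").set_index("gene")
    rna = read_tsv(out / "rna.tsv").set_index("gene")
    samples = read_tsv(out / "samples.tsv")
    depth = read_tsv(out / "depth.tsv")
    gene_sets = read_gmt(out / "genesets.gmt")

    summary: dict = {}
    diff_all, enrich_all, corr_all = [], [], []
    retained: dict[str, set] = {}
    for cohort in ("adult", "pediatric"):
        cohort_samples = samples.loc[samples["cohort"] == cohort, "sample_id"].tolist()
        mat = quantprot.complete_case_filter(quant, cohort_samples)
        retained[cohort] = set(mat.index)
        pairs = synthio.paired_samples(samples, cohort)
        diffs = quantprot.paired_differences(mat[cohort_samples], pairs)
        result = quantprot.moderated_t(diffs)
        result.insert(0, "cohort", cohort)
        diff_all.append(result)

        sig_up = set(result.loc[(result["p_value"] < config.alpha) & (result["log2fc"] > 0), "gene"])
        enr = quantprot.geneset_enrichment(sig_up, set(mat.index), gene_sets)
        enr.insert(0, "cohort", cohort)
        enr["reported"] = (enr["fdr"] < config.enrich_fdr) & (enr["score"] >= config.enrich_min_score)
        enrich_all.append(enr)

        # protein-RNA concordance for the significant genes
        for gene in sorted(sig_up):
            if gene in rna.index:
                rho, p = quantprot.spearman_corr(
                    mat.loc[gene, cohort_samples], rna.loc[gene, cohort_samples]
                )
                corr_all.append({"cohort": cohort, "gene": gene, "spearman_rho": rho, "p_value": p})

        summary[cohort] = {
            "n_retained": int(len(mat)),
            "n_significant": int((result["p_value"] < config.alpha).sum()),
            "n_up_at_relapse": int(
                ((result["p_value"] < config.alpha) & (result["log2fc"] > 0)).sum()
            ),
            "enriched_sets": enr.loc[enr["reported"], "gene_set"].tolist(),
        }
    summary["n_retained_intersection"] = int(len(retained["adult"] & retained["pediatric"]))

    write_tsv(pd.concat(diff_all, ignore_index=True), out / "diff_proteins.tsv")
    write_tsv(pd.concat(enrich_all, ignore_index=True), out / "enrichment.tsv")
    write_tsv(pd.DataFrame(corr_all), out / "correlations.tsv")

    pairs_all = synthio.paired_samples(samples)
    mt_table, mt_p = quantprot.mtdna_ratio(depth, pairs_all)
    write_tsv(mt_table, out / "mtdna_pairs.tsv")
    summary["mtdna"] = {
        "n_pairs": int(len(mt_table)),
        "median_ratio_pct": float(np.median(mt_table["ratio_pct"])),
        "wilcoxon_p": mt_p,
    }

    # PCA over every sample, tumor and control alike
    complete_all = quant[samples["sample_id"].tolist()].dropna()
    scores, explained = quantprot.pca_overview(complete_all)
    scores.insert(0, "sample_id", scores.index)
    write_tsv(scores.reset_index(drop=True), out / "pca_scores.tsv")
    summary["pca_explained"] = [float(x) for x in explained]
    return summary


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "dbgen": _stage_dbgen,
    "identify": _stage_identify,
    "annotate": _stage_annotate,
    "quant": _stage_quant,
}


def demo(out_dir: str | Path, seed: int = 0) -> dict:
    """The repository's living example: a small cohort through every stage."""
    config = PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        synth={
            "n_pairs_adult": 8, "n_pairs_pediatric": 6, "n_controls": 3,
            "n_protein_coding": 10, "n_pseudogene": 4, "n_lincrna": 2,
            "n_antisense": 2, "n_proteins": 400,
        },
    )
    return run_pipeline(config)
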