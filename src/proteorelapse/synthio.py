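"""Synthetic diagnosis/relapse cohort generator.

Emits a fully self-contained toy cohort with the statistical structure the
downstream proteogenomic analysis assumes: a small genome (nuclear contig +
chrM) with protein-coding, pseudogene, lincRNA, antisense and immunoglobulin
genes plus intergenic space; expressed transcripts with TPM values straddling
1.0; somatic SNVs with known missense/synonymous/non-coding truth; fusion
transcripts; target/decoy PSM tables drawn from two score distributions; a
TMT-style log2-ratio protein matrix for paired diagnosis/relapse samples with
a spiked mitochondrial program at relapse; and per-sample mt/nuclear WGS
depth summaries with a configurable relapse fold change.

Every generator is a pure function of (config, inputs): a fixed seed yields
byte-identical output files. Truth tables are written alongside each dataset
for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dbgen
from .io import (
    ensure_dir,
    write_fasta,
    write_gff3,
    write_gmt,
    write_transcript_blocks,
    write_tsv,
    write_vcf,
)
from .models import (
    GeneModel,
    STOP_CODONS,
    TranscriptModel,
    VariantRecord,
    revcomp,
    translate_nt,
)

_BASES = np.array(list("ACGT"))
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP_CODONS = np.array([c for c in _CODONS if c not in STOP_CODONS])

# rng stream ids, one per generator stage
_S_REFERENCE, _S_VARIANTS, _S_FUSIONS, _S_QUANT, _S_DEPTH, _S_PSMS = range(6)


@dataclass
class SynthConfig:
    """Tunable study conditions for the synthetic cohort.

    Defaults mirror the real cohort where the analysis states them: 22 adult
    and 16 pediatric diagnosis/relapse pairs (38 patient-matched pairs in
    total), five bone-marrow controls, and a ~1.3-fold relapse increase of
    the mitochondrial-to-nuclear depth ratio.
    """

    seed: int = 0
    # cohort structure
    n_pairs_adult: int = 22
    n_pairs_pediatric: int = 16
    n_controls: int = 5
    # toy genome
    n_protein_coding: int = 16
    n_ig_genes: int = 2
    n_pseudogene: int = 6
    n_lincrna: int = 3
    n_antisense: int = 3
    n_intergenic_transcripts: int = 3
    chrm_length: int = 1500
    chr1_length: int | None = None  # None = sized automatically
    # variants / fusions
    n_missense: int = 8
    n_synonymous: int = 4
    n_noncoding_snv: int = 4
    n_fusions: int = 2
    # protein matrix
    n_proteins: int = 800
    frac_mito: float = 0.08
    n_inflammatory: int = 4
    relapse_log2fc_mito: float = 1.0
    relapse_log2fc_inflammatory: float = 1.0
    quant_sd: float = 0.3
    patient_effect_sd: float = 0.2
    control_shift_sd: float = 0.4
    rna_sd: float = 0.5
    frac_missing: float = 0.03
    # depth summaries
    mt_depth_foldchange: float = 1.3
    mt_nuc_ratio_mean: float = 60.0
    nuclear_depth_mean: float = 30.0
    depth_noise_sd: float = 0.05
    # PSM simulation
    target_score_mean: float = 30.0
    decoy_score_mean: float = 10.0
    score_sd: float = 4.0
    frac_true: dict = field(
        default_factory=lambda: {
            "canonical": 0.9, "novel_candidate": 0.25, "saaa": 0.8, "fusion": 0.8
        }
    )
    frac_multi_psm: float = 0.6
    frac_novel_relapse_up: float = 0.3
    novel_relapse_log2fc: float = 1.0
    pi_noise_sd: float = 0.2
    # expression
    tpm_expressed_frac: float = 0.85

    def validate(self) -> None:
        counts = [
            self.n_pairs_adult, self.n_pairs_pediatric, self.n_controls,
            self.n_protein_coding, self.n_pseudogene, self.n_lincrna,
            self.n_antisense, self.n_proteins, self.chrm_length,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        fracs = [
            self.frac_mito, self.frac_multi_psm, self.frac_novel_relapse_up,
            self.frac_missing, self.tpm_expressed_frac, *self.frac_true.values(),
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must be in [0, 1]")
        if self.mt_depth_foldchange <= 0:
            raise ValueError("mt_depth_foldchange must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 1))
    return "ATG" + body


def _split_exons(rng: np.random.Generator, length: int, n_exons: int, min_exon: int = 20) -> list[int]:
    """Interior cut points partitioning [0, length) into n_exons blocks."""
    if n_exons == 1:
        return []
    while True:
        cuts = sorted(rng.choice(np.arange(min_exon, length - min_exon), size=n_exons - 1, replace=False))
        if all(b - a >= min_exon for a, b in zip([0, *cuts], [*cuts, length])):
            return [int(c) for c in cuts]


@dataclass
class Reference:
    """In-memory synthetic reference bundle."""

    genome: dict[str, str]
    genes: list[GeneModel]
    tx_models: dict[str, TranscriptModel]  # all transcripts incl. intergenic
    transcripts: dict[str, str]
    expression: pd.DataFrame  # transcript_id, tpm
    canonical: dict[str, str]  # protein name -> sequence
    cds_spans: dict[str, tuple[int, int]]  # transcript coords of CDS

    @property
    def expression_series(self) -> pd.Series:
        return self.expression.set_index("transcript_id")["tpm"]

    def ig_transcripts(self) -> set[str]:
        from .models import is_ig_gene

        return {
            t.transcript_id
            for g in self.genes
            if is_ig_gene(g)
            for t in g.transcripts
        }


def generate_reference(config: SynthConfig) -> Reference:
    """Toy genome, gene models, spliced transcripts and an expression table."""
    config.validate()
    rng = np.random.default_rng([_S_REFERENCE, config.seed])

    plan: list[tuple[str, str]] = []  # (biotype, name)
    plan += [("protein_coding", f"GENC{i + 1:03d}") for i in range(config.n_protein_coding)]
    plan += [("IG_V_gene", f"IGHV{i + 1}-1") for i in range(config.n_ig_genes)]
    plan += [("pseudogene", f"PSDG{i + 1:03d}P") for i in range(config.n_pseudogene)]
    plan += [("lincRNA", f"LINC{i + 1:04d}") for i in range(config.n_lincrna)]
    plan += [("antisense", f"GENC{i + 1:03d}-AS1") for i in range(config.n_antisense)]

    genes: list[GeneModel] = []
    tx_models: dict[str, TranscriptModel] = {}
    transcripts: dict[str, str] = {}
    canonical: dict[str, str] = {}
    cds_spans: dict[str, tuple[int, int]] = {}
    placements: list[tuple[int, str]] = []  # (genomic offset, pre-mRNA)

    cursor = 300
    for idx, (biotype, name) in enumerate(plan):
        gene_id = f"G{idx + 1:04d}"
        tid = f"TX{idx + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = biotype in ("protein_coding", "IG_V_gene")
        if coding:
            u5 = _rand_nt(rng, int(rng.integers(40, 90)))
            n_codons = int(rng.integers(60, 120))
            cds = _rand_cds(rng, n_codons)
            u3 = str(rng.choice(sorted(STOP_CODONS))) + _rand_nt(rng, int(rng.integers(40, 90)))
            mrna = u5 + cds + u3
            n_exons = int(rng.integers(2, 4))
        else:
            mrna = _rand_nt(rng, int(rng.integers(180, 400)))
            n_exons = int(rng.integers(1, 3))
        cuts = _split_exons(rng, len(mrna), n_exons)
        bounds = [0, *cuts, len(mrna)]
        pre = ""
        exon_pre: list[tuple[int, int]] = []
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            exon_pre.append((len(pre), len(pre) + (b - a)))
            pre += mrna[a:b]
            if k < len(bounds) - 2:
                intron_len = int(rng.integers(60, 160))
                pre += "GT" + _rand_nt(rng, intron_len - 4) + "AG"
        L = len(pre)
        g0 = cursor
        if strand == "+":
            exons = [(g0 + s, g0 + e) for s, e in exon_pre]
            placements.append((g0, pre))
        else:
            exons = sorted((g0 + L - e, g0 + L - s) for s, e in exon_pre)
            placements.append((g0, revcomp(pre)))
        model = TranscriptModel(
            transcript_id=tid, gene_id=gene_id, chrom="chr1", strand=strand, exons=exons
        )
        if coding:
            u5_len, cds_len = len(u5), len(cds)
            model.utr5 = model.to_genomic(0, u5_len)
            model.cds = model.to_genomic(u5_len, u5_len + cds_len)
            model.utr3 = model.to_genomic(u5_len + cds_len, len(mrna))
            cds_spans[tid] = (u5_len, u5_len + cds_len)
            canonical[name] = translate_nt(cds)
        genes.append(
            GeneModel(gene_id=gene_id, name=name, chrom="chr1", strand=strand,
                      biotype=biotype, transcripts=[model])
        )
        tx_models[tid] = model
        transcripts[tid] = mrna
        cursor = g0 + L + int(rng.integers(200, 450))

    # intergenic "assembled" transcripts in the tail of chr1
    for i in range(config.n_intergenic_transcripts):
        tid = f"TXI{i + 1:03d}"
        length = int(rng.integers(180, 320))
        g0 = cursor
        model = TranscriptModel(
            transcript_id=tid, gene_id="", chrom="chr1", strand="+",
            exons=[(g0, g0 + length)],
        )
        tx_models[tid] = model
        cursor = g0 + length + int(rng.integers(200, 400))

    chr1_len = cursor + 300
    if config.chr1_length is not None:
        if config.chr1_length < chr1_len:
            raise ValueError(
                f"chr1_length={config.chr1_length} too small for gene layout ({chr1_len} nt needed)"
            )
        chr1_len = config.chr1_length
    chr1 = np.array(list(_rand_nt(rng, chr1_len)))
    for g0, seq in placements:
        chr1[g0 : g0 + len(seq)] = list(seq)
    genome = {"chr1": "".join(chr1), "chrM": _rand_nt(rng, config.chrm_length)}

    for tid, model in tx_models.items():
        if tid.startswith("TXI"):
            transcripts[tid] = model.extract(genome)

    # expression: TPM values on both sides of 1.0, one transcript pinned at 1.0
    tids = sorted(transcripts)
    expressed = rng.random(len(tids)) < config.tpm_expressed_frac
    tpm = np.where(
        expressed,
        np.round(np.exp(rng.uniform(np.log(1.2), np.log(40.0), len(tids))), 4),
        np.round(rng.uniform(0.05, 0.95, len(tids)), 4),
    )
    if expressed.all():
        tpm[-1] = 0.5
    if not expressed.any():
        tpm[0] = 5.0
    low = np.flatnonzero(tpm <= 1.0)
    if len(low):
        tpm[low[0]] = 1.0  # exact boundary value, excluded by the strict filter
    expression = pd.DataFrame({"transcript_id": tids, "tpm": tpm})

    return Reference(
        genome=genome, genes=genes, tx_models=tx_models, transcripts=transcripts,
        expression=expression, canonical=canonical, cds_spans=cds_spans,
    )


# ------------------------------------------------------------ variants

def simulate_variants(config: SynthConfig, ref: Reference) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Somatic SNVs with known truth labels.

    Missense SNVs fall in the CDS of expressed protein-coding transcripts and
    record the expected amino-acid substitution; synonymous SNVs change a
    codon silently; the remainder are intronic/intergenic. REF always matches
    the reference genome base at POS (1-based).
    """
    rng = np.random.default_rng([_S_VARIANTS, config.seed])
    expr = ref.expression_series
    coding_tids = sorted(
        tid for tid in ref.cds_spans if expr[tid] > 1.0
    )
    if not coding_tids:
        raise ValueError("no expressed coding transcripts for requested SNVs")

    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []
    used_positions: set[int] = set()

    def add_cds_snv(tid: str, want_missense: bool) -> None:
        model = ref.tx_models[tid]
        mrna = ref.transcripts[tid]
        cds_start, cds_end = ref.cds_spans[tid]
        n_codons = (cds_end - cds_start) // 3
        for _ in range(200):
            ci = int(rng.integers(1, n_codons))
            codon = mrna[cds_start + 3 * ci : cds_start + 3 * ci + 3]
            k = int(rng.integers(0, 3))
            choices = [b for b in "ACGT" if b != codon[k]]
            rng.shuffle(choices)
            for alt in choices:
                new_codon = codon[:k] + alt + codon[k + 1 :]
                if new_codon in STOP_CODONS:
                    continue
                old_aa, new_aa = translate_nt(codon), translate_nt(new_codon)
                if want_missense != (old_aa != new_aa):
                    continue
                tpos = cds_start + 3 * ci + k
                (gs, _ge), = model.to_genomic(tpos, tpos + 1)
                if gs in used_positions:
                    continue
                used_positions.add(gs)
                g_ref = ref.genome[model.chrom][gs]
                g_alt = alt if model.strand == "+" else revcomp(alt)
                variants.append(
                    VariantRecord(
                        chrom=model.chrom, pos=gs + 1, ref=g_ref, alt=g_alt,
                        transcript_id=tid,
                        consequence="missense" if want_missense else "synonymous",
                    )
                )
                truth_rows.append(
                    {
                        "chrom": model.chrom, "pos": gs + 1, "ref": g_ref, "alt": g_alt,
                        "transcript_id": tid,
                        "consequence": "missense" if want_missense else "synonymous",
                        "protein_pos": ci + 1 if want_missense else -1,
                        "ref_aa": old_aa if want_missense else ".",
                        "alt_aa": new_aa if want_missense else ".",
                    }
                )
                return
        raise RuntimeError("could not place CDS SNV")

    n_cds = config.n_missense + config.n_synonymous
    replace = n_cds > len(coding_tids)
    picked = list(rng.choice(coding_tids, size=n_cds, replace=replace))
    for tid in picked[: config.n_missense]:
        add_cds_snv(tid, want_missense=True)
    for tid in picked[config.n_missense :]:
        add_cds_snv(tid, want_missense=False)

    # non-coding SNVs: intronic or intergenic positions
    spans = sorted(g.span for g in ref.genes)
    for _ in range(config.n_noncoding_snv):
        for _try in range(200):
            pos0 = int(rng.integers(0, len(ref.genome["chr1"])))
            exonic = any(
                s <= pos0 < e
                for t in ref.tx_models.values()
                for s, e in t.exons
            )
            if exonic:
                continue
            g_ref = ref.genome["chr1"][pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != g_ref]))
            variants.append(
                VariantRecord(chrom="chr1", pos=pos0 + 1, ref=g_ref, alt=alt,
                              consequence="non_coding")
            )
            truth_rows.append(
                {"chrom": "chr1", "pos": pos0 + 1, "ref": g_ref, "alt": alt,
                 "transcript_id": ".", "consequence": "non_coding",
                 "protein_pos": -1, "ref_aa": ".", "alt_aa": "."}
            )
            break
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


# ------------------------------------------------------------ fusions

def simulate_fusions(config: SynthConfig, ref: Reference) -> pd.DataFrame:
    """In-frame fusion transcripts between expressed protein-coding genes."""
    rng = np.random.default_rng([_S_FUSIONS, config.seed])
    expr = ref.expression_series
    coding = sorted(tid for tid in ref.cds_spans if expr[tid] > 1.0)
    if len(coding) < 2 * config.n_fusions:
        raise ValueError("not enough expressed coding transcripts for fusions")
    picked = list(rng.choice(coding, size=2 * config.n_fusions, replace=False))
    gene_by_tid = {t.transcript_id: g.name for g in ref.genes for t in g.transcripts}
    rows = []
    for i in range(config.n_fusions):
        ta, tb = picked[2 * i], picked[2 * i + 1]
        sa, ea = ref.cds_spans[ta]
        sb, eb = ref.cds_spans[tb]
        ka = int(rng.integers(5, (ea - sa) // 3 - 5))
        kb = int(rng.integers(5, (eb - sb) // 3 - 5))
        cut_a = sa + 3 * ka
        cut_b = sb + 3 * kb
        seq = ref.transcripts[ta][:cut_a] + ref.transcripts[tb][cut_b:eb]
        rows.append(
            {
                "fusion_id": f"FUS{i + 1:02d}",
                "gene5": gene_by_tid[ta],
                "gene3": gene_by_tid[tb],
                "junction": cut_a,
                "frame": sa % 3,
                "sequence": seq,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ samples

STAGES = ("D", "R1", "R1-P", "R2", "R2-P", "R3", "PR", "BM-control")


def make_samples(config: SynthConfig) -> pd.DataFrame:
    """Paired diagnosis/relapse sample metadata plus bone-marrow controls."""
    rows = []
    for cohort, n, prefix in (
        ("adult", config.n_pairs_adult, "A"),
        ("pediatric", config.n_pairs_pediatric, "P"),
    ):
        for i in range(n):
            patient = f"{prefix}{i + 1:03d}"
            rows.append({"sample_id": f"{patient}-D", "patient_id": patient,
                         "stage": "D", "cohort": cohort})
            rows.append({"sample_id": f"{patient}-R1", "patient_id": patient,
                         "stage": "R1", "cohort": cohort})
    for i in range(config.n_controls):
        rows.append({"sample_id": f"BM{i + 1:02d}", "patient_id": f"BM{i + 1:02d}",
                     "stage": "BM-control", "cohort": "control"})
    return pd.DataFrame(rows)


def validate_samples(samples: pd.DataFrame) -> None:
    bad_stage = set(samples["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")
    by_patient = samples.groupby("patient_id")["stage"].apply(set)
    for patient, stages in by_patient.items():
        if any(s.startswith(("R", "PR")) for s in stages) and "D" not in stages:
            raise ValueError(f"patient {patient} has relapse/PR sample but no diagnosis sample")


def paired_samples(samples: pd.DataFrame, cohort: str | None = None) -> pd.DataFrame:
    """(patient_id, diagnosis sample, first relapse sample) per complete pair."""
    df = samples if cohort is None else samples[samples["cohort"] == cohort]
    rows = []
    for patient, grp in df.groupby("patient_id", sort=True):
        stages = dict(zip(grp["stage"], grp["sample_id"]))
        relapse = next((stages[s] for s in ("R1", "R2", "R3", "PR") if s in stages), None)
        if "D" in stages and relapse:
            rows.append({"patient_id": patient, "diagnosis": stages["D"], "relapse": relapse})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ quant matrix

def simulate_quant(
    config: SynthConfig, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Protein matrix (log2 ratios to a reference pool), a matched RNA table,
    and the per-gene truth labels.

    Null proteins are centered at zero; the mitochondria-labeled set is
    shifted by ``relapse_log2fc_mito`` at relapse only, with no matching RNA
    shift (protein-RNA correlation ~0); a small inflammatory set is shifted
    at both levels with strongly correlated RNA, emulating signals that do
    replicate at the mRNA level.
    """
    validate_samples(samples)
    rng = np.random.default_rng([_S_QUANT, config.seed])
    n_mito = max(1, round(config.frac_mito * config.n_proteins))
    mito = [f"MRP{'SL'[i % 2]}{i + 1}" for i in range(n_mito)]
    inflam = ["GZMA", "GZMB", "GZMH", "GZMM", "CR1"][: config.n_inflammatory]
    n_null = config.n_proteins - n_mito - len(inflam)
    null = [f"PROT{i + 1:04d}" for i in range(n_null)]
    genes = mito + inflam + null

    sample_ids = samples["sample_id"].tolist()
    is_relapse = samples["stage"].str.startswith(("R", "PR")).to_numpy()
    is_control = (samples["cohort"] == "control").to_numpy()
    patients = samples["patient_id"].tolist()
    uniq_patients = sorted(set(patients))
    pat_idx = np.array([uniq_patients.index(p) for p in patients])

    G, S = len(genes), len(sample_ids)
    effect = np.zeros(G)
    effect[: n_mito] = config.relapse_log2fc_mito
    effect[n_mito : n_mito + len(inflam)] = config.relapse_log2fc_inflammatory
    if "CR1" in inflam:
        effect[genes.index("CR1")] = -config.relapse_log2fc_inflammatory

    pat_eff = rng.normal(0.0, config.patient_effect_sd, size=(G, len(uniq_patients)))
    ctrl_shift = rng.normal(0.0, config.control_shift_sd, size=G)
    x = (
        pat_eff[:, pat_idx]
        + rng.normal(0.0, config.quant_sd, size=(G, S))
        + np.outer(effect, is_relapse.astype(float))
        + np.outer(ctrl_shift, is_control.astype(float))
    )

    # RNA: inflammatory genes track protein (plus effect); mito genes do not
    rna = rng.normal(0.0, config.rna_sd, size=(G, S))
    for gi in range(n_mito, n_mito + len(inflam)):
        rna[gi] = x[gi] + rng.normal(0.0, 0.3 * config.rna_sd, size=S)

    quant = pd.DataFrame(np.round(x, 4), index=pd.Index(genes, name="gene"), columns=sample_ids)
    rna_df = pd.DataFrame(np.round(rna, 4), index=pd.Index(genes, name="gene"), columns=sample_ids)

    # sprinkle missing values over null genes only (spiked truth stays complete)
    if config.frac_missing > 0 and n_null > 0:
        mask = rng.random((n_null, S)) < config.frac_missing
        block = quant.iloc[n_mito + len(inflam) :].to_numpy()
        block[mask] = np.nan
        quant.iloc[n_mito + len(inflam) :] = block

    group = ["mito"] * n_mito + ["inflammatory"] * len(inflam) + ["null"] * n_null
    truth = pd.DataFrame({"gene": genes, "group": group, "true_log2fc": np.round(effect, 4)})
    return quant.reset_index(), rna_df.reset_index(), truth


# ------------------------------------------------------------ depth summaries

def simulate_depth(config: SynthConfig, samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean mt and nuclear read depth with a relapse ratio fold.

    Each patient has a baseline mt/nuclear ratio; relapse samples multiply it
    by ``mt_depth_foldchange`` under lognormal noise.
    """
    validate_samples(samples)
    rng = np.random.default_rng([_S_DEPTH, config.seed])
    uniq_patients = sorted(set(samples["patient_id"]))
    base_ratio = {
        p: config.mt_nuc_ratio_mean * np.exp(rng.normal(0.0, 0.25))
        for p in uniq_patients
    }
    rows = []
    for row in samples.itertuples():
        nuc = config.nuclear_depth_mean * np.exp(rng.normal(0.0, 0.1))
        ratio = base_ratio[row.patient_id] * np.exp(rng.normal(0.0, config.depth_noise_sd))
        if row.stage.startswith(("R", "PR")):
            ratio *= config.mt_depth_foldchange
        rows.append(
            {"sample_id": row.sample_id, "mt_depth": round(ratio * nuc, 3),
             "nuclear_depth": round(nuc, 3)}
        )
    depth = pd.DataFrame(rows)
    truth = pd.DataFrame({"parameter": ["mt_depth_foldchange"], "value": [config.mt_depth_foldchange]})
    return depth, truth


# ------------------------------------------------------------ PSM simulation

def simulate_psms(
    config: SynthConfig,
    peptides: pd.DataFrame,
    samples: pd.DataFrame,
    ig_transcripts: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Target/decoy PSM table, flanking-ion evidence, and peptide truth.

    A class-specific fraction of target peptides is "true" and draws its
    search score from the target distribution; all decoys and the remaining
    targets draw from the decoy distribution. True PSMs observe an
    isoelectric-focusing fraction consistent with the peptide's predicted pI;
    false PSMs land in a random fraction. Novel/SAAA/fusion targets carry
    per-sample reporter intensities relative to a reference-pool channel,
    with a subset of true novel peptides upshifted at relapse.
    """
    validate_samples(samples)
    rng = np.random.default_rng([_S_PSMS, config.seed])
    ig_transcripts = ig_transcripts or set()
    boundaries = dbgen.DEFAULT_FRACTION_BOUNDARIES
    n_bins = len(boundaries) - 1
    sample_ids = samples["sample_id"].tolist()
    is_relapse = dict(zip(sample_ids, samples["stage"].str.startswith(("R", "PR"))))

    psm_rows: list[dict] = []
    frag_rows: list[dict] = []
    truth_rows: list[dict] = []
    quant_cols = [f"intensity_{s}" for s in sample_ids]

    psm_counter = 0
    for row in peptides.itertuples():
        is_decoy = row.pep_class == "decoy"
        if is_decoy:
            is_true = False
        else:
            p_true = config.frac_true.get(row.pep_class, 0.0)
            from_ig = row.transcript_id in ig_transcripts
            is_true = (not from_ig) and rng.random() < p_true
        relapse_up = (
            row.pep_class == "novel_candidate" and is_true
            and rng.random() < config.frac_novel_relapse_up
        )

        cohorts: list[str] = []
        if is_true:
            if rng.random() < 0.8:
                cohorts.append("adult")
            if rng.random() < 0.5:
                cohorts.append("pediatric")
            if not cohorts:
                cohorts.append("adult")
        else:
            cohorts.append("adult" if rng.random() < 0.6 else "pediatric")

        quantified = (not is_decoy) and row.pep_class != "canonical"
        base_ratio = rng.normal(0.0, 0.4, size=len(sample_ids)) if quantified else None
        if quantified and relapse_up:
            base_ratio = base_ratio + np.array(
                [config.novel_relapse_log2fc if is_relapse[s] else 0.0 for s in sample_ids]
            )

        for cohort in cohorts:
            n_psms = (2 if rng.random() < config.frac_multi_psm else 1) if is_true else 1
            for _ in range(n_psms):
                psm_counter += 1
                score = rng.normal(
                    config.target_score_mean if is_true else config.decoy_score_mean,
                    config.score_sd,
                )
                if is_true:
                    obs_pi = row.predicted_pi + rng.normal(0.0, config.pi_noise_sd)
                    fraction = dbgen.assign_hirief_fraction(obs_pi, boundaries)
                    if fraction == dbgen.OUT_OF_RANGE:
                        fraction = 0 if obs_pi < boundaries[0] else n_bins - 1
                else:
                    fraction = int(rng.integers(0, n_bins))
                rec = {
                    "psm_id": f"psm{psm_counter:07d}",
                    "peptide_id": row.peptide_id,
                    "sequence": row.sequence,
                    "pep_class": row.pep_class,
                    "is_decoy": is_decoy,
                    "cohort": cohort,
                    "score": round(float(score), 4),
                    "fraction": fraction,
                }
                if quantified:
                    ref = float(np.exp(rng.normal(np.log(1e6), 0.3)))
                    noise = rng.normal(0.0, 0.1, size=len(sample_ids))
                    intens = ref * np.exp2(base_ratio + noise)
                    rec["intensity_refpool"] = round(ref, 2)
                    rec.update(dict(zip(quant_cols, np.round(intens, 2))))
                else:
                    rec["intensity_refpool"] = np.nan
                    rec.update(dict.fromkeys(quant_cols, np.nan))
                psm_rows.append(rec)

        if row.pep_class == "saaa" and not is_decoy:
            p, L = int(row.sub_pos), len(row.sequence)
            if is_true:
                sites = sorted({s for s in (p - 1, p) if 1 <= s <= L - 1})
            else:
                candidates = [s for s in range(1, L) if s not in (p - 1, p)]
                rng.shuffle(candidates)
                sites = sorted(candidates[:2])
            frag_rows.append(
                {"sequence": row.sequence, "sub_pos": p,
                 "matched_sites": ";".join(map(str, sites))}
            )

        if not is_decoy:
            truth_rows.append(
                {"peptide_id": row.peptide_id, "sequence": row.sequence,
                 "pep_class": row.pep_class, "is_true": is_true,
                 "relapse_up": relapse_up, "cohorts": "|".join(cohorts)}
            )

    return pd.DataFrame(psm_rows), pd.DataFrame(frag_rows), pd.DataFrame(truth_rows)


# ------------------------------------------------------------ gene sets

def make_genesets(config: SynthConfig, quant_truth: pd.DataFrame, seed_offset: int = 17) -> dict[str, list[str]]:
    """GMT-style gene sets: the true mitochondrial program, the inflammatory
    set, and several random null sets drawn from unspiked genes."""
    rng = np.random.default_rng([seed_offset, config.seed])
    mito = quant_truth.loc[quant_truth["group"] == "mito", "gene"].tolist()
    inflam = quant_truth.loc[quant_truth["group"] == "inflammatory", "gene"].tolist()
    null = quant_truth.loc[quant_truth["group"] == "null", "gene"].tolist()
    sets = {"MITOCHONDRIAL_PROGRAM": mito, "INFLAMMATORY_RESPONSE": inflam}
    for i in range(5):
        sets[f"RANDOM_SET_{i + 1}"] = sorted(rng.choice(null, size=min(40, len(null)), replace=False))
    return sets


# ------------------------------------------------------------ cohort writer

@dataclass
class Cohort:
    """Everything the pipeline consumes, in memory and on disk."""

    config: SynthConfig
    reference: Reference
    variants: list[VariantRecord]
    variant_truth: pd.DataFrame
    fusions: pd.DataFrame
    samples: pd.DataFrame
    quant: pd.DataFrame
    rna: pd.DataFrame
    quant_truth: pd.DataFrame
    depth: pd.DataFrame
    depth_truth: pd.DataFrame
    peptides: pd.DataFrame
    psms: pd.DataFrame
    fragments: pd.DataFrame
    psm_truth: pd.DataFrame
    genesets: dict[str, list[str]]


def generate_cohort(config: SynthConfig, out_dir: str | Path | None = None) -> Cohort:
    """Run every generator stage in order; optionally write all files."""
    config.validate()
    ref = generate_reference(config)
    variants, variant_truth = simulate_variants(config, ref)
    fusions = simulate_fusions(config, ref)
    samples = make_samples(config)
    quant, rna, quant_truth = simulate_quant(config, samples)
    depth, depth_truth = simulate_depth(config, samples)
    db = dbgen.build_search_database(
        ref.transcripts, ref.expression_series, ref.canonical, variants,
        fusions, ref.tx_models,
    )
    psms, fragments, psm_truth = simulate_psms(
        config, db.peptides, samples, ig_transcripts=ref.ig_transcripts()
    )
    genesets = make_genesets(config, quant_truth)

    cohort = Cohort(
        config=config, reference=ref, variants=variants, variant_truth=variant_truth,
        fusions=fusions, samples=samples, quant=quant, rna=rna, quant_truth=quant_truth,
        depth=depth, depth_truth=depth_truth, peptides=db.peptides, psms=psms,
        fragments=fragments, psm_truth=psm_truth, genesets=genesets,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = ensure_dir(out_dir)
    ref = cohort.reference
    write_fasta(ref.genome, out / "genome.fa")
    write_gff3(ref.genes, out / "annotation.gff3")
    write_fasta(ref.transcripts, out / "transcripts.fa")
    write_fasta(ref.canonical, out / "canonical.fa")
    write_transcript_blocks(list(ref.tx_models.values()), out / "transcript_blocks.tsv")
    write_tsv(ref.expression, out / "expression.tsv")
    write_vcf(cohort.variants, {c: len(s) for c, s in ref.genome.items()}, out / "somatic.vcf")
    write_tsv(cohort.fusions, out / "fusions.tsv")
    write_tsv(cohort.samples, out / "samples.tsv")
    write_tsv(cohort.quant, out / "quant.tsv")
    write_tsv(cohort.rna, out / "rna.tsv")
    write_tsv(cohort.depth, out / "depth.tsv")
    write_tsv(cohort.psms, out / "psms.tsv")
    write_tsv(cohort.fragments, out / "fragments.tsv")
    write_gmt(cohort.genesets, out / "genesets.gmt")
    from .dbgen import SearchDatabase

    SearchDatabase(cohort.peptides).write(out)
    truth = ensure_dir(out / "truth")
    write_tsv(cohort.variant_truth, truth / "variants.tsv")
    write_tsv(cohort.quant_truth, truth / "quant.tsv")
    write_tsv(cohort.depth_truth, truth / "depth.tsv")
    write_tsv(cohort.psm_truth, truth / "peptides.tsv")
    cohort.config.to_yaml(out / "config.yaml")
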