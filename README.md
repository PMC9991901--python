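# proteorelapse

A proteogenomic analysis pipeline for paired diagnosis/relapse leukemia
cohorts profiled by isobaric-label (TMT) mass spectrometry with matched
WGS/WES and RNA-seq. It is aimed at computational proteomics researchers who
want a tested, reusable implementation of the workflow that (i) discovers
**novel peptides** — confident peptide identifications absent from the
canonical proteome, arising from UTRs, introns, pseudogenes, lincRNAs,
antisense transcripts, intergenic regions or non-canonical splicing — and
(ii) quantifies **relapse-associated proteome changes**, including the
mitochondrial program and its mtDNA correlate.

The package covers:

- **Search-space construction** (`dbgen`): three-frame translation of
  expressed transcripts (TPM > 1), in-silico tryptic digestion (cleave after
  K/R, not before P, ≤2 missed cleavages, 7–40 aa), subtraction of the
  canonical proteome under I/L equivalence, single-amino-acid-alteration
  (SAAA) peptides from somatic SNVs via six-frame translation of mutated
  windows, fusion-junction peptides, pseudo-reversed decoys, and peptide pI
  prediction (bisection on the Henderson–Hasselbalch net charge with
  Bjellqvist pKas) for isoelectric-focusing consistency.
- **Identification filtering** (`identfilter`): class-specific target-decoy
  FDR with q-value monotonization,

  FDR̂(s) = #decoys ≥ s ⁄ max(1, #targets ≥ s),  q(s) = min over t ≤ s FDR̂(t),

  followed by canonical re-subtraction, immunoglobulin-gene removal, a
  flanking-ion check for substituted residues, and a predicted-pI filter.
- **Genomic annotation** (`pepannot`): splice-aware peptide→genome mapping,
  classification into protein-coding (5'UTR / 3'UTR / intronic /
  exon-variant / other), pseudogene, lincRNA, antisense, intergenic or
  overlapping categories, outlier-sample detection (value > 2 × Q3), and
  paired novel-peptide differential abundance (PSM > 1 filter).
- **Cohort statistics** (`quantprot`): gene-symbol-centric quantification,
  complete-case filtering, the empirical-Bayes **moderated paired t**
  (s̃²_g = (d₀s₀² + d_g s_g²)/(d₀ + d_g), t̃_g = m_g/(s̃_g/√n) on d₀+d_g df)
  with BH adjustment, Wilcoxon matched-pairs and Spearman tests,
  hypergeometric gene-set over-representation with enrichment score
  (k/n)/(K/N), PCA, and the mitochondrial-DNA abundance ratio
  100·(mt/nuclear)_relapse ⁄ (mt/nuclear)_diagnosis tested against a
  theoretical median of 100.
- **Synthetic cohorts** (`synthio`): a deterministic generator producing a
  toy genome/annotation, expressed transcripts, somatic SNVs, fusions,
  target/decoy PSM tables, a spiked protein matrix with matched RNA, and
  per-sample depth summaries — all with truth labels, so every stage is
  testable without downloads. Defaults mirror a 22 adult + 16 pediatric
  pair cohort (38 diagnosis/relapse pairs) with a 1.3-fold relapse increase
  in the mt/nuclear depth ratio.

See `docs/methods.md` for the model details, assumptions and limitations.

## Worked example

Generate a synthetic cohort and run two of the headline analyses:

```sh
$ proteorelapse synth --out demo_cohort --seed 7
cohort written to demo_cohort

$ proteorelapse mtdna --depth demo_cohort/depth.tsv \
    --samples demo_cohort/samples.tsv --out mt.tsv
median ratio 129.8% (signed-rank P vs 100 = 8.06e-08, n = 38)

$ proteorelapse diff --quant demo_cohort/quant.tsv \
    --samples demo_cohort/samples.tsv --cohort adult --out diff.tsv
77 proteins at P < 0.05
```

The mtDNA line says that across the 38 patient pairs the
mitochondrial-to-nuclear depth ratio at relapse is ~30% above its diagnosis
value (the generator's planted fold is 1.3) and that the one-sample
signed-rank test against the theoretical median of 100 rejects decisively.
The `diff` command reports the number of proteins whose paired
relapse-vs-diagnosis moderated-t test falls below P < 0.05 in the adult
cohort; with the default generator ~8% of proteins are planted with a +1
log2 relapse shift.

The whole chain runs from a single command:

```sh
proteorelapse pipeline demo --out demo_run --seed 7
```

which writes every intermediate table plus `report.json`. With seed 7 the
demo identifies 246 confident novel peptides (114 annotated to
protein-coding genes, 39 to pseudogenes, 37 intergenic, 24 lincRNA, 32
antisense), finds the planted `MITOCHONDRIAL_PROGRAM` and
`INFLAMMATORY_RESPONSE` gene sets enriched among relapse-upregulated
proteins in both cohorts, and reports an mtDNA median pair ratio of 129.2%
(P = 1.2e-4 over the demo's 14 pairs).

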