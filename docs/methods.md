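# Methods

`proteorelapse` implements a proteogenomic workflow for paired
diagnosis/relapse leukemia cohorts: building a customized peptide search
space from transcriptomic and genomic evidence, filtering putative novel
peptides by class-specific target-decoy FDR plus curation rules, classifying
the survivors by their genomic origin, and running the cohort-level
statistics (paired differential protein abundance, gene-set
over-representation, protein–RNA concordance, and mitochondrial-DNA
abundance from WGS depth). Because real deposited cohorts are far beyond
desk scale, every stage is exercised end-to-end on a bundled synthetic
cohort whose truth labels make parameter recovery measurable.

## Search-space construction (`dbgen`)

**Expression filter.** Only transcripts with TPM strictly greater than 1.0
enter the database; a transcript at exactly 1.0 is excluded.

**Three-frame translation.** Each transcript is translated in frames 0/1/2
with the standard genetic code. Stop codons and codons containing N split a
frame into separate ORF fragments; no minimum fragment length is applied
before digestion (fragments shorter than 7 aa vanish there).

**Tryptic digestion.** Cleavage C-terminal to K/R except before P, up to 2
missed cleavages, peptide length 7–40 aa. These are standard search-engine
defaults; the digestion enumerates (peptide, offset) pairs so every database
entry stays traceable to its source transcript, frame, and amino-acid
offset.

**Canonical subtraction.** A peptide is "novel" only if its I/L-collapsed
sequence does not occur as a substring of the I/L-collapsed canonical
proteome (concatenated with separator sentinels). Isoleucine and leucine are
isobaric and indistinguishable by standard MS, so all identity checks in the
package collapse them. Exact substring search is deterministic and
conservative compared with a heuristic aligner.

**SAAA peptides.** For each somatic SNV inside a transcript, the altered
base is substituted and a ±120 nt window (enough to contain any 40-aa
tryptic peptide covering the variant) is translated in six frames by
default — the forward three frames plus the reverse complement — then
digested. Peptides must contain the altered residue and be absent from the
canonical proteome; the altered residue's position within the peptide is
recorded for flanking-ion curation. Six-frame mode is the default even
though the transcript strand is known, mirroring how variant databases are
commonly built; a three-frame mode is available.

**Fusion peptides.** Fusion transcripts are three-frame translated and
digested; only peptides whose codon range crosses the recorded junction
offset are kept (and subtracted against the canonical proteome).

**Decoys.** Pseudo-reversal (reverse the sequence, keep the C-terminal
residue fixed) preserves tryptic termini and amino-acid composition. Decoys
colliding with any target sequence are discarded; each decoy remembers the
class of its target so FDR can be estimated per class.

**Peptide pI.** The isoelectric point is found by bisection on the
Henderson–Hasselbalch net-charge function over the N-terminus, C-terminus
and the D/E/C/Y/H/K/R side chains, using a fixed Bjellqvist pKa table
shipped as a module constant so results are bit-reproducible. The charge is
strictly decreasing in pH, so bisection on [0, 14] converges; the returned
pH has |net charge| < 1e-4.

## Identification filtering (`identfilter`)

FDR is estimated separately within each peptide class (novel candidate,
SAAA, fusion): at score threshold s, FDR̂(s) = #decoys ≥ s / max(1,
#targets ≥ s); the q-value is the running minimum of FDR̂ over decreasing
thresholds, clipped to [0, 1]. Ties in score rank decoys above targets
(pessimistic). No +1 correction and no rescoring are applied — this is the
simplest defensible estimator.

The curation chain runs in a fixed, logged order and each stage only
removes: confidence filter (min q < 0.01 per peptide; `psm_count` counts
only confident PSMs, with an all-PSMs option) → post-search canonical
subtraction against an extended reference collection → removal of peptides
overlapping immunoglobulin genes (biotype `IG_*` or symbol matching
`IG[HKL]`) → for SAAA peptides, a simplified flanking-ion check: at least
one matched b/y ion whose cleavage site flanks the substituted residue on
each side, with terminal substitutions requiring only the single definable
flank (mass-tolerance handling and spectrum parsing are out of scope;
fragment evidence arrives pre-matched) → an optional predicted-pI
consistency filter.

The pI filter keeps a peptide when at least one supporting PSM observed an
isoelectric-focusing fraction whose midpoint lies within the tolerance
(default 1.0 pH) of the predicted pI. The first and last fractions of the
strip are treated as open-ended: in IPG-IEF a peptide whose pI lies beyond
the strip range focuses at the strip end, so a predicted pI outside the
range on the matching side counts as distance zero. Without this rule every
strongly basic tryptic peptide would be discarded by construction.

## Genomic annotation (`pepannot`)

A peptide's transcript-coordinate range (frame + 3×offset, length 3×length)
is mapped to genomic intervals by walking the transcript's exon blocks,
splice- and strand-aware; interval lengths always sum to three times the
peptide length, and translating the genome slices back (reverse-complemented
on minus strands) reproduces the peptide.

Classification: no overlapping gene → intergenic; more than one distinct
gene → overlapping; one gene → its biotype. Within a single protein-coding
gene: entirely inside the annotated 5'/3'UTR → utr5/utr3; inside the gene
with no exon overlap → intronic; overlapping annotated CDS → exon variant
(a canonical in-frame peptide cannot reach this point, it was subtracted
upstream); everything else (e.g. spanning a UTR/intron boundary) → other.
Category percentages use all peptides of the cohort as denominator;
subcategory percentages use only peptides annotated to solely one
protein-coding gene; both are rounded half-up to one decimal. Cohort
presence and overlaps compare I/L-collapsed sequences.

Outlier samples per peptide: a sample is flagged when its linear-scale
abundance exceeds twice the third quartile of the peptide's values, with Q3
computed by linear interpolation on sorted order statistics ("type 7") over
all samples of the cohort including the candidate. Fewer than four observed
samples yields no calls.

Novel-peptide differential abundance reuses the moderated-t engine below on
relapse-minus-diagnosis log2 differences, restricted to peptides with more
than one confident PSM in the cohort.

## Cohort statistics (`quantprot`)

**Gene-centric quantification.** Per gene and sample, the median of
peptide-level log2 ratios of peptides uniquely mapped to that gene; shared
peptides are dropped. Cohort matrices are complete-case filtered (a protein
must be quantified in every sample of the cohort).

**Moderated t.** Per feature, the mean paired difference m and sample
variance s² (df = n−1) are combined with a scaled inverse-chi-square prior
(d₀, s₀²) fitted by matching the mean and variance of log s² to the
theoretical moments of a scaled F distribution (trigamma inversion by
Newton iteration): s̃² = (d₀s₀² + d·s²)/(d₀+d), t = m/√(s̃²/n) on d₀+d
degrees of freedom, two-sided p, BH adjustment across features. Setting the
prior df to 0 recovers the classical paired t exactly; infinite prior df
pools all variances (z-like statistic). Degenerate all-zero variances fall
back to the classical t with a warning. Protein-level significance follows
the raw P < 0.05 convention; gene sets are reported at BH-FDR < 0.01 with
enrichment score ≥ 3.

**Classical tests.** Wilcoxon matched-pairs signed-rank: zero differences
dropped, exact p for n ≤ 25 without ties, normal approximation with tie and
continuity correction otherwise. Spearman correlation with mid-ranked ties
and the t-approximation for p.

**Gene sets.** Hypergeometric upper-tail over-representation with
enrichment score (k/n)/(K/N); gene sets are user-supplied GMT files — no
ontology content is bundled.

**mtDNA abundance.** Per sample r = mean mitochondrial depth / mean nuclear
depth; each diagnosis/relapse pair contributes 100·r_R/r_D, tested against
the theoretical median 100 with the one-sample signed-rank test. chrM is
modeled as a linear contig; only mean depth is consumed, so circularity is
irrelevant.

**PCA.** Row-centered SVD; an optional leverage-based sample-QC flag exists
for hypodiploid-like outlier samples but is off by default.

## The synthetic cohort (`synthio`)

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular genome:

- A nuclear contig laid out with protein-coding genes (5'UTR, multi-exon
  CDS starting ATG with no internal stop, 3'UTR, ≥1 intron), immunoglobulin
  genes, pseudogenes, lincRNAs, antisense genes and intergenic space, plus a
  short chrM contig. One transcript per gene (the "solely one gene"
  annotation logic stays testable); a few intergenic "assembled" transcripts
  exist in the alignment table but not the annotation, which is how
  intergenic-category peptides arise. Retained-intron transcripts are not
  generated, so the intronic subcategory is exercised by constructed
  fixtures in the test suite rather than the demo.
- TPM values straddle 1.0 with one transcript pinned exactly at the
  boundary.
- Somatic SNVs with missense/synonymous/non-coding truth labels; REF always
  matches the reference base.
- PSM scores from two Gaussians — targets N(30, 4), decoys and false
  targets N(10, 4), a clearly separated regime (≈5σ) as the recovery
  analyses assume; class-specific fractions of targets are "true". True
  PSMs observe an isoelectric-focusing fraction consistent with the
  peptide's predicted pI (noise sd 0.2 pH); false PSMs land in random
  fractions. A configurable fraction of true peptides carries >1 PSM.
- The protein matrix is log2 ratios to a reference pool: null proteins
  centered at 0 (noise sd 0.3 plus a patient random effect of sd 0.2 that
  cancels in paired differences), a mitochondria-labeled set (8% of
  proteins) shifted by +1 log2 unit at relapse with *uncorrelated* RNA, and
  a small inflammatory set shifted at both protein and RNA level with
  strongly correlated RNA. Missing values are sprinkled over null proteins
  only.
- Depth summaries: lognormal noise around a per-patient baseline
  mt/nuclear ratio, multiplied by the configured fold (default 1.3,
  matching the ≈30% relapse increase the analysis is designed to detect) in
  relapse samples.
- Default cohort structure: 22 adult + 16 pediatric diagnosis/relapse pairs
  (38 pairs) plus 5 bone-marrow controls.

Everything is a pure function of the config and its seed; a fixed seed
yields byte-identical output files. Truth tables (true SAAAs, planted novel
peptides, spiked proteins, true depth fold) are written alongside each
dataset.

What the generator deliberately does **not** model: read-level data (depth
summaries only), spectra (PSM tables only), tumor purity (samples are
treated as pure), multi-transcript genes, TMT batch structure beyond the
reference-pool ratio, and any sequence homology between genes. Passing
recovery tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated assumptions, not performance on real
spectra.

## Numerical choices and problem sizes

- FDR estimator ties are pessimistic (decoys first); q-values are invariant
  to stable reordering of the input.
- The bisection tolerance for pI is 1e-6 pH; the BH implementation is
  statsmodels'.
- The demo pipeline and the reproduction script use a reduced cohort (8 + 6
  pairs, ~20 genes, ~400 proteins) so the complete chain runs in seconds;
  calibration suites use 200 null replicates of 10 000 PSMs and 20
  replicates for recovery analyses. These sizes give Monte-Carlo error well
  inside the asserted bands.

## Known limitations

- The canonical subtraction is substring-exact (after I/L collapse); it
  does not model near-isobaric substitutions beyond I/L or deamidation
  artifacts.
- The flanking-ion curation is the decision rule only; it trusts the
  provided matched-ion lists.
- The class-specific FDR treats the class column as given; finer-grained
  classes (e.g. per annotation category) would need the caller to relabel.
- With no +1 correction, the q-value of the single top-scoring target is 0
  by construction; at realistic list sizes this is immaterial, but the
  estimator is anti-conservative for tiny classes (the fusion class in the
  demo has tens of entries).
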