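# Methods

venomkit reimplements, at desk scale, the computational pipeline used to
characterize the Duvernoy's-gland (venom-gland) transcriptome of a small
rear-fanged snake from six individuals: paired-end read processing, combination
of multiple de novo assemblies into a clustered species consensus, translated
toxin annotation, a read-realignment chimera screen, EM-based expression
quantification, family-level composition, and concordant negative-binomial
differential expression. Because the pipeline's raw inputs are multi-gigabyte
sequencing runs, the package ships a synthetic-data generator with exact ground
truth; every downstream stage is validated against that truth.

## Synthetic data generator (`venomkit.simulate`)

**Reference.** Twelve toxin families (3FTx, CRISP, SVMPIII, CTL, AChE, fused,
KUN, PDE, PLA2, PLB, VEGF, waprin) plus a nontoxin pool. Family paralog counts
default to the study species' consensus (9/2/8/7/3/1/1/1/1/1/1/1 = 36 toxins).
Toxin paralogs descend from a per-family random ancestor protein at 25%
amino-acid divergence; nontoxins are independent random proteins. Coding
sequences back-translate each protein with random synonymous codons, so
`translate`/`longest_orf` recover the protein exactly. Toxin proteins carry a
signal peptide annotated as the first 20 codons (a typical secretion-peptide
length; only its transfer, not its inference, is in scope). Protein lengths are
uniform on 160–240 aa (toxins) and 160–280 aa (nontoxins): long enough that
merged fragments (~180 bp) sit well inside transcripts, short enough to keep
alignment costs at desk scale. Real 3FTx precursors are shorter (~80–100 aa);
the generator trades that realism for a non-degenerate coverage geometry.

**Expression.** The family profile defaults to the study's average composition
(3FTx 54.3%, CRISP 24.0%, SVMPIII 18.4%, CTL 3.1% of toxin expression; the
remaining 0.2% split equally over the eight minor families), with toxins taking
63.7% of total expression. Per individual, family shares are log-normally
perturbed (σ = 0.3) and within-family transcript weights are log-normal
(σ = 0.5); TPM closes to 10⁶. Each locus is heterozygous with probability 0.3,
expressing the reference allele and a variant at 0.5% nucleotide divergence,
TPM split 50/50. The divergence default keeps allele pairs far above the 98%
clustering threshold while remaining retainable by the 2-substitution read
mapper (see Quantification); at 1% divergence the strict mapper — unlike a real
Bowtie 2 run — would drop a quarter of variant-allele reads.

**Assemblies.** Three contig sets per individual emulate three assemblers. Each
set carries every expressed allele, with per-set perturbations: exact
duplicates (5%), 5′/3′ truncations of up to 10% of the sequence (10% of
contigs), and injected chimeras (5′ half of one transcript joined to the 3′
half of another) at a rate of 0.1 per base contig; junction coordinates are
recorded in the truth table.

**Reads.** 150 bp pairs from fragments targeting a 400 bp mean. Fragment
lengths are log-normal (mean 400, log-sd 0.8): a Normal(400, 40) model cannot
reproduce the observed 74–83% pair-merge rates, since 150 bp mates only overlap
when the fragment is under ~290 bp, and the heavy left tail of real sheared
libraries is what makes merging common. Fragment placement emulates shearing of
intact molecules: with probability 0.4 the piece is anchored at a molecule
boundary (each sheared molecule contributes two end pieces among roughly L/f
interior ones), otherwise the virtual start is uniform with up to
(f − read_length) bases of overhang, clipped at the boundaries. Without
boundary-anchored pieces, transcript edge bases receive ~1/400 the interior
coverage rate and the chimera screen's zero-coverage rule removes most genuine
transcripts at desk depth. Given a fragment length f, the source transcript is
drawn ∝ TPM × max(L − f + 1, 1) — the count of valid placements — which is the
generative model under which TPM is the recoverable quantity. Sequencing errors
are substitutions at `per_base_error` (default 0: the study conditions for the
screen and recovery checks are error-free); correct calls are Q37, errors Q11,
and an optional Q2 3′-tail mode exercises quality trimming.

**What the generator does not emulate:** coverage-driven assembly contiguity,
indels, strand-specific chemistry, quality-score profiles, expression-linked
codon bias, and genuine paralog phylogenies. Passing the end-to-end checks
therefore demonstrates the pipeline's logic and statistics are sound, not that
it would reach the same operating characteristics on real libraries.

## Read processing (`venomkit.readproc`)

3′ trimming removes trailing bases below Phred 5 (hard threshold, no adapter
logic); a pair is dropped when either mate empties. Merging scans every overlap
offset between R1's 3′ end and reverse-complemented R2's 5′ end and keeps the
offset maximizing the overlap score (matches − mismatches, ties to the longer
overlap); raw match count would let long spurious overlaps — a quarter of whose
bases match by chance — beat short true ones. An overlap is accepted at ≥ 10 bp
and ≤ 10% mismatches; disagreeing bases take the higher-quality call and the
overlap quality is the per-base maximum. `summarize_runs` reports the mean and
population SD (denominator n) of read pairs and merge percentages, and a pooled
merge percent (Σ merged / Σ pairs); these conventions reproduce the published
six-library summary exactly.

## Annotation (`venomkit.annotate`)

Contigs are translated in all six frames, frames split at stop codons, and
segments sharing an exact 5-mer with a reference protein are aligned locally
(BLOSUM62, gap open 11 / extend 1, via Biopython's PairwiseAligner). The seed
requirement is BLAST-like and deterministic; alignments scoring near the E-value
floor essentially always contain a 5-residue exact run. Significance uses
E = K·m·n·e^(−λS) with fixed gapped constants λ = 0.267, K = 0.041 (m = frame
length, n = summed reference length) — approximate but deterministic; the
hit floor is E ≤ 10⁻⁴. A best hit with amino-acid identity (identical /
aligned residue pairs) above 80% is auto-annotated, copying the family and
mapping the reference signal-peptide interval through the alignment onto contig
nucleotide coordinates. Weaker hits above the floor are "manual" (the best
hit's family is proposed and, in pipeline runs, accepted — no curator);
anything else stays unannotated and never reaches the consensus. Paralog labels
(`3FTx-1`, …) order family members by descending mean TPM, ties to the smaller
id. `peptide_fragment_scan` slides a short peptide (e.g. a 14-residue venom
fragment) ungapped across every offset of each protein, including overhangs,
and reports the maximum identical-residue count — it is the exhaustive
computation, not a heuristic.

## Chimera screen (`venomkit.chimera`)

Merged reads are re-aligned to the annotated contigs keeping only perfect,
gap-free, full-length occurrences on either strand (every matching locus
counts; seeded on the read's leading 25-mer, which is exact and complete).
A transcript with any zero-coverage base is removed. Survivors are screened
with the flanking-length imbalance statistic: at site i, L and R are the mean
aligned read lengths left (inclusive) and right of the site over the reads
covering it, and D_i = |L − R| / max(L, R) ∈ [0, 1]. The screen flags a
transcript when D exceeds 0.75 at an internal site, with three guards that make
the statistic meaningful at finite depth:

* **internal sites only** — sites closer than the mean aligned read length to
  either end are skipped; read truncation at transcript ends makes D large
  there even under ideal uniform coverage;
* **boundary-censored reads excluded** — alignments touching position 0 or L
  (clipped end pieces; the strict-matching analog of soft-clipped reads) carry
  no flanking-length information and would fake imbalance where they pile up;
* **minimum support 10** — D estimated from fewer than 10 interior reads is
  sampling noise (a single read yields D ≈ 1 near its own ends).

At an assembly-chimera junction no read can span the joint, so either coverage
collapses (zero-coverage removal) or the reads ending exactly at the junction
drive D → 1 beside it. Flagged transcripts are removed in pipeline mode
(`keep_flagged` preserves them for inspection). On generator defaults the
screen catches ≥ 98% of injected chimeras while fully removing ≤ 5% of
genuine expressed loci (a locus counts as lost only when every contig
representing it — truncated copies and both alleles included — is removed).

## Clustering (`venomkit.cluster`)

Pairwise identity is the strand-maximum global alignment (match +1, mismatch
−1, gap −2) with identical aligned bases divided by the shorter sequence's
length — cd-hit-est's convention, under which containment scores 1.0. Greedy
clustering sorts contigs longest-first (ties by id) and assigns each to the
first cluster whose representative it matches at the threshold: 98% within an
individual (collapsing alleles), 95% across individuals for the consensus.
A provably conservative edlib edit-distance screen (bound
2(1−t)·L_short + ΔL, applied with 50% margin) skips full alignments that
cannot reach the threshold; a brute-force all-pairs oracle over 200 random
instances confirms the partition is unchanged. Exact duplicates, including
reverse-complement duplicates, are collapsed beforehand, keeping the
lexicographically smallest id.

## Quantification (`venomkit.quant`)

Reads map to the consensus wherever they match with ≤ 2 substitutions (no
indels) on either strand — a deterministic stand-in for default Bowtie 2.
Candidates come from exact lookups of three disjoint 25-mers (pigeonhole:
with ≤ 2 errors one window is clean), so the search is complete for merged
reads ≥ 75 bp. Expected counts come from an EM over compatibility classes:
E-step weights θ_t/ℓ̃_t, M-step re-normalizes, uniform start, convergence at
max |Δθ| < 10⁻⁶; the observed-data log-likelihood is non-decreasing and is
recorded. Effective length is ℓ̃ = max(L − mean merged read length + 1, 1) and
TPM_t = 10⁶ (EC_t/ℓ̃_t)/Σ_u(EC_u/ℓ̃_u). Families are member sums of EC and TPM.
Zero imputation is count-zero multiplicative replacement — per sample, zeros
become half the smallest nonzero value and nonzero entries rescale so the
composition still closes to 10⁶ — a hyperparameter-free simplification of
Bayesian-multiplicative replacement that preserves closure and monotonicity.
The composition table reports each toxin family as a percent of total toxin
TPM per sample, with the average column computed from mean family TPM (not the
mean of per-sample percentages) and sub-0.1% entries printed as "<0.1%".

## Differential expression (`venomkit.destats`)

Each covariate (sex, state, SVL, latitude, longitude) is tested one at a time
against toxin-transcript and family-summed expected counts (features with total
EC < 10 are excluded; continuous covariates are centered). Two branches:

* **Wald (DESeq2-style).** Median-of-ratios size factors. Gene-wise dispersion
  solves the Pearson-residual moment equation Σ(y−μ)²/(μ+αμ²) = n−p at the
  initial fit (design-aware, hence robust to true effects), then shrinks
  halfway in log space toward a running-median trend over the mean axis — the
  "local fit" stand-in. The Wald statistic uses a variance-matching small-sample
  correction: the SE is inflated by √(ν/(ν−2)) with ν = 2(n−p), since the
  shrunk dispersion estimate carries roughly twice the residual degrees of
  freedom and the ratio is t-like rather than normal. Without the correction
  the two-sided normal reference rejects ~11% of nulls at n = 6; with it,
  measured type-I error is 0.059–0.066 across independent null seeds.
* **LRT (edgeR-style).** TMM normalization factors (doubly-trimmed weighted
  mean of M-values against the upper-quartile-nearest reference, factors
  scaled to multiply to 1) on library-size offsets. A common dispersion
  maximizes the Cox–Reid adjusted profile likelihood under the full design
  (evaluated on ≤ 200 evenly spaced features), moderated toward each feature's
  moment estimate with prior weight 10. The statistic 2Δℓ is referred to χ²₁;
  measured null type-I error is 0.040–0.058.

p-values are BH-adjusted per method (statsmodels, NaN passthrough) and a
feature is significant only when both adjusted values fall below α = 0.05 —
the concordance rule, never more liberal than either test. Power at a 4-fold
binary effect (n = 3+3, μ = 500, dispersion 0.1) exceeds 0.95 at p < 0.01 for
both branches, and the median estimated log₂ fold change of truly DE features
recovers the simulated value within ±0.1. Median-of-ratios factors match
DESeq2's `estimateSizeFactors` exactly on a frozen cross-check matrix; the
simplified TMM matches edgeR's `calcNormFactors` to ~1%.

## Pipeline (`venomkit.pipeline`)

Stage order: trim/merge → per-assembly annotation → combine + deduplicate →
chimera screen → 98% within-individual clustering → 95% consensus →
quantification of each individual against the consensus → family aggregation,
composition, imputation → differential expression. Annotation precedes
combination, so unannotated contigs never reach the consensus. All randomness
derives from one seed through per-stage seed sequences; a rerun is
reproducible to the byte. Intermediates are written in standard formats
(FASTA, TSV) so any stage can be re-run in isolation or swapped for an
external tool.

## Problem sizes

Default desk-scale conditions: 36 toxin references (the study's family
breakdown), 200 nontoxins, 6 individuals, 3 assembly sets each, 10⁵ read pairs
per individual (~5–6 × 10⁴ merged reads). The nontoxin pool is an order of
magnitude below the real 2409 because it is interchangeable plumbing — every
per-contig code path is identical — while the toxin complement, which carries
the science, is full size. The DE calibration uses 2000 simulated features at
n = 6. A full pipeline run takes ~1.5 minutes on one CPU; the complete test
suite runs in ~3 minutes.

## Known limitations

E-values use fixed Karlin–Altschul constants rather than per-scoring-system
estimates; the read mapper ignores indels and quality scores; the imbalance
screen's 0.75 threshold is taken as given and its exact normalization is a
design choice (relative difference of mean flanking lengths, normalized by the
larger); minor toxin families at the study's real proportions (0.025% of toxin
expression each) are below the coverage needed to survive the zero-coverage
rule at desk depth, so the consensus recovers the four major families plus
whichever minor loci achieve full coverage; and the DE machinery is a
calibrated simplification, not a numerical clone, of DESeq2 and edgeR.
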