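# Methods

This note records the statistical model behind the package, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions a maintainer should
know about.

## Translation states

The translation state of a gene is the polysomal : non-polysomal
signal ratio on the log2 scale, `log2 TL = log2 PL − log2 NP`, computed
per replicate after normalization and averaged afterwards
(log-transform first, average second; the alternative order is not
equivalent and the package commits to this one). `NP = 0` or missing
values yield a missing TL, never ±inf. Differentials are
`Δlog2 TL = mean log2 TL(mut) − mean log2 TL(WT)`; the same contract on
TC signals gives `Δlog2 TC`. No global polysome-shift adjustment is
applied (a hook exists but defaults off): results therefore speak to
gene-specific changes only, and a genuinely global loading shift would
be invisible. Genes missing a replicate use the remaining replicates
for that genotype's mean and drop out of Δ only when a side has no
values at all.

## Preprocessing

The RMA-style route is followed: log2 transformation (exactly once, in
`preprocess`), quantile normalization (each array mapped rank-for-rank
onto the across-array mean of order statistics; ties receive the mean
of the tied order-statistic means, which makes the map deterministic
and idempotent), and, for probe-level data, Tukey median-polish
summarization (column effects after ≤ 10 sweeps or max |median| <
1e-6). Detection calls are deliberately simple log2-signal thresholds
(A below 6.0, M in [6.0, 7.0), P above, defaults chosen to sit between
the generator's dropout and expressed abundance modes): the
Wilcoxon-based MAS5 call and the RMA convolution background are array
black boxes, not the subject of this package, and the downstream
statistics only need a P/M/A partition.

## DTG calling

The moderated t follows the standard empirical-Bayes variance
moderation for gene-wise two-sample tests: per-gene pooled variance
s²_g with d_g = n₁+n₂−2 df is shrunk to
s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g), and t = Δ/(s̃·√(1/n₁+1/n₂)) is
referred to a t distribution with d₀+d_g df. The prior (d₀, s₀²) is
moment-matched on log s²_g with a Newton inversion of the trigamma
function; when the observed log-variances are under-dispersed relative
to trigamma(d_g/2) — which happens by construction on synthetic data
with homogeneous noise — the fit falls back to d₀ = ∞ (all genes share
s₀²) with a logged warning. The implementation reproduces R limma's
`eBayes` to machine precision on heterogeneous-variance fixtures (kept
as a test). Noiseless data (s̃ = 0) take a degenerate path: any
non-zero Δ gets t = ±inf, p = 0; Δ = 0 gets p = 1.

Four prefiltered universes are tested independently ("All", "P/M" = P
or M in ≥ 50% of arrays, "Stable" = panel SD ≤ its nearest-rank 0.80
quantile with ties included, "Stable and P/M" = stable and devoid of
any Absent call), each with its own prior fit and its own BH
adjustment (m differs per set); the reported t/p/FDR columns are those
of "All". The union's realized FDR is slightly above the nominal
per-set level — reported, not corrected. A DTG needs |Δlog2 TL| ≥ 1.0
(twofold) and FDR < 0.05 in ≥ 1 set.

The ad hoc route takes per-replicate TL fold changes — mutant
replicate i paired with wild-type replicate i when counts match
(samples processed in parallel), otherwise each mutant replicate
against the wild-type mean — and flags (i) |FC| ≥ 1.0 in every
replicate with a common sign (the "same direction" reading of
all-replicate twofold is an interpretation, documented here), (ii)
CV = SD/|mean| < 0.5 (undefined at mean 0, hence false), (iii)
SD < 0.5; a gene is DTG(ad hoc) when any flag holds and
|mean FC| ≥ 0.59 (1.5-fold). Note a structural property worth knowing:
with fraction-level noise σ, paired replicate FCs have SD 2σ, so at
σ = 0.3 the expected sample SD (~0.53) sits just above the 0.5 cut of
criterion (iii) — on such data the ad hoc route recovers roughly 80%
of the FDR route's calls, not nearly all of them, whereas on low-noise
arrays (replicate SDs mostly < 0.5) it captures nearly everything.

## Stability classification

Panel SDs (ddof = 1) of replicate log2 TL are thresholded at the
nearest-rank (1 − top_fraction) quantile; genes strictly above are
"variable" (ties land stable), so exactly the top 20% by SD is flagged
up to ties. Genes need ≥ 3 non-missing replicates, otherwise they are
uncomputable and neither flag is set. The identical code path on TC
panels classifies transcript-level variability. Under the generator's
noise model the threshold is σ_TL·√(χ²₀.₈(n−1)/(n−1)), which the tests
verify by Monte Carlo.

## Clustering

Fuzzy c-means replaces the pairwise-dissimilarity fanny formulation:
same membership exponent (m = 1.1) and Euclidean distance, objective
Σ u^m‖x−c‖², alternating closed-form updates, k-means++ seeding from
the caller's seed, stop at objective decrease < 1e-9 or 5000
iterations. At m = 1.1 memberships are nearly crisp and the hard
assignment coincides with Lloyd's k-means on separable data (asserted
against scikit-learn's KMeans). Points coinciding with one or more
centers split membership equally among the zero-distance centers.
Genes are canonically sorted before seeding so results are invariant
to input row order. k defaults to 6 and is a judgement call; a
silhouette helper (`choose_k`) is provided. Empty hard clusters are
permitted and appear in median tables as missing rows with count 0.

## Sequence features

The uORF scanner opens a candidate at every ATG strictly upstream of
the main CDS start and walks in-frame to the first stop anywhere in
the transcript; candidates with no stop are discarded; uORFs running
past the main start are counted but flagged `overlaps_main_orf`.
Minimum length is 1 coding codon; CUG starts are not considered. Bin
association uses 0.2-wide Δlog2 TL bins with a (−0.2, 0.2) no-change
reference bin and open-ended extremes (edges config-exposed); each
bin × class 2×2 table against the reference uses Yates-corrected χ²
when all expected counts are ≥ 5 (the standard convention) and
Fisher's exact test otherwise, with `*`/`**` tiers at 0.05 and 1e-4.
The long/short main-ORF split is 1,086 nt. The bin-vs-reference
Student-t table is implemented generically (`bin_ttest_table`) because
the length analysis is meaningful in both orientations — mean Δlog2 TL
per length bin (the `length_bin_analysis` default, deciles of the
length distribution, reference = the bin holding the median) or mean
length per Δ bin; the pipeline emits the former. "Ranked sign test" is
read as the Wilcoxon signed-rank test (exact for n ≤ 25 without ties,
normal approximation with continuity correction above), and a plain
binomial sign test is reported alongside since the phrase is
ambiguous.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) with fold enrichment
(k/n)/(K/N) and BH adjustment across tested categories. The category
map is taken as given (ancestor propagation is a data-preparation
concern); the adjustment method is a documented package choice.

## The synthetic generator

The generator emulates the *structure* of a seedling polysome
microarray study: PL/NP/TC triplets per genotype × replicate,
~20,000 genes, 2–12 replicates, a planted coregulated regulon
(default 200 genes at Δlog2 TL = +1.5 in the first mutant, annotated
"ribosome", grouped into 2–4-member paralog families), uORF-bearing
genes (default 25% of genes, 1–3 uORFs) repressed by −1.0 log2 units
in the first mutant, a CDS-length-dependent shift
`slope·(cds − median cds)/1000` confined to the second mutant (default
slope +0.3 log2/kb so that short-CDS genes are translationally
inhibited there), additive Gaussian log2 noise applied independently
to PL and NP (so replicate log2 TL has SD σ√2; the array noise
magnitude is not pinned down by real-data constraints — σ = 0.3 is a
free default, at which a 12-replicate panel's 80th-percentile SD
threshold lands near 0.49), TC generated independently of TL, and a
dropout fraction (default 15%) of genes near the detection floor that
become Absent-prone. Baselines: log2 TL ~ N(1.0, 0.8) (most mRNAs
majority-polysomal), log2 abundance ~ N(9.0, 1.5) vs a dropout mode at
N(4.5, 0.8) against thresholds 6/7. All sampling derives from one
seeded generator; identical configs and seeds are bit-identical.

What it does *not* emulate — and hence what passing tests do not show
about real data: probe-level effects beyond the optional
median-polish exercise mode, gene-specific variance heterogeneity
(variances are homogeneous, so the empirical-Bayes prior legitimately
collapses to d₀ = ∞), correlated replicates or batch structure,
intensity-dependent (heteroskedastic) array noise, global polysome
shifts, 3'-bias, or cross-hybridization. Transcript sequences are
synthetic scaffolds (C/T-filler leaders with planted uORFs, stop-free
safe-codon main ORFs), built so uORF counts round-trip exactly; they
are not meant to look like genomic sequence.

## Problem sizes

Tests and the acceptance script run on scaled-down instances chosen to
exercise every code path while keeping the suite quick: 250–5,000-gene
datasets for recovery and calibration (20 seeds for the recovery
study), 20,000 genes × 12 replicates for the stability acceptance
check, 1,000 transcripts for the uORF round-trip, and an 800-gene
three-genotype experiment for the end-to-end determinism check.

## Known limitations

Per-set FDR control does not control the union's FDR exactly; the
detection calls are threshold stand-ins; the fanny objective is
approximated by c-means (near-identical partitions at m = 1.1, but not
the same objective); the moderated test assumes exchangeable
within-group variances and two groups (no array weights, duplicate
correlation, or multi-factor contrasts).
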