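# Methods

This note records the models, parameter choices and numerical decisions
behind `bgregulome`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and file handling

All internal coordinates are 0-based half-open, matching BED/narrowPeak
semantics; VCF positions are converted at the I/O boundary. Malformed
records in peak and variant files are skipped and counted rather than
fatal — real peak calls contain oddities, and the counts surface in the
log — while structural corruption (wrong column counts, non-numeric
scores) raises immediately. Every report table carries a commented
`# key=value` header with the resolved configuration hash and seed, so a
run can be reproduced from its own output.

## Consensus peaks

Replicate peak sets sharing a dataset id are merged at peak level: any
pair of peaks with at least 1 bp of overlap is coalesced into the spanning
interval and given the maximum member score. Book-touching intervals do
not merge. This is a deterministic peak-level analogue of merging
replicate alignments before peak calling; it cannot recover peaks that
fall below the calling threshold in every replicate.

The reference dataset is the one with the most peaks (ties broken by
lexicographically smallest id so the choice is total and
order-independent). Consensus sites keep the *reference* peak's interval,
and the overlap count k is 1 plus the number of non-reference datasets
with at least 1 bp of intersection — the BEDtools-intersect default, since
no minimum overlap fraction is imposed. Counting at thresholds k ≥ 2,
k ≥ 3, k = K therefore yields nested site sets.

Gene assignment deliberately uses a fully specified three-step rule —
gene-body overlap, then a strand-aware upstream promoter window (default
2000 bp, configurable), then nearest TSS — instead of replicating any
annotation tool's internal priority scheme. Ties within a step resolve to
the gene earliest in coordinate order. Candidate filtering keeps sites in
blood-group genes and removes erythroid transcription-factor genes
(KLF1/GATA1-type entries flagged in the annotation); the excluded-TF check
runs first so such genes are reported under that reason. Ranking is the
total order (k desc, reference peak score desc, best motif relative score
desc, contig, start).

## Motif model

The position weight matrix is built from a count matrix as
`w[j][b] = log2(((c[j][b] + q·bg[b]) / (N_j + q)) / bg[b])` with the
pseudocount q shared across bases proportionally to the background.
Defaults: q = 0.8 and a uniform background, the common TFBS/Biopython
convention; both are exposed in the configuration because relative scores
at the third decimal place depend on them. Log base 2 reports scores in
bits; any base gives identical relative scores. With q = 0 a zero count
produces a −inf weight, which is allowed (consensus scores stay finite)
but leaves relative scores and p-values undefined; a zero column total
with q = 0 is an error.

Scanning evaluates every window on both strands; a reverse-strand hit is
reported at its forward-strand interval with strand "−", and its `window`
field holds the sequence actually scored (the reverse complement of the
genomic slice). Windows containing N are skipped and counted. The default
report threshold is relative score ≥ 0.8, the JASPAR web default. Note
the known property of relative scores that random sequence frequently
exceeds 0.8 for short, core-dominated matrices — which is why hits carry
an exact p-value as well.

P-values use the standard dynamic-programming convolution of per-column
score distributions under the background. The user-facing granularity
(default 10⁻³ of the score range) is internally subdivided by the motif
length so that accumulated per-column rounding stays within half a
granularity step; the reported tail probability therefore brackets the
exhaustive enumeration answer within one step, which the tests verify
exhaustively for L ≤ 6.

## Variant impact

A variant pairs with a hit when its position lies in the half-open motif
interval. Substitution is strand-aware (ref/alt complemented for "−"
hits) and guarded: if the window base does not match the expected
reference base the operation fails loudly, because a mismatch almost
always means an assembly or coordinate slip. Δ = rel_wt − rel_mut is
antisymmetric under the reverse substitution, and `rel_wt` is taken from
the stored hit so there is no recomputation drift. The "core" flag marks
variants in the matrix's four highest-information columns — defined from
the matrix itself rather than a hard-coded WGATAR string, keeping the
module matrix-agnostic. Only SNVs are scored.

The frequency triage uses Hardy–Weinberg AF² for the expected homozygote
frequency, with no inbreeding correction. A variant is a "candidate fit"
for a recessive phenotype when AF² is within a factor of 10 of the stated
prevalence (order-of-magnitude agreement, the resolution this informal
argument supports), and "too rare" below an AF floor of 10⁻³.

## Haplotypes and linkage disequilibrium

Unphased two-locus genotypes are coded as minor-allele doses 0/1/2. Every
sample with at least one homozygous locus resolves uniquely into two
haplotypes. Double heterozygotes are phase-ambiguous; the default
counting rule assigns all of them to the more common configuration —
AB/ab versus Ab/aB, judged by the product of frequencies estimated from
the unambiguous samples, with ties resolving to AB/ab (cis-common,
logged). The EM alternative runs the standard two-locus algorithm
(posterior phase split, tolerance 10⁻⁸ on the frequencies, at most 1000
iterations), initialized from the counting-rule estimate so that EM's
monotone ascent guarantees it never ends below that rule. Tables without
double heterozygotes reduce to direct gamete counting and are reported as
mode "direct".

LD follows the LDpair conventions: D = p_AB − p_A·p_B, D_max is
min(p_A·p_b, p_a·p_B) for D > 0 and min(p_A·p_B, p_a·p_b) for D < 0, and
D′ = |D|/D_max is reported non-negative (the sign is recoverable from D).
r² = D²/(p_A p_a p_B p_b), so r² ≤ D′² always. Numerical choices: |D| <
10⁻¹² snaps to exact independence (D′ = 0, r² = 0 unless a haplotype is
absent, in which case D′ = 1 by convention); when a haplotype frequency
is exactly zero and D ≠ 0 the table sits on the edge of the feasible
region where |D| = D_max identically, and D′ is returned as exactly 1.0
rather than through the division. Monomorphic loci raise an explicit
error instead of returning undefined statistics.

## Expression association

Geometric MFI is exp(mean(log values)); non-positive values are the
caller's problem to filter, by design. ΔΔCt is
(mean target Ct − mean reference Ct) − calibrator ΔCt with complete
triplicates required. The sign convention is fixed as target − reference,
so *higher* ΔΔCt means *lower* expression; no claim is made about any
particular plot's axis orientation. ANOVA is the classic equal-variance
one-way analysis (not Welch), with all pairwise pooled-t comparisons
Bonferroni-adjusted by the number of pairs and capped at 1; the degenerate
all-identical case returns F = 0, p = 1 rather than NaN. OLS fits
y = β₀ + β₁·dose₁ + β₂·dose₂ with t-based 95% CIs on n − 3 df and no
multiplicity adjustment. A rank-deficient design — dose₁ ≡ dose₂, the
complete-LD situation — raises a collinearity error instructing
single-locus analysis, which the CLI then performs. The luciferase ratio
test averages per-well firefly/Renilla ratios within each experiment,
scales to the baseline construct's grand mean, and compares per-experiment
means with a two-sided paired t-test; an all-zero difference vector
reports p = 1 with a degenerate flag instead of erroring. Ratios are not
invariant to rescaling Renilla alone — that is a property of the assay's
normalization, and is documented rather than hidden.

## Synthetic data: what it emulates, and what it does not

The bundled count matrix (`GATA1SYN.1`) is a synthetic GATA-type matrix —
consensus AAGATAAA with a strong 4-column GATA core and informative
flanks — constructed for simulation; it is not a JASPAR database profile.

The default manifest is a structural replica of a four-dataset study
design: two candidate motifs planted 710 bp apart inside a 25-kb
"CR1-like" blood-group gene, one decoy motif inside an excluded-TF gene
and one inside a non-blood-group gene (so both filter paths are
exercised), a core-disrupting SNV at MAF 0.157 plus a rare one at
1.31 × 10⁻⁵, and an n = 396 cohort. The genome is i.i.d. background at GC
0.41 on a single 60-kb contig; after planting, any non-planted window
scanning above relative score 0.90 is disrupted, so the planted sites are
the only strong matches and the truth table is unambiguous. Peaks are
centered on their motifs with Normal(0, 20 bp) end jitter constrained to
keep the motif covered; the first dataset never drops a true site (so the
reference exists for every site and the k = K recovery fraction is
(1 − miss)^(K−1) analytically), receives extra false peaks so it is
always the reference, and false peaks are constructed never to overlap a
planted motif. The default miss rate is 0: the default bundle represents
the clean four-dataset condition, and the miss rate is a manifest
parameter for sensitivity tests.

The cohort draws two haplotypes per sample i.i.d. from frequencies
(0.833, 0.010, 0.004, 0.153) — locus-1 MAF 0.157, with ≈2.8% of samples
expected to carry genotypes separating the two loci. Geometric MFI is
lognormal around exp(log 1000 − 0.5·dose₁) with σ = 0.3 on the log scale
(flow-cytometry-like multiplicative noise); ΔΔCt is 1.0·dose₁ +
Normal(0, 0.3) cycles, and Ct triplicates are constructed symmetrically
around their means so the standard normalization recovers the sampled
ΔΔCt exactly. dose₂ has no direct effect: any association it shows arises
only through linkage. Randomness is a seeded PCG64 generator with spawned
child streams per component, so bundles are byte-identical given a seed,
across platforms.

What passing tests therefore show: the pipeline's operations are correct
against independent oracles, and under the stated study shape the
pipeline recovers planted truth (sites at k = K, the disrupting SNV first
by Δ, ~95% CI coverage for the planted log-scale effect, uniform null
p-values). What they do not show: performance on real ChIP-seq noise
(non-Gaussian peak jitter, correlated false peaks, blacklist artifacts),
LD decay along real chromosomes, population structure, or the exact
relative-score values a specific database matrix yields on a specific
genome build — those depend on external data and tool versions and are
documented reproduction goals, not unit tests.

## Problem sizes used by the test suite

Oracle equivalence tests run on random instances up to 10³ intervals (200
instances), 10⁴ simplex draws for the LD closed forms, full 4^L
enumeration for motif lengths ≤ 6, and 500 simulated cohorts of n = 396
for the coverage/uniformity checks. These sizes make the suite complete
in well under a minute of numerical work while keeping every estimate's
Monte-Carlo error far below the asserted tolerances.
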