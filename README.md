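# bgregulome

Tools for mining the transcription-factor "regulome" of blood-group genes
from ChIP-seq peak data, and for the cohort genetics that connects a
regulatory variant to expression on the red-cell surface.

The package addresses a concrete scientific workflow: erythroid
transcription factors such as GATA1 bind short WGATAR motifs in and around
blood-group genes, and single-nucleotide variants (SNVs) that disrupt these
motifs can silence antigen expression (the textbook case is the
Duffy-negative GATA-box variant; a recent one is the low-CR1 Helgeson
phenotype). Finding such variants requires (i) consensus binding sites
supported by several independent ChIP-seq experiments, (ii) motif-level
scoring of how badly an SNV damages the binding site, and (iii) cohort
evidence that genotype dose predicts expression. `bgregulome` implements
all three stages as a tested library with a thin CLI, exercisable entirely
on synthetic data with recorded ground truth.

## What it computes

**Consensus peaks.** Replicate peak sets are coalesced (≥1 bp overlap,
maximum member score), the dataset with the most peaks becomes the
reference, and each reference peak becomes a consensus site with an overlap
count *k* = 1 + the number of other datasets intersecting it. Sites are
annotated to genes (body → upstream promoter window → nearest TSS),
restricted to blood-group genes, with transcription-factor genes such as
*KLF1*/*GATA1* excluded, and ranked by (*k*, peak score, best motif score).

**Motif scoring.** A JASPAR-format count matrix is turned into a log₂-odds
position weight matrix with background-proportional pseudocounts,

    w_jb = log2( (c_jb + q·bg_b) / (N_j + q) / bg_b ),

windows are scored on both strands, and reported as the JASPAR *relative
score* (s − s_min)/(s_max − s_min) ∈ [0, 1] plus a FIMO-style exact p-value
P(S ≥ s) obtained by dynamic-programming convolution of the discretized
per-column score distributions. A variant's impact is
Δ = rel(wild type) − rel(mutant), with a flag when it lands in the motif's
highest-information (core) columns, and a Hardy–Weinberg triage comparing
the expected homozygote frequency AF² against a phenotype prevalence.

**Cohort genetics.** Two-locus haplotype frequencies from unphased 0/1/2
genotype doses (double heterozygotes resolved to the most common
configuration, or by the standard EM algorithm), linkage disequilibrium
D = p_AB − p_A·p_B, D′ = |D|/D_max and r² = D²/(p_A p_a p_B p_b),
geometric mean fluorescence intensity, ΔΔCt from qPCR triplicates, one-way
ANOVA with Bonferroni post-hoc comparisons, OLS regression of expression on
the two dose covariates, and firefly/Renilla luciferase ratio testing.

**Synthetic data.** `simulate` writes a complete input bundle — genome with
planted motifs (two of them 710 bp apart inside a "CR1-like" gene, plus
decoys that must be filtered out), four jittered peak sets, a VCF with a
core-disrupting SNV at minor allele frequency 0.157 and a very rare one at
1.31 × 10⁻⁵, and an n = 396 cohort with a dose-dependent expression effect
— together with a JSON manifest of the planted truth.

## Worked example

```sh
bgregulome simulate --seed 7 -o bundle
bgregulome mine \
    --peaks d1=bundle/peaks_d1.narrowPeak --peaks d2=bundle/peaks_d2.narrowPeak \
    --peaks d3=bundle/peaks_d3.narrowPeak --peaks d4=bundle/peaks_d4.narrowPeak \
    --genome bundle/genome.fa --genes bundle/genes.bed \
    --pwm bundle/motif.jaspar --vcf bundle/variants.vcf --out candidates.tsv
bgregulome ld    --table bundle/cohort.tsv --out ld.tsv
bgregulome assoc --table bundle/cohort.tsv --out assoc.tsv
```

The top of `candidates.tsv` shows both planted motifs recovered at the
maximal overlap count, ahead of the lower-scoring noise sites:

```
contig  start   end     overlap_count  datasets      reference_score  gene  category  ...  best_relative_score
chrS    30563   31021   4              d1,d2,d3,d4   948.613          CR1L  body      ...  1.0
chrS    29871   30215   4              d1,d2,d3,d4   653.416          CR1L  body      ...  1.0
```

`candidates.tsv.impacts.tsv` ranks the planted core-disrupting SNV first by
Δ relative score; its AF² ≈ 0.0246 makes it a plausible match for a ~1%
recessive phenotype, while the second variant is far too rare to explain it:

```
variant_id  strand  rel_wt  rel_mut  delta   core_disrupted  allele_frequency  homozygote_frequency  fit_flag
simsnv_m2   -       1.0     0.847    0.153   True            0.157             0.0246                candidate_fit
simsnv_m1   +       1.0     0.951    0.049   False           1.31e-05          1.72e-10              too_rare
```

`ld.tsv` estimates the cohort's haplotype structure: with 106 double
heterozygotes resolved by the counting rule, the two loci are in strong but
incomplete linkage (D′ = 0.990, r² = 0.936), and 7/396 samples carry
genotypes that separate the loci:

```
n_samples  n_double_het  estimation_mode  p_AB    p_Ab    p_aB    p_ab    D      D_prime  r_squared  n_separable
396        106           counting-rule    0.8346  0.0076  0.0013  0.1566  0.131  0.9904   0.9362     7
```

`assoc.tsv` shows the dose effect lands on locus 1, not locus 2: the OLS
coefficient for `dose_locus1` on geometric MFI is −555 (p = 1.8 × 10⁻⁶)
while `dose_locus2` is not significant (p = 0.26); on ΔΔCt the locus-1
coefficient is +1.02 cycles per dose (p = 1.7 × 10⁻¹⁹) — lower expression
means more amplification cycles.

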