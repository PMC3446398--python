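# Methods

This note documents the models, estimators and numerical choices behind
`daehap`, what the synthetic-data generators do and do not emulate, and the
known limitations of the analysis.

## Differential allelic expression

The assay measures the allele-A/allele-B peak ratio at a transcribed
heterozygous marker SNP in replicate, in both cDNA and genomic DNA. Since
the two alleles are present 1:1 in genomic DNA, the gDNA ratio captures
assay bias, and the normalized estimate is the difference of mean log2
ratios:

    norm_log2_ratio = mean(log2 cDNA ratios) − mean(log2 gDNA ratios)

Replicates are combined as the mean of log-ratios (never the log of the
mean ratio) so the two alleles are treated symmetrically: inverting every
ratio exactly negates the estimate. The standard error is the Welch
combination of the two replicate variances, zero when each assay has a
single replicate. Ratios are always allele-A/allele-B in the order given by
the input record; alleles are never re-sorted.

A sample is called DAE when `|norm_log2_ratio|` **strictly** exceeds
`log2(threshold_fold)` with `threshold_fold = 1.2` (log2 ≈ 0.263) by
default. The strict boundary is a reproducibility choice: exact equality is
measure-zero in real data, and a strict rule makes the boundary case
unambiguous. An optional mode additionally requires a per-sample one-sample
t-test of the replicate log-ratios against zero at α = 0.05; it is off by
default because the fold threshold is the primary published rule, while the
exact per-sample significance procedure used historically is not fully
specified — both modes are exposed rather than guessing one.

## Haplotypes and diplotypes

Five built-in haplotype patterns span seven tag SNPs (rs1799943,
rs11571579, rs9534174, rs206070, rs144848, rs4942440, rs9567576); hap2 and
hap5 are the low-expression class, hap1/hap3/hap4 the high-expression
class. Patterns are loaded from a TSV pattern file, so other haplotype
systems can be analyzed; the full 7-allele vector defines each pattern.

For DAE samples the marker SNP rs144848 is heterozygous G/T, and the G
allele occurs only on hap1, so such samples necessarily carry hap1. The
second haplotype is resolved by subtracting the anchored pattern's allele
from each unphased genotype and matching the residual vector against the
pattern table. A residual that matches no pattern raises an
unresolvable-haplotype error (callers exclude the sample with a logged
warning — exclusion, not imputation); a residual matching several patterns
(possible on reduced SNP subsets) raises an ambiguity error listing the
candidates. Diplotype groups count low-expression haplotypes: 0 → HH,
1 → HL, 2 → LL.

Pairwise LD uses the standard definitions `D = p_AB − p_A p_B`,
`D′ = |D|/D_max` with the sign-dependent `D_max`, and
`r² = D²/(p_A p_a p_B p_b)`. A monomorphic locus yields an undefined flag
with NaN statistics rather than an exception.

General unphased cohorts are phased with a standard EM over diplotype
compatibility classes: the haplotype space is the union of resolutions
compatible with at least one sample, initial frequencies are uniform (which
also serves as the deterministic tie-break between symmetric modes), the
observed-data log-likelihood is monotone non-decreasing, and iteration
stops when the largest frequency change falls below 1e-8 or after 500
iterations. With phase-unambiguous data (≤ 1 heterozygous site per sample)
the first M-step equals direct counting.

## Association tests

* **Sign test**: exact binomial tail at p = 1/2; one-sided `P(X ≥ k)`, the
  default direction being "carriers show DAE more often" (the published
  unanimous-carrier p-value equals a one-sided five-trial tail); two-sided
  is `min(1, 2·min(tails))`. Both sides are reported.
* **Carriage × DAE proportions**: Pearson chi-square without continuity
  correction by default (correction switchable); zero margins yield an
  undefined-statistic flag. No multiplicity correction across haplotypes by
  default; a Bonferroni switch exists and is logged in the report.
* **DAE magnitude by group**: Wilcoxon rank-sum, exact null distribution
  for combined n ≤ 20 without ties, otherwise the normal approximation with
  tie correction; two-sided.

## Downstream expression

qPCR Ct data are normalized by ΔΔCt: `ΔCt = Ct_gene − mean(Ct_hk1,
Ct_hk2)` per sample, `ΔΔCt = ΔCt − mean ΔCt(reference group)`, relative
expression `2^(−ΔΔCt)`. Because the housekeeping mean is subtracted per
sample, any per-sample plate offset cancels exactly. The housekeeping pair
is chosen as the candidate pair with the most stable per-sample Ct
difference, minimizing `Σ_i |ΔCt_i − median ΔCt|`; ties break
lexicographically. Array log-intensities are assumed pre-normalized
(probe-level preprocessing is out of scope) and pass through unchanged.

Genotype associations use one-way ANOVA with genotype as a three-level
factor (an additive-trend linear fit is reported as a secondary output);
group contrasts use a two-sided t-test, Welch (unequal-variance) by default
with a pooled-variance option for exact emulation of the classical Student
form — the published analyses do not state which variant was used. Groups
absent from a cohort (e.g. no LL individuals in a blood panel) are skipped
with a log message, not imputed.

## TFBS screening

Matrices are nucleotide frequency tables regularized with a pseudocount of
0.01 per row (spread evenly over the four bases) before normalization, so
zero counts never produce log 0 and scores are invariant to scaling all
counts by a constant. Per-position information content is

    I(i) = Σ_b f(i,b) · ln(4 f(i,b))

(0 for a uniform row, → ln 4 for a degenerate one). For a placement of the
matrix on a window,

    Current = Σ_i I(i) · f(i, base_i)
    mss     = (Current − Min) / (Max − Min)

where Min and Max substitute the per-position worst and best base. The core
similarity score is the identical quantity restricted to the core block —
the five consecutive positions maximizing ΣI(i), leftmost on ties. Both
strands are always scanned; ties between placements break toward the
smaller offset, then the forward strand. A non-ACGT base contributes the
Min value for its position (flagged in the log). A matrix with Max = Min is
uninformative and scores 1 everywhere by convention.

Candidate *cis*-regulatory SNPs pass four criteria in order: (1) the SNP
lies inside an annotated regulatory element (BED, 0-based half-open, SNP
coordinates 1-based; the conversion is centralized and tested); (2) some
matrix exceeds both similarity cutoffs (default 0.9/0.9, the flat published
cutoffs — profile-specific cutoff tables of the original scanning software
are proprietary and not emulated); (3) a passing match overlaps the SNP
position; (4) the alleles differ, either in pass/fail status
(presence/absence) or in mss by more than a configurable δ (default 0,
meaning any difference). The report records the first criterion that
eliminated each SNP; SNPs failing criterion 1 are never scored.

The "40 bp of surrounding sequence" windowing is ambiguous between total
width and per-side flank; windows here are 41 bp (20 bp flanking each side
of the SNP) and the width is configurable.

## Carrier risk models

The Cox proportional-hazards partial likelihood is maximized by
Newton–Raphson from β = 0, with step halving if a step would decrease the
likelihood; convergence requires the score max-norm below 1e-8 within 50
iterations, and the final gradient is below 1e-6 by contract. Ties are
handled by Breslow's approximation by default (Efron optional — the two
agree to numerical noise on continuous times and the Efron path matches
lifelines exactly on heavily tied data). Baseline hazards can be stratified
by study; left-truncated (age-interval) records with an entry-age column
are handled through explicit risk-set construction. Monotone likelihoods
and non-convergence are flagged on the estimate rather than raised.

Models: per-allele (one log-HR per minor-allele copy), genotype 2-df
(heterozygote and rare-homozygote HRs plus a 2-df likelihood-ratio test),
and a haplotype model in which posterior-expected haplotype dosages
(summing to 2 per carrier) enter additively with the reference haplotype(s)
excluded, giving per-copy HRs versus the reference. Between-study
heterogeneity is a likelihood-ratio test of study-specific versus shared
log-HRs, both study-stratified; studies without events or genotype
variation contribute no degree of freedom and are logged.

The count-based Cochran–Armitage trend test (scores 0/1/2, permutation
variance, Z signed positive for minor-allele excess among affected) is a
companion statistic to the model-based trend p-value; on a genotype count
table alone it is the only trend test computable, and it does not reproduce
a model-based p-value that used individual follow-up times.

**Deliberate simplification**: the published single-SNP analysis used a
retrospective likelihood with pedigree adjustment to correct for the
non-random ascertainment of mutation carriers. That machinery is not
reimplemented here; all models are standard cohort analyses, do not adjust
for ascertainment or familial relationships, and every risk report carries
that label. The published haplotype analysis itself used a standard cohort
model with the same caveat.

## Synthetic data

The generators emulate the statistical structure of the study:

* **Diplotypes** — haplotype pairs drawn i.i.d. from the five-haplotype
  pool at its population frequencies (27.5 / 24.2 / 18.8 / 11.7 / 5.0 %,
  renormalized over the 87.2% the five haplotypes jointly cover), i.e.
  random mating / haplotype-level Hardy–Weinberg with no population
  structure.
* **Allelic measurements** — the true cDNA ratio for a marker heterozygote
  is the ratio of its two haplotypes' transcription levels (defaults: 1.0
  for high-, 0.7 for low-expression haplotypes, so one low haplotype gives
  1/0.7 ≈ 1.43); the true gDNA ratio is 1. Each replicate multiplies the
  truth by log-normal noise, median-unbiased on the log scale, with a
  default coefficient of variation of 10% — the assay's true CV is not
  published; 10% is a realistic sequencing peak-ratio precision and it is
  configurable. Three replicates per assay by default, matching triplicate
  plating. Marker-homozygous samples yield no record.
* **Expression** — per gene, log2 expression = effect × (number of
  low-expression haplotypes) + Normal(0, SD); housekeeping genes have
  effect 0 by construction. Default target effects mirror the magnitudes
  reported downstream of the haplotypes (a 1.74-fold drop for SPP1 per low
  haplotype, +0.125 for MUC16); housekeeping noise SDs (0.05, 0.05, 0.5,
  0.5) span stable and unstable normalizers so pair selection is
  exercised. Ct mode inverts the sign around a base Ct of 24 (higher
  expression → lower Ct).
* **Carriers** — 2,754 carriers across 11 studies by default (the genotyped
  cohort size), Hardy–Weinberg genotypes at minor-allele frequency 0.16
  (the frequency implied by the published genotype table), exponential
  event times with hazard λ₀·exp(β·g), β = ln 0.85 by default, independent
  exponential censoring with scale 70 years chosen so roughly 59% of
  carriers are affected, matching the published case fraction; study labels
  round-robin. A haplotype-cohort variant draws haplotype pairs and plants
  per-copy log-HRs, yielding integer dosages (the degenerate-posterior
  case).

All randomness flows from one master seed through per-generator substreams
(numpy `SeedSequence.spawn`), so each generator is individually
reproducible and consuming one stream never perturbs another.

What the generators do **not** emulate: pedigree/kinship structure and
ascertainment of carrier families, age-cohort-specific incidence (event
times are exponential), microarray probe-level noise, mutation phase, and
population structure. Passing tests therefore demonstrate correctness of
the estimators under the assumed sampling model, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

* Thresholds: DAE fold threshold must exceed 1; similarity cutoffs lie in
  [0, 1]; frequency maps must sum to 1 within 1e-9.
* EM: uniform initialization, tolerance 1e-8 on frequencies, cap 500
  iterations; degenerate inputs return point masses.
* Cox: Newton–Raphson from 0, score tolerance 1e-8, 50 iterations, step
  halving, |β| > 50 flagged as monotone likelihood.
* Chi-square tables with a zero margin, ANOVA with one genotype class and
  LD at a monomorphic locus return flagged "undefined" results instead of
  raising, because they occur routinely in small stratified data.
* Writers are atomic (write-to-temp, rename), so failed runs leave no
  partial output.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses cohorts of 20,000 carriers for hazard-ratio
recovery (3 SE on the log-HR ≈ 0.09 at that size), 400 samples for
expression recovery, 500 replicates for test calibration, and the built-in
26-SNP planted screen. These sizes give comfortably tight Monte-Carlo error
for every reported quantity while keeping the script's runtime in the tens
of seconds.

## Known limitations

* No retrospective-likelihood/kinship adjustment (see above); absolute
  hazard-ratio estimates on ascertained family data would be biased.
* The haplotype pattern table assumes the tag-SNP panel fully distinguishes
  the common haplotypes; rarer haplotypes outside the table are excluded,
  not modelled.
* The TFBS screen ships only toy matrices; real screens require a licensed
  matrix library supplied by the user in TRANSFAC flat-file format.
* VCF support is deliberately minimal (biallelic sites, unphased GT).
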