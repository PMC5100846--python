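# Methods

This note documents the statistical procedures `decaykit` implements, the
conventions it fixes where the underlying methods admit more than one
reading, and what the synthetic-data tests do and do not establish.

## Sequence features

Coding sequences are validated on ingest: length a positive multiple of 3,
alphabet {A,C,G,T} only (ambiguity codes are rejected into a reasons
report rather than dropped silently), uppercased.

**GC by codon position.** GC1/GC2/GC3 are the proportions of G/C at each
codon position. The terminal stop codon is excluded by default: GC3 is of
interest as the wobble position read during elongation, which stop codons
do not undergo. A flag includes it for comparison with conventions that
count the full CDS.

**CAI.** Relative adaptiveness is w(c) = (count(c) + pc) / max over the
synonymous family, with pseudo-count pc = 0.5 by default so unobserved
codons keep w > 0 (and CAI > 0). CAI is the geometric mean of w over
codons, excluding stop codons and the single-codon amino acids Met (ATG)
and Trp (TGG), which carry no usage information — the standard Sharp & Li
convention. The mean is accumulated in log space, so sequences of 10⁴
codons do not underflow; tests check agreement with a brute-force
log-space oracle to 10⁻¹².

**nTE.** Per-codon normalized translational efficiency weights (supply
versus demand of the decoding tRNA) are aggregated to a per-transcript
score by the arithmetic mean over sense codons. The aggregation rule is a
convention, not part of the score's definition, so a geometric-mean option
is exposed; the arithmetic mean is the default because nTE weights are
already ratios on a bounded scale and zero weights should not annihilate
the score.

**Poly-proline.** A transcript is poly-proline positive when it contains
≥ 4 consecutive proline codons (CCN), the run length at which elongation
stalling becomes pronounced. The threshold is a parameter (`min_run`).

## Rate kinetics

k = ln 2 / t½ converts half-lives to first-order rate constants.
Metabolic-labeling experiments observe k_obs = k_deg + ln 2 / T_doubling
(loss per cell includes dilution by growth); `correct_for_dilution`
subtracts the dilution term, and corrected rates ≤ 0 — observed loss no
faster than dilution — are set to missing with a logged count rather than
raised, so genome-wide table assembly is robust to a handful of
non-physical rows. The doubling time is a required user input; it is a
property of the culture, not of the data files. Copy numbers per cell are
TPM/10⁶ × 60,000 (the assumed total mRNA pool of an exponentially growing
yeast cell); synthesis rates come from the steady-state balance
synthesis = copies × k_deg.

## Predictor table

Most genome-wide predictors are roughly log-normal and are transformed
log₁₀(x) or log₁₀(x + 1); proportions (GC by position), nTE and ΔG
(negative-valued) stay untransformed. Transforms are applied at assembly,
on original units; out-of-domain values become missing with a logged
count. The response — the rate constant — is never transformed (it is
approximately normal already). Sources are outer-joined over the response
genes; rows are never dropped at assembly, and per-column coverage is
logged (genome-wide sources cover different gene sets). Complete-case
handling happens per fitted model.

**Outlier filter.** Extreme rates are removed by Tukey fences
[Q1 − f·IQR, Q3 + f·IQR] with f = 1.5 and type-7 (linear interpolation)
quartiles, fixed for cross-platform determinism. The filter is two-sided
by default; a one-sided-upper option exists because rate constants are
bounded below and some analyses drop only fast-decay outliers. The filter
is defined as a single pass — it is not iterated to a fixed point. On
normal data the fences exclude ~0.7% of points; on realistic rate
distributions the exclusion stays well under 5%.

## Regression model building

All fits are ordinary least squares of the rate constant on transformed
predictors, on the complete cases for the chosen terms; per-term p-values
are two-sided t-tests. Rank-deficient designs are rejected with the
collinear terms named. AIC is the Gaussian-likelihood convention
statsmodels uses (n·ln(2πRSS/n) + n + 2(k+1)); only differences between
models on the same rows are meaningful.

**Screening.** One single-predictor fit per column; results sorted by
ascending p with alphabetical tie-break, so every downstream decision is
reproducible bit for bit. No multiple-testing correction is applied at
screening — the screen is a candidate filter, not an inference.

**Backward.** Start from all univariately significant predictors
(p < α = 0.05); repeatedly refit and drop the single highest-p term while
any term has p ≥ α (alphabetical tie-break). The removal order is logged.

**Forward.** Add candidates in order of ascending univariate p. A new
term insignificant in the joint fit is removed again. If adding a term
renders an existing term insignificant, the two models (with the new term
but without the displaced one, versus without the new term) are compared
and the one with higher R² is retained. Candidates that failed screening
are never added. Retention significance uses the per-term t-test; a
drop-one F-test gives identical decisions for single terms.

**AIC reduction.** Greedy backward elimination minimizing AIC, stopping
when no single removal lowers it. Final AIC ≤ starting AIC by
construction.

**Categorical variance.** One-way ANOVA reports R² = SS_between/SS_total
and the F-test p. Genes may carry several GO SLIM terms; the default
treatment is one binary indicator per label (so multi-label genes
contribute to several columns), with an exclusive single-label mode
available in the generator for strict one-way designs. model++ refits the
reduced continuous model plus indicators for every label with ≥ 10 member
genes (configurable); the prevalence floor prevents degrees-of-freedom
explosion from rare labels. Indicators are complete (absence of a label
is information, not missingness), so model++ uses exactly the reduced
model's rows and its R² cannot decrease.

**Rank-sum comparison.** Wilcoxon rank-sum, exact enumeration when both
groups have n ≤ 10 and the pooled sample is tie-free, otherwise the
normal approximation with continuity and tie correction. The continuity
correction matters: without it the asymptotic p can differ from the exact
p by > 0.03 at n = 10 per group; with it the difference stays below 0.01.

**Residual outliers.** Transcripts with residual > mean + 2·SD (one-sided:
degrading faster than predicted) are flagged and their feature medians
contrasted with the rest. An exact fit leaves only float noise in the
residuals; a spread below 10⁻¹⁰ of the response scale is treated as zero
and flags nothing.

## qPCR decay

Relative abundance is the ΔCt quantity Y = 2^(Ct_ref − Ct_gene). The
reversed exponent (2^(Ct_gene − Ct_ref), the reciprocal) appears in some
legacy spreadsheets and is available as `convention="as_printed"`; the
default is the standard convention because a decaying transcript must
show decreasing Y. The convention used is recorded in output metadata.
Amplification efficiency is assumed to be exactly 2 per cycle.

Each replicate is normalized to its own t = 0 value (every replicate must
include one; normalization is idempotent). The decay constant is
estimated by unweighted least squares of ln Y on time over all replicate
points jointly; per-time aggregation (mean ± SEM, SEM undefined at n = 1
and optionally suppressed below n = 3 to match common reporting) is for
display, and coincides with the all-points fit when replicates are
balanced. A non-positive estimated k (rising signal) is flagged, not
raised.

**Bootstrap.** Case resampling of (t, ln Y) pairs, 1,000 resamples by
default, percentile 2.5/97.5 intervals on k and on the fitted line per
time point; resamples with fewer than two distinct times are redrawn. The
seed is mandatory in the CLI and recorded in outputs. Construct
comparisons use the bootstrap distribution of k_a − k_b over the stored
draws; a pair is "significant" when that interval excludes zero. Measured
coverage of the 95% interval on k under the default synthetic conditions
is ~93–95%.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, which is what makes the tests informative and also bounds what
they show.

- **Coding sequences** start ATG, end TAA, and are built by sampling an
  amino-acid sequence (uniform over the 20 residues), planting ≥ 4-proline
  runs in a declared fraction of genes (10% by default) and breaking
  accidental runs elsewhere, then assigning third-position G/C to exactly
  round(target·n) codons. The realized GC3 therefore hits the target to
  within rounding (± 0.5/n_codons), and the poly-proline positive set
  equals the planted set. Lengths are log-normal with median 350 codons.
- **Predictor tables** are multivariate normal on the transformed scale
  (identity correlation by default), back-transformed to original units
  and pushed through the regular assembly path. The response is
  k = 0.15 + Σ βⱼ zⱼ + ε min⁻¹ with β in SD units of the transformed
  predictors; when a target R² is set (0.43 by default, the scale of the
  genome-wide analyses this emulates), σ is solved from β'Rβ so the
  population R² equals the target. Noise is redrawn for the ~10⁻³
  fraction of rows that come out non-positive, a negligible truncation.
  Default size is 4,000 genes, the complete-case scale of genome-wide
  yeast datasets.
- **Categories** shift the response additively per label; shifts that
  drive rates non-positive are rejected with a clear error, so planted
  destabilizing effects should stay small against the 0.15 min⁻¹ mean.
- **qPCR tables** put the decay into the gene Ct (Ct rises by k·t/ln 2)
  with independent Gaussian Ct noise (SD 0.2 by default) on gene and
  reference in every observation; replicates model independent cultures.
  Default design: constructs at k = 0.035/0.025/0.015 min⁻¹, six time
  points at (0, 10, 20, 30, 45, 60) min, three replicates. The grid spans
  at least one half-life of the stablest default construct (t½ ≈ 46 min);
  shorter courses measurably degrade slope precision for slow decays,
  which is why a 0–30 min design is not the default.

What the synthetic data does *not* emulate: measurement-error correlation
between predictors (real genome-wide datasets share platform biases),
non-linear predictor-rate relationships, missingness that is informative
rather than random, real codon-usage distributions, and qPCR efficiency
below 2. Passing recovery tests on these generators demonstrates the
estimators are correct and calibrated under the stated model, not that
the model is true of any particular organism's data.

## Numerical conventions

Quartiles are type 7; stepwise tie-breaks are alphabetical; all
stochastic procedures take explicit seeds and are bit-reproducible given
them; missing values serialize as "NA" in TSV outputs; CAI accumulates in
log space; bootstrap slopes are computed vectorized over resamples.

## Problem sizes used in the calibration suite

The acceptance computations use 1,000 random sequences for the CAI
oracle, 100 five-candidate designs (n = 300) for stepwise-versus-
exhaustive agreement, 100 and 500 replicates at n = 4,000 genes for R²
and coefficient-coverage checks, 500 simulated time courses (single
construct, k = 0.025, 500 bootstrap resamples each) for qPCR recovery
and CI coverage, and 100 null datasets at n = 4,000 for screening and
model++ calibration. These sizes put Monte-Carlo error comfortably inside
each check's acceptance band.
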