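# Methods

This note records the statistical model, the synthetic-data model, the
defaults and the numerical choices behind `intergen`, and what the test
suite does and does not establish.

## Design and per-contig model

Samples belong to four groups CC, CJ, JC, JJ (parental then offspring
treatment letter; C control, J jasmonic acid), default sizes 6/5/6/6 —
the post-exclusion layout of the emulated study. Expression per contig is
modelled as a Gaussian cell-means model with **group-specific error
variances**: Y_ij = μ + t_i + ε_ij, ε_ij ~ N(0, σ_i²). Group means and
unbiased variances are estimated per contig (`fit_groups`); the pooled
variance is the (n_g−1)-weighted average.

Two diagnostics compare the variance structures per contig:

* **Folded F** — F = max_g s²_g / min_g s²_g with df (n_argmax−1,
  n_argmin−1) and two-sided p = min(1, 2·min(P(F′≥F), P(F′≤F))). The
  classical folded F is a two-group test; this max/min extension selects
  the extreme pair, so even under homoscedasticity its p-values are
  concentrated toward small values (≈19% below 0.05 at n = 6/5/6/6) and
  p-values near 1 are rare. Two consequences, both deliberate: the
  per-contig p is interpretable only as a screening statistic, and in
  `hetero_summary` the Storey correction pins π₀ = 1 (i.e. BH), because
  the smoother estimate of π₀ collapses on such a family. Measured on
  homoscedastic Gaussian truth this yields a significant fraction of
  ~0.000 at FDR 0.05, and 0.75 power when one group's variance is
  inflated 9×. Bartlett's test would be the textbook alternative; the
  folded F is kept as the primary statistic because the screening
  question is "which group is extreme", and the argmax-group tabulation
  is the object of interest.
* **ΔBIC** — Gaussian log-likelihoods with ML variances; k = 5
  (homoscedastic) vs 8 (heteroscedastic); ΔBIC = BIC_hom − BIC_het > 0
  favours group-specific variances.

## Contrasts and FDR

Seven zero-sum contrasts over (CC, CJ, JC, JJ): direct_in_C (1,−1,0,0),
direct_in_J (0,0,−1,1), parental_in_C (1,0,−1,0), parental_in_J
(0,1,0,−1), joint_same (1,0,0,−1), joint_cross (0,−1,1,0), interaction
(1,−1,−1,1). Under the heteroscedastic model a contrast c has estimate
Σc_g μ̂_g, se² = Σc_g² s²_g/n_g and Satterthwaite df
se⁴ / Σ[(c_g² s²_g/n_g)² / (n_g−1)]; for a two-group contrast this is
exactly Welch's t (verified against an independent implementation to
1e-10). The homoscedastic path (pooled s², df N−4) exists for the model
comparison and for demonstrating why it fails: with a 1:9 variance ratio
and the unbalanced n it rejects at ~0.18 instead of 0.05, while the
Satterthwaite test stays in [0.035, 0.065].

**Storey q-values**: π₀ is estimated by the smoother — π̂₀(λ) =
#{p>λ}/(m(1−λ)) over λ ∈ {0, 0.05, …, 0.90}, a cubic smoothing spline
evaluated at λ = 0.90, clipped to (0, 1] — and q is π̂₀ times the BH
step-up quantity (max-rank tie convention). With π₀ pinned to 1 the
output equals BH exactly, which is the oracle test. By default all
contig × contrast p-values are corrected in one pooled family (the
"simultaneous" reading); per-contrast families are available
(`fdr_pooling="per_contrast"`) because the pooling unit in the emulated
study is ambiguous. Significance default q ≤ 0.1.

Set summaries are exact set algebra; the reported unions are
direct = direct_in_C ∪ direct_in_J, parental likewise, joint, and any.
A union of two FDR-0.1 sets does not itself have FDR 0.1: true positives
overlap heavily (a planted direct effect appears in both backgrounds)
while false positives are mostly disjoint, so the union's empirical FDR
runs near 0.13 in the recovery simulations. The recovery acceptance
check therefore estimates sensitivity and FDR over three replicate
simulations (pooled counts), not from a single run.

## Normalisation and QC

RPKM = count / (length/1000) / (mapped_total/10⁶). `mapped_total` is
supplied metadata and by default excludes spike-mapped reads (flag to
include), keeping biological RPKM comparable across spike batches. Log
transform is natural log with offset 1 (log1p); the base and offset are
config knobs — analyzed contigs pass a 10× coverage floor, which makes
the offset negligible, and all downstream tests are base-invariant.

Spike-in QC: per sample, OLS of log observed count on log expected
concentration (zeros dropped and counted); per within-group sample pair,
Bland–Altman bias and 1.96·sd limits of agreement on spike rows.
Candidate normalisations (log RPKM, total-count, median-of-ratios,
upper-quartile) are ranked lexicographically by median |bias| then
median limits width, ties broken by name. On synthetic data whose only
library distortion is a scalar size factor all four candidates are
near-equivalent; the ranking op is exercised by planting per-sample
offsets instead.

## Filtering

Coverage(contig, group) = mean over the group's samples of
count × read_length / length, with read_length default 91 (101 bp reads
minus a 10 nt trim). "Pooled" group coverage (sum instead of mean) is
available behind a flag since the phrasing "average of at least 10 reads
per nucleotide in all four groups" admits both readings. Partition:
contigs shorter than 500 bp are reported as a separate `short` subset
(the length rule is applied first); the remainder are `analyzed`
(≥10× in all groups), `low_everywhere` (<10× in all groups) or `partial`
(<10× in some groups only — candidates for on/off regulation that the
variance model cannot test). The partition is asserted disjoint and
exhaustive on every run.

## GO enrichment

Contigs map to putative genes (exactly one gene per contig); a gene's
annotation is the union over its contigs; unannotated genes are dropped
and tallied. Per term, a two-sided Fisher exact test on the
(significant × carries-term) 2×2 table over the annotated reference set;
BH FDR across terms in one pooled family (per-namespace families would
also be defensible; pooled is the default). Gene-level significance
feeds from contig FDR 0.20 in the pipeline examples (a relaxed
threshold that enlarges the gene set while bounding the expected false
fraction at 20%). `most_specific` drops any significant term with a
significant descendant, using a caller-supplied parent map only — no
ontology is downloaded; tests use toy DAGs. Because the exact test is
discrete, its null p-values are conservative rather than uniform; the
calibration test checks uniformity of the randomized p-values and
conservativeness of the raw ones.

## LC-MS arm

Per ionisation mode: intensities scaled to a total of 10 000 per sample;
signals kept if positive in ≥5 samples. PCA is mean-centred SVD with
unit-variance scaling by default (pareto and none available) and a
deterministic sign convention (largest-|loading| positive). PLS-DA uses
an indicator response (one-hot beyond two classes); Q² is 1 − PRESS/TSS
under k-fold CV (folds reduced with a warning when a class is small);
the permutation p is (1 + #{perm Q² ≥ observed}) / (n_perm + 1) with
n_perm = 999 in study-sized runs and 199 in the test suite. OPLS is the
single-response Trygg–Wold algorithm (one predictive component, k = 1
orthogonal components by default), written in-package because no
installed library provides OPLS; the S-plot reports cov(t, x) and
corr(t, x) per signal and selects |corr| ≥ 0.8 ∧ |cov| in the top 10%.
The emulated study selected S-plot signals *visually*, so no threshold
reproduces its exact set; thresholds are explicit knobs and the test
surface is planted-effect recovery.

Per-signal ANOVA: eligibility needs ≥3 positive intensities in every
group; zeros among eligible signals are replaced by half the signal's
minimum positive value before the natural-log transform (configurable —
the replacement adds real noise and is a large part of why power on
zero-inflated signals is modest); two-way fixed-effects ANOVA with
interaction, Type-II sums of squares; signals whose residuals fail
Shapiro–Wilk at p ≤ 0.05 are recorded ineligible, not errored. The
engine is a vectorised projection implementation (QR residual sums over
shared design matrices) validated against `statsmodels.anova_lm(typ=2)`
to 1e-8; BH FDR is applied across the pooled p-values of all three
effects of all eligible signals. High-confidence signals are the
intersection of the S-plot selection and ANOVA significance (q ≤ 0.1).
Summary percentages print with one decimal at ≥10 and two below
(round-half-even), matching the convention of the emulated study's
summary table.

## Phenolics

Two technical replicates per plant are averaged (single missing
replicate falls back with a flag); the per-plant value is modelled as
value ~ seed_weight + parental × offspring with Type-II sums of squares
(Type I/III available). With a constant covariate the treatment F values
reduce exactly to the plain two-way ANOVA. Coefficients are verified
against an explicit normal-equations solve to 1e-10.

## Synthetic-data model

All randomness flows from one seed through named `SeedSequence` child
streams (fixed spawn order: lengths, coverage, effects, hetero, library,
counts, spikes, peaks_negative, peaks_positive, phenolics), so outputs
are byte-identical per seed and extending one stream cannot perturb
another.

**Counts**: contig lengths are piecewise log-uniform hitting
(min, median, max) = (200, 809, 17258) bp; baseline per-nucleotide depth
is lognormal around 25 (sd 1.0 on the log scale); expected count =
depth × length / read_length × library factor (lognormal, CV 0.2 — the
between-library variation is a knob, not a fidelity claim); counts are
negative binomial with dispersion α = 0.05 (var = μ + αμ²). Effects are
planted on the log scale (default shift 1.0, random sign): direct shifts
offspring-J groups, parental shifts parental-J groups, interaction adds
the pure non-additive pattern (+,−,−,+)·δ/2 — note any pure interaction
also moves individual two-group contrasts. Heteroscedasticity multiplies
the CJ group's dispersion by 9 in a 44% subset (the fraction the
emulated study found significant). Spike-ins: 92 rows on a deterministic
2-fold concentration ladder (23 levels × 4), counts independent of
group; real ERCC catalog concentrations are deliberately not reproduced.
After log(RPKM), NB dispersion inflation appears as inflated log-scale
group variance, which is what the folded-F arm consumes. The truth table
records effect class, per-group true log means, approximate log-scale
variances and the contig→gene map.

**Peaks**: per mode (defaults 1210 negative / 7728 positive signals,
the emulated study's detected totals), baseline ln intensity ~
N(4.0, 1.5²) per signal, within-group sd 0.5, the same 2×2 effect
machinery, and independent Bernoulli(0.2) zeroing per cell to exercise
presence filters and the zero policy.

**Phenolics**: value = 20 + 5 × seed_weight(mg) + group effects + N(0,
1.5²), two technical replicates at sd 0.5; seed weights lognormal around
0.6 mg. Default group effects (direct +2, interaction −1) emulate the
qualitative pattern of induction that is dampened in offspring of
treated parents.

What the generator does **not** emulate: compositional biases that would
distinguish RPKM from its competitors, correlated expression between
contigs of one gene, batch/lane effects, retention-time drift or
intensity-dependent missingness in LC-MS (zeros are missing completely
at random), and assembly artefacts. Passing tests therefore demonstrate
correctness and calibration of the statistics under the stated model,
not robustness to those real-data pathologies.

## Problem sizes and tolerances

The default simulated study (2000 contigs, ~9000 signals) is sized so a
full pipeline pass takes tens of seconds; calibration tests use 5000 –
10000 Monte-Carlo replicates, recovery tests 2000 contigs × 3 seeds, and
permutation tests 199 permutations (the study-scale 999 is a parameter).
Numerical agreement thresholds: 1e-10 for closed-form oracles (Welch,
Fisher enumeration, normal equations, exact BH equivalence), 1e-8 for
linear-algebra oracles (PCA, Type-II ANOVA vs statsmodels). Degenerate
inputs have fixed conventions: zero contrast se with zero estimate → p =
1, with nonzero estimate → p = 0 (flagged); folded F with a zero minimum
and positive maximum → p = 0; all-zero sample columns are errors.
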