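# Methods

This note documents the models, numerical choices and limitations of
`fragmrd`. Everything quantitative stated here is computed by the test suite
or `scripts/acceptance.py`; nothing is quoted from external data.

## Fragment pools as histograms

A cfDNA sample is a multiset of integer fragment lengths (bp). `fragmrd`
stores every pool as a length histogram, which is lossless and makes each
"randomly sample *n* fragments with replacement" step a single multinomial
draw over ≤ ~600 length bins — distributionally identical to drawing
fragments one at a time, but O(#bins) instead of O(*n*). Without-replacement
sampling uses the multivariate hypergeometric distribution. This is the
design decision that makes 200 per-fold refits with million-fragment FS
draws run in seconds on one CPU.

Fragment lengths from paired-end alignments are defined as the absolute
template length of the first-in-pair, properly-paired, non-duplicate,
non-secondary read with mapping quality ≥ 20 (configurable); lengths above
600 bp are discarded. The 600 bp cap covers the mono- and dinucleosomal
range with margin; 20 is a conventional mapping-quality floor. Extraction
streams the whole file, so plain SAM works and no index is required.

## Score table

Each bootstrap iteration draws `n_sample = 10,000` fragments from the
tumour-tagged pool and from the non-malignant pool, forms the two empirical
densities, and scores each length `s(L) = log2(d_t / d_nt)` with:

* clip to `[-cap, +cap]`, `cap = 5`; when exactly one density is zero the
  cap is assigned outright;
* `s(L) = 0` wherever the *combined* sampled count is ≤ `min_count = 20`.
  The low-count rule is interpreted on the combined tumour + non-tumour
  count within the iteration: both draws have the same size, so a per-pool
  rule would be nearly equivalent, and the combined rule guards both tails.
  It takes precedence over the cap.

The final table is the arithmetic mean of `n_boot = 1000` iteration score
vectors (a median aggregate is available); averaging is what "smooths" the
sparsely covered bins, and the test suite verifies that across-build
variance falls as `n_boot` grows. Draws are with replacement by default
(bootstrap semantics; a without-replacement flag exists). One RNG stream is
seeded per build and consumed sequentially by the iterations, so a build is
exactly reproducible from its seed. Lengths never seen in either draw score
0, making the table total over its support.

Sampling is from the full pools as given; the non-malignant pool is not
pre-downsampled before the 10,000-read draws.

## Patient FS

`patient_fs` draws 10⁶ fragments (with replacement, uniformly across pool
sizes) and averages `s(L)`. The estimator is unbiased for
`E[FS] = Σ_L p(L) s(L)` with standard error `sd(s)/√n`; both facts are
asserted against the closed form in the tests. The MRD threshold is the
control mean + 2 sample standard deviations (n−1 denominator), and calls use
strict inequality. Reproducibility is characterised by repeated
subsampling: `fs_replicates` reports both the t-based 95% CI of the mean of
10 replicate FS values and their min–max range (the CI is the headline
number; both are emitted because either spread measure is defensible).

## Variant FS

The VFS averages `s(L)` over a variant's supporting fragments, merging pre-
and postoperative plasma so more fragments contribute. The null threshold
for a variant with *n* reads is the mean + 2 SD of 1000 VFS values of
*n*-read draws from the pooled non-malignant fragments (all controls merged,
not per-control). Thresholds are cached per (score-table id, *n*) with an
RNG stream derived from (seed, *n*), so values do not depend on request
order and a rebuilt table never reuses stale thresholds. Below 8 supporting
reads a variant is indeterminate; otherwise tumour when VFS strictly exceeds
the threshold, blood otherwise. The +1/−1/0 performance score used to pick
the read minimum is provided as `vfs_performance_score`.

## Variant tracking

Baseline triage uses pipeline detection only: a variant called in the
blood-cell pellet is germline (if also called in tissue) or CHIP, and both
are excluded downstream; otherwise a variant called in tissue or
preoperative plasma is trackable; variants seen only postoperatively are
uninformative. Raw supporting reads do not promote a variant at baseline —
the lowered read cutoffs apply only to postoperative tracking of variants
that are already baseline-informed. Postoperatively, a trackable variant
counts as detected when its raw supporting reads reach the cutoff *r*, and
pipeline-called variants count regardless of *r* (the upstream caller has
already accepted them; a flag disables this).

The grid search maximises accuracy against recurrence over
*r* ∈ [1, 8] × *k* ∈ [1, 6]. Ties break deterministically: highest accuracy,
then larger *r*, then **smaller** *k*. Larger *r* is the stringent choice on
the axis where sequencing noise actually creates false positives (stray
reads). On the *k* axis, stringency buys nothing once *r* filters noise, but
it silently disenfranchises patients who simply have few trackable variants:
with a clean training fit (ties everywhere), a maximal *k* would turn every
held-out low-variant-burden recurrent patient into a guaranteed false
negative. Preferring smaller *k* keeps those patients detectable at no
observed specificity cost.

## Combined model and cross-validation

Training fits, in order: the score table (tumour side pooled from training
patients' mutation-carrying fragments only), control FS values and their
threshold under that table, the variant cutoffs, and finally the AND/OR
combination logic by training accuracy (cutoffs first, then logic given both
call vectors). A logic tie resolves to AND, the specificity-first choice
given the clinical cost of a false-positive MRD call. Note that with logic
restricted to {AND, OR} the combined training accuracy is not guaranteed to
dominate both single-modality accuracies in adversarial cases; on cohorts
where both channels are informative (the setting this model targets) it
does, and the tests check this empirically.

The cross-validation repeats 20 random partitions into 10 folds (sizes
⌊N/10⌋–⌈N/10⌉, i.e. 3–4 patients for N = 36, unstratified), holding each
fold out once. Per repeat the RNG is seeded `seed + repeat`; per fold a
child seed is drawn, so runs are exactly reproducible. Inside CV the
score-table rebuild uses `n_boot = 100` (200 fold-fits × 1000 iterations
would be needless; the final model uses 1000, and build-variance checks show
the reduction is benign). Held-out patients' tumour-tagged fragments never
enter the fold's table; each fold records the contributing patient ids so
tests audit this by construction. Final calls are positive at ≥ 11 of 20
repeats (strict majority). The permuted-FS negative control recomputes the
CV with each patient's FS taken from a uniformly random (possibly
identical) other patient's plasma, variants untouched.

Per-patient FS values inside fitting and prediction use a seed derived from
(model seed, patient id) via CRC32, making predictions deterministic
functions of the fitted model and the patient.

Evaluation reports the confusion matrix, accuracy/sensitivity/specificity/
NPV with exact Clopper–Pearson 95% CIs (scipy), and the two-group log-rank
test with Kaplan–Meier curves (lifelines; recurrence as event, follow-up as
time, censoring at last follow-up). If every patient lands in one predicted
group the log-rank statistic is reported as undefined rather than forced.
Wilcoxon rank-sum and paired t-test helpers cover the usual cohort
comparisons (controls vs patients; preop vs postop).

## Clinical-benefit bootstrap

Each of 10,000 iterations resamples the cohort with replacement, draws each
patient's prediction Bernoulli(positive-call probability from CV), computes
sensitivity for recurrence, and allocates `0.058 · N` expected benefiters:
the sensitivity fraction to the positive group, the remainder to the
negative group. Allocation uses expected (fractional) counts, which makes
conservation exact within every iteration and the perfect-classifier limit
exactly zero for the negative group. Iterations without a recurrent patient
in the resample (sensitivity undefined) or with an empty group are excluded
from the affected summary and counted. Summaries are medians with
2.5–97.5 percentile intervals. A no-resampling flag yields the closed form
`benefit_rate · N · (1 − sens) / N_neg` for fixed 0/1 predictions.

## Synthetic cohort generator

Length profiles are discrete truncated-normal mixtures on [1, 600] bp:
non-tumour mono/dinucleosomal modes 167 ± 10 and 334 ± 25 (weights 0.8/0.2),
tumour modes shifted shorter to 145 ± 12 and 300 ± 30 (weights 0.85/0.15).
The modes reproduce the qualitative tumour-shorter shift; they are modelling
choices, not measured values. A patient pool mixes the two profiles at a
tumour fraction; origin histograms are retained as hidden truth.

The default cohort is 36 patients with 14 recurrences and 15 controls,
2 × 10⁶ fragments per plasma pool. Recurrent patients keep a postoperative
tumour fraction uniform on [0.05, 0.15]; non-recurrent patients have none.
Preoperative tumour fractions are uniform on [0.02, 0.10] for everyone.
Variant counts per patient are Poisson (trackable mean 8 with a floor of 3,
CHIP mean 5, germline mean 3) at ~5000× depth; allele fractions are half the
tumour fraction (heterozygous), CHIP allele fractions uniform on
[0.005, 0.05], germline 0.5. Non-recurrent postoperative plasma carries a
1 × 10⁻⁴ noise allele fraction so the variant channel sees realistic stray
reads; the synthetic "pipeline" calls a postoperative variant at ≥ 25 reads.
Supporting-fragment lists are capped at 200 per variant to keep tables
small; mutation-carrying preoperative reads double as the patient's
tumour-tagged reference fragments (~10²–10³ per patient, cohort totals in
the low tens of thousands). Follow-up is uniform on [6, 24] months for
recurrent and [20, 36] for non-recurrent patients, so events occur within
follow-up.

What the generator does **not** emulate: GC and capture bias, per-locus
error profiles and trinucleotide context, inter-patient variability in the
baseline length distribution, tumour fractions drifting over time, and any
correlation between variant burden and outcome beyond the tumour-fraction
link. Passing tests therefore demonstrate the machinery is correct and the
method recovers truth under its own assumptions — not clinical performance
on real plasma.

## Problem sizes

The default test-and-acceptance configuration uses 2 × 10⁶-fragment pools,
10⁶-fragment FS draws, 1000-iteration score tables (100 inside CV), the full
20 × 10 cross-validation, and 10,000-iteration benefit bootstraps. These are
the package's standard operating sizes; the histogram representation keeps
the complete suite in the tens of seconds.

## Known limitations

* The AND/OR logic space cannot express "ignore one channel"; a cohort where
  one channel is pure noise is better served by the single-modality runs,
  which `run_ttfcv` reports alongside the combined counts.
* FS thresholds assume approximate normality of control FS (mean + 2 SD);
  with 15 controls the attained specificity is nominal, not exact.
* The VFS null pools all controls; per-control heterogeneity is not
  propagated into the threshold.
* The benefit simulation equates sensitivity for recurrence with sensitivity
  for chemotherapy benefit and ignores treatment received by the cohort; its
  output is hypothesis-generating, not causal.
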