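# Methods

This note documents the models, parameter choices and known limitations
of `tissuemrs`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The classification problem

Each sample is a 1D ¹H CPMG spectrum of an intact tissue biopsy on a
shared chemical-shift axis, with a pathologist-scored tumor cell
content (TC, %) and a patient identifier. Patients contribute one or
two biopsies, so samples are not independent — any validation that
splits samples rather than patients leaks patient-level structure
(shared metabolic baseline, instrument session) into the test set and
inflates performance. Everything in the package is organized around
that constraint.

## Preprocessing chain

Stages run in a fixed order; each is a pure function of the spectra.

1. **Region selection** keeps −0.08–4.7 ppm (inclusive on the grid).
2. **Negative-spike repair** replaces each maximal run of negative
   points with the value of its nearer non-negative neighbor. Both
   neighbors of an interior run are adjacent, so the tie rule (prefer
   left) means interior runs take the left value; a run touching an
   edge takes the nearest interior non-negative value. The rule is
   deterministic, local, and independent of processing order.
3. **Offset removal** subtracts the per-spectrum minimum.
4. **AsLS baseline**: minimize Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δᵈz)² with
   wᵢ = p if yᵢ > zᵢ else 1−p, iterated from wᵢ = 1 until the weight
   pattern is stable (or 50 iterations, with a warning on cycling).
   Defaults λ = 10⁷, p = 10⁻⁴, d = 2. Numerics: the normal system is
   solved by sparse LU with iterative refinement using
   extended-precision residuals — the condition number reaches ~λ/p, and
   in plain double precision the residual b − Az itself cancels to only
   ~10⁻⁸ absolute accuracy, which caps the solution accuracy well above
   what a reference dense solver comparison requires. A relative
   tolerance guard (10⁻⁹·max|y|) on the weight update prevents
   solver-precision noise from flipping weights at exact-equality
   points (e.g. constant spectra).
5. **Alignment**: within each of 39 intervals (equal-width by default;
   the interval set is configurable because published interval choices
   are study-specific), every spectrum is shifted by the integer lag
   maximizing Pearson correlation with the reference segment, the
   reference being the spectrum with the highest mean correlation to
   all others. Vacated positions take the segment's edge value.
   max_lag defaults to 10% of the interval width. Ties prefer the
   smallest |lag|, then the negative one.
6. **Deletions**: the area upfield from 3.0 ppm, the ethanol window
   3.691–3.642 ppm, and the fatty-acid residual 4.400–4.200 ppm.
7. **Mean normalization** over the retained (post-deletion) variables;
   every output row has mean exactly 1.

The default axis (4.70 down to −0.08 ppm at 5.26·10⁻⁴ ppm/point, 9088
points) is chosen so the retained region is exactly 2759 variables;
digital resolution is a free parameter of the generator, not a measured
quantity.

Applying the chain twice is *not* the identity: the second AsLS pass
re-estimates a lower envelope of the already-corrected spectra and
renormalization follows. On noise-free input every other stage is
exactly inert on the second pass (verified to ~10⁻¹⁶); with noise,
correlation alignment additionally has an intrinsic ±1-point lag
ambiguity in low-signal intervals.

## Scaling and PLS-DA

Modified VAST scaling: x′ᵢⱼ = (xᵢⱼ − mⱼ)·(mⱼ/sⱼ), i.e. mean-centering
followed by multiplication with the stability weight mⱼ/sⱼ (not
classical autoscaling). Both statistics come from training rows only
and are re-applied unchanged to test rows; near-constant variables
(sⱼ ≤ 10⁻¹²·max s) get weight 0. Note the consequence: the PLS weight
for variable j is proportional to mⱼ·corr(xⱼ, y), so stable high-mean
variables dominate over high-contrast but volatile ones.

PLS-DA is NIPALS PLS1 on the scaled matrix and the centered 0/1 class
code, deflating both X and y; the intercept is the class-code mean.
Classes are coded 0 (non-involved) / 1 (tumor) with decision threshold
0.5; a score exactly at threshold is called tumor, on the argument that
a margin-assessment application should err toward flagging tumor.
Coding {−1,1} would shift the threshold but not the decisions. If
deflation exhausts the y-covariance the extraction stops early and the
model records the reduced component count.

VIP scores use SSYₐ = qₐ²·tₐᵀtₐ as the per-component y-variance share;
with unit-norm weight vectors, mean(VIP²) = 1 holds identically.

## Double cross-validation

Monte-Carlo leave-20%-out at both levels: each repetition draws whole
patients at random until the held-out side first reaches 20% of
samples. The repetition counts (80 outer, 20 inner) follow the
repeated-random-split reading: 80 repetitions cannot be 5-fold
partitions. The inner loop computes, for every candidate latent count
A = 1…15, the mean validation accuracy over 20 grouped splits (VAST
refit per split; one NIPALS run per split, truncated per A) and picks
the smallest A attaining the maximum. The outer model is refit on the
full outer-training set with that A. Metrics are computed per outer
repetition and averaged; pooled-prediction metrics are also recorded.
Samples excluded from training by a labeling scheme are scored whenever
their patient is held out, preserving the no-leakage contract; their
pooled metrics average over all such repetitions (a per-repetition
model ensemble rather than one final model — the alternative of a
single final model would score them with data their patient helped
fit).

Permutation testing shuffles sample labels by default (patients can
legitimately contribute both classes, so patient-block shuffling —
also implemented — is stricter than the data require), re-runs the
full double CV per permutation (usually at reduced repetition counts),
and reports p = (1 + #{null ≥ observed}) / (1 + n_perm).

## Synthetic cohort generator

The generator emulates the features of CPMG HR MAS breast-tissue
spectra that the analysis depends on:

- **Cohort design**: 328 samples / 228 patients in four TC strata
  (65 at 0%, 5 at 1–4%, 32 at exactly 5%, 226 above 5%). Per-stratum
  patient counts in such cohorts overlap (patients span strata), so
  only the totals bind: 100 patients contribute two samples, 128 one,
  with tumor+normal pairs preferred so grouped CV actually faces
  patients spanning both classes. TC above 5% is drawn from a
  right-skewed Beta(1.2, 5) over 7–95% (median ≈ 20%).
- **Metabolite model**: nine metabolites at literature consensus
  shifts. Relative peak heights reflect proton multiplicity — the
  choline N(CH₃)₃ singlets concentrate nine protons in one narrow
  line, which is the physical reason the 3.20–3.23 ppm region dominates
  tissue spectra. Expected concentration is max(b + s·tc, 0): glucose
  declines with tumor content (Warburg-type consumption, s = −2.5 from
  b = 3.0) while ascorbate, lactate, creatine, glycine, taurine, GPC,
  PCho and free choline rise; PCho has the steepest rise (s = 4.0 from
  a low normal-tissue level b = 0.15, so even low-TC samples show a
  severalfold fold-change), matching its role as the dominant marker.
- **Noise structure**: a mean-one lognormal patient multiplier per
  metabolite (σ = 0.25) shared across a patient's samples — this is
  the within-patient correlation that motivates grouped CV — and a
  mean-one lognormal sample residual (σ = 0.15). Mean-one
  parameterization keeps the expectation exactly linear in tc, which
  the Monte-Carlo slope-recovery test exploits.
- **Artifacts**: a broad Gaussian baseline hump at a random position
  (amplitude 0.5, width 1 ppm), per-metabolite shift jitter
  (σ = 0.0015 ppm), an ethanol CH₂ quartet inside 3.642–3.691 ppm in
  10% of spectra, a broad residual at 4.2–4.4 ppm, and additive
  Gaussian noise (σ = 0.02, i.e. roughly 1–2% of a major peak).

What the generator does *not* emulate: time-domain effects (FID
truncation, phasing and apodization artifacts), the huge lipid signals
of fat-rich biopsies (the CPMG T₂ filter is assumed ideal),
composition-driven spectral differences beyond the tumor-content axis,
J-coupling fine structure (multiplets are collapsed to height-weighted
centroid lines), water-suppression residues, and field/shim
variability beyond per-metabolite jitter. Passing tests therefore
demonstrate that the *pipeline* is correct and leak-free and that it
recovers planted effects of realistic size — not that any particular
accuracy will transfer to clinical spectra.

One consequence visible in the reports: with 263 tumor vs 65 normal
samples and a fixed 0.5 threshold, errors concentrate in the minority
normal class (high sensitivity, lower specificity). This is a property
of the threshold convention under imbalance, kept deliberately; schemes
that exclude ambiguous low-TC samples from training shift the balance
back toward specificity.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full 328-sample cohort
with 20 outer / 10 inner double-CV repetitions for scheme metrics, the
permutation test at 5×5 repetitions with 19 permutations, and the null
calibration on a 60-sample / 45-patient cohort at a coarser 5·10⁻³ ppm
grid with 4×3 repetitions — sizes chosen to average enough Monte-Carlo
splits for stable percentages while keeping a full run in minutes on
one CPU. The full 80×20 protocol is the library default
(`DCVConfig()`), and all counts are configurable.

## Known limitations

- The 39 alignment intervals default to equal widths; real studies
  choose them around peak groups. Interval files are supported.
- AsLS weight iteration can 2-cycle on adversarial inputs; the
  implementation then returns the last iterate with a warning.
- `performance` reports NaN for a metric whose class is absent from a
  held-out set; aggregates use NaN-aware means.
- The JCAMP-DX reader covers the standard XYDATA/AFFN dialect only
  (no DIFDUP compression, no multi-block files).
- Patient-block permutation swaps label blocks only between patients
  with equal sample counts.
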