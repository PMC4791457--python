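# Methods

This package implements a complete analysis chain for forehead fNIRS
deception-detection experiments: raw two-wavelength light intensities and a
stimulus-event table go in; per-question hemodynamic features, relevant-voxel
masks, false-color topograms, and cross-validated per-class classification
metrics come out.  Because no recordings from such a study are publicly
available, a synthetic-cohort generator with known ground truth is a
first-class part of the package; everything below states what the pipeline
computes, what the generator emulates, and which design choices were open.

## Measurement model and preprocessing

Each *voxel* (source–detector region) yields one intensity signal per
wavelength (730 and 850 nm — one on each side of the 780 nm isosbestic
crossover, so the two chromophores are separable).  The modified
Beer–Lambert law relates the change in optical density against a resting
baseline to chromophore concentration changes:

    ΔOD(k) = log10( I_b / I(k) ) = α_Hb · ΔC_Hb(k) + α_HbO2 · ΔC_HbO2(k)

* **Logarithm base.** Decadic, the optical-density convention. The base only
  rescales concentration units uniformly and cancels from every class
  contrast.
* **Baseline reference.** `I_b` is the arithmetic mean of the *unfiltered*
  intensity over the baseline interval (the baseline is defined as the
  resting light measurement, before any processing).  Note the mean optical
  density over a noisy baseline is then not identically zero (the mean of a
  log is not the log of a mean); it is exactly zero when the baseline is
  constant.
* **Extinction coefficients.** The default 2×2 table uses widely tabulated
  decadic hemoglobin extinction values at 730/850 nm (Hb 1102.2 / 691.3,
  HbO2 390.0 / 1058.0 cm⁻¹ M⁻¹) scaled for μmol/L concentrations with an
  effective pathlength of 1.  Source–detector distance and the differential
  pathlength factor are deliberately folded into these effective
  coefficients: every statistic the analysis uses (class contrasts,
  selection rules, classifier inputs) is invariant to the overall scale.
  The table is user-configurable (`ExtinctionTable.from_csv`); its condition
  number must stay below 1e8.
* **Inversion.** The per-sample 2×2 system is solved exactly
  (`numpy.linalg.solve`), not by a pseudo-inverse, so the forward model is
  reproduced to machine precision (~1e-12 relative in practice).
* **Blood volume and oxygenation.** ΔB = ΔC_HbO2 + ΔC_Hb and
  ΔO = ΔC_HbO2 − ΔC_Hb, elementwise; the identities ΔB ± ΔO = 2·ΔC are exact
  by construction.

### Low-pass filter

Cardiac (~1 Hz) and respiratory (~0.3 Hz) oscillations are removed by a
Hamming-window FIR low-pass with a 0.14 Hz cutoff applied to the raw
intensities before the OD computation.  Open choices, resolved as follows:

* **Order:** 21 taps at fs ≈ 2 Hz (transition band ≈ 0.3 Hz, stopband
  attenuation ≈ 52 dB at 0.9 Hz single-pass).  Taps are renormalized to unit
  DC gain.
* **Phase:** zero-phase (forward–backward, `filtfilt`) by default so the 5-s
  post-stimulus windows stay aligned with the events; a causal single-pass
  mode is available (`FilterConfig(zero_phase=False)`).
* **Domain:** the filter runs on intensities, not OD.  Because the intensity
  modulations are at the percent level, filtering intensities and filtering
  OD agree to first order; the exact linear-domain commutation
  (filter∘invert = invert∘filter on OD) is verified in the tests.
* A 0.14 Hz passband necessarily smooths the hemodynamic response kernel
  itself (the kernel has most of its energy above the cutoff).  Consequently
  "noiseless recovery" checks of the inversion/epoching arithmetic run with
  the filter disabled (`preprocess_recording(..., filter_config=None)`);
  with the filter enabled the recovered series equals the *filtered* planted
  series, which is the correct linear-systems statement of fidelity.

## Epoching

The response to each question is reduced to the per-voxel mean of ΔB (and
ΔO) over the 5 s immediately following the stimulus — the end of the spoken
question — since the hemodynamic peak follows within ~1.6 s.  Windows are
half-open, [t_event, t_event + 5 s), on the sample grid t_k = k / fs, so a
boundary sample is never counted twice by consecutive questions.  The
implementation evaluates this defining predicate directly (bracketed by
floor/ceil bounds), so it agrees with an exhaustive scan of the grid for any
(fs, t, Δt).  At non-integer sampling rates the sample count per window can
differ by one between questions (the 5-s interval covers 10.02 sample
periods at 2.004 Hz); the count is recorded per question.  A window-offset
knob allows starting the window at the expected peak latency instead of the
stimulus; the default offset is 0.

Class-level means average the question means within each response class
m ∈ {1: induced lie, 2: induced truth, 3: non-induced lie, 4: non-induced
truth}.  Absent classes are reported absent, never zero-filled.  The
per-class *activity level* is the scalar mean of ΔB question means over the
relevant voxels and the questions of that class.

## Relevant-voxel selection

Three per-subject criteria operate on the ΔB question means (ΔO masks can be
computed as well, but classification defaults to ΔB only, blood volume being
the measure that carries the class differences):

* **Heuristic.** |ΔB̄_v^(m=a) − ΔB̄_v^(m=b)| ≥ 1 μmol/L for the pairs (1,2)
  and (3,4).  Total fallback: no qualifier → the two largest-difference
  voxels; one qualifier → it plus the runner-up.  A heuristic mask therefore
  always contains ≥ 2 voxels.  The threshold's unit is μmol/L in this
  package's concentration scale and is configurable, since its effective
  size depends on the extinction/pathlength convention.
* **Non-parametric.** The closed interquartile intervals [Q1, Q3] of the two
  classes' question-mean samples are disjoint (boxplot IQRs do not overlap).
  Quartiles use linear interpolation between order statistics (the common
  default in scientific software; configurable via `quartile_method`).
* **Parametric.** Two-sample two-tailed t-tests at α = 0.1 for the three
  contrasts (1 vs 2, 3 vs 4, {1,2} vs {3,4}), with *no* multiple-testing
  correction — the criterion is intentionally liberal, it feeds a
  cross-subject aggregation step.  Pooled-variance Student by default
  (groups are small and unpaired in the design); Welch by flag.  Degenerate
  zero-variance-in-both-groups voxels get p = 1 if the means agree and p = 0
  otherwise, with a logged warning.  Under a simulated null the per-voxel
  selection rate calibrates to α (verified at 10 000 replicates).

**Aggregation.** Per-subject masks are combined into the smallest voxel set
containing at least one relevant voxel for every subject.  For V ≤ 16 the
minimum-cardinality cover is found exactly (ascending-size exhaustive
search; among minimum covers the most frequently flagged voxels are
preferred, then the lowest indices).  For larger V a greedy cover (most
not-yet-covered subjects first, ties to the lowest voxel index) with a
redundancy-elimination pass is used; greedy alone is a ln(n)-approximation
and measurably misses the optimum on a few percent of small random
instances, which motivated the exact path.  Subjects with all-zero masks
cannot be covered and are excluded with a warning.  Per-voxel subject
frequencies are reported alongside the cover.

## Topograms

Question and class means are rendered as false-color maps over a 2×8
forehead strip (voxels 1–8 left hemisphere, 9–16 right; the exact probe
geometry is not standardized, so the layout is a documented convention
loaded from a CSV and fully replaceable).  The minimum value maps to blue
and the maximum to red through piecewise-linear RGB interpolation across
blue–cyan–green–yellow–red anchors; values are interpolated bilinearly
between voxel centers; non-relevant voxels are painted black.  Two
properties are enforced by construction:

* masked voxels are excluded from the interpolation (their cells are filled
  from the nearest unmasked voxel before interpolating), so a masked voxel's
  stored value can never influence any pixel; and
* each voxel cell has an odd pixel size (default 17 px) so its exact center
  pixel carries the palette color of its own normalized value.

For one subject the rendered set is M class-reference images plus Q question
images (Q + M = 34 for the standard 30-question, 4-class interview), all on
one shared per-subject color scale by default so question images are
directly comparable to the references (per-image scaling is available).
Question order is randomized by a seed for presentation; rendering is fully
deterministic given inputs and seed.

## Classification

The selection analysis cannot separate non-induced lies from non-induced
truths, so the standard problem is tri-class (IL / IT / non-induced); a
bi-class problem (induced vs non-induced) is also provided.  Features are
the ΔB question means of the selected voxels (ΔO columns by flag).

Evaluation is per-subject stratified 10-fold cross-validation (30 questions,
balanced 10/10/10 after the tri-class merge, hence exactly one question per
class per fold) with an RBF-kernel SVM.  The (C, γ) pair is chosen by a
nested stratified 3-fold grid search *inside each training fold* on the
canonical log2 grid (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, step 2); features are
standardized using training-fold statistics only.  A reduced 3×3 grid is
provided for Monte-Carlo studies that repeat many cross-validation runs.
Out-of-fold predictions (each question predicted exactly once) form the
confusion matrix, from which one-vs-rest per-class metrics follow:

    specificity = TN / (FP + TN),  sensitivity = TP / (TP + FN),
    accuracy = (TP + TN) / (TP + TN + FP + FN)

Ratios with zero denominators are reported as absent, not as 0.  Class
balance is handled by stratification; no class weights.  Calibration is
verified empirically: with permuted labels the tri-class accuracy is
statistically indistinguishable from 1/3.

## Synthetic cohort

The generator emulates a 10-subject, 30-question mock-theft interview with
three stages: stage 1 non-induced (a shuffled balanced mix of m=3 and m=4),
stage 2 induced lies, stage 3 induced truths.  Defaults, chosen once as the
package's study conditions:

| parameter | default | why |
|---|---|---|
| sampling rate | 2.004 Hz | the imager class being emulated |
| voxels | 16 (2×8 strip) | ditto |
| informative voxels | V1, V8 | the recurrent pair in reported selections |
| HRF | gamma kernel, peak 1.6 s, 12 s support, shape 2 | reported peak latency; smooth unimodal shape, 0 at onset, unit peak |
| ΔB amplitudes (μmol/L) | IL 4.0, IT 1.0, NL 2.1, NT 1.9 | IL strongest; NL slightly above NT (so the two are *not* discriminable and merge into one class); few-μmol/L cortical scale. No published amplitude exists; these are the package's calibration conditions, not literature values |
| chromophore split | 75 % on ΔC_HbO2, 25 % on −ΔC_Hb | typical activation polarity; scaled so the planted ΔB amplitude equals the configured value (ΔO responds at twice ΔB) |
| noise (μmol/L) | cardiac 0.4 @ 1.1 Hz, respiratory 0.3 @ 0.3 Hz, drift 0.1 @ 0.02 Hz, white 0.05 | cardiac/respiratory sit above the 0.14 Hz cutoff (the filter removes them; 1.1 Hz aliases to 0.9 Hz at this rate and is still attenuated ≥ 50 dB); the drift survives the filter and stresses the baseline-relative design |
| timing | 30 s baseline, first question at 45 s, 20 s between questions | keeps 5-s windows non-overlapping and leaves room for the HRF tail |
| baseline intensity | ~1000 a.u., integer-valued per channel | integer values make the baseline average exact in floating point, so quiet voxels invert to exactly zero in noiseless runs |

Per-subject seeds derive deterministically from the master seed; optional
between-subject amplitude variability scales each subject's responses by a
truncated normal factor.  The generator refuses configurations whose
forward-modelled intensities are not strictly positive and finite.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: motion artifacts and optode-coupling drift,
spatially correlated physiological noise, habituation across interview
stages, hemodynamic nonlinearity or response-shape variability, and any
psychology of deception.  Synthetic results demonstrate that the pipeline's
arithmetic, calibration, and power behave as specified under its own
assumptions; they say nothing about the effect size in real interviews.

## Numerical choices and degenerate inputs

* Exact 2×2 linear solves; extinction matrices with condition number > 1e8
  are rejected.
* Window indices come from the defining predicate, not from rounded
  endpoints; empty windows raise.
* All-equal topogram values normalize to the midpoint 0.5 with a warning;
  an all-masked topogram raises.
* Heuristic ties (equal differences) resolve to the lowest voxel index via a
  stable sort; grid-search ties keep the first (smallest C, then γ) entry.
* Cross-validation folds are reduced (with a log message) when the smallest
  class has fewer members than the requested fold count; single-class
  inputs raise.
* Recordings must have strictly positive finite intensities, a baseline that
  precedes all events, sorted events with unique question ids, and room for
  the 5-s analysis window after every event; violations raise structured
  errors naming the offending row/column.

## Problem sizes used in the shipped checks

Monte-Carlo checks are sized to run on one CPU in minutes: selection-rule
calibration at 10 000 replicates; window arithmetic against the exhaustive
oracle at 1 000 random (fs, t, Δt) triples; cover minimality against brute
force at 200 random instances with ≤ 12 voxels; classifier calibration at 50
label permutations and power at 10 subjects (full grid) or 20 seeds × 3
effect levels (reduced grid).  The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch for a given
master seed.

## Known limitations

* The on-disk dialect is this package's own transparent CSV convention;
  proprietary acquisition formats and SNIRF are not read (SNIRF export would
  be the natural extension point).
* The human visual evaluator of the original workflow is out of scope: the
  package renders the topogram stimuli but does not model the rater.
* The voxel-to-scalp layout is a convention, not an anatomical registration.
* Cross-subject (leave-one-subject-out) generalization is deliberately not
  implemented; evaluation is within-subject, matching the per-subject
  reporting the analysis is designed around.
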