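# Methods

This package simulates and analyses retinal ganglion cell (RGC) structure
and function in a three-group cohort — healthy controls, multiple sclerosis
without a history of optic neuritis (NON), and with such a history (HON) —
the way a combined multifocal pattern-ERG (mfPERG) / OCT study does it.
Because no raw recordings are publicly deposited for this design, the
package pairs every analysis stage with a synthetic forward model whose
group-level parameters are calibrated to published summary tables, so each
stage can be validated by parameter recovery.

## Stimulus and sequence model

The multifocal stimulus is a dartboard of 36 checkerboard elements in four
eccentricity rings (4/8/12/12 elements; ring radii 0.0–3.6–7.6–14.3–22.7°).
Each element independently either reverses its pattern (state 1) or holds
(state 0) once per two frames of a 75 Hz display, i.e. one state per
26.67 ms.  All elements follow one mother maximal-length sequence (period
2^m − 1 from an m-stage linear-feedback shift register), each delayed by a
distinct shift — the standard multifocal construction.  With m = 14 the mean
reversal rate is (75/2)·2^13/(2^14 − 1) = 18.75 reversals/s.

Feedback taps are configurable; the default degree-14 polynomial is
x^14 + x^13 + x^12 + x^2 + 1 with an all-ones seed register.  Every default
polynomial in `DEFAULT_TAPS` (degrees 2–16) was verified maximal by an
exhaustive state walk; non-primitive taps are rejected at generation time
by the same check.  Any primitive polynomial gives statistically equivalent
stimulation; fixing one gives bit-reproducibility.

Default shift spacing is 400 states (≈10.7 s), far beyond the 120 ms
analysis epoch; `build_geometry` validates that all pairwise circular shift
separations exceed the epoch so that kernels cannot cross-contaminate.

## Kernel extraction

For a binary pattern-reversal design, the first slice of the second-order
kernel is the response component locked to state transitions.  It is
computed as the ±1-weighted epoch average

    K(τ) = Σ_k a_k · r(t_k + τ) / n₁,   a_k = 2 b_k − 1,

where b_k is the element's state, t_k the state onset, and n₁ the number of
usable reversal states.  Over one full cycle of a maximal-length sequence
this estimator is an *exact* inverse of the linear forward model (the
shift-and-add property cancels all overlap and cross-element terms
identically), which the round-trip test verifies to below 10⁻⁶ µV.  The
conventional 1/period cross-correlation normalization would return half the
template; the n₁ normalization is chosen so that the recovered kernel *is*
the local response waveform.

Acquisition polarity: multifocal second-order kernels conventionally come
out inverted, so the generator inserts negated templates (`polarity=-1`)
and the analysis flips extracted kernels back before measurement; a double
flip is an error.

Artifact handling mirrors recording practice: each repetition is divided
into 32 segments; segments whose peak-to-peak exceeds a threshold are
flagged, and every analysis epoch overlapping a flagged segment is dropped
from the average.  The pipeline threshold defaults to 250 µV because the
stimulus-locked superposition of 36 calibrated element responses alone
spans roughly 180 µV peak-to-peak per segment, while simulated blinks
(200–500 µV, 100–300 ms) push segments well above 250 µV.  For quiet,
manually constructed recordings the op-level default of 100 µV applies.
Three repetitions are averaged pointwise, weighted by usable states.

## Waveform measurement

Extracted kernels are band-pass filtered at 3–45 Hz with a zero-phase
(forward–backward) order-3 Butterworth filter.  Order 3 was chosen
numerically: it holds the 10–30 Hz passband within 5% (gain 0.953 at
30 Hz) while attenuating 100 Hz below 1% and removing DC; order 2 fails
the passband requirement.

Right-eye element maps are mirrored about the vertical meridian onto the
left-eye visual-field frame (an involution that preserves ring
membership).  Kernels are averaged within rings and globally (the mean of
all 36 elements); N1, P1 and N2 — the multifocal analogues of the
transient-PERG N35, P50 and N95 — are measured by windowed extremum
search:

* search windows (defaults, configurable): N1 15–40 ms, P1 35–65 ms,
  N2 60–100 ms, chosen to bracket all published group medians;
* baseline: mean over 0–10 ms;
* amplitudes: N1 from baseline (≤0), P1 from the N1 trough to the P1 peak
  (≥0), N2 from the P1 peak to the N2 trough (≤0);
* peak times at the extremum sample (0.83 ms resolution at 1200 Hz); ties
  resolve to the earliest sample; a window without a strict interior
  extremum is flagged unmeasurable, never silently zeroed.

## Synthetic cohort

`sample_cohort` draws 14/12/11 subjects by default with truncated-normal
demographics matching the published cohort table; one eye per subject is
selected Bernoulli(0.5), and right-eye data are generated in right-eye
coordinates so the laterality flip is genuinely exercised.

Per-subject mfPERG parameters are drawn per ring and component:
amplitudes Normal(group mean, group SD) in the *measured* conventions
above, peak times Normal(group median, range/4) — only medians and ranges
are published for times.  Component amplitudes share a subject-level
response-strength factor (correlation 0.6 between any two components,
marginals unchanged): real component amplitudes co-vary strongly, and
independent draws frequently produce N2/P1 combinations that no waveform
can realize under the measurement chain (see below).  Time draws are kept
ordered (≥8 ms apart) and inside the search windows.

**Template calibration.**  Each ring's response template is a sum of
signed Gaussian lobes (N1/P1/N2 widths 8/12/15 ms FWHM) plus a late
positive "recovery" lobe (18 ms FWHM, centered 100–112 ms).  Because the
published amplitudes are defined through the measurement chain, lobe
amplitudes and centers are fitted by bounded least squares so that the
template, band-pass filtered and peak-measured exactly as in the pipeline,
reproduces the drawn targets; pipeline parameter recovery is therefore
unbiased by construction.  Numerical choices: sub-sample (parabolic)
extremum interpolation makes the objective smooth; the zero-phase filter is
applied as a precomputed matrix; lobe signs are fixed and centers bounded
to ±5–8 ms of their targets (otherwise the fit chases the high-pass
undershoot after P1); lobe magnitudes are bounded by twice the largest
target with a mild parsimony penalty (otherwise huge mutually cancelling
lobes satisfy the conventions unphysiologically).  The recovery lobe exists
because the filtered trace has near-zero area, so a large P1 forces a
trough into the N2 window; the late lobe absorbs that constraint outside
the measured windows.  A small fraction of draws (≈2% foveally, up to
≈10% in peripheral rings) remains infeasible and calibrates to the floor
with ≤0.3 µV truncation — well below the between-subject SDs — and the
residual is recorded on the template.

**Recordings.**  One repetition = one full sequence cycle at 1200 Hz
(exactly 32 samples per state), built by circular superposition of each
element's template at its reversal events (linear and time-invariant by
construction), plus white noise (default SD 5 µV) and Poisson blink
transients (default 2/min).  Three repetitions per subject by default.

**OCT data.**  Macular layer maps (total retina, mRNFL, GCL, IPL, INL,
ONL, ORL) cover a 30°×25° grid (0.25° spacing) centered on the fovea.
Maps are radially piecewise-constant over the ETDRS regions — 1 mm foveal
disc, 1–3 mm parafoveal and 3–6 mm perifoveal annuli, using 1 mm ≈ 3.44°
(emmetropic schematic eye, configurable) — blended over a configurable
smoothing length (default 0.005 mm, sub-pixel) and overlaid with a smooth
texture whose mean is removed per region, so region means recover the
per-subject targets to <0.5 µm.  The foveal GCL depression arises directly
from the low published center-ring GCL values.  GCIPL is always the
pointwise GCL + IPL sum.  The peripapillary profile holds 768 samples on
the 3.5 mm disc circle, indexed by eye-relative angle from the temporal
meridian (the device convention, identical for both eyes; a
`mirror_profile` utility serves screen-coordinate imports).  Sector values
are constructed so that the papillomacular bundle (PMB, 30° span),
temporal (T, 90°) and global (G) means hit their targets exactly, with a
double-hump S/I elevation that leaves G unchanged.  Default sector spans:
T 315°–45°, S 45°–135°, N 135°–225°, I 225°–315°, PMB ±15°.

## Statistics

* One-way ANOVA for amplitude and thickness measures, Kruskal–Wallis for
  mfPERG peak times — the study's fixed family→test policy (per-group
  Shapiro–Wilk p-values are always reported; a data-driven gate at
  α = 0.05 is available via `policy="shapiro"`).
* Post hocs: each patient group vs controls only, pooled-variance
  (Student) t for parametric families, Mann–Whitney U otherwise,
  Holm-adjusted over the two comparisons.  Pooled-variance rather than
  Welch t because the pooled form reproduces the published adjusted post
  hoc p-values (0.031, 0.0012) exactly from the printed summary
  statistics.
* Holm–Bonferroni step-down is implemented directly (sort, multiply by
  m−i, running maximum, cap at 1) and cross-checked against
  statsmodels in the tests.  Families: post hocs within each measure,
  omnibus tests within each table block, correlations within each panel.
* `anova_from_summary` and `posthoc_from_summary` recompute the omnibus F
  and post hoc p-values from (mean, SD, n) alone — sufficient statistics
  for these tests — which is how the published table values are
  reproduced without subject-level data.  Equivalence with raw-data ANOVA
  is property-tested to 10⁻¹⁰.
* Structure–function association: Pearson r with two-sided t-test
  (n−2 df), Holm within each panel (foveal N2 amplitude and parafoveal P1
  peak time, each against PMB/T pRNFL and parafoveal/perifoveal GCL).

Missing disc scans (the published disc analyses carry two fewer degrees of
freedom than the macular ones) are emulated by dropping a configurable
number of patient disc scans chosen by the seeded RNG; group membership of
the missing scans is not published.

## What the generator does and does not emulate

It emulates: the m-sequence stimulation geometry and timing, linear
superposition of local responses with realistic component morphology,
recording noise and blink artifacts with segment-level rejection, eye
laterality, group-calibrated between-subject variability, segmented OCT
thickness structure with exact sector statistics.  It does not emulate:
nonlinear retinal adaptation (the forward model is strictly linear, so the
kernel identity is exact rather than approximate), correlated
structure–function pathology within subjects (functional and structural
draws are independent, so between-modality correlations are near zero in
synthetic cohorts and the correlation battery is validated by separate
simulation-consistency checks), drifts/line noise, fixation losses, eye
movements, media opacities, or real segmentation error in OCT maps.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated model, not robustness to every pathology of real
recordings.

## Problem sizes

The default pipeline configuration uses the full 2^14 − 1 cycle.  The test
suite and the acceptance script run the same code on shorter cycles —
11- and 12-stage registers (periods 2047 and 4095) with proportionally
reduced shift spacing — and one repetition per subject, which leaves every
estimator identity intact (the kernel inverse is exact at any maximal
length) while keeping runs to seconds.  Monte-Carlo checks use 400–1000
replicates.  Group-mean recovery checks accept within 3 standard errors of
the published group SD at the published group size, the sampling
uncertainty those conditions imply.
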