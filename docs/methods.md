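# Methods

This note documents the models, conventions and numerical choices behind
the package; the README gives the overview and a worked example.

## Stimulus space and level arithmetic

Electrode places use a 1-based continuous coordinate, apical to basal;
integer values are physical contacts, fractional values are current-steered
virtual channels decomposed as `place = apical_electrode + α` with
α ∈ [0, 1] the fraction of current on the basal electrode of the adjacent
pair. The basal array edge resolves to `(n−1, α = 1)` so the electrode pair
stays valid. The default array has 16 contacts at 1.1 mm pitch (so a
3-electrode span is ≈3.3 mm); both are configurable.

Stimulation levels are current amplitudes in μA. Procedure steps are
defined in dB and applied multiplicatively (`×10^(ΔdB/20)`, amplitude
decibels), because electrical stimulation levels are currents. Pulse-train
metadata (20-ms probes, 500-ms maskers, ~140 μs phase duration, ~255 pps,
monopolar biphasic) is carried on stimulus objects and validated for
non-overlapping biphasic pulses; it does not otherwise enter the
simulation. The hardware limitation that interaural stimulation cannot be
synchronized better than ~5 ms is treated as dataset metadata, not
simulated.

## Adaptive procedures

**Bekesy tracking.** Ten alternating ascending/descending sequences; 1 dB
steps for sequences 1–4, 0.5 dB for 5–10. A sequence ends at the level
where the audibility response changes (first audible going up, first
inaudible coming down); the next sequence starts two step sizes beyond
that endpoint, using the step size of the sequence being entered. The
threshold estimate is the 20% trimmed mean of the final six endpoints.
Endpoint averaging is done in the dB domain and converted back to μA
(configurable to μA-domain averaging); the source procedure does not state
the averaging domain, and dB is the domain the steps are defined in. A
configurable ceiling (default 4000 μA) and floor (0.5 μA) abort runaway
tracks — including the degenerate "always audible" listener — with a
safety error that carries the partial sequence logs.

For a deterministic listener the estimate is provably within half a fine
step (0.25–0.5 dB) of the true threshold for any start at least a few
coarse steps below threshold; the calibration study measures a worst-case
error of 0.25 dB over a 20-point threshold grid.

**Double-staircase loudness balance.** Two interleaved 1-up-1-down
staircases start 4 dB above and below the predicted match and alternate
trials. A trial presents the fixed reference and the adaptive comparison;
"comparison louder" moves the comparison down, otherwise up. Reversal
levels are recorded at the trial where the response direction changes;
steps are 1 dB until the fourth reversal and 0.5 dB for the next six. The
balanced level is the dB-domain mean of the last six reversal levels of
each staircase (12 values pooled). The interleave schedule and decision
rule are not specified by the source procedure beyond the step/reversal
schedule; strict alternation and 1-up-1-down are the standard choices. In
deterministic mode an exact loudness tie counts as "reference louder",
which biases the converged track upward by at most half a fine step — a
deliberate convention so that a masker balanced against an MCL reference
never lands below MCL (see the null-fidelity argument below).

Both engines take listeners as plain callables bound to their stimulus
context (`audible(level_ua)`, `comparison_louder(level_ua)`); simulated
listeners and replayed sessions provide these closures.

## The simulated listener

Per ear: an unmasked threshold profile (baseline μA plus a low-order
polynomial in place), an MCL profile a fixed headroom (default 10 dB)
above threshold, a logistic psychometric function in dB re threshold
(slope default 8/dB; lapse and guess rates; infinite slope = deterministic
step), and a loudness offset in dB. Loudness comparisons are logistic in
the dB loudness difference (slope default 4/dB).

Masking elevates thresholds additively in μA with a two-sided Gaussian
place profile: gain × exp(−(p−peak)²/2σ²), with separate apical and basal
σ (electrode units) to emulate apical/basal asymmetry, separate
ipsilateral and contralateral gain/σ, and the contralateral peak displaced
from the masker place by an interaural place offset (emulating imperfect
alignment of the two arrays). Masker level scales the gain linearly from 0
at the masker-place threshold to 1 at MCL (clamped outside); the study
condition presents maskers at MCL, i.e. scale 1.

The default cohort draws six subjects around field-plausible centres:
baseline thresholds 150–250 μA with a gentle place slope, ipsilateral peak
gains 60–100 μA, ipsilateral σ 1.6–2.4 electrodes with mild apical/basal
asymmetry, interaural offsets within ±1 electrode, and contralateral
σ and gain at 0.5× and 0.6× the ipsilateral values — a cohort whose
contralateral masking is genuinely sharper and weaker, as the analysis is
meant to detect. The probe grid is 1–13 in 0.5-electrode steps with
maskers at electrodes 3 (apical) and 9 (middle); the masking magnitudes
are order-of-magnitude choices, not calibrated to any particular subject.

What the generator does **not** emulate: biophysical current spread or
neural-survival variation, loudness growth beyond monotone-in-dB,
attention/criterion drift across sessions, or efferent feedback (whose
absence in CI stimulation is the point of the comparison). Passing tests
therefore show that the analysis recovers the statistical structure it
assumes — peaked, asymmetric, psychometrically noisy masking profiles —
not that real listeners satisfy those assumptions.

**Protocol emulation.** `generate_experiment_dataset` measures unmasked
thresholds once per probe place, measures contralateral masked thresholds
per masker location, places the ipsilateral masker at the measured
contralateral peak (absolute-maximum mode by default, Gaussian-fit mode
optionally), balances its level against the contralateral masker with the
double staircase, then measures ipsilateral masked thresholds. Tracking
starts 6 dB below the relevant (estimated) unmasked threshold. Every run
is reproducible from (parameters, design, seed); per-subject streams are
spawned from the design seed.

## Analysis conventions

* **Shift functions** require identical probe-place sets for masked and
  unmasked rows; mismatches raise an alignment error listing the offending
  places — no silent interpolation. Negative shifts are preserved.
* **Range normalization** is min–max to [0, 1]; divide-by-peak is a config
  switch (the two coincide when the minimum shift is 0). A constant
  function is a degenerate-function error. Min–max scaling commutes with
  linear interpolation at measured points, so normalization order is
  immaterial.
* **Interpolation** is piecewise linear between measured points only;
  requests outside the measured span raise an extrapolation error. Windowed
  areas are computed exactly on the piecewise-linear breakpoints (window
  edges included by interpolation), so the `grid_step` (default 0.01
  electrodes) only affects exported resampled functions.
* **Windows** are ±3 electrodes around the contralateral peak for *both*
  functions of a pair; the integral runs over the intersection with the
  measured span and the achieved coverage fraction is reported, keeping
  truncation by array edges or comfort limits visible.
* **Peaks**: default mode is the absolute maximum of measured shifts, with
  ties (plateaus from quantized adaptive estimates) resolved to the mean of
  the tied places — for a symmetric plateau this recovers the true peak
  exactly. The Gaussian mode fits `a + b·exp(−(x−c)²/2σ²)` by bounded
  least squares (initialized at amplitude = max−min, centre = argmax,
  σ = span/2/2.355, baseline = min; centre constrained to the measured
  span) and reports the fitted place and magnitude `a + b`; it falls back
  to absolute mode, with the fallback recorded, when the optimizer fails or
  the RMS residual exceeds 25% of the peak shift. Both modes always report
  the argmax place so Gaussian/absolute discrepancies are visible.
* **Difference measures**: one area ratio and one peak ratio per
  subject × masker location; pooling across locations happens only at the
  inference stage.
* **Peak-aligned averaging** re-indexes each function to place-relative-
  to-peak on a grid anchored at 0 and averages pointwise over functions
  covering each grid point, reporting the contributing count per point.

## Robust inference

The 20% trimmed mean removes `g = floor(0.2·n)` observations per tail
(the Wilcox convention). The percentile bootstrap draws 2000 resamples of
size n with replacement, computes each resample's trimmed mean, sorts
them, and takes the CI bounds directly from order statistics: the
`ceil(α/2·B)`-th and `(B − ceil(α/2·B))`-th smallest — ranks 50 and 1950
at B = 2000, 95% confidence. No interpolation between order statistics is
applied and ties are kept as-is. Significance: the entire interval below
the null ratio of 1. The pooled n is reported with every interval. A
floating-point guard keeps the rank computation exact when `α/2·B` is a
whole number up to rounding error.

Calibration (recomputed by the acceptance script and tests): on Gaussian
n = 12 samples the nominal 95% CI covers the true trimmed mean ≈93–94% of
the time over 1000 replicates — slightly anticonservative, as percentile
bootstraps at small n are known to be.

## Null fidelity and recovery

With identical ipsilateral/contralateral masking parameters, zero
interaural offset and deterministic listeners, the pipeline returns both
difference measures as exactly 1.0: the loudness balance converges at or
marginally above MCL (tie convention above), the masking scale clamps to
1, so ipsilateral and contralateral measurement runs traverse identical
levels and quantization cancels exactly. This symmetric-null check and a
100-replicate stochastic recovery study (sharper-contralateral cohorts;
pooled area trimmed mean below 1 in ≥95% of replicates, observed 100%) are
part of the acceptance report.

## Problem sizes and determinism

Default study sizes — 6 subjects × 25 probe places × (1 unmasked +
2 locations × 2 masked conditions), 100 replicate datasets for the
recovery study, 1000 replicates for bootstrap coverage — were chosen so
the full pipeline and its studies run in seconds on a single core while
keeping Monte-Carlo error well inside the tolerances asserted by the
tests. All stochastic components accept explicit seeds; datasets, analyses
and the acceptance report are bit-reproducible from them.

## Known limitations

* The generator's masking profile is Gaussian by construction, the same
  family the Gaussian peak-fit assumes; fit-quality conclusions on real,
  non-Gaussian masking functions do not follow from these tests.
* Loudness balancing assumes loudness is monotone in dB with a fixed
  interaural offset; real loudness growth functions are compressive and
  place-dependent.
* The percentile bootstrap at n = 12 is mildly anticonservative (see
  coverage above); no multiple-testing correction is applied across the
  two measures.
* Apical/basal asymmetry of the averaged profiles is reported
  descriptively only; the pipeline does not test slope differences.
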