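# cimasking

Analysis pipeline for **contralateral vs. ipsilateral masking in bilateral
cochlear-implant (CI) listeners**, together with a parametric simulated
listener so every stage can be validated end-to-end without human subjects.

## The scientific problem

A masker presented to one ear raises detection thresholds in the opposite
ear (contralateral masking). In acoustic hearing this cross-ear masking
pattern is much sharper and far smaller than same-ear (ipsilateral)
masking, and part of that difference is attributed to medial olivocochlear
(MOC) efferent feedback onto outer hair cells. Cochlear implants bypass
outer hair cells entirely, so comparing the **spatial tuning** of
contralateral and ipsilateral masking functions in bilateral CI users asks
directly which features of contralateral masking survive without the MOC
route.

The measurements this package models and analyses:

* thresholds for 20-ms biphasic pulse-train probes, placed with **current
  steering** at continuous electrode places `p = apical_electrode + α`
  (α = fraction of current on the basal electrode of the pair), on grids as
  fine as 0.1 electrodes;
* a **modified Bekesy tracking** procedure (10 alternating
  ascending/descending sequences; 1 dB steps for the first four, 0.5 dB for
  the final six; threshold = 20% trimmed mean of the final six sequence
  endpoints);
* 500-ms maskers at most-comfortable level (MCL), contralateral maskers at
  fixed electrodes (apical 3, middle 9), the ipsilateral masker placed at
  the **peak of the contralateral masking function** and loudness-balanced
  to the contralateral masker with a **double-staircase** procedure.

## The statistic at its core

For each subject *s* and masker location *l*, the masked threshold shift
function is `Δ(p) = T_masked(p) − T_unmasked(p)` (μA) vs. probe place *p*.
Each function is range-normalized, `Δ̃(p) = (Δ(p) − min Δ)/(max Δ − min Δ)`,
and linearly interpolated between measured points. With `p̂` the place of
the contralateral masking peak, the two difference measures are

```
area ratio  R_area = ∫_{p̂−3}^{p̂+3} Δ̃_contra(p) dp  /  ∫_{p̂−3}^{p̂+3} Δ̃_ipsi(p) dp
peak ratio  R_peak = max Δ_contra / max Δ_ipsi
```

(±3 electrodes ≈ ±3.3 mm; integrals restricted to the measured span, with
the achieved window coverage reported). Ratios below 1 mean sharper /
weaker contralateral masking. The ratios are pooled across masker
locations and summarized by a **20% trimmed mean** with a **percentile
bootstrap** CI (2000 resamples; 95% CI = 50th and 1950th smallest
bootstrap trimmed means); a reduction is significant when the whole CI
lies below 1.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1     # simulate 6 listeners
python analysis/02_masking_functions.py            # masking functions + measures
python analysis/03_pooled_inference.py             # pooled bootstrap inference
python analysis/04_parameter_recovery.py --seed 1  # calibration studies
```

The simulated cohort has genuinely sharper (σ ratio 0.5) and weaker (gain
ratio 0.6) contralateral masking. The analysis prints:

```
area difference measure (contra/ipsi): 20% trimmed mean = 0.722, 95% CI [0.668, 0.782], n = 12 -> significant reduction
peak difference measure (contra/ipsi): 20% trimmed mean = 0.585, 95% CI [0.551, 0.619], n = 12 -> significant reduction
12/12 subject x location cells show a contralateral area reduction
area recovery: pooled trimmed mean < 1 in 100% of 100 replicates (mean 0.713, range 0.654-0.781)
Bekesy tracking: max |error| = 0.250 dB over 20 thresholds
bootstrap CI coverage: 93.4% (nominal 95%)
```

i.e. the pipeline recovers the simulated contralateral sharpening (area
ratio well below 1 in every subject × location cell), its adaptive
tracking is accurate to within half a fine step, and the bootstrap CI has
near-nominal coverage. The same pipeline runs on measured data via the CLI:

```bash
cimask analyze --data thresholds.csv --out results/analysis
cimask report --results results/analysis
```

with `thresholds.csv` in the tidy schema documented in
`cimasking.pipeline_io` (XLSX ingest with a column map is supported).

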