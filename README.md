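# gaitshotgun

Shotgun gait analysis for treadmill walking studies: detect step events by
iterative template matching, compute a large unselected battery of
spatiotemporal, nonlinear and physiological gait measures, and rank the
measures' discriminative relevance with three complementary statistical
routes (ANOVA screening, multinomial logistic regression, partial least
squares regression).

## Who this is for

Movement scientists who record multichannel treadmill data — vertical
ground reaction force F_z, center-of-pressure trajectories COP_x/COP_y,
tri-axial trunk accelerations, surface EMG, breath-by-breath metabolics —
and want an *a-priori-unbiased* answer to "which of the many candidate
measures actually separates my groups or conditions?".  Instead of
pre-selecting a handful of outcomes, the package computes the full catalog
(61 measures for a force-plate + accelerometer + metabolic montage, 113
when breathing frequency and a five-muscle EMG montage are added) and lets
the statistics rank them.

## The method in brief

**Event detection.**  Initial step events come from peaks of F_z (one per
step, separated by at least half a step period estimated from the
spectrum).  They are then refined on a center-of-pressure channel: slice an
epoch of 40% of the mean stride duration around every event, average the
epochs into a template, shift each event to the lag of maximal normalized
cross-correlation between its epoch and the template, and repeat to a fixed
point.  Events are finally anchored at the template maximum (≈ heel
contact).

**Measure catalog.**  Per observation (subject × condition):

- spatiotemporal: mean/CV of step width, stride length, stride duration;
  mean/CV of the signal value at event instants per channel;
- regularity: template mean and across-epoch variance; sample entropy
  (m = 3, tolerance r chosen from {0.01,…,0.07}·SD by minimum estimated
  relative error) of the Hilbert amplitude, and of sin(phase), with its
  standard error;
- long-range correlation: DFA scaling exponent α of the stride-duration
  and event-position series (α = 0.5 white noise, > 0.5 persistent);
- stability: largest Lyapunov exponent (Rosenstein; M = 7, τ = 20 samples)
  of accelerations, EMG envelopes, and their principal components, plus
  the PCA eigenvalue spectra;
- EMG: median frequency of the raw signal; envelope measures after
  140 Hz high-pass → Hilbert rectification → 2 Hz low-pass;
- metabolics: mean/CV of V̇E, V̇O₂, V̇CO₂, RER, BF, HR and the cost of
  transport C_met = V̇O₂ / (body mass × speed) in mL·kg⁻¹·m⁻¹.

**Ranking.**  Route 1: per-measure ANOVA (repeated-measures one-way, or
mixed two-way with a between factor; Bonferroni threshold 0.05/N), keep the
seven smallest-p measures, z-score them, fit a multinomial logistic model,
and order by the Euclidean norm ‖β‖ of each measure's coefficients over all
pairwise category contrasts (for three categories β₁₃, β₂₃ and the derived
β₁₂ = β₁₃ − β₂₃).  Route 2: PLS2 regression of a centered indicator
response on *all* z-scored measures with seven components, ordered by the
norm of each measure's coefficient row.  Both report the in-sample correct
rate (fraction of observations whose arg-max predicted category is right).
For two-condition multi-group designs, each measure is first collapsed to
the per-subject relative difference (x₁ − x₂)/mean(x₁, x₂).

A synthetic study generator with known ground truth (step events,
fractional-Gaussian-noise stride intervals with chosen Hurst exponent,
phase-locked EMG bursts, plantable group/condition effects) makes the whole
pipeline testable end to end.

## Worked example

```python
from gaitshotgun import (study_a_spec, generate_gait_recording, initial_events,
                         refine_events, assign_legs, spatiotemporal_measures)

spec = study_a_spec(duration_s=300.0)          # 5-minute trial, 1 m/s belt
rec, truth = generate_gait_recording(spec, seed=1)

init = initial_events(rec.signals["fz"])       # force-peak estimates
refined, template = refine_events(rec.signals["copy"], init)
events = assign_legs(refined, rec.signals["copx"])
st = spatiotemporal_measures(rec.signals["copx"], rec.signals["copy"],
                             rec.signals["fz"], events, belt_speed=1.0)
```

prints, via the obvious f-strings:

```
detected events: 533 (ground truth: 533)
mean stride duration: 1.125 s (truth 1.125 s)
stride-duration CV: 0.028
mean step width: 11.2 cm (truth 11.2 cm)
DFA alpha of the detected stride series: 0.82 (generator H = 0.75)
```

Every detected step was found, the spatiotemporal means match the
generator's ground truth to the millimeter/millisecond, and the long-range
correlation of the detected stride series tracks the Hurst exponent the
stride intervals were drawn with.

The same flow is available from the shell:

```sh
gaitshotgun simulate --design studyA --seed 42 --out data/
gaitshotgun extract  --data data/ --design data/design.csv --config studyA --out measures.csv
gaitshotgun rank     --measures measures.csv --design data/design.csv --mode studyA --out report/
```

`report/` then holds `anova.csv`, `logistic.csv`, `pls.csv` and a
human-readable `report.txt` with both rankings and correct rates.

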