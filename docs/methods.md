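# Methods

This note documents the models and numerical choices behind `gaitshotgun`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Step-event detection

Initial events are maxima of the vertical ground reaction force above its
60th percentile, separated by at least half a step period; the step rate is
the dominant spectral peak (averaged periodogram, Welch segments of ~1/8 of
the series) of the rectified, detrended force in the 0.6–6 Hz band.  A
spectral peak below three times the median band power raises
"no dominant rhythm" rather than returning a meaningless frequency.

Refinement alternates between (a) averaging epochs (a window of
`window_frac` = 0.4 × the mean stride duration, centered on each event)
into a template and (b) shifting each event by the lag, within ±25% of the
window, that maximizes the *normalized* cross-correlation between its epoch
and the template.  Normalization matters: the unnormalized covariance of an
epoch with the template is not maximized at zero lag even when the epoch
equals the template (a neighboring window with larger variance can win), so
only the normalized form makes exact events a fixed point of the loop.
Ties are broken toward the smallest |lag| (then the negative lag), keeping
the search deterministic.  Convergence is an exact integer fixed point
(tolerance 0 samples) with a cap of 50 iterations and a warning on
non-convergence; two events closer than half a window raise
"event collision".  After convergence all events are shifted uniformly so
each sits at the template maximum, which for center-of-pressure data is
approximately heel contact.  Refinement runs on the anterior–posterior COP
by default: it repeats every step, whereas the mediolateral COP alternates
sign between legs and would cancel in an across-step template.

EMG burst timing is found the same way, initialized with every second
refined force-plate event (a muscle bursts once per stride; the parity
whose events lie nearer the bursts is chosen), without the final
re-anchoring so the electro-mechanical delay between heel contact and
muscle onset is preserved.  All envelope analysis runs at 100 Hz (the
envelope is band-limited to 2 Hz, so decimation from the EMG rate loses
nothing).

## Measures

**Sample entropy** uses embedding length m = 3, Chebyshev distance,
self-matches excluded, on series standardized to unit SD.  Template pairs
are counted once (i < j) for the whole tolerance grid in a single pass
(a numba-compiled loop with early exit; a pure-numpy fallback gives
identical counts).  For each grid tolerance r ∈ {0.01, …, 0.07} the
conditional probability CP = A/B gives SampEn = −ln CP; the standard error
of CP is estimated binomially, σ_CP = √(CP(1−CP)/B), which ignores the
overlap correlation between template pairs and therefore understates the
error somewhat on strongly correlated series — a deliberate simplification;
the selection criterion (minimize max(σ_CP/CP, σ_CP/(CP·SampEn))) is
unaffected in ordering for the signals at hand.  The reported value is the
entropy at the criterion-minimizing tolerance, with its SE.  "Sample
entropy" of a raw signal means the entropy of its analytic (Hilbert)
amplitude; "sample entropy of phase" is computed on sin(φ) of the unwrapped
phase, which removes the 2π wrap discontinuity — the phase representation
is a documented package default, since wrapped, unwrapped and detrended
phase are all defensible.  With this narrow tolerance grid, white-noise-like
series of a few thousand samples can have no m = 3 matches at any grid
tolerance; the result is then missing (NaN) with a warning, which is the
faithful behavior rather than a defect.

**DFA** integrates the mean-centered series, uses ~20 log-spaced
non-overlapping box sizes in [4, N/4], first-order detrending per box, and
fits a single slope to log F(n) vs log n over all box sizes (no crossover
splitting).  Series shorter than 64 samples are refused; at 30-second
trials the stride-duration series is therefore missing its α and the
catalog carries a NaN there.

**Lyapunov (Rosenstein)** delay-embeds with M = 7, τ = 20 samples by
default; the temporal (Theiler) exclusion window is one mean period
(reciprocal of the spectral mean frequency) and the divergence slope is fit
from 0 to half a mean period, divided by the sample interval (units 1/s).
Distances are floored at 10⁻¹² of the embedding scale so noise-free
periodic signals yield a flat divergence curve (λ ≈ 0) instead of amplified
rounding error.  Both the exclusion window and the fit range are exposed as
parameters; map-like data (e.g. the chaotic logistic map used as a
calibration oracle) needs a short fit range before the curve saturates.

**PCA** eigen-decomposes the channel covariance of mean-centered signals
and reports eigenvalues as fractions of total variance plus the component
time series for downstream Lyapunov analysis.

**Metabolics.**  C_met = mean V̇O₂ (mL/min) / (body mass (kg) × speed
(m/min)), i.e. mL O₂ per kg per meter.  The per-breath C_met series is
V̇O₂ divided by a constant, so its CV equals the CV of V̇O₂ and is reported
as such.

**Catalog layout.**  Names follow `modality.measure.channel`
(`force_plate.sampen_phase.copy`); channel-less measures use two parts.
The force-plate block has 34 columns, accelerometer 15, metabolics 12 (six
variables) or 14 (adding breathing frequency), EMG 50 (ten families × five
muscles, with the PCA-eigenvalue and PC-Lyapunov families indexed by
component instead of muscle) — 61 columns for the one-group configuration
and 113 for the full montage.  Accelerometer entropy is computed on the
Hilbert amplitude and no phase-entropy columns are emitted for it, matching
the catalog definition this package follows.  "Event position" is the
signal value at the refined event instants (the main alternative — temporal
position within the cycle — is not implemented).  Legs are pooled; per-leg
qualified columns are emitted only when a manifest declares leg identity,
which the synthetic manifests do not.

## Statistical ranking

The repeated-measures one-way ANOVA uses the subject × condition
interaction as error; the mixed two-way ANOVA tests the group effect
against subjects-within-groups and condition/interaction against the
within-subject residual (verified against an independent implementation to
nine digits, including unbalanced groups).  Partial η² =
SS_effect/(SS_effect + SS_error).  A zero error variance under a non-zero
effect is reported as F = ∞, p = 0; a fully degenerate 0/0 case as F = 0,
p = 1.  The Bonferroni threshold is exactly 0.05/N for the family of N
measures analyzed.

The multinomial logistic model is fit by Newton–Raphson with intercepts and
a numerically negligible ridge (10⁻⁸).  If the fit fails to converge in 100
iterations, or converges with a coefficient magnitude beyond 30 on z-scored
predictors (a diagnostic of quasi-separation: such log-odds are not
interpretable), it is refit with an escalating ridge (10⁻⁴, then 10⁻²) and
flagged — in-sample maximum likelihood on small samples separates easily,
and unbounded coefficients would dominate the ‖β‖ ranking with noise.
Intercepts are excluded from ‖β‖.  The reference category defaults to the
last in sorted order; the ‖β‖ over *all* pairwise contrasts is invariant to
that choice.  Wald p-values come from the inverse Hessian.  Prediction ties
are broken toward the reference category.

PLS2 uses NIPALS deflation on column-centered, unit-variance X and a
centered indicator Y; scores are mutually orthogonal, X = T Pᵗ + δ holds to
machine precision, and at full rank the predictions coincide with ordinary
least squares.  The coefficient matrix is β = W(PᵗW)⁻¹Qᵗ.

Selection default is the k = 7 most significant measures (smallest p, ties
by larger η² then name); the alternative threshold mode (p < 0.05/N) is a
flag.  In two-condition multi-group mode the observations entering both
regressions are per-subject relative differences, screened by a
between-subjects one-way ANOVA; the mixed two-way table on the raw
measures is attached to the report separately.  Note that this transform
cancels any pure group main effect by construction — the group signal this
design detects is a group-dependent condition *response* — and that the
in-sample correct rate is not monotone in the number of included measures
(the in-sample likelihood is).

## Synthetic generator

Stride intervals are `mean + SD · fGn(H)` with fractional Gaussian noise
from circulant embedding (Davies–Harte), whose second-order structure is
exact — verified against the closed-form autocovariance — making the stride
series a trustworthy oracle for the correlation analyses.  Defaults emulate
the target study conditions: 1.1 s stride period with 3% stride-to-stride
CV and H = 0.75 (healthy treadmill walking), 0.10 m step width, 100 Hz
force/COP/acceleration sampling, 735 N body weight with an asymmetric
double-bump force profile per step, per-step sawtooth anterior–posterior
COP, smoothed-alternating mediolateral COP, harmonic trunk accelerations
with additive noise, five muscles with stride-phase-locked band-limited
(150–400 Hz at 1 kHz) noise bursts, and per-breath metabolic variables with
6% within-trial and 10% between-subject CV.  The one-group spec has 14
subjects × 3 conditions × 5 min; the three-group spec 19 + 19 + 19 subjects
× 2 conditions × 4 min.  Group/condition effects are planted by shifting
generator parameters in units of their between-subject SD.

The generator reproduces the *structure* real recordings share —
quasi-periodicity with known events, long-memory stride fluctuations,
burst-like EMG, plantable effects — not the morphology of pathological
gait: no asymmetry beyond a small step-split jitter, no nonstationarity,
drift, missing data or movement artifacts, and measurement noise is
Gaussian.  Passing tests therefore certify the estimators and the
statistical machinery, not clinical sensitivity on real populations.

A second, measure-level generator draws the wide measure table directly
from a subject-random-effects model (baseline 10, subject SD 1, residual
SD 1, so measures are positive and relative differences well-behaved).
It exists because exercising the ranking layer over 50 seeds × 57 subjects
through full signal synthesis would be disproportionate; the statistical
layer sees statistically equivalent input either way.

## Problem sizes used in tests

Signal-level tests run 30–120-second recordings (300 s for the long
worked example); DFA calibration uses 20 series of 10⁴ samples; ranking
simulations use 10–50 seeds of the measure-level generator at the study
design sizes above.  These sizes were chosen to make the expected effects
statistically decisive while keeping the default suite quick.

## Known limitations

- The binomial SampEn error bar ignores template-pair overlap (see above).
- Step width from |ΔCOP_x| between successive contralateral events is a
  treadmill proxy, not a kinematic marker measurement; stride length is
  belt speed × stride duration and is missing when no belt speed is given.
- The mixed ANOVA assumes sphericity (no Greenhouse–Geisser correction);
  with two conditions this is moot.
- In-sample correct rates are optimistic by construction; the designs are
  too small for a train/test split, and no PLS coefficient significance
  test is provided.
- EMG events assume one burst per muscle per stride; muscles with double
  bursts would need a different initialization parity per burst.
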