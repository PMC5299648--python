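# Methods

## Model

A recording period's signal-averaged beat is treated as a discrete-time
signal, and the relation between an earlier period's beat `x` and a later
period's beat `y` is modelled as a rational transfer function in `z` with a
monic denominator and no feedthrough,

    y = G x,   G(z) = B(z) / A(z),   deg B <= deg A - 1,

estimated in the output-error sense: the parameters minimise
`sum_t (y[t] - sim(G, x)[t])^2`, where `sim` runs the difference equation
with zero initial conditions. Goodness of fit (GF) is the normalised-RMS
score `100 (1 - ||y - y_sim|| / ||y - mean(y)||)`; it is invariant under
joint affine maps of both signals and equals 100 only for a perfect
simulation.

Zero initial conditions are an explicit modelling choice rather than a
nuisance: SAECGs are referenced to their isoelectric baseline (see below),
so the system is genuinely at rest at the window start, and co-estimating
`m` initial states would add free parameters with no physiological meaning.

## Preprocessing

* **Band-pass 0.5–45 Hz**, 4th-order Butterworth applied forward–backward
  (zero phase). The band keeps the diagnostic ECG content; the 0.5 Hz edge
  removes baseline wander, the 45 Hz edge mains and muscle noise.
* **R-peak detection**: derivative → squaring → 150 ms moving-window
  integration → adaptive two-level threshold with a 250 ms refractory
  period, refined to the local maximum of the filtered signal within
  ±50 ms. The running signal/noise levels are initialised from the
  25th/75th percentiles of all candidate peak heights rather than from the
  head of the recording — a single large artifact beat early on would
  otherwise freeze the threshold above every normal beat (the detector has
  no search-back stage).
* **Segmentation**: beat length `L = round(fs * mean RR)` from the realized
  peaks, window anchored 35 % before the R peak (covers the P wave and the
  full T wave); boundary windows are dropped.
* **Artifact rejection**: one pass; a beat is abnormal iff its peak
  absolute amplitude exceeds 2x that of the mean beat. "Amplitude" is read
  as the max absolute sample; the rule is scale-equivariant and is not
  iterated after recomputing the mean.
* **Averaging**: beats are already R-aligned by construction; each window
  may additionally slide by up to ±2 samples to maximise correlation with
  the ensemble mean (micro-alignment, standard in high-resolution SAECG
  work). Under measurement noise the per-beat R argmax wobbles by a sample;
  without micro-alignment that jitter adds a smoothing bias to the average
  that dominates the noise floor. The averaged beat is finally baseline-
  corrected to the mean of its leading 20 ms (pre-P isoelectric segment).
  The high-pass leaves every beat riding on a small negative DC offset, and
  an SAECG that starts at a nonzero level breaks the zero-initial-condition
  simulation with an irreducible head transient (GF saturates near 95 even
  on noise-free data); referencing to the isoelectric level removes it.

## Estimation

Two stages, with the second never accepting a cost increase:

1. **Initialisation.** Equation-error (ARX) linear least squares on the
   zero-padded difference equation, followed by Steiglitz–McBride-style
   re-solves on data prefiltered by `1/A` of the previous estimate. Any
   estimate whose poles leave the unit circle is pole-reflected
   (`r -> 1/conj(r)`) before being used as a prefilter, and a pure-FIR
   least-squares solution is kept as a guaranteed-finite fallback. The
   candidate with the lowest simulation cost starts stage 2. On noise-free
   data the plain ARX solution is exact, so recovery there is to machine
   precision.
2. **Refinement.** Damped Gauss–Newton (Levenberg–Marquardt) on the
   simulation error with an analytic Jacobian (filtered, delayed copies of
   the input and of the simulated output). Damping x10 on rejection, x0.1
   on acceptance; stop at relative cost change < 1e-8 or 100 iterations.
   The step matrix carries a constant Tikhonov floor of `1e-3` times the
   mean curvature. This floor regularises the *trajectory only* — a
   converged point still has zero gradient of the unmodified cost — but it
   suppresses steps along near-flat directions. Those flat directions are
   real: a band-limited beat leaves the out-of-band response of the model
   unconstrained, so coefficient vectors far apart can fit equally well.
   Without the floor, per-subject fits drift to scattered points of that
   valley and coefficient-averaged generalized models become meaningless or
   unstable; with it, fits stay clustered near their (similar)
   initialisations.

No stability constraint is imposed during estimation (the simulation window
is finite); stability is reported as a diagnostic, and an unstable model
whose evaluation simulation overflows is scored NaN and excluded from
column means.

## Order selection

The grid covers all no-feedthrough combinations with denominator order up
to 5 (15 combinations). Each subject x pair x combination cell records the
GF of the estimated model; failed cells are excluded from means (never
zero-filled). The optimized order maximises the mean GF over pairs and
subjects (unweighted mean of pair means), with mean GFs compared at a
granularity of **0.1 GF points** and ties resolved toward the smaller
denominator, then numerator, order. The granularity is a deliberate part
of the selection rule: the systematic advantage of an over-ordered model
under observation noise is of order 0.01 GF points — far below run-to-run
variability — and an exact argmax would therefore essentially always pick
the largest order in the grid. Treating sub-0.1 differences as ties is what
makes the rule recover a true generating order (measured: 0/20 recoveries
of a (2,3) truth at 40 dB noise with an exact argmax, ~85–95/100 with the
0.1 granularity). An exact scan remains available (`decimals=None`).

## Generalization

ITFs at the optimized order are averaged coefficient-wise per period pair
(well-defined because every denominator is monic; the mean denominator is
monic too and no-feedthrough structure is preserved). Evaluation simulates
each subject's own aligned input SAECG through the subject's ITF and
through the pair GTF, scoring both against the measured output SAECG;
column means and sample SDs (n−1) plus the mean ITF−GTF difference make up
the subject table. The difference may take either sign.

## Synthetic trials

The generator emulates a 14-subject, three-period, single-lead design with
5-minute recordings at 1024 Hz, scaled by default to 60 s at 256 Hz to keep
routine analysis fast (all parameters configurable up to the full-scale
values). Ingredients:

* **Beat morphology**: sum of five Gaussians (P, Q, R, S, T) with typical
  lead-II amplitudes and timings, R placed 35 % into the window to match
  the segmentation convention.
* **Rhythm and noise**: RR = 60/HR + N(0, 20 ms); white noise of 0.02 mV;
  0.2 Hz sinusoidal baseline wander of 0.1 mV (inside the high-pass
  stopband, so the filter is exercised); artifact beats scaled x3 with
  probability 0.02 per beat (guaranteed to trip the x2 rejection rule).
* **Intervention**: the during/after beat equals the before beat passed
  through a known ground-truth transfer function, so estimation targets
  are exact. The default pair TFs (orders 4/5, DC gain 1) are built by
  prescribing the early impulse response — a dominant lag-1 tap followed by
  a negative lobe. The negative lobe is load-bearing: R-peak alignment of
  the SAECG pair cancels any shift of the output's R argmax, so a
  no-feedthrough ground truth is recoverable only if its response leaves
  the discrete argmax in place. The default dynamics beyond 2nd order are
  deliberately weak; on noise-free data the saturated grid is then
  parsimony-equivalent above order (1,2), while under the default
  measurement noise the grid reproduces the familiar pattern of monotone
  improvement up to (4,5). (A variant with strong 5th-order poles makes the
  order identifiable even noise-free, but destabilises noisy estimation —
  per-subject fits split between local minima and the averaged model can
  leave the unit circle — and implies unphysiologically large beat
  changes.)
* **Subject heterogeneity**: one knob (`subject_variation_sd`, default
  0.005) scales both multiplicative Gaussian perturbation of the
  ground-truth TF coefficients and the perturbation of the template's wave
  amplitudes/timings/widths. The default was calibrated once so the
  resulting ITF-vs-GTF mean GF differences (~0.5–2 points) sit at the scale
  reported for the original trial (0.23 / 0.98 / 1.47); it was not revised
  afterwards.
* **Seeding**: hierarchical (master seed, subject index, period index) so
  adding subjects never reshuffles earlier ones; identical config + seed is
  bit-identical.

What the generator does **not** emulate: real HRV spectra and
respiration coupling, multi-lead geometry, pathological beats, electrode
artifacts other than amplitude scaling, and — most importantly — real
between-subject morphology diversity. Real R amplitudes vary tens of
percent across people; the default heterogeneity is far smaller, because
coefficient-averaged GTFs degrade sharply once subjects differ enough for
their (partly non-identifiable) coefficient estimates to de-cluster, with
`subject_variation_sd` around 0.02 the averaged model can even go unstable.
Passing tests therefore demonstrate correctness of the pipeline's
operations and its behaviour in the regime the original analysis reports
(small ITF-vs-GTF differences), not robustness of coefficient averaging to
realistic population heterogeneity — a known limitation of the method
itself.

## Numerical choices and degenerate inputs

* GF of identical vectors returns exactly 100.0; a constant reference
  signal raises a degenerate-data error (zero norm).
* `estimate_tf` requires more than `10 * den_order` samples and a
  non-constant output; simulation raises an instability error naming the
  first non-finite sample.
* Grid cells and subjects fail independently: a failed cell is excluded
  from means with a warning, a failed subject is excluded from the trial
  (the run aborts below two subjects).
* Reports round to 2 decimals (the conventional table precision); full
  precision is written to companion JSON so rounding never propagates.
* Alignment of an SAECG pair requires a 10-sample overlap; averaging mixed
  model orders is a parameter error.

## Scale of routine runs

Default test and acceptance runs use 20–60 s periods at 256 Hz with 1–14
subjects; the full pipeline on a 14-subject, 60 s trial completes in well
under a minute on one core. These sizes were chosen as the package's
standard quick-analysis configuration; the full-scale study geometry
(300 s at 1024 Hz) runs through the identical code path via `TrialConfig`.
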