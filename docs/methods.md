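# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phasecode`. It is the package's account of *why* the code
does what it does; the README covers *how* to run it.

## Scientific setting

Human medial-temporal-lobe (MTL) micro-electrode recordings during virtual
navigation yield two simultaneous signals per site: spike trains of sorted
units and the local field potential (LFP). Two coding schemes are of
interest beyond plain firing-rate modulation:

* **Phase locking** — a unit fires preferentially at one phase of a
  narrowband LFP oscillation, regardless of behavior.
* **Phase coding** — the *preferred phase itself* depends on a behavioral
  variable, here the prospective navigational goal (one of six delivery
  targets). A phase-coding cell can show no rate change at all.

Human MTL oscillations are slower (~3 Hz "slow theta") and far less
stationary than rodent theta, so both analyses are conditioned on an
oscillation actually being present, at a frequency discovered per channel
rather than imposed a priori.

## Pipeline

### Artifact rejection

Epileptiform transients corrupt both phase estimates and spike trains.
A sample is marked bad when either envelope criterion fires:

* **A (slow/large events)**: `|hilbert(lowpass_80Hz(x))|` exceeds its
  session mean + 4 SD. The 80 Hz low-pass (4th-order Butterworth,
  zero-phase) removes spike-waveform contamination first.
* **B (fast events)**: `|hilbert(bandpass_25_80Hz(x))|` exceeds its
  session mean + 4 SD.

Contiguous bad samples become intervals, and any surviving good epoch
shorter than 1 s is conservatively flipped to bad. Baseline and SD are
single-pass session statistics (no iterative re-estimation).

Design notes. For criterion B we take the standard analytic envelope of
the band-passed trace; rectification is implicit in the magnitude. An
explicit rectify-then-envelope double transform was evaluated and roughly
doubles the threshold-event rate on artifact-free noise, which the
sub-second merge rule then amplifies to ~4–8% excluded time; the analytic
envelope keeps artifact-free exclusion near 1–2%, in line with the
envelope-tail expectation of a 4 SD rule. Because threshold events cluster
and the merge rule absorbs sub-second gaps, *white* noise (fast-moving
envelope) excludes a few percent while 1/f-like signals exclude ~1%.

### Adaptive band discovery and phase tracking (MODAL)

1. **Spectrogram** — 6-cycle Morlet wavelet power at 1–50 Hz in 0.5 Hz
   steps, unit-energy wavelets, log10 units. Bad epochs are excluded from
   all averages.
2. **Aperiodic background** — power is averaged over time (linear units),
   log-transformed, and a robust line (IRLS, Tukey bisquare, c = 4.685,
   MAD scale — the conventional `robustfit` configuration) is fit against
   log10 frequency. Averaging power rather than log-power matters: the
   fitted line then sits at the *mean power* level, which is the right
   reference for the per-sample gating below (a mean-log line sits ~0.25
   log10 lower and passes ~57% of oscillation-free samples instead of
   1/e ≈ 37%).
3. **Bands** — maximal runs of ≥ 2 contiguous bins whose spectrum exceeds
   the fit by a detection margin (default 0.15 log10 ≈ 1.4× power). The
   margin exists because the wavelet-estimated spectrum of an exact power
   law is not perfectly log-log linear: smooth curvature residuals of up
   to ~0.12 log10 straddle any fitted line, so with a zero margin roughly
   half of all bins sit above it and every aperiodic channel sprouts wide
   spurious bands. 0.15 is an upper envelope of that curvature and far
   below a genuine narrowband excess (a 2× amplitude oscillation adds
   ~+0.7 log10 in-band). `margin=0` restores the strict exceedance rule.
4. **Frequency sliding** — per band, the artifact-masked trace is
   band-passed with a zero-phase FIR (plateau passband, 15% transition
   zones, ~3 cycles of the lower edge long), the analytic angle gives
   phase, and the derivative of unwrapped phase gives instantaneous
   frequency, median-filtered over 10 log-spaced windows (10–400 ms) and
   averaged. Samples whose frequency leaves the band are "phase slips"
   and marked invalid. Phase convention: 0 at the filtered-signal peak,
   ±π at the trough, −π/2 on the ascending zero crossing.
5. **Detection gating** — spectra and fits are recomputed in 10 s
   non-overlapping windows; a sample stays valid only while its
   instantaneous power at the bin nearest its instantaneous frequency
   exceeds the window's fit line.

Limitation: instantaneous Morlet power is chi-square(2) distributed, so
oscillation-free samples exceed the mean-power line with probability
1/e ≈ 0.37. Gating therefore *enriches* valid samples toward genuine
oscillatory bouts (empirically ~0.85 valid when the oscillation is always
on, ~0.36 when absent) but cannot push false detections to zero; analyses
downstream treat validity as a weighting of evidence, not proof of an
oscillation at every sample. Downstream phase analyses are restricted to
bands intersecting 1–10 Hz by default (10–30 Hz available for the
alpha/beta variant).

### Phase-locking statistics

Spike phases are looked up at the nearest LFP sample (≤ 0.25 ms error at
2 kHz); spikes on invalid samples are dropped. Locking is tested with the
Rayleigh test using the standard approximation
`p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n))`, thresholded at
p < 0.005 per band — stricter than a Bonferroni-corrected 0.05 across the
1–2 bands typical per channel. Two controls:

* **Watson–Williams** against all valid LFP phases of the band (circular
  one-way ANOVA with the `1 + 3/(8κ̂)` correction). A non-sinusoidal
  waveform distorts the LFP phase distribution itself; a unit is only
  interesting if its preference differs from that baseline. The F
  approximation degrades when either group's resultant length is ≤ 0.45,
  which is flagged (not fatal) on the result.
* **Frequency specificity** — locked in exactly one band at p < 0.005
  with p > 0.1 in every other band.

### Goal decoding from spike phase

Each spike contributes features `(sin φ, cos φ)` and the label of its
delivery; deliveries are half-open `[start, end)` and split at the
midpoint into planning/arrival halves. The decoder is multinomial
logistic regression (L2, fixed C = 1) with stratified 5-fold CV
(chronological folds when a class has fewer members than folds), accuracy
pooled over held-out folds.

Chance level varies with the per-cell label distribution, so significance
is permutation-based: the chronologically ordered label vector is rotated
by a random offset in `[1, n−1]` — preserving exact class counts and the
labels' block structure across deliveries — and the full CV decode is
re-run; `p = (1 + #{null ≥ obs}) / (1 + n_perm)` (add-one rule, p never
0). Defaults: 500 rotations for single-cell inference, fewer acceptable
for calibration sweeps. Sub-seeds are derived deterministically from a
master seed and the unit id.

The HFA variant detects high-frequency-activity events (65–120 Hz
analytic power z-scored over good samples, runs above z = 1.96, event =
run center) and feeds the event times through the identical machinery.

### Rate analyses

Per-half-delivery rates (Hz, not counts — half durations are equal within
but not across deliveries) enter a two-way fixed-effects ANOVA, factors
goal × period plus interaction, type-II sums of squares; the interaction
is dropped (with a flag) if a design cell is empty. Population prevalence
of significant cells is tested with exact upper-tail binomial tests at
the per-test alpha; regional enrichment and coding-overlap with
chi-square tests of independence; behavioral learning with a
Kruskal–Wallis test over chronological quintiles of drive time. The
HFA–rate control correlates z-scored HFA power with the spike train
convolved with a 500 ms Gaussian kernel (SD = 250 ms; boxcar available),
circular-rotation shuffle p-values.

## Synthetic ground truth

The generator exists so every stage has an oracle with known truth:

* **LFP** — Gaussian 1/f^χ background (spectrally shaped white noise,
  χ = 1 default) plus, per band, an amplitude-modulated sinusoid whose
  instantaneous frequency wanders slowly (smoothed Gaussian drive, hard
  clipped) inside `f_center ± f_halfwidth`. `amplitude` is the
  oscillation RMS relative to the in-band background RMS (default 2).
  Bouts follow an alternating renewal process with exponential bout/gap
  durations (mean bout 10 s) matching the premise that these oscillations
  are intermittent; 50 ms raised-cosine ramps avoid onset clicks.
* **Artifacts** — raised-cosine transients scaled in units of the
  artifact-free signal SD, directly exercising the 4 SD rule.
* **Task** — gamma-distributed delivery durations (shape 4) rescaled to
  tile the session; 73 deliveries per session by default (the task's
  typical count); goals uniform on 1–6 excluding immediate repeats.
* **Spikes** — inhomogeneous Poisson by thinning with intensity
  `λ0 · g(goal) · exp(κ cos(φ − μ_goal)) / I0(κ)` during bouts (von
  Mises phase modulation, the standard circular analog of phase locking,
  which makes κ recovery testable) and `λ0 · g(goal)` otherwise. Outside
  deliveries the goal is undefined and the unit fires at λ0.
  `modulate_period` restricts the modulation to one delivery half for
  period-specificity experiments.

What the generator does *not* emulate: non-sinusoidal waveform shape,
cross-frequency coupling, spike-sorting errors, non-Poisson firing
(bursting, refractoriness), electrode drift, and genuinely epileptiform
morphology (artifacts are smooth bumps). Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to every pathology of real intracranial data.

## Problem sizes and numerical choices

Simulation-based tests use 60–600 s sessions at 2 kHz (500 Hz where only
the decoding stage is exercised), 50–100 units for calibration sweeps,
and 100–500 permutations depending on the p-value resolution a check
needs; these sizes keep every Monte-Carlo estimate's sampling error well
inside the asserted tolerance. Times are float64 seconds throughout;
sample lookup is `round((t − t0)·fs)`; intervals are half-open. LFP
samples are stored float32 on disk (spike times and labels round-trip
exactly as text). The spectrogram is float32 in memory (~48 MB per
channel-minute at 2 kHz). Ties in permutation ranks count toward the
null (conservative); the add-one rule keeps p > 0.
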