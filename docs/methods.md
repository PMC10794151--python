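# Methods

## The measurement problem

Whole-cell voltage-clamp recordings from cells with small sodium currents
(tens to a few hundred pA, e.g. chondrocytes and other non-excitable cells)
are characterized through a fixed chain: leak/capacitance correction (P/4),
run averaging, baseline referencing, pharmacological isolation of the
channel of interest by trace subtraction (tetrodotoxin separates TTX-S from
TTX-R current; 20 nM ProTx II isolates the Na_v1.7 component), a peak I-V
curve, the chord-conductance transform G(V) = |I_peak| / |V - E_r|, a
Boltzmann fit of G/G_max, single-exponential fits of the falling phase, and
channel-density arithmetic from cited single-channel constants.  navclamp
implements that chain end to end and pairs it with a closed-form simulator
so every stage is testable without recording hardware.

## Gating model

Each channel pool follows Hodgkin-Huxley-style first-order gating,

    I_pool(t) = g_eff * m(t) * h(t) * (V - E_rev),
    m_inf(V) = 1 / (1 + exp((V_1/2,m - V) / k_m)),
    h_inf(V) = 1 / (1 + exp((V - V_1/2,h) / k_h)),
    dm/dt = (m_inf - m) / tau_m(V),   dh/dt = (h_inf - h) / tau_h(V),

with one addition: a voltage-dependent **first latency** L(V).  After a
voltage transition the gates hold their pre-step values for L(V) before
relaxing.  The latency is not cosmetic.  For a latency-free first-order
m*h current with h decaying toward ~0, the peak time is
tau_m * ln(1 + tau_h/tau_m), which is strictly below tau_h, while the
post-peak single-exponential fit returns a value at or slightly above
tau_h.  Measured fast sodium currents, however, peak *later* than their
fitted decay constant (time-to-peak 1.4 ms vs tau 1.0 ms at 0 mV; 0.5 vs
0.3 ms at +50 mV).  No choice of tau_m can reconcile the two; a rest-state
dwell before activation can, and is the minimal phenomenological stand-in
for the multi-step activation path of real channels.  Single-channel
recordings show exactly such first latencies.

Because the command voltage is piecewise constant under a step protocol,
every gate trajectory has an exact exponential solution per segment; the
simulator evaluates those closed forms on the 100 kHz sample grid.  There
is no integration error, only sampling of a continuous trace (halving the
sample interval moves the sampled peak by < 0.1%, which is tested).

Three pools share the gating machinery:

| pool          | blocked by            | inactivation              |
|---------------|-----------------------|---------------------------|
| `g_nav17`     | TTX and ProTx II      | fast (tau_h table)        |
| `g_ttxs_other`| TTX only              | fast (tau_h table)        |
| `g_ttxr`      | neither               | slow (tau_h x 36)         |

plus an ohmic leak `g_leak`.  The slow TTX-R pool supplies the persistent
(slow-inactivating) current read out at 10 ms.  Drugs act as static
conductance scale factors; wash-in kinetics are out of scope.

Time-constant and latency tables are anchored at -20, 0 and +50 mV and
interpolated log-linearly in voltage (latencies linearly), clamped at the
outermost anchors.  Steady-state inactivation is not characterized by the
published experiments; the defaults (midpoint -70 mV, slope 7 mV) are
stated, not inferred, and give h ~ 0.95 at the -90 mV holding potential.

## Calibration

The published gating numbers are *apparent* values - outputs of the full
measurement chain, not microscopic constants.  `calibrate_gating` therefore
runs the complete noise-free pipeline (simulate control + saturating TTX,
P/4, average, baseline, subtract, I-V, G/G_max with the simulator's
reversal, Boltzmann fit, falling-phase fits, refined time-to-peak) as its
oracle, and iterates:

* `v_half_m += target_V1/2 - fitted_V1/2`, `k_m *= target_k / fitted_k`;
* `tau_h(Va) *= target_tau(Va) / fitted_tau(Va)` per anchor;
* `tau_m(Va) = tau_h(Va) / 10` (fixed ratio);
* `L(Va) += target_ttp(Va) - measured_ttp(Va)`.

Fixing tau_m at tau_h/10 makes the peak-erosion factor (the fraction of
the peak conductance lost to inactivation by the time the current peaks)
essentially voltage independent, so the apparent activation curve is an
undistorted Boltzmann and the loop converges in a handful of iterations
(tolerances 0.02 mV / 0.01 ms, bounded at 30 iterations, residuals reported
on failure).  A parameter set that already satisfies the targets passes
through unchanged.  The calibrated set is cached per process and serves as
the package default (`default_params()`); the fitted tau differs from the
simulator's tau_h by less than 5% at voltages >= -20 mV, which is asserted
as an invariant.

Default targets: V1/2 = -14.2 mV, k = 6.1 mV; tau = 3.3 / 1.0 / 0.3 ms and
time-to-peak = 1.8 / 1.4 / 0.5 ms at -20 / 0 / +50 mV.

## Default parameter choices

* **Amplitudes.** The default cell is a high-expressing representative
  (TTX-S peak ~300 pA at 0 mV, within the observed "tens to hundreds of pA"
  range) rather than the 82-87 pA responder *mean*.  The reason is the
  activation threshold: with the activation curve pinned at (-14.2, 6.1), a
  87 pA cell carries only ~2 pA at -40 mV, below any sensible detection
  criterion, whereas the reported currents begin to activate at -40 mV.
  The default amplitude puts ~8 pA at -40 mV and ~1.7 pA at -50 mV, so the
  5 pA criterion (about 2.5x the 2 pA noise s.d.) lands the threshold at
  exactly -40 mV.  Pool split: Na_v1.7 : other-TTX-S : TTX-R =
  5.1 : 2.8 : 3.3 nS, matching the published fractions (TTX-S ~62% of the
  total current, ProTx II-S ~40%).
* **Reversal potentials.**  The simulator uses E_rev = +65 mV, near the
  Nernst potential for the 145/10 mM Na+ gradient of the recording
  solutions (+67.8 mV at 294 K); a conductance reversing at the published
  E_r = -60.6 mV could not carry inward current at 0 mV.  The printed
  -60.6 mV is retained verbatim as an analysis-side constant ("published"
  reversal mode) because the published conductance-density and
  channel-count arithmetic is built on it.  The mode is an explicit config
  field, never inferred.
* **Noise** is additive white Gaussian, sigma = 2 pA, matching the visual
  noise floor of small-current recordings; every stochastic operation takes
  an explicit seed, and per-sweep seeds derive from
  `SeedSequence((master_seed, sweep_counter))`.
* **Filtering.**  The 2 kHz low-pass character can be emulated by a
  Gaussian kernel (sigma_t = 0.1325 / f_c); it is off by default so
  analysis tests see the unsmoothed model.  Capacitive edge transients
  (linear RC, R_s = 10 MOhm) are likewise optional and default-off, since
  published traces are shown post-compensation; they are linear in the step
  amplitude, so the P/4 correction removes them exactly, which is tested.

## Preprocessing conventions

P/4 subpulses are quarter-amplitude steps delivered from the subsweep
holding level in the same polarity as the main step; each subsweep is
referenced to its own pre-step baseline and their sum forms the linear
template subtracted from the main sweep.  Correction is applied per repeat,
then repeats are averaged, then the average is baseline-referenced to the
final 5 ms before step onset (whether the published analysis corrected
before or after averaging is unstated; per-repeat correction is this
package's choice and is exact for linear components either way).  The peak
search window is step onset to onset + 10 ms - it covers every observed
time-to-peak while excluding the off-step transient.  The persistent
current is the mean over a +/-0.25 ms window centred 10 ms after onset
(the published definition does not say whether the readout was
instantaneous; a short mean is robust to noise and changes the noise-free
value by < 0.1%).

## Fits

The Boltzmann fit runs bounded least squares over (V1/2, k, amplitude) with
the amplitude constrained to [0.8, 1.2] (the curve is already normalized;
the free amplitude absorbs the finite-grid maximum), initial guesses from
the half-maximum crossing and the 10-90% rise width, and a warning flag
when k pins at a bound.  Chord conductance uses |V - E_r|, so the result is
positive under either sign convention, and points with driving force below
5 mV are excluded.  The falling-phase fit is a single exponential
A*exp(-(t - t_peak)/tau) + C from the measured peak to the step end -
single because that is how the source data were characterized, window
maximal because the model has a single fast inactivation process.
Time-to-peak uses 3-point parabolic refinement; at 100 kHz this moves
values by < 0.01 ms.

## Channel-density arithmetic

The chain current density -> conductance density -> channels is pure
dimensional bookkeeping around two cited constants (gamma = 6.4 pS,
P_o = 0.4-0.6 at 0 mV) and a textbook specific capacitance of 1 uF/cm^2 =
0.01 pF/um^2.  The per-cell count multiplies the *2-decimal-rounded* areal
density by a default cell area of 3500 um^2; that area is back-solved so
densities of 0.10 and 0.15 /um^2 give exactly 350 and 525 channels - it is
a reconstruction of the published endpoints, not a measurement, and the
unrounded product is logged alongside.  "Paper-arithmetic" mode carries the
printed intermediates (E_r = -60.6 mV, 2.4 pA/pF) rather than recomputing
them per cell, so the published derivation is reproducible digit for digit;
the computed intermediate 2400/60.6 = 39.60 pS/pF differs from the printed
39.7 only by rounding.

## Cohort generator

`generate_cohort` plants an exact number of responder cells (fast gating,
peak drawn uniformly from 40-124 pA, mean ~82 pA) among non-responders of
two phenotypes: low-amplitude cells (3-22 pA, safely below the 30 pA
boundary even after noise) and slow-inactivating cells (tau_h scaled x8,
so tau(0 mV) ~ 8 ms exceeds the 5 ms fast cutoff while the amplitude may be
large).  Per-cell capacitance is uniform on 25-45 pF.  The responder
classifier demands a measured peak strictly above 30 pA *and* a fitted
tau at or below 5 ms, so each decoy phenotype fails exactly one criterion.
Cohort families record a single 0 mV step with 8-run averaging - the only
quantities the classifier consumes - keeping a 77-cell cohort run at a few
seconds; the full 12-voltage protocol is exercised by the single-cell
pipeline.

## Secretome screen and Ca2+ flux

The candidate screen is a deterministic three-criterion filter over PSM
counts: molecular weight inside 10-30 or 30-100 kDa (closed bounds; a
protein at exactly 30 kDa is assigned by its declared fraction label),
unique presence or strictly >2-fold enrichment in *both* treated conditions
relative to vehicle ("unique" requires >= 1 treated PSM, no further floor),
and a secreted annotation.  No normalization or significance testing is
applied, matching the screen it reproduces.  The packaged fixture plants
six passers - HSP70 and midkine among them; the other four are synthetic
placeholders since the remaining published hit identities are not printed -
plus decoys that each fail exactly one criterion.

Fluorescence traces are normalized to F/F0 with F0 the mean of *all*
pre-stimulus frames ("initial intensity" without a stated count), and the
transient AUC integrates F/F0 - 1 (baseline-referenced, so a flat trace
scores 0 and the measure is invariant to the raw intensity scale; whether
the published AUC subtracted baseline is unstated, so the integrand is
configurable in the sense that the un-referenced integral is one line away).

## What the synthetic data does and does not show

The simulator reproduces the deterministic phenomenology of fast
voltage-gated sodium currents under a step protocol - activation delay,
fast inactivation, pharmacological pool structure, leak, Gaussian noise,
P/4 subsweeps - with ground truth known exactly.  It does not model
single-channel stochasticity, series-resistance voltage error, temperature,
drug kinetics, space-clamp artifacts, or cell-to-cell gating variability
(cohort cells differ in amplitude, kinetic class and capacitance only).
Passing tests therefore demonstrate that the *analysis chain* is correct
and unbiased under realistic signal scales and noise, not that real
recordings are free of the artifacts listed above.

## Problem sizes

Default sweeps are 55 ms at 100 kHz (5500 samples); a full paired
control/TTX run with P/4 is 120 sweeps and takes ~0.2 s.  Calibration
converges in < 1 s.  The noisy-recovery study uses 100 replicates of
12 voltages x 8 runs on shortened 16 ms sweeps; the cohort study uses 77
cells x 8 runs of a single 0 mV step.  The whole test suite runs in about
half a minute on one CPU.
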