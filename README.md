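# navclamp

Whole-cell voltage-clamp analysis of small sodium currents, built for the
study of functional Na_v1.7 channels in non-excitable cells such as human
osteoarthritic chondrocytes — where peak currents are tens to a few
hundred pA and every derived number passes through a long measurement
chain that deserves tests.

The package covers that chain end to end:

* **Simulator** — a closed-form Hodgkin–Huxley-style voltage-step
  simulator (first-order m·h gating plus a first-latency, three drug-
  defined channel pools, leak, P/4 subsweeps, Gaussian noise) whose
  defaults are *calibrated* so that the full analysis pipeline reproduces
  the published apparent gating values exactly.
* **Preprocessing** — P/4 leak/capacitance subtraction, run averaging,
  baseline referencing.
* **Isolation** — TTX-sensitive and ProTx II-sensitive components by
  point-by-point trace subtraction; peak, persistent current (10 ms),
  percent inhibition.
* **Activation** — peak I–V, chord conductance G(V) = |I_peak|/|V − E_r|,
  Boltzmann fit of G/G_max:  G/G_max(V) = 1 / (1 + exp((V₁/₂ − V)/k)).
* **Kinetics** — single-exponential inactivation τ(V) and time-to-peak.
* **Density** — pA/pF → pS/pF → channels/µm² → channels/cell from cited
  single-channel conductance γ and open probability P_o.
* **Cohort** — responder classification (fast-inactivating, peak > 30 pA)
  and descriptive summaries.
* **Secretome screen** — the deterministic three-criterion PSM filter
  (MW window, >2-fold or unique enrichment in both treatments, secreted).
* **Ca²⁺ flux** — F/F₀ normalization and transient AUC.

See `docs/methods.md` for the model, its assumptions and every numerical
convention.

## Worked example

```python
from navclamp import default_params, measure_pipeline, estimate_density

params = default_params()          # calibrated gating model (cached)
m = measure_pipeline(params)       # noise-free simulate -> isolate -> fit

print(f"V1/2 = {m.v_half:.1f} mV, k = {m.k:.1f} mV")
print(f"tau(-20/0/+50 mV) = {m.tau[-20.0]:.1f} / {m.tau[0.0]:.1f} / {m.tau[50.0]:.1f} ms")
print(f"time to peak at 0 mV = {m.ttp[0.0]:.1f} ms")

est = estimate_density(2.4 * 34, 34, v_test=0.0, e_rev=-60.6,
                       gamma=6.4, p_open=0.6)
print(f"conductance density = {est.conductance_density:.2f} pS/pF")
print(f"channel density = {est.channels_per_um2_rounded:.2f} /um^2 "
      f"-> {est.channels_per_cell} channels per cell")
```

prints

```
V1/2 = -14.2 mV, k = 6.1 mV
tau(-20/0/+50 mV) = 3.3 / 1.0 / 0.3 ms
time to peak at 0 mV = 1.4 ms
conductance density = 39.60 pS/pF
channel density = 0.10 /um^2 -> 350 channels per cell
```

The first block is the *recovered* activation and kinetics of the
calibrated simulator run through the full measurement chain (isolation by
saturating-TTX subtraction, peak I–V, G/G_max, Boltzmann and exponential
fits) — the fitted midpoint, slope, inactivation time constants and
time-to-peak of the TTX-sensitive current.  The second block is the
channel-count arithmetic: a current density of 2.4 pA/pF at 0 mV against
the reported reversal of −60.6 mV gives 39.60 pS/pF, and with γ = 6.4 pS
and P_o = 0.6 that is 0.10 channels/µm², i.e. 350 channels on a
3500 µm² cell (P_o = 0.4 gives 0.15/µm² and 525 channels).

A command-line interface mirrors the stages:

```
navclamp simulate  --out fam/ --seed 5          # control/TTX/ProTx II family
navclamp analyze-cell --family fam/ --out cell.json
navclamp cohort    --n-cells 77 --n-responders 13 --seed 1 --out cohort/
navclamp density   --out density.json
navclamp secretome --table psm.tsv --out hits.tsv
navclamp caflux    --trace ca.tsv --out ca.json
navclamp fixtures  --out fixtures/ --seed 0     # regenerate shipped fixtures
```

Sweep families are stored as one wide CSV per condition (column 1 =
`time_ms`, one column per voltage × repeat × role) plus a JSON sidecar
with protocol, units, capacitance and provenance; the format round-trips
at full float precision.

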