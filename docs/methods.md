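# Methods

## The model and what it is for

`cortexdamage` simulates a small patch of thalamocortical tissue with
conductance-based, multi-compartment neurons, and asks how a reduction of
specific membrane resistance (Rm) — the electrical operationalisation of
blast-induced membrane pore formation — changes two measurements:

1. the mean action-potential (AP) rate, summed over all neurons, and
2. the band power of a simulated local field potential (LFP) in the
   1–40 Hz and 40–100 Hz ranges.

Damage is a single scalar: level *d* scales every targeted compartment's
Rm to (1 − *d*)·Rm (10% damage → Rm at 90% of baseline), applied at the
same level across all neurons, to one of three membrane locations — the
whole cell, the axons alone (axon proper plus initial segment), or the
soma and dendrites. The leak reversal is untouched, so resting potential
is preserved; damage acts purely as added shunt.

## Neuron models

Fourteen cell types (six excitatory cortical, six inhibitory cortical,
thalamic relay and reticular cells) are mapped onto five dynamical
classes: regular spiking, fast spiking, intrinsic bursting,
low-threshold spiking, and thalamic (T-type-carrying). Desk-scale
templates use 8–10 compartments (soma, axon initial segment, one or two
axonal segments, basal/apical/distal dendrites); compartment-class labels
are what the damage model targets, so the partial-damage experiments
transfer unchanged to finer morphologies supplied through configuration.

Passive parameters: Cm = 0.01 F/m², Ra = 3 Ω·m, Rm = 1.0 Ω·m² for
somatodendritic membrane and 0.05 Ω·m² for the unmyelinated axonal
membrane, E_leak = −70 mV. The leaky axon concentrates a large share of
the baseline leak — and hence of the absolute conductance added by
fractional damage — around the spike-initiation zone.

Channels are Hodgkin–Huxley-style with Boltzmann steady states and
constant time constants ≥ 0.5 ms: transient Na (m²h) and delayed
rectifier K (n²) as the spike machinery, a persistent Na current (6 S/m²,
soma) providing subthreshold amplification, M-type K for adaptation,
L-type Ca + Ca-activated K for bursting, T-type Ca for rebound classes.
E_Na = +50 mV, E_K = −95 mV, with the resting potential (−70 mV) much
closer to E_K — the membrane's "inhibitory" operating point that makes
added leak suppressive.

Two deliberate asymmetries place spike initiation in the axon:
the axonal Na variant activates 7 mV more negative than the somatic one
(as axon-initial-segment channels do in cortex), and the axon carries the
denser Na complement. The soma carries just enough transient Na to
regenerate the back-propagated spike above the 0 mV detection threshold.
This is what gives axonal damage its potency: a shunted initiation zone
raises the ignition threshold for every spike, whereas somatodendritic
damage only attenuates the synaptic input en route.

## Numerical integration

All state advances by exponential Euler at a 50 µs step (20 kHz), exact
for linear membrane dynamics over a step. Gate steady states and
relaxation factors are pre-tabulated on a 0.02 mV grid; each step the
gates are advanced to the step midpoint (half relaxation), conductances
are formed from the midpoint state, the voltages take one exponential
Euler step, and the gates complete the half step.

Two choices keep the explicit scheme converged at 50 µs, and both are
verified by the dt-halving test (halving the step changes a 5 s
single-neuron spike count by < 1%):

* gate time constants are floored at 0.5 ms (spikes are ~2 ms wide), and
* neurite diameters and the 300 Ω·cm axial resistivity keep every
  compartment-to-compartment coupling time constant well above the step
  (the explicit treatment of the cable term is the accuracy bottleneck,
  not the gate kinetics).

A blow-up detector aborts the run if any voltage leaves [−150, +80] mV.

## Network

The full-scale patch is 150 × 150 × 2,871 µm: 25 microcolumns of 23 or
24 neurons (pattern 23,24,23,24,23 per block of five → 15 × 23 + 10 × 24
= 585 neurons), every column containing all 14 types, placed uniformly
at random inside the column footprint and the type's layer band (layer
boundaries at 10/35/50/75% of the depth; thalamic cells in a 300 µm block
beneath). The desk-scale default is 2 microcolumns (47 neurons), used for
every simulation experiment in the test suite.

Connections are realised independently per ordered neuron pair with
type-pair probabilities in the printed [0.01, 0.25] range (documented
defaults: excitatory→excitatory 0.10, excitatory→inhibitory 0.20,
inhibitory→excitatory 0.25, thalamocortical→L4/L6 0.15, others 0.05),
weighted u·exp(−r/100 µm) with u ~ U(0,1], and delayed at 1 s/m of
soma-to-target distance. Axo-axonic cells ignore the probability matrix
and contact the axon initial segment of every pyramidal and spiny
stellate cell. Excitatory rows carry AMPA+NMDA (dual-exponential, NMDA
with Jahr–Stevens magnesium block), inhibitory rows GABA_A.

Background drive: 10% of neurons receive independent per-step
Bernoulli(λ = 0.005) EPSP trains (≈100 events/s at 50 µs steps) on a
dendritic compartment ~300 µm from the soma. Dendritic delivery is
deliberate: each EPSP's somatic efficacy then carries the dendrite→soma
electrotonic transfer (length constant ∝ √Rm), the component of synaptic
efficacy most sensitive to membrane damage. The drive peak conductance
(10 nS) was calibrated once (scripts/calibrate_drive.py) so that the
undamaged desk-scale patch fires at the tens-of-APs/s aggregate scale
(~82 APs/s at the reference seed) and 50% whole-cell damage silences it;
it was not revisited afterwards.

All randomness flows from the configuration seed through three salted
streams (placement, wiring, drive), making every run — including the full
sweep's CSV outputs — byte-for-byte reproducible.

## Measurements

Raw output is recorded at 20 kHz; the first second is discarded to let
the model settle. Two chains mirror standard practice:

* AP channel: anti-aliased polyphase resample to 5 kHz, 9th-order
  Butterworth high-pass at 50 Hz (zero-phase), upward threshold crossing
  with a 2 ms lockout. The Table-style rate analysis applies this chain
  per neuron to the somatic traces and sums the counts; the aggregate
  channel with the 2.5×10⁻⁸ V threshold is also available.
* LFP channel: the raw LFP is the 1/r-weighted sum of all compartment
  membrane potentials at a virtual electrode 500 µm above the patch
  centre (1/r² optional; output in model units, V/µm); resampled to
  1 kHz and low-pass filtered with an 8th-order Butterworth at 300 Hz
  (zero-phase). "300 Hz roll-off" is read as the −3 dB corner.

Zero-phase (forward–backward) filtering was chosen so band-power
comparisons are not phase-distorted; the effective attenuation is the
squared single-pass magnitude.

## Spectral statistics

The LFP spectrum is parametric: Burg's lattice recursion (forward +
backward prediction error), model order chosen by AIC
(argmin N·ln σ²_p + 2p, p ≤ 20). The one-sided PSD
S(f) = 2σ²/(fs·|1 + Σ a_k e^(−i2πfk/fs)|²) is evaluated on a 0.1 Hz
grid. Per-frequency 99% confidence intervals come from a delta-method
expansion (Cov(â) ≈ σ²Γ⁻¹/N with Γ the model autocovariance matrix,
Var(σ̂²) ≈ 2σ⁴/N, applied on the log scale to keep bounds positive); a
parametric bootstrap (simulate from the fitted model, refit, percentile)
is available as the cross-check and agrees with the asymptotic widths to
~10%. Intervals are computed on the linear power scale; dB displays
transform the bounds.

Band power is the plain sum of the density over the half-open,
lower-inclusive grid [f_lo, f_hi) — 390 points for 1–40 Hz, 600 for
40–100 Hz — with variance the sum of per-frequency variances.
Baseline-vs-damage comparisons use
t = (P_base − P_dam)/√(Var_base + Var_dam) with Welch–Satterthwaite
degrees of freedom built from a χ²-analogy per band (df = 2·mean²/var; an
infinite-df normal fallback is available), two-sided p from the Student-t
CDF, and a Bonferroni factor equal to the number of
(level × location × band) comparisons in the sweep.

Note that plain AIC overfits with the textbook probability (~20–25%
chance that some higher order wins by a χ²(1) fluctuation), so order
selection on synthetic AR(p) data returns exactly p in roughly 3 out of
4 seeds and never underfits; the tests assert that behaviour.

## What the desk-scale experiment does and does not replicate

With 2 microcolumns, 20 s runs and a fixed seed, the sweep reproduces the
qualitative structure of the damage experiment:

* aggregate firing falls monotonically with damage level for every
  location (baseline ≈ 82 APs/s at the reference seed);
* whole-cell damage is the most severe at every level and silences the
  network from the 40–50% levels (0 APs/s over 20 s at 50%, at every
  seed tried);
* axon-only damage suppresses firing at least as strongly as
  soma-and-dendrite damage at every level ≥ 20% — the location effect,
  here attributable to the shunted axonal initiation zone.

It does **not** replicate the full-scale finding that the 1–40 Hz band
loses more power (in dB) than the 40–100 Hz band at intermediate damage.
At 47 neurons the LFP's high band is dominated by spike waveforms (which
collapse with damage) while its low band is dominated by the Poisson
drive's subthreshold EPSPs (which persist); in the full-scale model the
low band is carried by recurrent synaptic activity that collapses with
network firing. Both band powers do fall under damage, and that is what
the tests assert. Absolute rates and dB magnitudes are likewise outside
the desk-scale contract: the full parameterisation of the original
14-type model lives in external publications, so only orderings, the
silencing endpoint and the self-contained printed quantities (damage
mapping, band-grid point counts, builder totals) are asserted.

Two printed full-scale numbers are intentionally not reproduced: the
total connection count (a seed-specific realisation) and the 36
axo-axonic interneurons (incompatible with every microcolumn containing
both axo-axonic types across 25 columns, which implies 50; the registry
follows the composition rule).

## Degenerate inputs and guards

Damage level ≥ 1 (zero resistance), compounded damage application,
constant series handed to Burg, empty or out-of-Nyquist bands, zero
bootstrap replicates, series shorter than the settle window, mismatched
PSD grids and non-finite signals all raise typed errors; a template with
no axonal compartments yields an empty damage set with a warning.

## Problem sizes used by the test suite

Simulation tests use the 2-microcolumn patch: 5 s runs for the rate
orderings (the orderings are already decisive there), 20 s for the
silencing endpoint, 2–3 s for determinism and sweep plumbing. Spectral
oracle tests use n = 4,000–19,000 synthetic AR samples and 100-replicate
coverage studies. These sizes are the package's reference conditions;
they are stated here so results are reproducible, and larger runs are a
matter of configuration only.
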