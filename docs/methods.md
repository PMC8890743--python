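# Methods

## Model

Two populations of conductance-based leaky integrate-and-fire neurons
represent CA1: N_E = 12000 pyramidal cells (PCs) and N_I = 200
parvalbumin-positive basket cells (PV+BCs), roughly the content of a
standard slice at the observed 60:1 ratio.  The membrane equation of each
neuron is

    C dV/dt = g_l (E_rest − V) + g_exc(t) (E_exc − V) + g_inh(t) (E_inh − V)
              + I_dendritic(t) + I_noise(t),

where g_exc collects recurrent AMPA, CA3 AMPA and (models 1–2) the external
drive conductance, g_inh the GABA_A input, I_dendritic the stereotyped
somatic current of dendritic spikes (model 3 only) and
I_noise = σ_n √(2 g_l C) ξ(t) a white-noise current whose scaling gives the
passive membrane a stationary voltage standard deviation of exactly σ_n
(default 1 mV), independent of the step size.  Threshold crossing at the
end of a step emits a spike; the neuron is reset and clamped at V_reset for
an absolute refractory period (2 ms for PCs, 1 ms for PV+BCs) during which
it integrates nothing.

Synaptic conductances are bi-exponential,
g(t) = g_peak · s · (e^{−(t−τ_l)/τ_d} − e^{−(t−τ_l)/τ_r}) for t ≥ τ_l, with
the closed-form normalization s that makes the kernel maximum exactly
g_peak; contributions of successive spikes add linearly.  Connectivity is
uniformly random per ordered pair with p_EE = 0.0164, p_EI = 0.1,
p_IE = 0.1, p_II = 0.2 (mean in-degrees 197 E←E and 40 I←I at the default
sizes) and p = 130/15000 for CA3→CA1.

### Drive variants

* **Model 1** (broad drive): n_E PCs receive Gaussian conductance pulses of
  width σ_g = 10 ms centered at the common t₀ = 50 ms; amplitudes are
  Gaussian with mean ḡ and sd CV_g·ḡ, clipped at zero.
* **Model 2** (pulsed drive): common amplitude ḡ, width σ_g = 3 ms, and
  per-cell center times ~ N(50 ms, σ_t²) with σ_t = 10 ms.
* **Model 3** (CA3-driven dendritic spikes): N_CA3 = 15000 Poisson neurons
  with rate r(t) = r₀ e^{−(t−t₀)²/2σ_t²}, r₀ = 8 Hz, σ_t = 10 ms, generated
  by thinning against the peak rate.  Each CA3 spike evokes the ordinary
  small EPSC (0.75 nS, 1/2 ms rise/decay, 1 ms delay; ≈ 0.4 mV EPSP at a
  −55 mV holding potential) irrespective of coincidence detection.  When at
  least 5 input spikes reach a PC dendrite within the sliding w_D = 2 ms
  window — and the dendrite is past its t_{r,D} = 5 ms refractory period and
  the soma is above the inhibitory reversal potential — a dendritic spike is
  triggered at the arrival of the threshold-th input (the earliest moment
  the condition is verifiable).  Its somatic current starts τ_D = 2 ms
  later: a 1/4 ms rise/decay kernel whose peak is the cell's fixed draw
  from lognormal(μ, σ) (variants: truncate-to-zero above 4 nA, resample
  above 4 nA, or a zero-clipped Gaussian with matching mean and sd).
  With r₀ = 8 Hz only ≈ 18% of CA3 cells fire at all, so of the ≈ 130
  anatomical CA3 inputs per PC only ≈ 26 are active; we add no further
  subsampling — the reduction emerges entirely from the rate profile.
* **Feedforward-inhibition variant**: an identical Gaussian conductance
  (ḡ_I, σ_g = 10 ms) to every PV+BC turns the circuit into an
  interneuron-network rhythm generator; runs are flagged as such in their
  metadata.

### Replay networks

Both populations are partitioned into K+1 contiguous groups (K = 9 by
default).  Two masks are applied to the random graph: E-group k makes no
synapses onto I-group k+1, and I-group k projects only onto E-group k.
Because an I→E block is only 1/(K+1) of the population, the within-block
I→E probability is scaled by K+1 (capped at 1) so each PC keeps the random
network's mean inhibitory in-degree of ≈ 20 — otherwise the ~2 remaining
inhibitory inputs per PC could not gate anything.  A replay event is
initiated by a short pulse (σ_g = 1.5 ms, 60 nS, t = 35 ms) onto group E₀
while all PCs receive a weakened broad sharp wave (ḡ = 30 nS); the E→I
conductance is reduced from 3 to 2 nS so that inhibition gates PC groups
cleanly.  With these settings the default demo produces 6 groups activating
in index order at ≈ 5 ms intervals together with a ≈ 190 Hz oscillation;
every active PC spikes once.  A run on the unmasked random graph with the
same drive activates all groups simultaneously and is rejected by the
sequence criterion (which demands strictly increasing activation times).

## Parameter provenance and calibration

The published model description fixes the architecture, drive parameters,
dendritic mechanism and connection probabilities but not the single-cell
membrane constants or most synaptic kernels (these sat in an unavailable
supplement).  We therefore reconstructed them in two steps, implemented as
packaged routines.

**PC membrane** (`ca1ripple.calibrate`).  Five single-neuron anchors
constrain the soma: injecting the dendritic-current kernel at rest with
noise off must depolarize by 1.28 mV at 0.1 nA and 12.78 mV (subthreshold)
at 1 nA, the minimal spiking peak must be ≈ 1.34 nA, and 5 / 10 nA kernels
must elicit exactly 2 / 4 spikes.  Subthreshold linearity makes the 1 nA
anchor fix the charge-to-capacitance ratio once τ_m is chosen, and the
threshold anchor fixes V_thresh − E_rest = 12.78 × 1.34 ≈ 17.13 mV.  The
remaining freedom (τ_m, V_reset) is pinned by the integer spike-count
anchors, which probe post-reset recovery: τ_m = 10 ms with V_reset 2 mV
below rest satisfies both.  The frozen result — C = 265.5 pF,
g_l = 26.55 nS, E_rest = −67 mV, V_thresh = −49.87 mV, V_reset = −69 mV,
E_exc = 0 mV, E_inh = −80 mV — also reproduces, without further tuning, the
0.4 mV Schaffer-collateral EPSP at a −55 mV hold (we obtain 0.402 mV),
which we read as evidence the reconstruction is close to the original.
PV+BC parameters are generic fast-spiking values (C = 100 pF, g_l = 10 nS,
E_rest = −65, V_thresh = −52, V_reset = −67 mV, E_inh = −75 mV, t_ref =
1 ms).

**Unknown synaptic kernels.**  The stated values are kept fixed: E→I AMPA
3 nS with 0.5/2 ms rise/decay; CA3→E 0.75 nS, 1/2 ms, 1 ms delay; I→E
latency 0.5 ms in model 3 and 1.0 ms in models 1–2.  The unpublished GABA_A
kernels were calibrated against the model-3 reference event at
(σ, μ) = (0.75, 0): I→E 6 nS and I→I 8 nS, both 0.45/1.2 ms, I→I latency
1.2 ms.  The I→I latency is the decisive rhythm parameter — at 0.6 ms the
interneuron network ran near 350 Hz; 1.2 ms places the coupled network in
the ripple band.  With these defaults the reference event gives
q_E ≈ 0.086, C_E ≈ 1.52, C_I ≈ 6.4, q_I = 1 and f ≈ 190–195 Hz with
std(f) ≈ 4–5 Hz across realizations (reference values: 0.084, 1.6, 6.1, 1).
E→E AMPA is set to a weak 0.2 nS (recurrent excitation in CA1 is sparse and
functionally minor here); results are insensitive to it.

## Numerics

* Exponential-Euler voltage update (conductances frozen over one step),
  dt = 0.01 ms by default; 0.02 ms is used for parameter sweeps (0.05 ms is
  the allowed ceiling).  Halving dt moves single-neuron spike times by
  < 0.1 ms on the calibration protocol.
* Synaptic and dendritic kernels are integrated as exact two-state
  exponential updates (the per-step decay factors are the analytic
  solution), so kernel peaks are exact at any dt.
* Transmission delays are whole steps (rounded); spike times are recorded
  at the end of the crossing step.
* Coincidence detection uses a circular per-step arrival-count history over
  the window; it is exactly equivalent to the continuous-time definition
  for step-quantized arrival times (property-tested against a brute-force
  window scan).
* The dendritic refractory clock starts at the trigger time, not at the
  somatic-current onset.
* Negative drive-amplitude draws are clipped at 0; model-2 peak times may
  fall outside the window (their Gaussian tails still contribute).
* All randomness derives from one master seed via named SeedSequence
  substreams (connectivity, noise, CA3, drive, peak currents, subset
  choice); realization r of a config uses child seeds (seed, r, 0/1), so
  realizations differ in both connectivity and noise and every output is
  bit-reproducible.
* Oscillation frequency: population rate on 1 ms bins over t₀ ± 30 ms,
  mean-subtracted, Hann-windowed, zero-padded FFT to ≤ 1 Hz grid, peak
  search in 80–350 Hz; a flat series yields NaN.  The estimator recovers
  sinusoidally modulated Poisson ground truth to within the window's
  spectral resolution across 100–300 Hz.  Frequency standard deviations use
  the sample (n−1) convention.
* Replay detection: a group activates when ≥ 50% of its cells spike within
  a 4 ms sliding window (0.25 ms grid); success requires strictly
  increasing group indices *and* activation times over ≥ 2 groups.

## Problem sizes in the shipped checks

The test suite exercises the full-scale reference network (12000/200/15000)
with 2 realizations and runs the (σ, μ) sweep on a 4×4 grid with 3
realizations at N_E = 3000, with p_EE and p_EI rescaled (197/3000 and 0.4)
so every mean in-degree of the full model is preserved; at that scale the
reference statistics reproduce within a few percent.  The acceptance script
uses the full-scale network with 10 realizations.

## What the synthetic inputs do and do not capture

CA3 is a memoryless inhomogeneous-Poisson population with a shared rate
envelope: no bursting, no cell assemblies, no spatial structure in the
Schaffer projection, and no CA3 rhythmicity.  Consequently the model
addresses how CA1 turns an unstructured sharp-wave envelope into a ripple —
passing tests say nothing about CA3-paced ripples or input-correlation
effects.  The LIF somata omit spike-rate adaptation, Ca²⁺/NMDA (slow)
dendritic spikes, gap junctions and synaptic plasticity; the LFP itself is
not modeled, so "ripple frequency" always means the spectral peak of the
population spike rate.

## Known limitations

* The membrane time constant is under-determined by the anchors (any τ_m in
  ≈ 8–12 ms admits a valid calibration); τ_m = 10 ms is a conventional
  choice, and all reconstructed defaults should be read as *a* consistent
  completion of the published constraints, not *the* original values.
* The replay connectome's within-group probabilities are a reconstruction
  (in-degree-preserving); the replay demonstrations are therefore
  qualitative: order, cadence and sparseness are reproduced, exact group
  counts depend on the drive envelope.
* The paper's printed lognormal-CDF value for x = 10 nA (0.9983) is
  inconsistent with its own formula, which gives 0.99893; the package
  implements the exact CDF (verified against scipy) — the substantive claim
  (> 99.8% of dendrites below 10 nA) holds either way.
* Spike rasters, connectomes, statistics and sweeps are exported as
  headered text/CSV/JSON only; no HDF5 writer is included.
* Sweeps return tidy DataFrames/CSV; heatmap plotting is left to the user.
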