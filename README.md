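# ca1ripple

Two-population spiking-network models of sharp wave/ripple (SPW/R)
generation and sequence replay in hippocampal area CA1.

During SPW/Rs the CA1 local field potential shows 140–200 Hz "ripple"
oscillations while pyramidal cells (PCs) spike remarkably sparsely — most
active PCs contribute one or two spikes per event — and parvalbumin-positive
basket cells (PV+BCs) fire on nearly every ripple cycle.  This package
implements a family of conductance-based leaky integrate-and-fire network
models that probe which kinds of CA3 drive reconcile ripple-band collective
oscillations with that sparse excitatory firing:

* **model 1** — temporally broad Gaussian conductance drive
  g_ext(t) = g⁰_ext · exp(−(t−t₀)²/2σ_g²) to a subset n_E of PCs, common
  center t₀, per-cell amplitudes ~ N(ḡ, (CV_g·ḡ)²);
* **model 2** — temporally narrow pulses, common amplitude ḡ, per-cell
  center times t₀ ~ N(50 ms, σ_t²);
* **model 3** — an explicit CA3 population of inhomogeneous-Poisson neurons
  with rate r(t) = r₀·exp(−(t−t₀)²/2σ_t²) whose coincident spikes (≥ 5
  arrivals within w_D = 2 ms) trigger dendritic spikes; each dendritic spike
  injects a stereotyped somatic current (1 ms rise / 4 ms decay) whose peak,
  in nA, is drawn once per cell from lognormal(μ, σ);
* **structured replay networks** — both populations split into K+1 groups
  with E-group k making no synapses onto I-group k+1 and I-group k
  inhibiting only E-group k, so that an initiating pulse to E₀ propagates by
  alternating E-pulse and I-gap (disinhibition) coding.

Both populations obey

    C dV/dt = g_l(E_rest − V) + g_exc(t)(E_exc − V) + g_inh(t)(E_inh − V)
              + I_dendritic(t) + I_noise(t),

with bi-exponential synaptic conductances (normalized so each kernel attains
its nominal peak), transmission delays, absolute refractoriness and white
membrane-voltage noise of strength σ_n = 1 mV.  The analysis pipeline
measures, per population, the spectral-peak oscillation frequency f of the
population rate, its standard deviation across independent realizations,
the spikes per active cell C and the active fraction q, plus the group
activation order for replay runs.

## Worked example

Run the dendritic-spike model (model 3) at full scale — N_E = 12000 PCs,
N_I = 200 PV+BCs, N_CA3 = 15000, (σ, μ) = (0.75, 0) — for three independent
realizations:

```python
from ca1ripple.experiments import ExperimentConfig, run_experiment

cfg = ExperimentConfig(variant="model3", master_seed=1, n_realizations=3)
agg, per_realization, _ = run_experiment(cfg)
print(agg.to_dict())
```

which prints (about 10 s per realization):

```
{'f_E': 188.80, 'f_I': 190.43, 'C_E': 1.525, 'C_I': 6.539,
 'q_E': 0.0873, 'q_I': 0.998, 'n_realizations': 3,
 'std_f_E': 3.95, 'std_f_I': 5.17}
```

Both populations oscillate in the ripple band (f ≈ 189 Hz, robust across
realizations: std(f) ≈ 4–5 Hz), about 8.7% of PCs participate with ~1.5
spikes each, and essentially all basket cells fire, ~6.5 spikes per cell —
the sparse-E / dense-I signature of in-vivo ripples.

The same things are available from the shell:

```bash
ca1ripple simulate --seed 1 --out runs/model3        # rasters + statistics
ca1ripple replay   --seed 3 --out runs/replay        # sequence replay demo
ca1ripple sweep    --seed 1 --out runs/sweep \
    --axis sigma 0.5,0.65,0.8,0.95 --axis mu -0.3,0,0.3,0.6
ca1ripple calibrate                                   # single-neuron anchors
ca1ripple analyze runs/model3/raster_E_r0.tsv
```

The replay demo reports the detected group sequence, e.g. groups 0–5
activating in order at ~5 ms intervals together with a ~190 Hz ripple, and
`--no-masks` runs the negative control (random connectivity, no sequence).

## Layout

- `ca1ripple.neurons` — LIF population dynamics, single-neuron protocols
- `ca1ripple.synapses` — bi-exponential kernels, exact state integration
- `ca1ripple.connectivity` — random and structured (replay) connectomes
- `ca1ripple.drive` — Gaussian sharp-wave drives, CA3 Poisson generator
- `ca1ripple.dendrites` — coincidence detection, peak-current distributions
- `ca1ripple.analysis` — rasters, rates, spectra, event statistics, sequences
- `ca1ripple.network` — the time-stepped event simulator
- `ca1ripple.experiments` — configs, runner, sweeps, replay, fixtures
- `ca1ripple.calibrate` — reconstruction of the PC membrane from anchors

See `docs/methods.md` for the model details, parameter provenance and known
limitations.
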