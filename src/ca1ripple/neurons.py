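"""Conductance-based leaky integrate-and-fire population dynamics.

Both CA1 populations follow

    C dV/dt = g_l (E_rest - V) + g_exc(t) (E_exc - V) + g_inh(t) (E_inh - V)
              + I_ext(t) + I_noise(t),

integrated with exponential Euler (the conductances are held constant over
one step, for which the membrane equation is solved exactly).  A neuron
crossing threshold at the end of a step emits a spike, is reset and is
clamped at the reset potential for an absolute refractory period, during
which it integrates nothing (including noise).  The white-noise current
I_noise = sigma_n * sqrt(2 g_l C) * xi(t) is scaled so that the stationary
voltage fluctuation of a passive membrane has standard deviation sigma_n.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .params import DendriteParams, NeuronPopulationParams
from .synapses import BiexpState, biexp_kernel

__all__ = [
    "PopulationState",
    "Population",
    "step_population",
    "noise_increment",
    "simulate_kernel_injection",
    "find_threshold_peak_current",
]


def noise_increment(params: NeuronPopulationParams, n: int, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-step voltage increments realizing the white-noise current.

    Follows the sqrt(dt) convention: the increment is
    sigma_n * sqrt(2 dt / tau_m) * N(0, 1), which gives the passive membrane a
    stationary voltage std of sigma_n independent of dt.
    """
    if params.noise_strength == 0.0:
        return np.zeros(n)
    scale = params.noise_strength * np.sqrt(2.0 * dt / params.membrane_time_constant)
    return scale * rng.standard_normal(n)


class PopulationState:
    """Mutable per-neuron state of one LIF population."""

    def __init__(self, n: int, params: NeuronPopulationParams, dt: float):
        if dt <= 0 or dt > 0.05:
            raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
        self.n = int(n)
        self.dt = float(dt)
        self.t = 0.0
        self.voltage = np.full(self.n, params.resting_potential)
        self.refractory_steps = np.zeros(self.n, dtype=np.int64)

    def copy(self) -> "PopulationState":
        new = object.__new__(PopulationState)
        new.n, new.dt, new.t = self.n, self.dt, self.t
        new.voltage = self.voltage.copy()
        new.refractory_steps = self.refractory_steps.copy()
        return new


class Population:
    """LIF population bound to fixed parameters and step size."""

    def __init__(self, n: int, params: NeuronPopulationParams, dt: float):
        self.params = params
        self.state = PopulationState(n, params, dt)
        self._ref_steps_total = int(round(params.refractory_period / dt))
        self._gl = params.leak_conductance
        self._cm = params.membrane_capacitance

    @property
    def n(self) -> int:
        return self.state.n

    @property
    def voltage(self) -> np.ndarray:
        return self.state.voltage

    def step(
        self,
        g_exc: np.ndarray | float = 0.0,
        g_inh: np.ndarray | float = 0.0,
        current_nA: np.ndarray | float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Advance one step; returns the indices of neurons that spiked.

        ``g_exc``/``g_inh`` are total conductances (nS, non-negative),
        ``current_nA`` additional somatic current (nA, e.g. dendritic spikes).
        """
        p, st = self.params, self.state
        dt = st.dt
        refractory = st.refractory_steps > 0

        g_tot = self._gl + g_exc + g_inh
        # pA throughout: nS * mV = pA, nA * 1e3 = pA
        drive = (
            self._gl * p.resting_potential
            + g_exc * p.excitatory_reversal
            + g_inh * p.inhibitory_reversal
            + np.asarray(current_nA) * 1e3
        )
        v_inf = drive / g_tot
        decay = np.exp(-dt * g_tot / self._cm)
        v_new = v_inf + (st.voltage - v_inf) * decay
        if rng is not None and p.noise_strength > 0.0:
            v_new = v_new + noise_increment(p, st.n, dt, rng)

        # refractory neurons stay pinned at the reset potential
        v_new = np.where(refractory, p.reset_potential, v_new)
        st.refractory_steps[refractory] -= 1

        if not np.all(np.isfinite(v_new)):
            raise FloatingPointError(
                "non-finite membrane voltage encountered "
                f"(dt={dt}, params={p.to_dict()})"
            )

        spiking = np.flatnonzero(v_new >= p.spike_threshold)
        if spiking.size:
            v_new[spiking] = p.reset_potential
            st.refractory_steps[spiking] = self._ref_steps_total
        st.voltage = v_new
        st.t += dt
        return spiking


def step_population(
    state: PopulationState,
    params: NeuronPopulationParams,
    g_exc: np.ndarray | float = 0.0,
    g_inh: np.ndarray | float = 0.0,
    current_nA: np.ndarray | float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PopulationState, np.ndarray]:
    """Functional single-step update; returns (new state, spiking indices)."""
    pop = object.__new__(Population)
    pop.params = params
    pop.state = state.copy()
    pop._ref_steps_total = int(round(params.refractory_period / state.dt))
    pop._gl = params.leak_conductance
    pop._cm = params.membrane_capacitance
    spikes = pop.step(g_exc=g_exc, g_inh=g_inh, current_nA=current_nA, rng=rng)
    return pop.state, spikes


def simulate_kernel_injection(
    params: NeuronPopulationParams,
    peak_nA: float,
    dendrite: DendriteParams | None = None,
    duration: float = 80.0,
    dt: float = 0.01,
    record_voltage: bool = True,
) -> dict:
    """Inject one stereotyped dendritic-spike current into a silent neuron.

    The neuron starts at rest with noise off; the current kernel (default
    1 ms rise / 4 ms decay) is triggered at t = 0 and arrives at the soma
    after the dendro-somatic delay.  Returns a dict with ``time``,
    ``voltage`` (if recorded), ``spike_times`` and ``peak_depolarization``
    (max voltage above rest before the first spike, or over the whole trace
    if none).
    """
    dendrite = dendrite or DendriteParams()
    n_steps = int(round(duration / dt))
    pop = Population(1, params, dt)
    t = (np.arange(n_steps) + 1) * dt
    current = biexp_kernel(
        t, dendrite.kernel_rise, dendrite.kernel_decay,
        peak=peak_nA, delay=dendrite.soma_delay,
    )
    voltage = np.empty(n_steps) if record_voltage else None
    spike_times: list[float] = []
    for i in range(n_steps):
        spiking = pop.step(current_nA=current[i])
        if spiking.size:
            spike_times.append(t[i])
        if record_voltage:
            voltage[i] = pop.voltage[0]
    if spike_times:
        upto = int(round(spike_times[0] / dt)) - 1
        peak_depol = float(np.max(voltage[:upto]) - params.resting_potential) \
            if (record_voltage and upto > 0) else float("nan")
    else:
        peak_depol = float(np.max(voltage) - params.resting_potential) \
            if record_voltage else float("nan")
    return {
        "time": t,
        "voltage": voltage,
        "spike_times": np.asarray(spike_times),
        "n_spikes": len(spike_times),
        "peak_depolarization": peak_depol,
    }


def find_threshold_peak_current(
    params: NeuronPopulationParams,
    dendrite: DendriteParams | None = None,
    lower: float = 0.0,
    upper: float = 5.0,
    resolution: float = 0.01,
    dt: float = 0.01,
) -> float:
    """Minimal dendritic-kernel peak current (nA) eliciting >= 1 somatic spike.

    Bisection between ``lower`` (no spike) and ``upper`` (must spike) down to
    ``resolution``; noise off, neuron at rest.
    """
    dendrite = dendrite or DendriteParams()

    def spikes(peak: float) -> bool:
        res = simulate_kernel_injection(
            params, peak, dendrite=dendrite, dt=dt, record_voltage=False
        )
        return res["n_spikes"] >= 1

    if not spikes(upper):
        raise RuntimeError(
            f"no somatic spike even at {upper} nA; parameters inconsistent "
            "with the calibration anchors"
        )
    lo, hi = lower, upper
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
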