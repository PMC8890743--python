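"""Time-stepped simulation of the two-population CA1 circuit.

One call to :func:`simulate_event` integrates a single sharp-wave event:
the E and I LIF populations (exponential Euler), bi-exponential synaptic
conductances with transmission delays (exact state updates), the external
drive of the chosen model variant, and — for the dendritic-spike variant —
per-cell coincidence detection on CA3 input with stereotyped somatic
currents.  All randomness (noise, CA3 spikes, drive amplitudes and peak
times, peak dendritic currents, driven-subset choice) derives from a single
master seed through named substreams, so a configuration plus seed
reproduces every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analysis import SpikeRaster
from .connectivity import Connectome
from .dendrites import CoincidenceDetector, sample_peak_currents
from .drive import (
    gaussian_conductance,
    generate_ca3_spikes,
    sample_model1_amplitudes,
    sample_model2_peaktimes,
)
from .neurons import Population, noise_increment
from .params import (
    DendriteParams,
    DriveSpec,
    NeuronPopulationParams,
    PeakCurrentDistribution,
    SynapseParams,
    default_e_params,
    default_i_params,
    default_projections,
)
from .synapses import BiexpState

__all__ = ["GaussianPulseSet", "SimulationResult", "simulate_event", "derive_streams"]

_STREAMS = ("noise", "ca3", "drive", "peaks", "subset")


def derive_streams(seed) -> dict:
    """Named independent random substreams from one master seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


@dataclass
class GaussianPulseSet:
    """A set of Gaussian conductance pulses targeting specific E cells."""

    ids: np.ndarray            # target neuron indices
    amplitudes: np.ndarray     # per-target peak conductance, nS
    t0: np.ndarray             # per-target center times, ms
    sigma_g: float             # common width, ms

    def conductance_at(self, t: float) -> np.ndarray:
        return self.amplitudes * np.exp(-((t - self.t0) ** 2)
                                        / (2.0 * self.sigma_g ** 2))


class _DelayBuffer:
    """Circular buffer of dense per-neuron increments scheduled in the future."""

    def __init__(self, n: int, delay_steps: int):
        self.delay = int(delay_steps)
        self.buf = np.zeros((self.delay + 1, n))
        self.pos = 0

    def schedule(self, idx: np.ndarray, amount) -> None:
        """``amount``: scalar or per-``idx`` array of increments."""
        row = (self.pos + self.delay) % self.buf.shape[0]
        np.add.at(self.buf[row], idx, amount)

    def pop(self) -> np.ndarray:
        out = self.buf[self.pos].copy()
        self.buf[self.pos] = 0.0
        self.pos = (self.pos + 1) % self.buf.shape[0]
        return out


@dataclass
class SimulationResult:
    rasters: dict                      # "E" | "I" | "CA3" -> SpikeRaster
    dendritic_spikes: Optional[SpikeRaster]
    peak_currents: Optional[np.ndarray]
    voltage_time: Optional[np.ndarray] = None
    voltage_traces: Optional[dict] = None   # pop -> (ids, array[time, id])
    metadata: dict = field(default_factory=dict)


def _build_pulses(drive: DriveSpec, n_e: int, streams: dict) -> list[GaussianPulseSet]:
    """Convert a model-1/2 drive spec into explicit pulse sets."""
    rng_drive, rng_subset = streams["drive"], streams["subset"]
    n_driven = min(drive.n_e_driven, n_e)
    ids = np.sort(rng_subset.choice(n_e, size=n_driven, replace=False))
    if drive.variant == "model1":
        amps = sample_model1_amplitudes(n_driven, drive.mean_amplitude,
                                        drive.amplitude_cv, rng_drive)
        t0 = np.full(n_driven, drive.center_time)
    elif drive.variant == "model2":
        amps = np.full(n_driven, drive.mean_amplitude)
        t0 = sample_model2_peaktimes(n_driven, drive.peak_time_spread,
                                     rng_drive, t0=drive.center_time)
    else:
        return []
    return [GaussianPulseSet(ids=ids, amplitudes=amps, t0=t0,
                             sigma_g=drive.pulse_width)]


def simulate_event(
    connectome: Connectome,
    drive: DriveSpec,
    e_params: Optional[NeuronPopulationParams] = None,
    i_params: Optional[NeuronPopulationParams] = None,
    projections: Optional[dict] = None,
    dendrite: Optional[DendriteParams] = None,
    peak_current_dist: Optional[PeakCurrentDistribution] = None,
    duration: float = 100.0,
    dt: float = 0.01,
    seed=0,
    ca3_raster: Optional[SpikeRaster] = None,
    extra_pulses: Optional[Sequence[GaussianPulseSet]] = None,
    peak_current_scale: Optional[np.ndarray] = None,
    include_e_population: bool = True,
    record_voltage: Optional[dict] = None,
) -> SimulationResult:
    """Simulate one sharp-wave event and return the spike rasters.

    ``extra_pulses`` adds Gaussian conductance pulses on top of (or instead
    of) the drive variant — used for replay initiation.
    ``peak_current_scale`` optionally multiplies the per-cell peak dendritic
    currents (used to weaken dendritic impact per replay group).
    ``include_e_population=False`` silences all E output (the pure
    interneuron-network control).  ``record_voltage={"E": ids, "I": ids}``
    stores voltage traces of selected neurons.
    """
    e_params = e_params or default_e_params()
    i_params = i_params or default_i_params()
    projections = projections or default_projections(drive.variant)
    streams = derive_streams(seed)
    n_e, n_i = connectome.n_e, connectome.n_i
    n_steps = int(round(duration / dt))

    pop_e = Population(n_e, e_params, dt)
    pop_i = Population(n_i, i_params, dt)

    def steps_of(latency: float) -> int:
        return max(1, int(round(latency / dt)))

    # conductance states on E: recurrent AMPA, CA3 AMPA, GABA; on I: AMPA, GABA
    syn = {name: projections[name] for name in ("EE", "EI", "IE", "II")}
    st_ee = BiexpState(n_e, syn["EE"].rise_time, syn["EE"].decay_time, dt)
    st_ie = BiexpState(n_e, syn["IE"].rise_time, syn["IE"].decay_time, dt)
    st_ei = BiexpState(n_i, syn["EI"].rise_time, syn["EI"].decay_time, dt)
    st_ii = BiexpState(n_i, syn["II"].rise_time, syn["II"].decay_time, dt)
    buf_ee = _DelayBuffer(n_e, steps_of(syn["EE"].latency))
    buf_ie = _DelayBuffer(n_e, steps_of(syn["IE"].latency))
    buf_ei = _DelayBuffer(n_i, steps_of(syn["EI"].latency))
    buf_ii = _DelayBuffer(n_i, steps_of(syn["II"].latency))

    # external Gaussian pulses (models 1/2 and/or replay initiation)
    pulses = list(extra_pulses or [])
    if drive.gamma:
        pulses += _build_pulses(drive, n_e, streams)
    ff_i_amp = drive.ff_inhibitory_amplitude

    # model 3: CA3 population, coincidence detection, dendritic currents
    model3 = drive.variant == "model3"
    ca3_deliveries = None
    detector = None
    st_dend = None
    peaks = None
    dend_spike_ids: list[np.ndarray] = []
    dend_spike_steps: list[int] = []
    if model3:
        dendrite = dendrite or DendriteParams()
        peak_current_dist = peak_current_dist or PeakCurrentDistribution()
        ca3_syn: SynapseParams = projections["CA3E"]
        if ca3_raster is None:
            ca3_raster = generate_ca3_spikes(
                drive.ca3_size, r0=drive.ca3_peak_rate, t0=drive.center_time,
                sigma_t=drive.peak_time_spread, duration=duration,
                rng=streams["ca3"],
            )
        st_ca3 = BiexpState(n_e, ca3_syn.rise_time, ca3_syn.decay_time, dt)
        # pre-sort CA3 spikes by arrival step (spike step + transmission delay)
        arrival = np.minimum(
            (ca3_raster.times / dt).astype(np.int64) + steps_of(ca3_syn.latency),
            np.iinfo(np.int64).max)
        order = np.argsort(arrival, kind="stable")
        arr_steps = arrival[order]
        arr_ids = ca3_raster.neuron_ids[order]
        indptr = np.searchsorted(arr_steps, np.arange(n_steps + 1))
        ca3_deliveries = (indptr, arr_ids)
        detector = CoincidenceDetector(n_e, dendrite, dt)
        st_dend = BiexpState(n_e, dendrite.kernel_rise, dendrite.kernel_decay, dt)
        buf_dend = _DelayBuffer(n_e, steps_of(dendrite.soma_delay))
        peaks = sample_peak_currents(n_e, peak_current_dist, streams["peaks"])
        if peak_current_scale is not None:
            peaks = peaks * np.asarray(peak_current_scale)
        ca3_counts = np.zeros(n_e, dtype=np.int32)

    # recording
    e_ids: list[np.ndarray] = []
    e_steps: list[int] = []
    i_ids: list[np.ndarray] = []
    i_steps: list[int] = []
    rec = record_voltage or {}
    v_time = None
    v_traces = {}
    if rec:
        v_time = (np.arange(n_steps) + 1) * dt
        for pop_name, ids in rec.items():
            v_traces[pop_name] = (np.asarray(ids),
                                  np.empty((n_steps, len(ids))))

    rng_noise = streams["noise"]
    amp_ee = syn["EE"].peak_conductance * st_ee.s
    amp_ie = syn["IE"].peak_conductance * st_ie.s
    amp_ei = syn["EI"].peak_conductance * st_ei.s
    amp_ii = syn["II"].peak_conductance * st_ii.s
    if model3:
        amp_ca3 = projections["CA3E"].peak_conductance * st_ca3.s
        dend_s = st_dend.s

    proj_ee = connectome["EE"]
    proj_ei = connectome["EI"]
    proj_ie = connectome["IE"]
    proj_ii = connectome["II"]
    proj_ca3 = connectome.projections.get("CA3E")

    for s in range(n_steps):
        t_now = (s + 1) * dt

        # advance synaptic kernels and collect arrivals scheduled for this step
        for state, buf in ((st_ee, buf_ee), (st_ie, buf_ie),
                           (st_ei, buf_ei), (st_ii, buf_ii)):
            state.step()
            inc = buf.pop()
            state.add_dense(inc)

        g_exc_e = st_ee.value
        if model3:
            st_ca3.step()
            st_dend.step()
            st_dend.add_dense(buf_dend.pop())
            # CA3 spikes arriving now: EPSC + coincidence counting
            indptr, arr_ids = ca3_deliveries
            ids_now = arr_ids[indptr[s]:indptr[s + 1]]
            if ids_now.size:
                targets = proj_ca3.targets_of(ids_now)
                if targets.size:
                    np.add.at(st_ca3.a_d, targets, amp_ca3)
                    np.add.at(st_ca3.a_r, targets, amp_ca3)
                    np.add.at(ca3_counts, targets, 1)
            fired = detector.step(ca3_counts, t_now, voltage=pop_e.voltage,
                                  inhibitory_reversal=e_params.inhibitory_reversal)
            ca3_counts[:] = 0
            if fired.size:
                # somatic current kernels start tau_D after the trigger
                buf_dend.schedule(fired, peaks[fired] * dend_s)
                dend_spike_ids.append(fired.copy())
                dend_spike_steps.append(s)
            g_exc_e = g_exc_e + st_ca3.value

        for pulse in pulses:
            if pulse.ids.size == 0:
                continue
            if abs(t_now - np.mean(pulse.t0)) < 8.0 * (pulse.sigma_g
                    + (np.ptp(pulse.t0) if pulse.t0.size else 0.0)):
                g_ext = pulse.conductance_at(t_now)
                g_exc_e = g_exc_e.copy() if g_exc_e is st_ee.value else g_exc_e
                np.add.at(g_exc_e, pulse.ids, g_ext)

        dend_current = st_dend.value if model3 else 0.0  # nA
        spikes_e = pop_e.step(
            g_exc=g_exc_e, g_inh=st_ie.value,
            current_nA=dend_current, rng=rng_noise,
        ) if include_e_population else np.empty(0, dtype=np.int64)

        g_exc_i = st_ei.value
        if ff_i_amp > 0.0:
            g_exc_i = g_exc_i + gaussian_conductance(
                t_now, ff_i_amp, drive.center_time, drive.pulse_width)
        spikes_i = pop_i.step(g_exc=g_exc_i, g_inh=st_ii.value, rng=rng_noise)

        if spikes_e.size:
            e_ids.append(spikes_e.copy())
            e_steps.append(s)
            t_ee = proj_ee.targets_of(spikes_e)
            if t_ee.size:
                buf_ee.schedule(t_ee, amp_ee)
            t_ei = proj_ei.targets_of(spikes_e)
            if t_ei.size:
                buf_ei.schedule(t_ei, amp_ei)
        if spikes_i.size:
            i_ids.append(spikes_i.copy())
            i_steps.append(s)
            t_ie = proj_ie.targets_of(spikes_i)
            if t_ie.size:
                buf_ie.schedule(t_ie, amp_ie)
            t_ii = proj_ii.targets_of(spikes_i)
            if t_ii.size:
                buf_ii.schedule(t_ii, amp_ii)

        for pop_name, (ids, arr) in v_traces.items():
            src = pop_e if pop_name == "E" else pop_i
            arr[s] = src.voltage[ids]

    def _raster(pop_name: str, id_chunks, step_chunks, n: int) -> SpikeRaster:
        if id_chunks:
            ids = np.concatenate(id_chunks)
            times = np.concatenate([
                np.full(c.size, (st + 1) * dt)
                for c, st in zip(id_chunks, step_chunks)
            ])
        else:
            ids = np.empty(0, dtype=np.int64)
            times = np.empty(0)
        return SpikeRaster(pop_name, ids, times, n, duration)

    rasters = {
        "E": _raster("E", e_ids, e_steps, n_e),
        "I": _raster("I", i_ids, i_steps, n_i),
    }
    dend_raster = None
    if model3:
        rasters["CA3"] = ca3_raster
        dend_raster = _raster("E", dend_spike_ids, dend_spike_steps, n_e)

    return SimulationResult(
        rasters=rasters,
        dendritic_spikes=dend_raster,
        peak_currents=peaks,
        voltage_time=v_time,
        voltage_traces=v_traces or None,
        metadata={
            "duration": duration, "dt": dt, "seed": repr(seed),
            "variant": drive.variant,
            "interneuron_ripple_variant": bool(ff_i_amp > 0.0),
            "n_e": n_e, "n_i": n_i,
        },
    )
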