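"""Parameter containers for neurons, synapses, dendrites and external drive.

The default values describe a two-population CA1 circuit: ``N_E`` pyramidal
cells (PCs) and ``N_I`` parvalbumin-positive basket cells (PV+BCs), coupled
uniformly at random, plus an optional CA3 input population for the
dendritic-spike model variant.  Membrane parameters of the excitatory cells
are *calibrated* (see :mod:`ca1ripple.calibrate`) so that the somatic response
to the stereotyped dendritic-spike current kernel reproduces the reference
anchors: a 1 nA kernel peak depolarizes the soma by 12.78 mV, the minimal
kernel peak that elicits a somatic spike is 1.34 nA, and 5 / 10 nA kernels
elicit 2 / 4 somatic spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "NeuronPopulationParams",
    "SynapseParams",
    "DendriteParams",
    "PeakCurrentDistribution",
    "DriveSpec",
    "default_e_params",
    "default_i_params",
    "default_projections",
    "DEFAULT_CONNECTIVITY",
]


@dataclass
class NeuronPopulationParams:
    """Conductance-based leaky integrate-and-fire parameters for one population.

    Units: capacitance pF, conductance nS, voltage mV, time ms.  With these
    units conductance*voltage yields pA; currents are stored in nA and
    converted internally.
    """

    membrane_capacitance: float  # Cm, pF
    leak_conductance: float      # g_l, nS
    resting_potential: float     # E_rest, mV
    excitatory_reversal: float   # E_exc, mV
    inhibitory_reversal: float   # E_inh, mV
    spike_threshold: float       # V_thresh, mV
    reset_potential: float       # V_reset, mV
    refractory_period: float     # t_ref, ms
    noise_strength: float = 1.0  # sigma_n, mV (std of free membrane voltage)

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ValueError("Cm and g_l must be positive")
        if not (
            self.inhibitory_reversal
            < self.resting_potential
            < self.spike_threshold
            < self.excitatory_reversal
        ):
            raise ValueError(
                "require E_inh < E_rest < V_thresh < E_exc; got "
                f"E_inh={self.inhibitory_reversal}, E_rest={self.resting_potential}, "
                f"V_thresh={self.spike_threshold}, E_exc={self.excitatory_reversal}"
            )
        if not (self.inhibitory_reversal <= self.reset_potential < self.spike_threshold):
            raise ValueError("V_reset must lie in [E_inh, V_thresh)")
        if self.refractory_period < 0 or self.noise_strength < 0:
            raise ValueError("t_ref and sigma_n must be non-negative")

    @property
    def membrane_time_constant(self) -> float:
        """tau_m = Cm / g_l in ms."""
        return self.membrane_capacitance / self.leak_conductance

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynapseParams:
    """Bi-exponential conductance synapse for one projection.

    The conductance evoked by a presynaptic spike at t=0 is, for t >= tau_l,

        g(t) = g_peak * s * (exp(-(t-tau_l)/tau_d) - exp(-(t-tau_l)/tau_r)),

    with ``s`` the normalization that makes the maximum exactly ``g_peak``.
    """

    rise_time: float           # tau_r, ms
    decay_time: float          # tau_d, ms
    peak_conductance: float    # g_peak, nS
    latency: float = 0.0       # tau_l, ms
    sign: str = "excitatory"   # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if not 0 < self.rise_time < self.decay_time:
            raise ValueError(
                f"need 0 < tau_r < tau_d, got tau_r={self.rise_time}, tau_d={self.decay_time}"
            )
        if self.peak_conductance < 0 or self.latency < 0:
            raise ValueError("g_peak and tau_l must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DendriteParams:
    """Coincidence-detection dendrite of a CA1 pyramidal cell.

    At least ``coincidence_threshold`` CA3 input spikes arriving within the
    sliding window ``integration_window`` trigger a dendritic spike, provided
    the dendrite is not refractory and (if ``voltage_gate``) the somatic
    voltage is above the inhibitory reversal potential.  The stereotyped
    somatic current starts ``soma_delay`` later and has a bi-exponential
    shape (``kernel_rise``/``kernel_decay``) normalized to the cell's peak
    current.
    """

    integration_window: float = 2.0     # w_D, ms
    coincidence_threshold: int = 5      # spikes
    soma_delay: float = 2.0             # tau_D, ms
    dendritic_refractory: float = 5.0   # t_{r,D}, ms
    kernel_rise: float = 1.0            # ms
    kernel_decay: float = 4.0           # ms
    voltage_gate: bool = True

    def __post_init__(self) -> None:
        if self.integration_window <= 0:
            raise ValueError("integration window must be positive")
        if self.coincidence_threshold < 1:
            raise ValueError("coincidence threshold must be >= 1")
        if min(self.soma_delay, self.dendritic_refractory, self.kernel_rise, self.kernel_decay) < 0:
            raise ValueError("all dendrite times must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PeakCurrentDistribution:
    """Across-cell distribution of the peak somatic current of a dendritic spike.

    ``family`` one of:

    - ``lognormal``: I_peak[nA] ~ lognormal(mu, sigma)
    - ``lognormal_truncate_to_zero``: lognormal draws > cutoff are mapped to 0
    - ``lognormal_resample``: lognormal draws > cutoff are redrawn until <= cutoff
    - ``gaussian``: normal with the same mean and sd as lognormal(mu, sigma),
      negative draws clipped to 0
    """

    family: str = "lognormal"
    mu: float = 0.0
    sigma: float = 0.75
    cutoff: float = 4.0  # nA, for the truncated variants

    _FAMILIES = ("lognormal", "lognormal_truncate_to_zero", "lognormal_resample", "gaussian")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {self._FAMILIES}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DriveSpec:
    """External excitation for one simulated sharp-wave event.

    variant "model1": broad Gaussian conductance pulses, common center time
    t0, per-cell amplitudes ~ N(mean_amplitude, (amplitude_cv*mean_amplitude)^2)
    clipped at 0.  variant "model2": short pulses, common amplitude, per-cell
    center times ~ N(t0, peak_time_spread^2).  variant "model3": CA3 modeled
    as ``ca3_size`` inhomogeneous-Poisson neurons with Gaussian rate profile
    (peak ``ca3_peak_rate``, width ``peak_time_spread``); the direct
    conductance drive is absent (gamma = 0).  ``ff_inhibitory`` optionally
    adds an identical Gaussian conductance drive to every I cell.
    """

    variant: str = "model1"
    n_e_driven: int = 400
    mean_amplitude: float = 65.0      # gbar, nS
    amplitude_cv: float = 0.5         # CV_g (model 1)
    pulse_width: float = 10.0         # sigma_g, ms
    center_time: float = 50.0         # t0, ms
    peak_time_spread: float = 10.0    # sigma_t, ms (models 2 and 3)
    ca3_size: int = 15000             # N_{E,CA3}
    ca3_peak_rate: float = 8.0        # r0, Hz
    ca3_connection_prob: float = 130.0 / 15000.0
    ff_inhibitory_amplitude: float = 0.0  # gbar_I, nS; > 0 enables drive to I cells

    _VARIANTS = ("model1", "model2", "model3")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown drive variant {self.variant!r}")
        if self.pulse_width <= 0:
            raise ValueError("pulse width sigma_g must be positive")
        if self.peak_time_spread < 0 or self.amplitude_cv < 0:
            raise ValueError("spreads must be non-negative")
        if not 0 <= self.ca3_connection_prob <= 1:
            raise ValueError("CA3 connection probability must be in [0, 1]")

    @property
    def gamma(self) -> int:
        """Whether the direct (non-dendritic) external conductance is present."""
        return 0 if self.variant == "model3" else 1

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Calibrated / reconstructed defaults
# --------------------------------------------------------------------------

# E (pyramidal cell) membrane.  Cm, g_l and the threshold distance are the
# output of ca1ripple.calibrate.calibrate_e_membrane(); reversal potentials,
# resting potential and t_ref are literature-standard CA1 PC values.
_E_REST = -67.0
_E_THRESH_OFFSET = 17.1252   # mV; = 12.78 mV/nA * 1.34 nA (threshold anchor)


def default_e_params() -> NeuronPopulationParams:
    """Calibrated default excitatory (pyramidal cell) parameters."""
    return NeuronPopulationParams(
        membrane_capacitance=265.517,      # pF (calibrated, see calibrate.py)
        leak_conductance=26.5517,          # nS -> tau_m = 10 ms
        resting_potential=_E_REST,
        excitatory_reversal=0.0,
        inhibitory_reversal=-80.0,
        spike_threshold=_E_REST + _E_THRESH_OFFSET,
        reset_potential=-69.0,
        refractory_period=2.0,             # ms
        noise_strength=1.0,                # mV
    )


def default_i_params() -> NeuronPopulationParams:
    """Default inhibitory (fast-spiking PV+ basket cell) parameters.

    Reconstructed: fast membrane, 1 ms absolute refractory period so the
    population can follow near-200 Hz ripple entrainment.
    """
    return NeuronPopulationParams(
        membrane_capacitance=100.0,
        leak_conductance=10.0,             # tau_m = 10 ms
        resting_potential=-65.0,
        excitatory_reversal=0.0,
        inhibitory_reversal=-75.0,
        spike_threshold=-52.0,
        reset_potential=-67.0,
        refractory_period=1.0,
        noise_strength=1.0,
    )


def default_projections(model: str = "model3") -> dict:
    """Default synaptic kernels per projection.

    Keys are projection names 'EE', 'EI' (E onto I), 'IE' (I onto E), 'II',
    'CA3E'.  The I->E latency is 0.5 ms in model 3 and 1.0 ms in models 1-2.
    CA3->E values (1/2 ms rise/decay, 0.75 nS, 1 ms delay) are as stated for
    the Schaffer-collateral EPSP; E->I AMPA peak 3 nS with 0.5 ms rise is the
    stated baseline; the remaining kernels are fast GABA_A / AMPA values
    typical of CA1 ripple models (reconstructed).
    """
    ie_latency = 0.5 if model == "model3" else 1.0
    return {
        "EE": SynapseParams(rise_time=0.5, decay_time=2.0, peak_conductance=0.2,
                            latency=1.0, sign="excitatory"),
        "EI": SynapseParams(rise_time=0.5, decay_time=2.0, peak_conductance=3.0,
                            latency=1.0, sign="excitatory"),
        "IE": SynapseParams(rise_time=0.45, decay_time=1.2, peak_conductance=6.0,
                            latency=ie_latency, sign="inhibitory"),
        "II": SynapseParams(rise_time=0.45, decay_time=1.2, peak_conductance=8.0,
                            latency=1.2, sign="inhibitory"),
        "CA3E": SynapseParams(rise_time=1.0, decay_time=2.0, peak_conductance=0.75,
                              latency=1.0, sign="excitatory"),
    }


#: Default network sizes and connection probabilities.
DEFAULT_CONNECTIVITY = {
    "N_E": 12000,
    "N_I": 200,
    "N_CA3": 15000,
    "p_EE": 0.0164,
    "p_EI": 0.1,
    "p_IE": 0.1,
    "p_II": 0.2,
    "p_CA3E": 130.0 / 15000.0,
}
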