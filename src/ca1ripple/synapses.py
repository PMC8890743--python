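"""Bi-exponential conductance kernels and their exact state-space integration.

A presynaptic spike at time 0 evokes, after the transmission delay tau_l,

    g(t) = g_peak * s * (exp(-(t - tau_l)/tau_d) - exp(-(t - tau_l)/tau_r))

for t >= tau_l and 0 before.  ``s`` normalizes the double exponential so that
its maximum equals ``g_peak``; contributions of successive spikes add
linearly.  The same kernel shape (with current instead of conductance
amplitude) is reused for the somatic impact of dendritic spikes.
"""

from __future__ import annotations

import numpy as np

from .params import SynapseParams

__all__ = [
    "biexp_normalization",
    "biexp_kernel",
    "biexp_peak_time",
    "deliver_spike",
    "BiexpState",
]


def biexp_normalization(tau_r: float, tau_d: float) -> float:
    """Normalization factor s such that max_t s*(e^{-t/tau_d} - e^{-t/tau_r}) = 1.

    Closed form:  1/s = (tau_r/tau_d)^{tau_r/(tau_d - tau_r)}
                        - (tau_r/tau_d)^{tau_d/(tau_d - tau_r)}.
    """
    if not 0 < tau_r < tau_d:
        raise ValueError(f"need 0 < tau_r < tau_d, got ({tau_r}, {tau_d})")
    ratio = tau_r / tau_d
    denom = tau_d - tau_r
    inv_s = ratio ** (tau_r / denom) - ratio ** (tau_d / denom)
    return 1.0 / inv_s


def biexp_peak_time(tau_r: float, tau_d: float) -> float:
    """Time (after the delay) at which the bi-exponential kernel peaks."""
    if not 0 < tau_r < tau_d:
        raise ValueError(f"need 0 < tau_r < tau_d, got ({tau_r}, {tau_d})")
    return np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)


def biexp_kernel(t, tau_r: float, tau_d: float, peak: float = 1.0, delay: float = 0.0):
    """Evaluate the normalized bi-exponential kernel at time(s) ``t``.

    Returns 0 for t < delay.  ``peak`` is the kernel maximum (conductance in
    nS or current in nA, depending on use).
    """
    t = np.asarray(t, dtype=float)
    s = biexp_normalization(tau_r, tau_d)
    tt = t - delay
    out = np.where(
        tt >= 0.0,
        peak * s * (np.exp(-np.clip(tt, 0.0, None) / tau_d)
                    - np.exp(-np.clip(tt, 0.0, None) / tau_r)),
        0.0,
    )
    return out if out.ndim else float(out)


def deliver_spike(synapse: SynapseParams, t_spike: float, t):
    """Postsynaptic conductance time course contributed by one presynaptic spike.

    The contribution starts at ``t_spike + synapse.latency``; multiple spikes
    superpose linearly (simply sum the returned arrays).
    """
    return biexp_kernel(
        np.asarray(t, dtype=float) - t_spike,
        synapse.rise_time,
        synapse.decay_time,
        peak=synapse.peak_conductance,
        delay=synapse.latency,
    )


class BiexpState:
    """Exact per-step integrator for a sum of bi-exponential kernels.

    Maintains two exponential traces a_d, a_r (one pair per neuron); the
    instantaneous amplitude is ``a_d - a_r``.  Each arriving spike increments
    both traces by ``peak * s`` (amplitudes may differ per event), after which
    the difference follows the normalized kernel exactly: the per-step decay
    multiplications are the analytic solution of the kernel ODEs, so the
    integration is exact at step boundaries for any dt.
    """

    def __init__(self, n: int, tau_r: float, tau_d: float, dt: float):
        if not 0 < tau_r < tau_d:
            raise ValueError(f"need 0 < tau_r < tau_d, got ({tau_r}, {tau_d})")
        self.n = int(n)
        self.s = biexp_normalization(tau_r, tau_d)
        self._decay_d = float(np.exp(-dt / tau_d))
        self._decay_r = float(np.exp(-dt / tau_r))
        self.a_d = np.zeros(self.n)
        self.a_r = np.zeros(self.n)

    def step(self) -> None:
        self.a_d *= self._decay_d
        self.a_r *= self._decay_r

    def add(self, idx, amplitude) -> None:
        """Register kernel onsets: ``amplitude`` is the kernel peak per event."""
        inc = amplitude * self.s
        np.add.at(self.a_d, idx, inc)
        np.add.at(self.a_r, idx, inc)

    def add_dense(self, inc: np.ndarray) -> None:
        """Add per-neuron increments that are already peak*s and dense."""
        self.a_d += inc
        self.a_r += inc

    @property
    def value(self) -> np.ndarray:
        """Current kernel amplitude per neuron (>= 0 up to rounding)."""
        return self.a_d - self.a_r
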