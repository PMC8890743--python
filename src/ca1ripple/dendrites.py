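"""Dendritic-spike generation by coincidence detection on CA3 input.

Each pyramidal cell owns one effective dendritic compartment.  When at
least ``coincidence_threshold`` CA3 input spikes arrive within the sliding
integration window ``w_D`` (and the dendrite is not refractory, and the
somatic voltage is above the inhibitory reversal potential if the gate is
on), a dendritic spike is triggered at the arrival time of the
threshold-th input — the earliest moment the condition is verifiable.
The stereotyped somatic current starts ``tau_D`` later: a bi-exponential
kernel (1 ms rise / 4 ms decay) whose maximum is the cell's peak current,
drawn once per neuron from a heavy-tailed distribution and constant over
time.  Currents of successive dendritic spikes superpose linearly.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .params import DendriteParams, PeakCurrentDistribution
from .synapses import biexp_kernel

__all__ = [
    "detect_dendritic_spikes",
    "sample_peak_currents",
    "dendritic_current",
    "lognormal_cdf",
    "CoincidenceDetector",
]


def detect_dendritic_spikes(
    input_times: np.ndarray,
    params: DendriteParams,
    voltage_at: Optional[Callable[[float], float]] = None,
    inhibitory_reversal: float = -80.0,
) -> np.ndarray:
    """Dendritic spike times of one neuron from its sorted CA3 arrival times.

    A spike is triggered at input time t when the half-open window
    (t - w_D, t] contains at least ``coincidence_threshold`` arrivals, no
    dendritic spike occurred in the preceding ``t_{r,D}``, and — if the
    voltage gate is on and ``voltage_at`` is given — the somatic voltage at
    t is above ``inhibitory_reversal``.
    """
    times = np.asarray(input_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("input times must be sorted")
    spikes: list[float] = []
    last = -np.inf
    lo = 0
    for j, t in enumerate(times):
        while times[lo] <= t - params.integration_window:
            lo += 1
        if j - lo + 1 < params.coincidence_threshold:
            continue
        if t - last < params.dendritic_refractory:
            continue
        if params.voltage_gate and voltage_at is not None:
            if voltage_at(t) <= inhibitory_reversal:
                continue
        spikes.append(t)
        last = t
    return np.asarray(spikes)


def lognormal_cdf(x, mu: float, sigma: float):
    """CDF of the lognormal distribution, (1 + erf((ln x - mu)/(sqrt(2) sigma)))/2."""
    from scipy.special import erf

    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, 0.5 * (1.0 + erf((np.log(np.clip(x, 1e-300, None)) - mu)
                                           / (np.sqrt(2.0) * sigma))), 0.0)
    return out if out.ndim else float(out)


def sample_peak_currents(n: int, dist: PeakCurrentDistribution,
                         rng: np.random.Generator | int) -> np.ndarray:
    """One peak somatic current (nA) per neuron, fixed for the whole simulation.

    Families: plain lognormal(mu, sigma); truncate-to-zero (draws above the
    cutoff mapped to 0); resample (draws above the cutoff redrawn);
    Gaussian with the mean exp(mu + sigma^2/2) and sd mean*sqrt(exp(sigma^2)-1)
    of the matching lognormal, negative draws clipped to 0.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if dist.family == "gaussian":
        mean = np.exp(dist.mu + dist.sigma ** 2 / 2.0)
        sd = mean * np.sqrt(np.expm1(dist.sigma ** 2))
        return np.clip(rng.normal(mean, sd, size=n), 0.0, None)
    draws = rng.lognormal(dist.mu, dist.sigma, size=n)
    if dist.family == "lognormal_truncate_to_zero":
        draws[draws > dist.cutoff] = 0.0
    elif dist.family == "lognormal_resample":
        bad = draws > dist.cutoff
        while np.any(bad):
            draws[bad] = rng.lognormal(dist.mu, dist.sigma, size=int(bad.sum()))
            bad = draws > dist.cutoff
    return draws


def dendritic_current(t, peak: float, params: DendriteParams | None = None):
    """Somatic current (nA) at time(s) ``t`` after the current onset.

    Bi-exponential kernel normalized so its maximum equals ``peak``.
    """
    if peak < 0:
        raise ValueError("peak current must be >= 0")
    params = params or DendriteParams()
    return biexp_kernel(t, params.kernel_rise, params.kernel_decay, peak=peak)


class CoincidenceDetector:
    """Vectorized per-step sliding-window coincidence detection.

    Used inside the network loop: arrival counts are pushed per step; the
    detector keeps a circular history over the integration window and
    returns the neurons whose dendrite fires this step.  The dendritic
    refractory clock starts at the trigger time.
    """

    def __init__(self, n: int, params: DendriteParams, dt: float):
        self.params = params
        self.n = int(n)
        self.dt = float(dt)
        self.w_steps = max(1, int(round(params.integration_window / dt)))
        self._hist = np.zeros((self.w_steps, self.n), dtype=np.int32)
        self._sum = np.zeros(self.n, dtype=np.int32)
        self._slot = 0
        self.ready_at = np.zeros(self.n)  # next time a dendritic spike is allowed

    def step(self, arrival_counts: np.ndarray, t_now: float,
             voltage: Optional[np.ndarray] = None,
             inhibitory_reversal: float = -80.0) -> np.ndarray:
        """Advance one step; returns indices of neurons triggering a dendritic spike.

        ``arrival_counts``: CA3 input spikes arriving at each dendrite this
        step; ``t_now`` the time at the end of the step.
        """
        self._sum += arrival_counts - self._hist[self._slot]
        self._hist[self._slot] = arrival_counts
        self._slot = (self._slot + 1) % self.w_steps
        elig = (arrival_counts > 0) & (self._sum >= self.params.coincidence_threshold) \
            & (self.ready_at <= t_now)
        if self.params.voltage_gate and voltage is not None:
            elig &= voltage > inhibitory_reversal
        fired = np.flatnonzero(elig)
        if fired.size:
            self.ready_at[fired] = t_now + self.params.dendritic_refractory
        return fired
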