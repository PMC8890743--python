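"""External excitation: Gaussian sharp-wave conductances and CA3 Poisson input.

Three variants of afferent sharp-wave drive to the CA1 pyramidal population:

* model 1 — temporally broad Gaussian conductance pulses (width sigma_g)
  with a common center time t0 and per-cell amplitudes drawn from a Gaussian
  (mean gbar, sd CV_g * gbar, clipped at 0);
* model 2 — temporally narrow pulses with a common amplitude gbar and
  per-cell center times drawn from N(t0, sigma_t^2);
* model 3 — an explicit CA3 population of inhomogeneous-Poisson neurons
  with Gaussian rate profile r(t) = r0 exp(-(t - t0)^2 / (2 sigma_t^2)),
  generated by thinning against the peak rate.

An optional feedforward drive applies one identical Gaussian conductance to
every basket cell (the interneuron-ripple variant of model 1).
"""

from __future__ import annotations

import numpy as np

from .analysis import SpikeRaster
from .params import DriveSpec

__all__ = [
    "gaussian_conductance",
    "sample_model1_amplitudes",
    "sample_model2_peaktimes",
    "generate_ca3_spikes",
    "expected_ca3_spikes_per_neuron",
    "feedforward_i_drive",
]


def gaussian_conductance(t, g0: float, t0: float, sigma_g: float):
    """Gaussian conductance profile g(t) = g0 exp(-(t - t0)^2 / (2 sigma_g^2))."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    t = np.asarray(t, dtype=float)
    out = g0 * np.exp(-((t - t0) ** 2) / (2.0 * sigma_g ** 2))
    return out if out.ndim else float(out)


def sample_model1_amplitudes(n_e: int, gbar: float, cv_g: float,
                             rng: np.random.Generator | int) -> np.ndarray:
    """Per-cell peak conductances ~ N(gbar, (cv_g*gbar)^2), clipped at 0 (nS)."""
    if cv_g < 0:
        raise ValueError("cv_g must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return np.clip(rng.normal(gbar, cv_g * gbar, size=n_e), 0.0, None)


def sample_model2_peaktimes(n_e: int, sigma_t: float,
                            rng: np.random.Generator | int,
                            t0: float = 50.0) -> np.ndarray:
    """Per-cell pulse center times ~ N(t0, sigma_t^2) (ms)."""
    if sigma_t < 0:
        raise ValueError("sigma_t must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return rng.normal(t0, sigma_t, size=n_e)


def expected_ca3_spikes_per_neuron(r0: float, sigma_t: float) -> float:
    """Gaussian-rate integral: expected spike count = r0 * sigma_t * sqrt(2 pi).

    (r0 in Hz, sigma_t in ms; the window is assumed to cover the pulse.)
    """
    return r0 * 1e-3 * sigma_t * np.sqrt(2.0 * np.pi)


def generate_ca3_spikes(
    n_ca3: int,
    r0: float = 8.0,
    t0: float = 50.0,
    sigma_t: float = 10.0,
    duration: float = 100.0,
    rng: np.random.Generator | int = 0,
) -> SpikeRaster:
    """Independent inhomogeneous-Poisson spike trains for the CA3 population.

    Thinning: homogeneous Poisson candidates at the peak rate ``r0`` are
    kept with probability r(t)/r0.  ``r0`` in Hz, times in ms.
    """
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if r0 == 0.0:
        return SpikeRaster("CA3", np.empty(0, dtype=np.int64), np.empty(0),
                           n_ca3, duration)
    rate_per_ms = r0 * 1e-3
    counts = rng.poisson(rate_per_ms * duration, size=n_ca3)
    total = int(counts.sum())
    ids = np.repeat(np.arange(n_ca3, dtype=np.int64), counts)
    times = rng.uniform(0.0, duration, size=total)
    keep = rng.random(total) < np.exp(-((times - t0) ** 2) / (2.0 * sigma_t ** 2))
    return SpikeRaster("CA3", ids[keep], times[keep], n_ca3, duration).sorted_by_time()


def feedforward_i_drive(n_i: int, gbar_i: float, sigma_g: float = 10.0,
                        t0: float = 50.0):
    """Identical Gaussian conductance drive for every I cell.

    Returns a callable t -> per-cell conductance array (nS); with
    ``gbar_i = 0`` the drive vanishes (baseline models).
    """
    def profile(t: float) -> np.ndarray:
        if gbar_i == 0.0:
            return np.zeros(n_i)
        return np.full(n_i, gaussian_conductance(t, gbar_i, t0, sigma_g))

    return profile
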