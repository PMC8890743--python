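"""Coincidence detection, peak-current distributions, somatic current kernel."""

import numpy as np
import pytest

from ca1ripple.dendrites import (
    CoincidenceDetector,
    dendritic_current,
    detect_dendritic_spikes,
    lognormal_cdf,
    sample_peak_currents,
)
from ca1ripple.params import DendriteParams, PeakCurrentDistribution


def brute_force_oracle(times, params):
    """O(n^2) reference: scan every input, count the window, apply refractoriness."""
    times = np.asarray(times, dtype=float)
    spikes = []
    last = -np.inf
    for j, t in enumerate(times):
        in_window = np.sum((times > t - params.integration_window) & (times <= t))
        if in_window >= params.coincidence_threshold and t - last >= params.dendritic_refractory:
            spikes.append(t)
            last = t
    return np.asarray(spikes)


def test_five_coincident_inputs_trigger_at_threshold_arrival(dendrite):
    """Five inputs within 2 ms trigger one dendritic spike at the 5th arrival."""
    times = np.array([0.0, 0.4, 0.8, 1.2, 1.6])
    spikes = detect_dendritic_spikes(times, dendrite)
    assert np.array_equal(spikes, [1.6])


def test_four_inputs_below_threshold_do_nothing(dendrite):
    assert detect_dendritic_spikes(np.array([0.0, 0.5, 1.0, 1.5]), dendrite).size == 0


def test_dense_train_yields_single_spike_within_refractory(dendrite):
    """10 inputs at 0.2 ms spacing: one dendritic spike only (t_rD = 5 ms)."""
    times = np.arange(10) * 0.2
    spikes = detect_dendritic_spikes(times, dendrite)
    assert spikes.size == 1 and spikes[0] == pytest.approx(0.8)


def test_two_qualifying_windows_outside_refractory(dendrite):
    """Coincidences at ~1 ms and ~7 ms produce two dendritic spikes."""
    burst1 = np.linspace(0.0, 1.0, 5)
    burst2 = np.linspace(6.0, 7.0, 5)
    spikes = detect_dendritic_spikes(np.concatenate([burst1, burst2]), dendrite)
    assert np.allclose(spikes, [1.0, 7.0])


def test_voltage_gate_blocks_hyperpolarized_soma(dendrite):
    times = np.array([0.0, 0.4, 0.8, 1.2, 1.6])
    spikes = detect_dendritic_spikes(times, dendrite,
                                     voltage_at=lambda t: -90.0,
                                     inhibitory_reversal=-80.0)
    assert spikes.size == 0


def test_oracle_equivalence_on_random_trains(dendrite):
    """Exact agreement with the brute-force window-scan on 1000 random trains."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = rng.integers(0, 60)
        times = np.sort(rng.uniform(0, 30, size=n))
        fast = detect_dendritic_spikes(times, dendrite)
        slow = brute_force_oracle(times, dendrite)
        assert np.array_equal(fast, slow)


def test_refractory_spacing_exact(dendrite):
    rng = np.random.default_rng(7)
    for _ in range(200):
        times = np.sort(rng.uniform(0, 50, size=rng.integers(10, 120)))
        spikes = detect_dendritic_spikes(times, dendrite)
        if spikes.size > 1:
            assert np.min(np.diff(spikes)) >= dendrite.dendritic_refractory


def test_online_detector_matches_offline_on_quantized_trains(dendrite):
    """The step-based network detector equals the offline detector when
    arrivals are quantized to simulation steps."""
    dt = 0.01
    rng = np.random.default_rng(3)
    for _ in range(50):
        n_steps = 3000
        counts = (rng.random(n_steps) < 0.02).astype(np.int32)
        counts *= rng.integers(1, 4, size=n_steps).astype(np.int32)
        det = CoincidenceDetector(1, dendrite, dt)
        online = []
        for s in range(n_steps):
            fired = det.step(np.array([counts[s]], dtype=np.int32), (s + 1) * dt)
            if fired.size:
                online.append((s + 1) * dt)
        arrival_times = np.repeat((np.flatnonzero(counts) + 1) * dt,
                                  counts[counts > 0])
        offline = detect_dendritic_spikes(arrival_times, dendrite)
        assert np.allclose(online, offline)


def test_lognormal_cdf_matches_scipy():
    """The closed-form CDF agrees with scipy.stats.lognorm across the support
    and exceeds 99.8% at x = 10 nA for (mu, sigma) = (0, 0.75)."""
    from scipy.stats import lognorm

    x = np.linspace(0.01, 20, 500)
    assert np.allclose(lognormal_cdf(x, 0.0, 0.75), lognorm(s=0.75).cdf(x),
                       atol=1e-12)
    assert lognormal_cdf(10.0, 0.0, 0.75) > 0.998
    assert lognormal_cdf(0.0, 0.3, 0.5) == 0.0


def test_degenerate_lognormal_sigma_zero():
    dist = PeakCurrentDistribution(family="lognormal", mu=0.4, sigma=0.0)
    draws = sample_peak_currents(1000, dist, 1)
    assert np.allclose(draws, np.exp(0.4))


def test_truncate_to_zero_fraction_matches_cdf():
    dist = PeakCurrentDistribution(family="lognormal_truncate_to_zero",
                                   mu=0.0, sigma=0.75, cutoff=4.0)
    draws = sample_peak_currents(200000, dist, 2)
    frac_zero = np.mean(draws == 0.0)
    expected = 1.0 - lognormal_cdf(4.0, 0.0, 0.75)
    assert frac_zero == pytest.approx(expected, abs=3 * np.sqrt(expected / 200000) + 1e-4)
    assert draws.max() <= 4.0


def test_resample_stays_below_cutoff_with_lognormal_shape():
    dist = PeakCurrentDistribution(family="lognormal_resample",
                                   mu=0.0, sigma=0.75, cutoff=4.0)
    draws = sample_peak_currents(100000, dist, 3)
    assert np.all((0.0 < draws) & (draws <= 4.0))


def test_gaussian_family_matches_lognormal_moments():
    """The Gaussian family uses the matching lognormal's mean/sd; clipping at
    zero shifts the sample mean to the censored-normal value
    m*Phi(m/s) + s*phi(m/s)."""
    from scipy.stats import norm

    mu, sigma = 0.0, 0.75
    dist = PeakCurrentDistribution(family="gaussian", mu=mu, sigma=sigma)
    draws = sample_peak_currents(400000, dist, 4)
    m = np.exp(mu + sigma ** 2 / 2)
    s = m * np.sqrt(np.expm1(sigma ** 2))
    censored_mean = m * norm.cdf(m / s) + s * norm.pdf(m / s)
    assert draws.mean() == pytest.approx(censored_mean, rel=0.01)
    assert np.all(draws >= 0.0)
    # without clipping the underlying draws match the lognormal moments
    raw = np.random.default_rng(4).normal(m, s, size=400000)
    assert raw.mean() == pytest.approx(m, rel=0.01)
    assert raw.std() == pytest.approx(s, rel=0.01)


def test_dendritic_current_peak_normalization(dendrite):
    t = np.linspace(0, 40, 400001)
    assert np.max(dendritic_current(t, 2.5, dendrite)) == pytest.approx(2.5, rel=1e-6)
    assert np.all(dendritic_current(t, 0.0, dendrite) == 0.0)


def test_overlapping_currents_superpose_linearly(dendrite):
    """Somatic currents of successive dendritic spikes add up linearly."""
    from ca1ripple.synapses import BiexpState

    dt = 0.01
    n = 1500
    state = BiexpState(1, dendrite.kernel_rise, dendrite.kernel_decay, dt)
    values = np.empty(n)
    onsets = {0: 2.0, 300: 3.0}  # step -> peak
    for i in range(n):
        state.step()
        if i in onsets:
            state.add(np.array([0]), onsets[i])
        values[i] = state.value[0]
    t = np.arange(n) * dt
    expected = dendritic_current(t - 0.0, 2.0, dendrite) \
        + dendritic_current(t - 300 * dt, 3.0, dendrite)
    expected[t < 300 * dt] = dendritic_current(t[t < 300 * dt], 2.0, dendrite)
    assert np.allclose(values, expected, atol=1e-10)
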