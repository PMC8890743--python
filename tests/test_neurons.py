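"""Single-neuron dynamics: leak fixed point, anchors, noise scaling, refractoriness."""

import numpy as np
import pytest

from ca1ripple.neurons import (
    Population,
    find_threshold_peak_current,
    simulate_kernel_injection,
)
from ca1ripple.params import NeuronPopulationParams


def test_rest_is_fixed_point(e_params_quiet):
    """With all inputs and noise off the voltage stays exactly at E_rest."""
    pop = Population(5, e_params_quiet, dt=0.01)
    for _ in range(2000):
        pop.step()
    assert np.allclose(pop.voltage, e_params_quiet.resting_potential, atol=1e-12)


def test_leak_relaxation_matches_closed_form(e_params_quiet):
    """Leak-only decay toward rest follows exp(-t/tau_m) to < 0.01 mV."""
    p = e_params_quiet
    pop = Population(1, p, dt=0.01)
    v0 = p.resting_potential + 10.0
    pop.state.voltage[:] = v0
    times, values = [], []
    for i in range(3000):
        pop.step()
        times.append((i + 1) * 0.01)
        values.append(pop.voltage[0])
    expected = p.resting_potential + (v0 - p.resting_potential) * np.exp(
        -np.asarray(times) / p.membrane_time_constant)
    assert np.max(np.abs(np.asarray(values) - expected)) < 0.01


@pytest.mark.parametrize(
    "peak, depol, n_spikes",
    [
        (0.1, 1.28, 0),
        (1.0, 12.78, 0),
        (5.0, None, 2),
        (10.0, None, 4),
    ],
)
def test_dendritic_kernel_injection_anchors(e_params_quiet, dendrite, peak, depol, n_spikes):
    """Stereotyped current injections reproduce the calibration anchors."""
    res = simulate_kernel_injection(e_params_quiet, peak, dendrite)
    assert res["n_spikes"] == n_spikes
    if depol is not None:
        assert res["peak_depolarization"] == pytest.approx(depol, abs=0.01)


def test_subthreshold_linearity(e_params_quiet, dendrite):
    """Peak depolarization is proportional to the kernel peak below threshold."""
    r01 = simulate_kernel_injection(e_params_quiet, 0.1, dendrite)
    r1 = simulate_kernel_injection(e_params_quiet, 1.0, dendrite)
    ratio = r1["peak_depolarization"] / r01["peak_depolarization"]
    assert ratio == pytest.approx(10.0, rel=0.01)


def test_threshold_current_bisection(e_params_quiet, dendrite):
    """Minimal spiking kernel peak sits at 1.34 nA for the calibrated membrane."""
    thr = find_threshold_peak_current(e_params_quiet, dendrite)
    assert thr == pytest.approx(1.34, abs=0.02)


def test_threshold_current_decreases_with_lower_spike_threshold(e_params_quiet, dendrite):
    """Moving V_thresh toward rest monotonically lowers the threshold current."""
    thresholds = []
    for offset in (17.1252, 12.0, 8.0):
        d = e_params_quiet.to_dict()
        d["spike_threshold"] = d["resting_potential"] + offset
        thresholds.append(find_threshold_peak_current(
            NeuronPopulationParams(**d), dendrite))
    assert thresholds[0] > thresholds[1] > thresholds[2]


def test_threshold_consistent_with_linear_response(e_params_quiet, dendrite):
    """threshold current * (peak depol per nA) ~ V_thresh - E_rest within 5%."""
    thr = find_threshold_peak_current(e_params_quiet, dendrite)
    per_na = simulate_kernel_injection(e_params_quiet, 1.0, dendrite)[
        "peak_depolarization"]
    gap = e_params_quiet.spike_threshold - e_params_quiet.resting_potential
    assert thr * per_na == pytest.approx(gap, rel=0.05)


def test_noise_off_means_exact_dynamics(e_params_quiet):
    """sigma_n = 0 produces bitwise-identical trajectories across rngs."""
    rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
    pops = [Population(3, e_params_quiet, dt=0.01) for _ in range(2)]
    for pop, rng in zip(pops, (rng1, rng2)):
        pop.state.voltage[:] = e_params_quiet.resting_potential + 5.0
        for _ in range(500):
            pop.step(rng=rng)
    assert np.array_equal(pops[0].voltage, pops[1].voltage)


@pytest.mark.parametrize("dt", [0.02, 0.01])
def test_noise_calibration_stationary_std(e_params, dt):
    """Passive-membrane voltage std equals sigma_n (1 mV) within 5%, any dt."""
    n = 4000
    pop = Population(n, e_params, dt=dt)
    rng = np.random.default_rng(1234)
    burn = int(60.0 / dt)
    for _ in range(burn):
        pop.step(rng=rng)
    samples = []
    sample_every = int(1.0 / dt)
    for i in range(int(30.0 / dt)):
        pop.step(rng=rng)
        if i % sample_every == 0:
            samples.append(pop.voltage.copy())
    v = np.concatenate(samples)
    assert np.std(v) == pytest.approx(e_params.noise_strength, rel=0.05)
    assert np.mean(v) == pytest.approx(e_params.resting_potential, abs=0.1)


def test_refractory_period_limits_firing(e_params):
    """No two spikes closer than t_ref; <= 50 spikes per E cell in 100 ms."""
    d = e_params.to_dict()
    d["noise_strength"] = 0.0
    p = NeuronPopulationParams(**d)
    pop = Population(1, p, dt=0.01)
    spike_times = []
    for i in range(10000):  # 100 ms, huge sustained current
        if pop.step(current_nA=20.0).size:
            spike_times.append((i + 1) * 0.01)
    assert len(spike_times) <= 50
    assert np.min(np.diff(spike_times)) >= p.refractory_period - 1e-9


def test_step_size_convergence_of_spike_times(e_params_quiet, dendrite):
    """Halving dt moves the 5 nA protocol's spike times by < 0.1 ms."""
    t1 = simulate_kernel_injection(e_params_quiet, 5.0, dendrite, dt=0.01)["spike_times"]
    t2 = simulate_kernel_injection(e_params_quiet, 5.0, dendrite, dt=0.005)["spike_times"]
    assert len(t1) == len(t2) == 2
    assert np.max(np.abs(t1 - t2)) < 0.1


def test_refractory_voltage_pinned_at_reset(e_params_quiet):
    """During the absolute refractory period the voltage stays at V_reset."""
    pop = Population(1, e_params_quiet, dt=0.01)
    fired = False
    for _ in range(400):
        spikes = pop.step(current_nA=10.0)
        if spikes.size:
            fired = True
            for _ in range(int(e_params_quiet.refractory_period / 0.01) - 1):
                pop.step(current_nA=10.0)
                assert pop.voltage[0] == e_params_quiet.reset_potential
            break
    assert fired


def test_nonfinite_voltage_raises(e_params_quiet):
    pop = Population(1, e_params_quiet, dt=0.01)
    with pytest.raises(FloatingPointError):
        pop.step(current_nA=np.nan)
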