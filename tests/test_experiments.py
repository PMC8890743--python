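"""End-to-end experiment runs: determinism, sweeps, replay, fixtures, CLI."""

import json

import numpy as np
import pytest

from ca1ripple.experiments import (
    ExperimentConfig,
    ReplaySettings,
    default_replay_config,
    generate_fixture,
    run_experiment,
    run_realization,
    run_replay_demo,
    run_sweep,
)


def _tiny_model1(seed=0, **drive):
    d = {"n_e_driven": 100, "mean_amplitude": 40.0, "amplitude_cv": 0.5,
         "pulse_width": 10.0}
    d.update(drive)
    return ExperimentConfig(variant="model1", n_e=600, n_i=40, p_ee=0.0164,
                            duration=100.0, dt=0.02, n_realizations=1,
                            master_seed=seed, drive=d)


def test_identical_seed_identical_rasters():
    cfg = _tiny_model1(seed=13)
    res1, _ = run_realization(cfg, 0)
    res2, _ = run_realization(cfg, 0)
    for pop in ("E", "I"):
        assert np.array_equal(res1.rasters[pop].times, res2.rasters[pop].times)
        assert np.array_equal(res1.rasters[pop].neuron_ids,
                              res2.rasters[pop].neuron_ids)


def test_different_realizations_differ():
    cfg = _tiny_model1(seed=13)
    res1, _ = run_realization(cfg, 0)
    res2, _ = run_realization(cfg, 1)
    assert not (res1.rasters["E"].n_spikes == res2.rasters["E"].n_spikes
                and np.array_equal(res1.rasters["E"].times,
                                   res2.rasters["E"].times))


def test_zero_drive_near_silence():
    """Without external drive only noise-driven stray spikes remain."""
    cfg = _tiny_model1(seed=2, mean_amplitude=0.0)
    res, stats = run_realization(cfg, 0)
    assert stats.q_E < 0.02
    assert stats.q_I < 0.2


def test_run_experiment_writes_outputs(tmp_path):
    cfg = _tiny_model1(seed=4)
    cfg.n_realizations = 2
    agg, per_real, _ = run_experiment(cfg, out_dir=tmp_path)
    assert agg.n_realizations == 2 and len(per_real) == 2
    assert np.isfinite(agg.std_f_I)
    for name in ("config.yaml", "raster_E_r0.tsv", "statistics.json",
                 "statistics_realizations.csv", "manifest.json"):
        assert (tmp_path / name).exists()


def test_sweep_row_count_and_determinism(tmp_path):
    cfg = _tiny_model1(seed=6)
    axes = {"gbar": [30.0, 50.0], "nE": [50, 100]}
    df1 = run_sweep(cfg, axes, n_realizations=2, out_csv=tmp_path / "s1.csv")
    df2 = run_sweep(cfg, axes, n_realizations=2, out_csv=tmp_path / "s2.csv")
    assert len(df1) == 4 * 2  # |grid| x realizations
    assert (tmp_path / "s1.csv").read_bytes() == (tmp_path / "s2.csv").read_bytes()


def test_sweep_single_point_reduces_to_run(tmp_path):
    cfg = _tiny_model1(seed=7)
    df = run_sweep(cfg, {"gbar": [40.0]}, n_realizations=1)
    _, stats = run_realization(cfg, 0)
    assert df.loc[0, "f_I"] == pytest.approx(stats.f_I, nan_ok=True)
    assert df.loc[0, "C_I"] == pytest.approx(stats.C_I, nan_ok=True)


def test_unknown_sweep_axis_rejected():
    with pytest.raises(ValueError):
        run_sweep(_tiny_model1(), {"bogus": [1.0]})


def test_config_yaml_round_trip(tmp_path):
    cfg = ExperimentConfig(variant="model3", n_e=3000, peak_currents={"sigma": 0.6},
                           replay=ReplaySettings(enabled=True, k=4))
    cfg.to_yaml(tmp_path / "c.yaml")
    loaded = ExperimentConfig.from_yaml(tmp_path / "c.yaml")
    assert loaded.to_dict() == cfg.to_dict()
    assert isinstance(loaded.replay, ReplaySettings)


def test_invalid_config_rejected():
    cfg = ExperimentConfig(variant="model3", n_e=200, n_i=20,
                           peak_currents={"family": "nonsense"})
    with pytest.raises(ValueError):
        cfg.resolve_peak_currents()
    with pytest.raises(ValueError):
        ExperimentConfig(variant="model1", e_params={"refractory_period": -1.0}
                         ).resolve_e_params()


def _reduced_replay(seed=3):
    cfg = default_replay_config(seed=seed, n_e=3000)
    cfg.p_ee = 197.0 / 3000
    cfg.p_ei = 0.4
    return cfg


def test_replay_sequence_on_structured_network():
    """Structured network: groups activate in index order at ripple cadence,
    active E cells spike about once."""
    demo = run_replay_demo(_reduced_replay())
    assert demo["success"]
    assert len(demo["sequence"]) >= 4
    assert demo["stats"].C_E < 1.5
    gaps = np.diff([t for _, t in demo["sequence"]])
    period = 1000.0 / demo["frequency"]
    assert np.all(gaps > 0)
    assert abs(np.mean(gaps) - period) < 2.5  # inter-group interval ~ 1/f


def test_replay_negative_control_random_network():
    """The same drive on an unmasked random connectome yields no sequence."""
    demo = run_replay_demo(_reduced_replay(), masks=False)
    assert not demo["success"]


def test_fixture_determinism(tmp_path):
    a = generate_fixture("modulated_poisson", tmp_path / "a", seed=5)
    b = generate_fixture("modulated_poisson", tmp_path / "b", seed=5)
    assert a[0].read_bytes() == b[0].read_bytes()
    (proto,) = generate_fixture("single_neuron_protocol", tmp_path)
    payload = json.loads(proto.read_text())
    assert payload["peaks_nA"] == [0.1, 1.0, 5.0, 10.0]


def test_frequency_rises_with_stronger_recurrent_inhibition(small_model3_config):
    """Raising p_II while lowering p_IE speeds up the network rhythm."""
    import copy

    base = small_model3_config
    mod = copy.deepcopy(base)
    mod.p_ii, mod.p_ie = 0.3, 0.05
    f_base = np.mean([run_realization(base, r)[1].f_E for r in range(2)])
    f_mod = np.mean([run_realization(mod, r)[1].f_E for r in range(2)])
    assert f_mod > f_base


def test_interneuron_variant_flagged_and_oscillates():
    """Feedforward drive to I cells alone produces a high-frequency rhythm."""
    cfg = ExperimentConfig(
        variant="model1", n_e=600, n_i=200, dt=0.02, n_realizations=1,
        master_seed=9,
        drive={"n_e_driven": 0, "mean_amplitude": 0.0,
               "ff_inhibitory_amplitude": 20.0},
    )
    res, stats = run_realization(cfg, 0)
    assert res.metadata["interneuron_ripple_variant"]
    assert stats.q_I > 0.9
    assert 100.0 <= stats.f_I <= 250.0


def test_cli_simulate_and_analyze(tmp_path):
    from click.testing import CliRunner

    from ca1ripple.cli import main

    cfg = _tiny_model1(seed=3)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    runner = CliRunner()
    out = runner.invoke(main, ["simulate", "--config", str(tmp_path / "cfg.yaml"),
                               "--seed", "3", "--out", str(tmp_path / "out")])
    assert out.exit_code == 0, out.output
    out2 = runner.invoke(main, ["analyze", str(tmp_path / "out" / "raster_E_r0.tsv")])
    assert out2.exit_code == 0, out2.output
    payload = json.loads(out2.output)
    assert payload["population"] == "E" and payload["n"] == 600
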