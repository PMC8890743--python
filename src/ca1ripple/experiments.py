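"""Configuration-driven experiment runner: single events, sweeps, replay.

An :class:`ExperimentConfig` plus a master seed determines every random
draw of a simulation — connectivity, drive amplitudes and peak times, CA3
spikes, membrane noise and peak dendritic currents all derive from named
substreams — so runs are exactly reproducible and realizations differ in
both connectivity and noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    EventStatistics,
    SpikeRaster,
    aggregate_realizations,
    detect_group_sequence,
    event_frequency,
    spike_statistics,
)
from .connectivity import Connectome, build_random_connectome, build_replay_connectome
from .network import GaussianPulseSet, SimulationResult, simulate_event
from .params import (
    DEFAULT_CONNECTIVITY,
    DendriteParams,
    DriveSpec,
    NeuronPopulationParams,
    PeakCurrentDistribution,
    SynapseParams,
    default_e_params,
    default_i_params,
    default_projections,
)

__all__ = [
    "ExperimentConfig",
    "ReplaySettings",
    "run_realization",
    "run_experiment",
    "run_sweep",
    "run_replay_demo",
    "generate_fixture",
]


@dataclass
class ReplaySettings:
    """Structured-network settings for the replay experiments."""

    enabled: bool = False
    k: int = 9                       # K: populations split into K+1 groups
    init_amplitude: float = 60.0     # nS, initiation pulse onto group E_0
    init_time: float = 25.0          # ms
    init_width: float = 1.5          # ms (sigma_g of the initiation pulse)
    preserve_inhibitory_in_degree: bool = True
    dendritic_scale_nonzero_groups: float = 1.0  # model-3 replay: weaken dendrites


@dataclass
class ExperimentConfig:
    """Complete description of one experiment (network + drive + analysis)."""

    variant: str = "model3"
    n_e: int = DEFAULT_CONNECTIVITY["N_E"]
    n_i: int = DEFAULT_CONNECTIVITY["N_I"]
    n_ca3: int = DEFAULT_CONNECTIVITY["N_CA3"]
    p_ee: float = DEFAULT_CONNECTIVITY["p_EE"]
    p_ei: float = DEFAULT_CONNECTIVITY["p_EI"]
    p_ie: float = DEFAULT_CONNECTIVITY["p_IE"]
    p_ii: float = DEFAULT_CONNECTIVITY["p_II"]
    p_ca3e: float = DEFAULT_CONNECTIVITY["p_CA3E"]
    duration: float = 100.0
    dt: float = 0.01
    n_realizations: int = 10
    master_seed: int = 0
    e_params: Optional[dict] = None      # overrides of default_e_params fields
    i_params: Optional[dict] = None
    projections: Optional[dict] = None   # name -> field overrides
    dendrite: Optional[dict] = None
    peak_currents: Optional[dict] = None  # PeakCurrentDistribution fields
    drive: Optional[dict] = None          # DriveSpec overrides
    replay: ReplaySettings = field(default_factory=ReplaySettings)

    # -- resolution into concrete parameter objects -------------------------
    def resolve_e_params(self) -> NeuronPopulationParams:
        base = default_e_params().to_dict()
        base.update(self.e_params or {})
        return NeuronPopulationParams(**base)

    def resolve_i_params(self) -> NeuronPopulationParams:
        base = default_i_params().to_dict()
        base.update(self.i_params or {})
        return NeuronPopulationParams(**base)

    def resolve_projections(self) -> dict:
        proj = default_projections(self.variant)
        for name, mods in (self.projections or {}).items():
            d = proj[name].to_dict()
            d.update(mods)
            proj[name] = SynapseParams(**d)
        return proj

    def resolve_dendrite(self) -> DendriteParams:
        base = DendriteParams().to_dict()
        base.update(self.dendrite or {})
        return DendriteParams(**base)

    def resolve_peak_currents(self) -> PeakCurrentDistribution:
        base = PeakCurrentDistribution().to_dict()
        base.update(self.peak_currents or {})
        return PeakCurrentDistribution(**base)

    def resolve_drive(self) -> DriveSpec:
        base = DriveSpec(variant=self.variant).to_dict()
        base.update({**(self.drive or {}), "variant": self.variant})
        base["ca3_size"] = self.n_ca3
        base["ca3_connection_prob"] = self.p_ca3e
        return DriveSpec(**base)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("replay"), dict):
            d["replay"] = ReplaySettings(**d["replay"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _realization_seeds(master_seed: int, realization: int):
    """Independent (connectivity, simulation) seed sequences per realization."""
    conn = np.random.SeedSequence(entropy=[int(master_seed), realization, 0])
    sim = np.random.SeedSequence(entropy=[int(master_seed), realization, 1])
    return conn, sim


def _build_connectome(config: ExperimentConfig, seed) -> Connectome:
    n_ca3 = config.n_ca3 if config.variant == "model3" else 0
    if config.replay.enabled:
        kp1 = config.replay.k + 1
        p_ie = config.p_ie
        if config.replay.preserve_inhibitory_in_degree:
            # I_k -> E_k only: scale the within-block probability so each E
            # cell keeps the random network's mean inhibitory in-degree
            p_ie = min(1.0, config.p_ie * kp1)
        return build_replay_connectome(
            config.n_e, config.n_i, k=config.replay.k, n_ca3=n_ca3,
            p_ee=config.p_ee, p_ei=config.p_ei, p_ie=p_ie, p_ii=config.p_ii,
            p_ca3e=config.p_ca3e, seed=seed,
        )
    return build_random_connectome(
        config.n_e, config.n_i, n_ca3=n_ca3,
        p_ee=config.p_ee, p_ei=config.p_ei, p_ie=config.p_ie, p_ii=config.p_ii,
        p_ca3e=config.p_ca3e, seed=seed,
    )


def _replay_extras(config: ExperimentConfig, connectome: Connectome):
    """Initiation pulse onto group E_0 and optional per-group dendritic scale."""
    r = config.replay
    e0 = np.flatnonzero(connectome.e_groups == 0)
    pulses = [GaussianPulseSet(
        ids=e0,
        amplitudes=np.full(e0.size, r.init_amplitude),
        t0=np.full(e0.size, r.init_time),
        sigma_g=r.init_width,
    )]
    scale = None
    if config.variant == "model3" and r.dendritic_scale_nonzero_groups != 1.0:
        scale = np.where(connectome.e_groups == 0, 1.0,
                         r.dendritic_scale_nonzero_groups)
    return pulses, scale


def run_realization(
    config: ExperimentConfig,
    realization: int = 0,
    connectome: Optional[Connectome] = None,
    record_voltage: Optional[dict] = None,
) -> tuple[SimulationResult, EventStatistics]:
    """Simulate one realization and measure the event statistics."""
    conn_seed, sim_seed = _realization_seeds(config.master_seed, realization)
    if connectome is None:
        connectome = _build_connectome(config, conn_seed)
    extra_pulses = scale = None
    if config.replay.enabled:
        extra_pulses, scale = _replay_extras(config, connectome)
    drive = config.resolve_drive()
    result = simulate_event(
        connectome,
        drive,
        e_params=config.resolve_e_params(),
        i_params=config.resolve_i_params(),
        projections=config.resolve_projections(),
        dendrite=config.resolve_dendrite() if config.variant == "model3" else None,
        peak_current_dist=(config.resolve_peak_currents()
                           if config.variant == "model3" else None),
        duration=config.duration,
        dt=config.dt,
        seed=sim_seed,
        extra_pulses=extra_pulses,
        peak_current_scale=scale,
        record_voltage=record_voltage,
    )
    result.metadata["realization"] = realization
    result.metadata["master_seed"] = config.master_seed
    t0 = drive.center_time
    stats = _measure(result, t0)
    return result, stats


def _measure(result: SimulationResult, t0: float) -> EventStatistics:
    r_e, r_i = result.rasters["E"], result.rasters["I"]
    c_e, q_e = spike_statistics(r_e)
    c_i, q_i = spike_statistics(r_i)
    return EventStatistics(
        f_E=event_frequency(r_e, t0=t0),
        f_I=event_frequency(r_i, t0=t0),
        C_E=c_e, C_I=c_i, q_E=q_e, q_I=q_i,
    )


def run_experiment(
    config: ExperimentConfig,
    out_dir=None,
    keep_results: bool = False,
) -> tuple[EventStatistics, list[EventStatistics], list[SimulationResult]]:
    """Run ``config.n_realizations`` independent realizations and aggregate.

    Realizations differ in both connectivity and noise.  With ``out_dir``,
    rasters of the first realization, per-realization statistics and the
    resolved configuration are written out.
    """
    per_real: list[EventStatistics] = []
    results: list[SimulationResult] = []
    first_result = None
    for r in range(config.n_realizations):
        result, stats = run_realization(config, r)
        per_real.append(stats)
        if r == 0:
            first_result = result
        if keep_results:
            results.append(result)
    agg = aggregate_realizations(per_real)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        for name, raster in first_result.rasters.items():
            raster.save(out_dir / f"raster_{name}_r0.tsv")
        pd.DataFrame([s.to_dict() for s in per_real]).to_csv(
            out_dir / "statistics_realizations.csv", index=False)
        (out_dir / "statistics.json").write_text(
            json.dumps(agg.to_dict(), indent=1))
        (out_dir / "manifest.json").write_text(json.dumps({
            "master_seed": config.master_seed,
            "n_realizations": config.n_realizations,
            "variant": config.variant,
            "metadata_r0": first_result.metadata,
        }, indent=1, default=str))
    return agg, per_real, results


#: sweepable parameter names -> how they modify the configuration
def _apply_axis(config: ExperimentConfig, name: str, value) -> ExperimentConfig:
    import copy

    cfg = copy.deepcopy(config)
    if name == "mu":
        cfg.peak_currents = {**(cfg.peak_currents or {}), "mu": float(value)}
    elif name == "sigma":
        cfg.peak_currents = {**(cfg.peak_currents or {}), "sigma": float(value)}
    elif name in ("gbar", "mean_amplitude"):
        cfg.drive = {**(cfg.drive or {}), "mean_amplitude": float(value)}
    elif name in ("n_e_driven", "nE"):
        cfg.drive = {**(cfg.drive or {}), "n_e_driven": int(value)}
    elif name == "r0":
        cfg.drive = {**(cfg.drive or {}), "ca3_peak_rate": float(value)}
    elif name in ("p_ii", "p_ie", "p_ei", "p_ee"):
        setattr(cfg, name, float(value))
    else:
        raise ValueError(f"unknown sweep axis {name!r}")
    return cfg


def run_sweep(
    config: ExperimentConfig,
    axes: dict,
    n_realizations: Optional[int] = None,
    out_csv=None,
    max_grid: int = 400,
) -> pd.DataFrame:
    """Sweep two (or one) config parameters over a grid.

    ``axes``: {name: values}; every grid point is simulated with
    ``n_realizations`` independent realizations (default: the config's).
    Returns a tidy DataFrame with one row per grid point and realization.
    """
    names = list(axes)
    if not 1 <= len(names) <= 2:
        raise ValueError("sweep supports one or two axes")
    grid = [(v,) for v in axes[names[0]]] if len(names) == 1 else [
        (a, b) for a in axes[names[0]] for b in axes[names[1]]]
    if len(grid) > max_grid:
        raise ValueError(f"grid of {len(grid)} points exceeds budget {max_grid}")
    n_real = n_realizations or config.n_realizations
    rows = []
    for values in grid:
        cfg = config
        for name, value in zip(names, values):
            cfg = _apply_axis(cfg, name, value)
        cfg.n_realizations = n_real
        for r in range(n_real):
            _, stats = run_realization(cfg, r)
            row = {name: value for name, value in zip(names, values)}
            row["realization"] = r
            row.update(stats.to_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_replay_demo(
    config: Optional[ExperimentConfig] = None,
    seed: int = 0,
    participation: float = 0.5,
    masks: bool = True,
) -> dict:
    """Run a structured-network replay event and report the group sequence.

    Returns a dict with the simulation result, the detected (group,
    activation time) sequence, whether the sequence is strictly increasing
    over >= 2 groups, and the co-measured oscillation frequency.  With
    ``masks=False`` the same drive and initiation pulse run on an
    *unstructured* random connectome (group labels kept for the readout) —
    the negative control, which must not produce a monotone sequence.
    """
    config = config or default_replay_config(seed=seed)
    if not config.replay.enabled:
        raise ValueError("config.replay.enabled must be True for the replay demo")
    connectome_seed, _ = _realization_seeds(config.master_seed, 0)
    if masks:
        connectome = _build_connectome(config, connectome_seed)
    else:
        from .connectivity import _partition_groups

        n_ca3 = config.n_ca3 if config.variant == "model3" else 0
        connectome = build_random_connectome(
            config.n_e, config.n_i, n_ca3=n_ca3,
            p_ee=config.p_ee, p_ei=config.p_ei, p_ie=config.p_ie,
            p_ii=config.p_ii, p_ca3e=config.p_ca3e, seed=connectome_seed,
        )
        connectome.e_groups = _partition_groups(config.n_e, config.replay.k + 1)
        connectome.i_groups = _partition_groups(config.n_i, config.replay.k + 1)
    result, stats = run_realization(config, 0, connectome=connectome)
    sequence = detect_group_sequence(
        result.rasters["E"], connectome.e_groups, participation=participation)
    groups = [g for g, _ in sequence]
    times = [t for _, t in sequence]
    # a replay needs distinct, ordered activations: simultaneous group
    # activation (as on an unmasked network) is not a sequence
    success = (
        len(groups) >= 2
        and all(b > a for a, b in zip(groups, groups[1:]))
        and all(t2 > t1 for t1, t2 in zip(times, times[1:]))
    )
    return {
        "result": result,
        "stats": stats,
        "sequence": sequence,
        "success": success,
        "frequency": stats.f_E,
    }


def default_replay_config(seed: int = 0, n_e: int = 12000, n_i: int = 200,
                          variant: str = "model1") -> ExperimentConfig:
    """Reference replay configuration (model-1-style drive, K = 9).

    Relative to the random model-1 network the sharp-wave amplitude and the
    E->I conductance are reduced so that I-cell spiking can gate E groups
    effectively: E cells then spike only when they see the inhibitory gap.
    The initiation pulse onto group E_0 precedes the sharp-wave peak.
    """
    return ExperimentConfig(
        variant=variant,
        n_e=n_e, n_i=n_i,
        n_realizations=1,
        master_seed=seed,
        drive={"n_e_driven": n_e, "mean_amplitude": 30.0, "amplitude_cv": 0.1,
               "pulse_width": 10.0, "center_time": 50.0},
        projections={"EI": {"peak_conductance": 2.0}},
        replay=ReplaySettings(enabled=True, k=9, init_time=35.0,
                              init_amplitude=60.0, init_width=1.5),
    )


def generate_fixture(kind: str, out_dir, seed: int = 0, **params) -> list:
    """Write small deterministic fixtures used by the test suite.

    kinds: ``modulated_poisson`` (sinusoidally rate-modulated Poisson raster,
    ground truth for the frequency estimator), ``grouped_sequence``
    (hand-built raster with groups firing at fixed spacing) and
    ``single_neuron_protocol`` (the current-injection protocol of the
    calibration anchors).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = []
    if kind == "modulated_poisson":
        n = int(params.get("n", 300))
        duration = float(params.get("duration", 200.0))
        f_mod = float(params.get("f_mod", 180.0))
        base_rate = float(params.get("base_rate", 30.0))  # Hz per neuron
        depth = float(params.get("depth", 0.9))
        rate_ms = base_rate * 1e-3
        counts = rng.poisson(rate_ms * duration * (1 + depth), size=n)
        ids = np.repeat(np.arange(n), counts)
        times = rng.uniform(0, duration, size=ids.size)
        accept = (1 + depth * np.sin(2 * np.pi * f_mod * times * 1e-3)) / (1 + depth)
        keep = rng.random(ids.size) < accept
        raster = SpikeRaster("E", ids[keep], times[keep], n, duration).sorted_by_time()
        path = out_dir / f"modulated_poisson_{int(f_mod)}Hz.tsv"
        raster.save(path)
        written.append(path)
    elif kind == "grouped_sequence":
        k = int(params.get("k", 9))
        per_group = int(params.get("per_group", 20))
        spacing = float(params.get("spacing", 5.0))
        duration = float(params.get("duration", 100.0))
        ids, times = [], []
        for g in range(k + 1):
            members = np.arange(g * per_group, (g + 1) * per_group)
            ids.append(members)
            times.append(np.full(per_group, 10.0 + g * spacing)
                         + rng.uniform(0, 0.5, per_group))
        raster = SpikeRaster("E", np.concatenate(ids), np.concatenate(times),
                             (k + 1) * per_group, duration).sorted_by_time()
        path = out_dir / "grouped_sequence.tsv"
        raster.save(path)
        labels = np.repeat(np.arange(k + 1), per_group)
        lpath = out_dir / "grouped_sequence_labels.tsv"
        np.savetxt(lpath, labels, fmt="%d")
        written += [path, lpath]
    elif kind == "single_neuron_protocol":
        protocol = {
            "kernel": {"rise_ms": 1.0, "decay_ms": 4.0, "soma_delay_ms": 2.0},
            "peaks_nA": [0.1, 1.0, 5.0, 10.0],
            "duration_ms": 80.0,
            "dt_ms": 0.01,
            "noise": 0.0,
        }
        path = out_dir / "single_neuron_protocol.json"
        path.write_text(json.dumps(protocol, indent=1))
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
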