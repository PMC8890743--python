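"""Measurement pipelines on spike rasters.

The statistics mirror the ones used to characterize simulated sharp
wave/ripple events: the oscillation frequency of the population rate (f_E,
f_I; spectral peak in a broad 80-350 Hz search band, with the 140-200 Hz
sub-band classified as the ripple range), its standard deviation across
independent network realizations, the mean number of spikes per active cell
(C_E, C_I) and the fraction of cells active at least once (q_E, q_I).  For
structured networks, :func:`detect_group_sequence` recovers the order in
which replay groups activate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeRaster",
    "EventStatistics",
    "RIPPLE_BAND",
    "population_rate",
    "oscillation_frequency",
    "event_frequency",
    "spike_statistics",
    "aggregate_realizations",
    "detect_group_sequence",
]

#: The ripple frequency band (Hz).
RIPPLE_BAND = (140.0, 200.0)

#: Default spectral search band (Hz) for the population-rate peak.
SEARCH_BAND = (80.0, 350.0)


@dataclass
class SpikeRaster:
    """Event list of one population: (neuron id, spike time in ms)."""

    population: str          # "E" | "I" | "CA3"
    neuron_ids: np.ndarray
    times: np.ndarray        # ms
    n: int                   # population size
    duration: float          # ms

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() > self.duration + 1e-9:
                raise ValueError("spike times must lie in [0, duration]")
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n:
                raise ValueError("neuron ids must lie in [0, n)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def sorted_by_time(self) -> "SpikeRaster":
        order = np.argsort(self.times, kind="stable")
        return SpikeRaster(self.population, self.neuron_ids[order],
                           self.times[order], self.n, self.duration)

    def spike_counts(self) -> np.ndarray:
        """Number of spikes per neuron."""
        return np.bincount(self.neuron_ids, minlength=self.n)

    # -- headered columnar text format --------------------------------------
    def save(self, path) -> None:
        raster = self.sorted_by_time()
        with open(path, "w") as fh:
            fh.write(f"# population={self.population} N={self.n} "
                     f"duration_ms={self.duration}\n")
            for nid, t in zip(raster.neuron_ids, raster.times):
                fh.write(f"{nid}\t{t:.6f}\n")

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing raster header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            data = np.empty((0, 2))
        return cls(population=meta["population"],
                   neuron_ids=data[:, 0].astype(np.int64), times=data[:, 1],
                   n=int(meta["N"]), duration=float(meta["duration_ms"]))


@dataclass
class EventStatistics:
    """Per-event (or realization-averaged) summary statistics."""

    f_E: float = np.nan
    f_I: float = np.nan
    C_E: float = np.nan
    C_I: float = np.nan
    q_E: float = np.nan
    q_I: float = np.nan
    n_realizations: int = 1
    std_f_E: float = np.nan
    std_f_I: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def in_ripple_band(self) -> bool:
        lo, hi = RIPPLE_BAND
        return bool(np.isfinite(self.f_E) and lo <= self.f_E <= hi)


def population_rate(raster: SpikeRaster, bin_ms: float = 1.0,
                    t_start: float = 0.0, t_stop: Optional[float] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Binned population rate in Hz: counts / (bin * N).

    Returns (bin centers in ms, rate in Hz).
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    t_stop = raster.duration if t_stop is None else t_stop
    edges = np.arange(t_start, t_stop + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(raster.times, bins=edges)
    rate = counts / (bin_ms * 1e-3) / raster.n
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def oscillation_frequency(rate: np.ndarray, bin_ms: float = 1.0,
                          band: tuple[float, float] = SEARCH_BAND,
                          min_resolution_hz: float = 1.0
                          ) -> tuple[float, float]:
    """Frequency (Hz) and power of the maximal spectral peak of a rate series.

    The series is mean-subtracted, Hann-windowed and zero-padded so the FFT
    resolution is at most ``min_resolution_hz``; the peak is searched within
    ``band``.  A flat series returns (nan, 0).
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size < 4 or np.ptp(rate) == 0:
        return float("nan"), 0.0
    x = (rate - rate.mean()) * np.hanning(rate.size)
    fs = 1000.0 / bin_ms  # Hz
    nfft = int(2 ** np.ceil(np.log2(max(rate.size, fs / min_resolution_hz))))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=bin_ms * 1e-3)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel) or spec[sel].max() == 0:
        return float("nan"), 0.0
    i = np.argmax(spec[sel])
    return float(freqs[sel][i]), float(spec[sel][i])


def event_frequency(raster: SpikeRaster, t0: float = 50.0,
                    half_window: float = 30.0, bin_ms: float = 1.0,
                    band: tuple[float, float] = SEARCH_BAND) -> float:
    """Spectral peak frequency of an event centered at ``t0``.

    The population rate is computed on ``bin_ms`` bins over
    [t0 - half_window, t0 + half_window] clipped to the raster duration.
    """
    start = max(0.0, t0 - half_window)
    stop = min(raster.duration, t0 + half_window)
    _, rate = population_rate(raster, bin_ms=bin_ms, t_start=start, t_stop=stop)
    f, _ = oscillation_frequency(rate, bin_ms=bin_ms, band=band)
    return f


def spike_statistics(raster: SpikeRaster) -> tuple[float, float]:
    """(C, q): spikes per active cell and fraction of active cells.

    q = (# neurons with >= 1 spike) / N; C = total spikes / active neurons,
    nan when no cell is active.
    """
    counts = raster.spike_counts()
    active = int(np.count_nonzero(counts))
    q = active / raster.n
    c = float(counts.sum() / active) if active else float("nan")
    return c, q


def aggregate_realizations(stats: Sequence[EventStatistics]) -> EventStatistics:
    """Element-wise mean over realizations; sample std (n-1) of the frequencies."""
    if not stats:
        raise ValueError("need at least one realization")
    arr = {name: np.array([getattr(s, name) for s in stats])
           for name in ("f_E", "f_I", "C_E", "C_I", "q_E", "q_I")}
    out = EventStatistics(
        **{name: float(np.nanmean(v)) for name, v in arr.items()},
        n_realizations=len(stats),
    )
    if len(stats) >= 2:
        out.std_f_E = float(np.nanstd(arr["f_E"], ddof=1))
        out.std_f_I = float(np.nanstd(arr["f_I"], ddof=1))
    return out


def detect_group_sequence(
    raster: SpikeRaster,
    group_labels: np.ndarray,
    participation: float = 0.5,
    window_ms: float = 4.0,
    step_ms: float = 0.25,
) -> list[tuple[int, float]]:
    """Activation order of replay groups.

    A group activates at the earliest window start t such that at least
    ``participation`` of its neurons spike within [t, t + window_ms).
    Returns (group, activation time) pairs sorted by time; groups that never
    reach the criterion are omitted.  A strictly increasing group index over
    the returned list indicates successful replay.
    """
    group_labels = np.asarray(group_labels)
    if group_labels.size != raster.n:
        raise ValueError("group_labels must have one entry per neuron")
    activations: list[tuple[int, float]] = []
    for g in np.unique(group_labels):
        members = np.flatnonzero(group_labels == g)
        need = int(np.ceil(participation * members.size))
        sel = np.isin(raster.neuron_ids, members)
        times = raster.times[sel]
        ids = raster.neuron_ids[sel]
        if times.size == 0 or need == 0:
            continue
        order = np.argsort(times)
        times, ids = times[order], ids[order]
        found = None
        for t in np.arange(0.0, raster.duration - window_ms + step_ms, step_ms):
            lo = np.searchsorted(times, t, side="left")
            hi = np.searchsorted(times, t + window_ms, side="left")
            if hi - lo >= need and np.unique(ids[lo:hi]).size >= need:
                found = float(t)
                break
        if found is not None:
            activations.append((int(g), found))
    activations.sort(key=lambda pair: pair[1])
    return activations
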