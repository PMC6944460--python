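"""Multi-electrode array (MEA) spike-train metrics.

Implements the analysis chain for 16-electrode well recordings of cultured
neurons: extracellular spike detection from raw voltage traces, per-electrode
burst detection, well-wide network-burst detection, a cross-correlogram
synchrony index, light-evoked response metrics, well-level quality control,
and control-normalized group summaries.

Definitions follow the Axion-style conventions used in the source study:

* spike — threshold crossing of the 200–3000 Hz band-passed trace at
  6 x (robust) SD;
* electrode burst — a maximal run of >= 5 spikes on one electrode with every
  inter-spike interval strictly below 100 ms;
* network burst — a maximal run of >= 50 well-pooled spikes with pooled ISI
  strictly below 100 ms and >= 35% of the well's electrodes contributing;
* synchrony index — the mass within +/-20 ms of the pair-averaged,
  unit-normalized cross-correlogram (so 1.0 for coincident trains and
  window/max_lag for independent homogeneous trains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


# --------------------------------------------------------------------------
# containers and configuration
# --------------------------------------------------------------------------

@dataclass
class WellRecording:
    """Spike trains for one MEA well.

    Parameters
    ----------
    trains
        One sorted array of spike times (seconds) per electrode, indexed by
        electrode id 0..n_electrodes-1.
    duration
        Recording length in seconds.
    well_id
        Optional label used by writers.
    """

    trains: list[np.ndarray]
    duration: float
    well_id: str = "well_0"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("recording duration must be positive")
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for e, t in enumerate(self.trains):
            if np.any(np.diff(t) < 0):
                raise ValueError(f"electrode {e}: spike times must be sorted")

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes in the well as (times, electrode ids), time-sorted.

        Simultaneous spikes on different electrodes are ordered by electrode
        id so pooled runs are deterministic.
        """
        times = np.concatenate([t for t in self.trains]) if self.trains else np.array([])
        elecs = np.concatenate(
            [np.full(len(t), e, dtype=int) for e, t in enumerate(self.trains)]
        ) if self.trains else np.array([], dtype=int)
        order = np.lexsort((elecs, times))
        return times[order], elecs[order]


@dataclass
class SpikeDetectConfig:
    fs: float = 12500.0
    band: tuple[float, float] = (200.0, 3000.0)
    threshold_sd: float = 6.0
    # a ~1 ms biphasic waveform spans ~3 ms after zero-phase band-passing;
    # crossings inside that span are one spike
    dead_time: float = 0.003
    polarity: str = "both"  # "both" | "neg" | "pos"
    order: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("band must lie inside (0, fs/2)")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")


@dataclass
class BurstConfig:
    min_spikes: int = 5
    max_isi: float = 0.100

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.max_isi <= 0:
            raise ValueError("max_isi must be positive")


@dataclass
class NetworkBurstConfig:
    min_spikes: int = 50
    max_isi: float = 0.100
    min_electrode_fraction: float = 0.35
    # participation denominator: "all" electrodes in the well (matches the
    # worked 6/16 = 0.375 definition) or only "active" ones
    denominator: str = "all"

    def __post_init__(self) -> None:
        if not 0 < self.min_electrode_fraction <= 1:
            raise ValueError("min_electrode_fraction must be in (0, 1]")


@dataclass
class SynchronyConfig:
    window: float = 0.020
    bin: float = 0.001
    max_lag: float = 0.5

    def __post_init__(self) -> None:
        if self.bin <= 0:
            raise ValueError("bin must be positive")
        if self.window > self.max_lag:
            raise ValueError("window must not exceed max_lag")


@dataclass
class EvokedConfig:
    n_stimuli: int = 10
    response_window: float = 0.100

    def __post_init__(self) -> None:
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")


@dataclass
class WellQCConfig:
    min_active_electrodes: int = 12
    active_rate_threshold: float = 5.0  # spikes per minute


@dataclass
class Burst:
    electrode: int
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class NetworkBurst:
    start: float
    end: float
    n_spikes: int
    electrodes: frozenset[int]
    participation: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EvokedStats:
    """Per-electrode evoked responses averaged over stimuli."""

    mean_count: np.ndarray            # spikes per stimulus window, per electrode
    mean_latency: np.ndarray          # s; NaN where no stimulus evoked a spike
    n_responding_stimuli: np.ndarray  # stimuli with >= 1 spike, per electrode
    n_stimuli: int


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------

def robust_sd(x: np.ndarray) -> float:
    """Gaussian-consistent robust SD: median absolute deviation x 1.4826.

    Preferred over the sample SD for thresholding because large spikes
    inflate a naive SD and raise the threshold against themselves.
    """
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) * 1.4826)


def bandpass(trace: np.ndarray, config: SpikeDetectConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the raw voltage trace."""
    sos = signal.butter(config.order, config.band, btype="bandpass",
                        fs=config.fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def detect_spikes(trace: np.ndarray, config: SpikeDetectConfig | None = None) -> np.ndarray:
    """Detect extracellular spikes by thresholding the band-passed trace.

    The threshold is ``threshold_sd`` x robust SD of the filtered trace.
    A spike is registered at each threshold crossing (negative-going,
    positive-going, or both per ``config.polarity``); crossings within
    ``dead_time`` of an accepted spike are discarded.

    Returns sorted spike times in seconds.
    """
    config = config or SpikeDetectConfig()
    filt = bandpass(trace, config)
    sd = robust_sd(filt)
    if sd == 0:
        return np.array([])
    thr = config.threshold_sd * sd

    if config.polarity == "neg":
        over = filt < -thr
    elif config.polarity == "pos":
        over = filt > thr
    else:
        over = np.abs(filt) > thr
    # indices where the trace enters the supra-threshold region
    crossings = np.flatnonzero(over & ~np.concatenate(([False], over[:-1])))
    if crossings.size == 0:
        return np.array([])
    # a crossing is a new spike only if the trace stayed sub-threshold for
    # dead_time since the previous supra-threshold sample (re-arming), so
    # filter ringing around one waveform is never double-counted
    supra = np.flatnonzero(over)
    dead = int(round(config.dead_time * config.fs))
    keep = [crossings[0]]
    for c in crossings[1:]:
        # last supra sample strictly before this crossing
        si = np.searchsorted(supra, c) - 1
        if c - supra[si] >= dead:
            keep.append(c)
    # timestamp each spike at the extremum of the filtered trace within the
    # dead-time window (stabler than the first ring of the crossing)
    n = len(filt)
    peaks = [c + int(np.argmax(np.abs(filt[c:min(c + dead, n)]))) for c in keep]
    return np.asarray(peaks, dtype=float) / config.fs


# --------------------------------------------------------------------------
# bursts
# --------------------------------------------------------------------------

def _isi_runs(times: np.ndarray, max_isi: float, min_spikes: int):
    """Yield (i, j) index bounds of maximal runs with every ISI < max_isi.

    A run is maximal when it cannot be extended on either side; an ISI of
    exactly ``max_isi`` breaks a run (strict inequality).
    """
    n = len(times)
    if n == 0:
        return
    ok = np.diff(times) < max_isi
    i = 0
    while i < n:
        j = i
        while j < n - 1 and ok[j]:
            j += 1
        if j - i + 1 >= min_spikes:
            yield i, j
        i = j + 1


def detect_bursts(train: np.ndarray, config: BurstConfig | None = None,
                  electrode: int = 0) -> list[Burst]:
    """Find electrode bursts: maximal runs of >= min_spikes spikes with every
    inter-spike interval strictly below max_isi.

    Burst start/end are the first/last spike times of the run.
    """
    config = config or BurstConfig()
    train = np.asarray(train, dtype=float)
    if np.any(np.diff(train) < 0):
        raise ValueError("spike times must be sorted")
    return [
        Burst(electrode=electrode, start=float(train[i]), end=float(train[j]),
              n_spikes=j - i + 1)
        for i, j in _isi_runs(train, config.max_isi, config.min_spikes)
    ]


def detect_network_bursts(well: WellRecording,
                          config: NetworkBurstConfig | None = None) -> list[NetworkBurst]:
    """Find network bursts from the well-pooled spike sequence.

    All spikes in the well are pooled into one sorted sequence (electrode
    tags retained); maximal runs with pooled ISI < max_isi and
    >= min_spikes spikes are kept when the fraction of contributing
    electrodes reaches min_electrode_fraction.
    """
    config = config or NetworkBurstConfig()
    times, elecs = well.pooled()
    if config.denominator == "active":
        denom = sum(1 for t in well.trains if len(t) > 0)
    else:
        denom = well.n_electrodes
    if denom == 0:
        return []
    out = []
    for i, j in _isi_runs(times, config.max_isi, config.min_spikes):
        members = frozenset(int(e) for e in elecs[i:j + 1])
        participation = len(members) / denom
        if participation >= config.min_electrode_fraction:
            out.append(NetworkBurst(start=float(times[i]), end=float(times[j]),
                                    n_spikes=j - i + 1, electrodes=members,
                                    participation=participation))
    return out


# --------------------------------------------------------------------------
# synchrony
# --------------------------------------------------------------------------

def synchrony_index(well: WellRecording,
                    config: SynchronyConfig | None = None) -> float:
    """Cross-correlogram synchrony index for one well.

    For every unordered pair of electrodes (each with >= 2 spikes) the
    histogram of pairwise spike-time differences within +/-max_lag is formed
    at bin width ``bin`` and normalized to unit mass; histograms are averaged
    across pairs and the summed mass within |lag| <= window is returned.

    The index lies in [0, 1]: 1.0 when trains are coincident copies (all
    mass at zero lag) and window/max_lag in the independent homogeneous
    limit (flat correlogram). Returns NaN when no pair produces any
    difference within the lag range.
    """
    config = config or SynchronyConfig()
    trains = [t for t in well.trains if len(t) >= 2]
    if len(trains) < 2:
        raise ValueError("need >= 2 electrodes with >= 2 spikes")

    n_bins = int(round(2 * config.max_lag / config.bin))
    edges = np.linspace(-config.max_lag, config.max_lag, n_bins + 1)
    in_window = np.abs((edges[:-1] + edges[1:]) / 2) <= config.window + 1e-12

    acc = np.zeros(n_bins)
    n_pairs = 0
    for a in range(len(trains)):
        ta = trains[a]
        for b in range(a + 1, len(trains)):
            tb = trains[b]
            # differences tb - ta restricted to +/-max_lag via searchsorted
            lo = np.searchsorted(tb, ta - config.max_lag, side="left")
            hi = np.searchsorted(tb, ta + config.max_lag, side="right")
            diffs = np.concatenate([
                tb[l:h] - t for t, l, h in zip(ta, lo, hi) if h > l
            ]) if np.any(hi > lo) else np.array([])
            if diffs.size == 0:
                continue
            hist, _ = np.histogram(diffs, bins=edges)
            total = hist.sum()
            if total > 0:
                acc += hist / total
                n_pairs += 1
    if n_pairs == 0:
        warnings.warn("all electrode pairs empty within the lag range; "
                      "synchrony undefined", RuntimeWarning)
        return float("nan")
    mean_hist = acc / n_pairs
    return float(mean_hist[in_window].sum())


# --------------------------------------------------------------------------
# evoked responses, QC, group normalization
# --------------------------------------------------------------------------

def evoked_metrics(well: WellRecording, stim_times: np.ndarray,
                   config: EvokedConfig | None = None) -> EvokedStats:
    """Per-electrode evoked spike count and first-spike latency.

    Counts spikes in (t_stim, t_stim + response_window] per stimulus and
    averages over stimuli; latency is averaged over stimuli that evoked at
    least one spike (others are excluded from the latency mean but counted).
    """
    config = config or EvokedConfig()
    stim_times = np.asarray(stim_times, dtype=float)
    if np.any(np.diff(stim_times) < 0):
        raise ValueError("stimulus times must be sorted")
    if np.any(np.diff(stim_times) < config.response_window):
        raise ValueError("response windows overlap")

    n_el = well.n_electrodes
    mean_count = np.zeros(n_el)
    mean_latency = np.full(n_el, np.nan)
    n_resp = np.zeros(n_el, dtype=int)
    for e, train in enumerate(well.trains):
        counts = []
        latencies = []
        for ts in stim_times:
            lo = np.searchsorted(train, ts, side="right")
            hi = np.searchsorted(train, ts + config.response_window, side="right")
            counts.append(hi - lo)
            if hi > lo:
                latencies.append(train[lo] - ts)
        mean_count[e] = float(np.mean(counts)) if counts else 0.0
        n_resp[e] = len(latencies)
        if latencies:
            mean_latency[e] = float(np.mean(latencies))
    return EvokedStats(mean_count=mean_count, mean_latency=mean_latency,
                       n_responding_stimuli=n_resp, n_stimuli=len(stim_times))


def well_qc(well: WellRecording,
            config: WellQCConfig | None = None) -> tuple[int, bool]:
    """Count active electrodes and decide inclusion.

    An electrode is active when its firing rate reaches
    ``active_rate_threshold`` spikes/min; the well is included only when
    *more than* ``min_active_electrodes`` electrodes are active (strict).
    """
    config = config or WellQCConfig()
    if well.duration <= 0:
        raise ValueError("zero-duration recording")
    rate_per_min = np.array([len(t) / well.duration * 60.0 for t in well.trains])
    n_active = int(np.sum(rate_per_min >= config.active_rate_threshold))
    return n_active, n_active > config.min_active_electrodes


def normalize_group(values, control_values) -> np.ndarray:
    """Normalize per-well metric values to the control-group mean.

    The control group then has mean 1 by construction; apply per
    plate / DIV batch.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control group is empty")
    m = control_values.mean()
    if m <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / m


# --------------------------------------------------------------------------
# per-well summary
# --------------------------------------------------------------------------

def well_metrics(well: WellRecording,
                 burst_config: BurstConfig | None = None,
                 nb_config: NetworkBurstConfig | None = None,
                 sync_config: SynchronyConfig | None = None,
                 qc_config: WellQCConfig | None = None) -> dict:
    """One summary row per well (the per-well metrics CSV schema)."""
    burst_config = burst_config or BurstConfig()
    nb_config = nb_config or NetworkBurstConfig()
    bursts = [b for e, t in enumerate(well.trains)
              for b in detect_bursts(t, burst_config, electrode=e)]
    nbs = detect_network_bursts(well, nb_config)
    n_active, included = well_qc(well, qc_config)
    try:
        sync = synchrony_index(well, sync_config)
    except ValueError:
        sync = float("nan")
    dur = well.duration
    return {
        "well_id": well.well_id,
        "firing_rate_hz": sum(len(t) for t in well.trains) / dur / max(well.n_electrodes, 1),
        "burst_frequency_hz": len(bursts) / dur,
        "mean_burst_duration_s": float(np.mean([b.duration for b in bursts])) if bursts else np.nan,
        "mean_spikes_per_burst": float(np.mean([b.n_spikes for b in bursts])) if bursts else np.nan,
        "network_burst_frequency_hz": len(nbs) / dur,
        "network_burst_duration_s": float(np.mean([b.duration for b in nbs])) if nbs else np.nan,
        "spikes_per_network_burst": float(np.mean([b.n_spikes for b in nbs])) if nbs else np.nan,
        "synchrony_index": sync,
        "n_active": n_active,
        "included": included,
    }
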