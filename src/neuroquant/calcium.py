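"""Calcium-transient detection and behavioral-state-resolved event rates.

Per-cell fluorescence traces from microendoscope recordings are converted to
dF/F, thresholded at median + 4 x MAD (MAD = median absolute deviation, used
unscaled to match the vendor parameter), and candidate peaks whose decay to
1/e of their height takes less than 0.20 s are rejected as noise. The
animal's position track defines movement epochs (speed > 10 cm/s sustained
for >= 1 s) and stationary epochs (the complement, same persistence rule);
event rates are normalized by the time spent in each state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class EventDetectConfig:
    mad_threshold: float = 4.0
    min_decay: float = 0.20           # s
    mad_scale: float = 1.0            # 1.4826 for Gaussian-consistent scaling
    baseline_percentile: float = 10.0  # F0 for dF/F
    smoothing_window: float = 0.15    # s, moving average before peak finding
    sustain_fraction: float = 0.5     # mean post-peak level vs peak height

    def __post_init__(self) -> None:
        if self.mad_threshold <= 0:
            raise ValueError("mad_threshold must be positive")
        if self.min_decay < 0:
            raise ValueError("min_decay must be >= 0")


@dataclass
class EpochConfig:
    speed_threshold: float = 10.0   # cm/s
    min_duration: float = 1.0       # s
    smoothing_window: float = 0.25  # s, centered moving average on positions

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("threshold and min_duration must be positive")


@dataclass
class Epoch:
    state: str  # "movement" | "stationary"
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CalciumEventSet:
    cell_id: str
    event_times: np.ndarray
    trace_duration: float

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be sorted")

    @property
    def total_rate(self) -> float:
        return len(self.event_times) / self.trace_duration


@dataclass
class StateRates:
    total_rate: float
    movement_rate: float
    stationary_rate: float
    ratio: float            # movement / stationary; NaN when undefined
    movement_time: float
    stationary_time: float


# --------------------------------------------------------------------------
# dF/F and event detection
# --------------------------------------------------------------------------

def dff(trace: np.ndarray, config: EventDetectConfig | None = None) -> np.ndarray:
    """Baseline-normalized fluorescence (F - F0) / F0.

    F0 is the configured percentile of the whole trace (default 10th).
    Raises ValueError when F0 <= 0.
    """
    config = config or EventDetectConfig()
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    f0 = float(np.percentile(trace, config.baseline_percentile))
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return (trace - f0) / f0


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    pad = np.pad(x, (win // 2, win - 1 - win // 2), mode="edge")
    return np.convolve(pad, np.ones(win) / win, mode="valid")


def detect_events(dff_trace: np.ndarray, frame_rate: float,
                  config: EventDetectConfig | None = None,
                  cell_id: str = "cell_0") -> CalciumEventSet:
    """Detect calcium transients in a dF/F trace.

    The trace is lightly smoothed (moving average of ``smoothing_window``)
    and candidate events are its local maxima above
    median + mad_threshold x MAD. Three shape filters separate transients
    from noise and from spurious maxima on the decay shoulder of an earlier
    transient:

    * rise — the candidate must climb mad_threshold x MAD above the minimum
      since the previous candidate (capped at 1 s back); shoulder bumps ride
      a decay and fail this;
    * persistence — the smoothed trace must stay above the 1/e level
      (relative to the local pre-event baseline, the median of the preceding
      0.5 s) for at least ``min_decay``;
    * sustained elevation — the mean of the raw trace just after the peak
      (a window one frame longer than ``min_decay``) must hold at least
      ``sustain_fraction`` of the peak height above baseline, which rejects
      noise spikes whose amplitude collapses immediately.

    Surviving events closer than ``min_decay`` are merged keeping the larger
    peak. Event times are (raw-trace) peak times.
    """
    if frame_rate is None or frame_rate <= 0:
        raise ValueError("frame rate required")
    config = config or EventDetectConfig()
    x = np.asarray(dff_trace, dtype=float)
    n = len(x)
    win = max(int(round(config.smoothing_window * frame_rate)), 1)
    s = _moving_average(x, win) if win > 1 else x

    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med))) * config.mad_scale
    if mad == 0:
        mad = np.finfo(float).tiny
    thr = med + config.mad_threshold * mad

    cands, _ = signal.find_peaks(s, height=thr)
    pre = max(int(round(0.5 * frame_rate)), 1)
    gap = max(int(round(0.1 * frame_rate)), 1)
    wcap = max(int(round(1.0 * frame_rate)), 1)
    m = max(int(round(config.min_decay * frame_rate)) + 1, 2)

    kept: list[int] = []
    prev_cand = -n
    for p in cands:
        lo = max(p - wcap, prev_cand, 0)
        rise = s[p] - np.min(s[lo:p]) if p > lo else s[p] - med
        if rise < config.mad_threshold * mad:
            continue
        prev_cand = p

        blo = max(p - pre - gap, 0)
        bhi = max(p - gap, blo + 1)
        base_s = float(np.median(s[blo:bhi]))
        level = base_s + (s[p] - base_s) / np.e
        below = np.flatnonzero(s[p:] < level)
        decay = (below[0] if below.size else n - p) / frame_rate
        if decay < config.min_decay:
            continue

        base = float(np.median(x[blo:bhi]))
        p0 = p + int(np.argmax(x[p:min(p + 2, n)]))
        y = x[p0:p0 + m] - base
        if len(y) < m or y[0] <= 0 or np.mean(y) < config.sustain_fraction * y[0]:
            continue
        kept.append(p0)

    # merge events closer than min_decay, keeping the larger peak
    merged: list[int] = []
    min_sep = config.min_decay * frame_rate
    for p in kept:
        if merged and p - merged[-1] < min_sep:
            if x[p] > x[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)

    times = np.asarray(merged, dtype=float) / frame_rate
    return CalciumEventSet(cell_id=cell_id, event_times=times,
                           trace_duration=n / frame_rate)


def detect_events_table(traces: pd.DataFrame, config: EventDetectConfig | None = None
                        ) -> list[CalciumEventSet]:
    """Run dF/F + event detection on every cell column of a traces table.

    Expects a ``time_s`` column plus one column per cell (raw fluorescence).
    """
    config = config or EventDetectConfig()
    t = traces["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least two samples")
    frame_rate = 1.0 / float(np.median(np.diff(t)))
    out = []
    for col in traces.columns:
        if col == "time_s":
            continue
        d = dff(traces[col].to_numpy(), config)
        out.append(detect_events(d, frame_rate, config, cell_id=col))
    return out


# --------------------------------------------------------------------------
# behavioral epochs
# --------------------------------------------------------------------------

def compute_speed(track: pd.DataFrame, config: EpochConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Speed (cm/s) from smoothed positions by central finite differences.

    Positions are smoothed with a centered moving average of
    ``smoothing_window`` seconds to suppress tracker jitter.
    Returns (times, speeds). Raises on non-monotonic timestamps.
    """
    config = config or EpochConfig()
    t = track["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = float(np.median(np.diff(t)))
    win = max(int(round(config.smoothing_window / dt)), 1)
    kernel = np.ones(win) / win

    def smooth(v):
        pad = np.pad(v, (win // 2, win - 1 - win // 2), mode="edge")
        return np.convolve(pad, kernel, mode="valid")

    x = smooth(track["x_cm"].to_numpy(dtype=float))
    y = smooth(track["y_cm"].to_numpy(dtype=float))
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return t, np.hypot(vx, vy)


def segment_epochs(track: pd.DataFrame, config: EpochConfig | None = None
                   ) -> list[Epoch]:
    """Segment the session into movement and stationary epochs.

    Movement epochs are maximal intervals with speed > speed_threshold
    sustained for >= min_duration; stationary epochs are maximal intervals
    with speed <= threshold under the same persistence rule. Shorter
    intervals stay unassigned. Epochs are non-overlapping and sorted.
    """
    config = config or EpochConfig()
    t, speed = compute_speed(track, config)
    moving = speed > config.speed_threshold

    epochs: list[Epoch] = []
    dt = float(np.median(np.diff(t)))
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n - 1 and moving[j + 1] == moving[i]:
            j += 1
        start, end = t[i], t[j] + dt  # interval covers the last sample
        if end - start >= config.min_duration:
            epochs.append(Epoch(state="movement" if moving[i] else "stationary",
                                start=float(start), end=float(end)))
        i = j + 1
    return epochs


# --------------------------------------------------------------------------
# state-resolved rates
# --------------------------------------------------------------------------

def state_rates(events: CalciumEventSet, epochs: list[Epoch]) -> StateRates:
    """Event rates normalized by time spent in each behavioral state.

    total_rate uses the whole trace duration; movement/stationary rates use
    events falling inside epochs of that state over the summed epoch time.
    The movement/stationary ratio is NaN when the stationary rate is zero.
    """
    if events.trace_duration <= 0:
        raise ValueError("zero trace duration")
    times = events.event_times

    def in_state(state: str) -> tuple[int, float]:
        cnt, total = 0, 0.0
        for ep in epochs:
            if ep.state != state:
                continue
            total += ep.duration
            cnt += int(np.sum((times >= ep.start) & (times < ep.end)))
        return cnt, total

    n_mov, t_mov = in_state("movement")
    n_sta, t_sta = in_state("stationary")
    mov_rate = n_mov / t_mov if t_mov > 0 else float("nan")
    sta_rate = n_sta / t_sta if t_sta > 0 else float("nan")
    ratio = mov_rate / sta_rate if (t_sta > 0 and sta_rate > 0
                                    and np.isfinite(mov_rate)) else float("nan")
    return StateRates(total_rate=len(times) / events.trace_duration,
                      movement_rate=mov_rate, stationary_rate=sta_rate,
                      ratio=ratio, movement_time=t_mov, stationary_time=t_sta)


def session_state_rates(traces: pd.DataFrame, track: pd.DataFrame,
                        event_config: EventDetectConfig | None = None,
                        epoch_config: EpochConfig | None = None) -> pd.DataFrame:
    """Per-cell state-resolved rates for one session (traces + track)."""
    events = detect_events_table(traces, event_config)
    epochs = segment_epochs(track, epoch_config)
    rows = []
    for ev in events:
        r = state_rates(ev, epochs)
        rows.append({"cell_id": ev.cell_id, "n_events": len(ev.event_times),
                     "total_rate_hz": r.total_rate,
                     "movement_rate_hz": r.movement_rate,
                     "stationary_rate_hz": r.stationary_rate,
                     "ratio": r.ratio})
    return pd.DataFrame(rows)
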