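"""Synthetic-data generators with exact ground truth.

Every downstream quantification in this package (puncta density, dendritic
distribution index, MEA burst metrics, calcium event rates) is exercised on
data from these generators, which emulate the study's three recording
modalities:

* 16-electrode MEA wells — homogeneous Poisson background firing with
  injected electrode bursts and network bursts at exactly specified times;
  optionally rendered to raw extracellular voltage traces;
* microendoscope calcium sessions — per-cell fluorescence traces with
  instant-rise / exponential-decay transients at Poisson event times, plus a
  synchronized open-field position track built from a movement/stationary
  epoch plan;
* fluorescence images of neurons — isotropic 2-D Gaussian puncta on a
  soma + dendrite mask over a sloped, noisy background, and 1-D dendritic
  intensity profiles in clustered or diffuse mode.

All generators are deterministic given their seed, and return the ground
truth (spike/burst times, event times, epoch boundaries, puncta) alongside
the data so recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mea import WellRecording
from .profiles import IntensityProfile

ARENA_CM = 20.0  # open-field side length


# --------------------------------------------------------------------------
# MEA wells
# --------------------------------------------------------------------------

@dataclass
class WellSimConfig:
    """Simulated MEA well: Poisson background plus injected (network) bursts.

    burst_spec entries: (electrode, start_s, n_spikes, intra_isi_s).
    network_burst_spec entries: (start_s, n_electrodes, spikes_per_electrode,
    intra_isi_s) — spikes are laid out round-robin over the participating
    electrodes at the pooled intra_isi spacing.
    """

    duration: float
    n_electrodes: int = 16
    background_rate: float = 0.0
    burst_spec: list = field(default_factory=list)
    network_burst_spec: list = field(default_factory=list)
    seed: int = 0
    collision_window: float = 0.002  # background spikes this close to an
    # injected spike are dropped, keeping injected bursts exactly as specified

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for spec in self.burst_spec:
            if spec[3] <= 0:
                raise ValueError("intra_isi must be positive")
        for spec in self.network_burst_spec:
            if spec[3] <= 0:
                raise ValueError("intra_isi must be positive")


@dataclass
class WellGroundTruth:
    bursts: list          # (electrode, spike_times array)
    network_bursts: list  # (electrodes list, pooled spike_times array)
    background: list      # per-electrode background times after collision pruning


def gen_spike_well(config: WellSimConfig) -> tuple[WellRecording, WellGroundTruth]:
    """Generate one well of spike trains with exactly known injected bursts.

    Raises ValueError when two injected bursts overlap on one electrode
    (the ground truth would be ambiguous).
    """
    rng = np.random.default_rng(config.seed)
    injected = [[] for _ in range(config.n_electrodes)]
    gt_bursts = []
    gt_nbs = []

    for electrode, start, n_spikes, isi in config.burst_spec:
        times = start + isi * np.arange(n_spikes)
        if times[-1] > config.duration:
            raise ValueError("injected burst extends past recording end")
        injected[electrode].append(times)
        gt_bursts.append((int(electrode), times))

    for start, n_el, spikes_per_el, isi in config.network_burst_spec:
        if n_el > config.n_electrodes:
            raise ValueError("network burst asks for more electrodes than the well has")
        pooled = start + isi * np.arange(n_el * spikes_per_el)
        if pooled[-1] > config.duration:
            raise ValueError("injected network burst extends past recording end")
        members = list(range(n_el))
        for k, t in enumerate(pooled):
            injected[members[k % n_el]].append(np.array([t]))
        gt_nbs.append((members, pooled))

    # reject overlapping injections per electrode
    inj_flat: list[np.ndarray] = []
    for e in range(config.n_electrodes):
        t = np.sort(np.concatenate(injected[e])) if injected[e] else np.array([])
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"electrode {e}: overlapping injected bursts")
        inj_flat.append(t)

    trains = []
    gt_background = []
    for e in range(config.n_electrodes):
        n_bg = rng.poisson(config.background_rate * config.duration)
        bg = np.sort(rng.uniform(0, config.duration, n_bg))
        if len(inj_flat[e]) and len(bg):
            # drop background spikes colliding with injected ones
            idx = np.searchsorted(inj_flat[e], bg)
            near_lo = np.where(idx > 0,
                               bg - inj_flat[e][np.maximum(idx - 1, 0)], np.inf)
            near_hi = np.where(idx < len(inj_flat[e]),
                               inj_flat[e][np.minimum(idx, len(inj_flat[e]) - 1)] - bg,
                               np.inf)
            bg = bg[np.minimum(near_lo, near_hi) >= config.collision_window]
        gt_background.append(bg)
        trains.append(np.sort(np.concatenate([bg, inj_flat[e]])))

    well = WellRecording(trains=trains, duration=config.duration)
    return well, WellGroundTruth(bursts=gt_bursts, network_bursts=gt_nbs,
                                 background=gt_background)


def bursty_well_config(duration: float, burst_rate: float,
                       n_electrodes: int = 16, background_rate: float = 1.0,
                       n_spikes: int = 5, intra_isi: float = 0.020,
                       seed: int = 0) -> WellSimConfig:
    """Well config with Poisson-injected electrode bursts at a target rate.

    Burst start times are sampled per electrode as a Poisson process and
    thinned so consecutive bursts stay separated by more than the 100 ms
    run-breaking interval (injected bursts never merge); the thinning loss
    is ~2% at 0.1 bursts/s.
    """
    rng = np.random.default_rng(seed)
    span = (n_spikes - 1) * intra_isi
    min_gap = span + 0.120
    burst_spec = []
    for e in range(n_electrodes):
        n = rng.poisson(burst_rate * duration)
        starts = np.sort(rng.uniform(0, duration - span, n))
        last_end = -np.inf
        for s in starts:
            if s - last_end > min_gap:
                burst_spec.append((e, float(s), n_spikes, intra_isi))
                last_end = s + span
    return WellSimConfig(duration=duration, n_electrodes=n_electrodes,
                         background_rate=background_rate,
                         burst_spec=burst_spec,
                         seed=int(rng.integers(2 ** 31)))


# --------------------------------------------------------------------------
# raw extracellular voltage traces
# --------------------------------------------------------------------------

def spike_waveform(fs: float, amplitude: float, width_s: float = 0.001) -> np.ndarray:
    """Biphasic extracellular spike template: one sine cycle, negative first.

    Peak (negative) deflection equals ``amplitude``.
    """
    n = max(int(round(width_s * fs)), 3)
    t = np.arange(n) / n
    return -amplitude * np.sin(2 * np.pi * t)


def gen_raw_trace(spike_times, fs: float, duration: float,
                  spike_amplitude: float = 50.0, noise_sd: float = 5.0,
                  seed: int = 0) -> np.ndarray:
    """White noise plus a biphasic waveform inserted at each spike time.

    The waveform onset is placed at sample round(t * fs). Raises ValueError
    for spike times beyond the trace duration or fs too low for the spike
    band (needs fs > 6000 Hz so the 200–3000 Hz detection band is valid).
    """
    if fs <= 2 * 3000:
        raise ValueError("fs must exceed twice the 3000 Hz band edge")
    spike_times = np.asarray(spike_times, dtype=float)
    n = int(round(duration * fs))
    if np.any(spike_times < 0) or np.any(spike_times > duration):
        raise ValueError("spike times must lie within [0, duration]")
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    w = spike_waveform(fs, spike_amplitude)
    for t in spike_times:
        i = int(round(t * fs))
        j = min(i + len(w), n)
        trace[i:j] += w[: j - i]
    return trace


# --------------------------------------------------------------------------
# calcium sessions
# --------------------------------------------------------------------------

@dataclass
class CalciumSimConfig:
    """Simulated microendoscope session.

    ``event_rate`` is either one Poisson rate (Hz per cell) for the whole
    session, or a mapping ``{"movement": hz, "stationary": hz}`` applied
    per epoch of the plan. ``epoch_plan`` entries are
    (state, duration_s, mean_speed_cm_s); durations must sum to the session
    duration. Traces are raw fluorescence F = f0 * (1 + dF/F).
    """

    n_cells: int
    duration: float
    frame_rate: float = 20.0
    event_rate: float | dict = 0.1
    decay_tau: float = 0.5
    amplitude: float = 0.2       # dF/F units
    noise_sd: float = 0.03      # dF/F units
    f0: float = 100.0           # baseline fluorescence, a.u.
    epoch_plan: list | None = None
    track_rate: float = 25.0    # behavioral camera frame rate, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.decay_tau <= 0:
            raise ValueError("frame_rate and decay_tau must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.epoch_plan is not None:
            total = sum(d for _, d, _ in self.epoch_plan)
            if abs(total - self.duration) > 1e-9:
                raise ValueError("epoch durations must sum to the session duration")
            for state, _, speed in self.epoch_plan:
                if state not in ("movement", "stationary"):
                    raise ValueError(f"unknown state {state!r}")
                expected = speed > 10.0
                if (state == "movement") != expected:
                    warnings.warn(
                        f"epoch state {state!r} with mean speed {speed} cm/s "
                        "straddles the 10 cm/s threshold; ground truth ambiguous",
                        UserWarning)
        if isinstance(self.event_rate, dict) and self.epoch_plan is None:
            raise ValueError("state-dependent event_rate requires an epoch_plan")


@dataclass
class CalciumGroundTruth:
    event_times: list[np.ndarray]     # per cell
    epochs: list | None               # (state, start_s, end_s) or None


def _poisson_times(rng, rate: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def gen_calcium_session(config: CalciumSimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame | None, CalciumGroundTruth]:
    """Generate fluorescence traces, a position track, and ground truth.

    Returns (traces, track, truth): ``traces`` has a ``time_s`` column plus
    one ``cell_<i>`` column per cell; ``track`` (or None without an epoch
    plan) has ``time_s, x_cm, y_cm`` at the behavioral frame rate.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate

    # epoch boundaries
    epochs = None
    if config.epoch_plan is not None:
        epochs = []
        cursor = 0.0
        for state, dur, speed in config.epoch_plan:
            epochs.append((state, cursor, cursor + dur, speed))
            cursor += dur

    traces = {}
    gt_events = []
    for c in range(config.n_cells):
        if isinstance(config.event_rate, dict):
            parts = [_poisson_times(rng, config.event_rate[state], a, b)
                     for state, a, b, _ in epochs]
            events = np.sort(np.concatenate(parts)) if parts else np.array([])
        else:
            events = _poisson_times(rng, float(config.event_rate),
                                    0.0, config.duration)
        dff = np.zeros(n_frames)
        for ev in events:
            onset = t >= ev
            dff[onset] += config.amplitude * np.exp(-(t[onset] - ev) / config.decay_tau)
        if config.noise_sd > 0:
            dff += rng.normal(0.0, config.noise_sd, n_frames)
        traces[f"cell_{c}"] = config.f0 * (1.0 + dff)
        gt_events.append(events)

    traces_df = pd.DataFrame({"time_s": t, **traces})

    track_df = None
    if epochs is not None:
        track_df = _gen_track(rng, epochs, config.duration, config.track_rate)
        epochs = [(s, a, b) for s, a, b, _ in epochs]

    return traces_df, track_df, CalciumGroundTruth(event_times=gt_events,
                                                   epochs=epochs)


def _gen_track(rng, epochs, duration: float, track_rate: float) -> pd.DataFrame:
    """Integrate per-epoch speeds into a 2-D open-field path.

    The speed magnitude follows the epoch plan with small (2%) jitter so the
    finite-difference velocity recovers the plan; only the heading varies —
    a slow meander steered back toward the arena center near the walls, so
    the path never needs hard reflections that would dent the speed.
    """
    n = int(round(duration * track_rate))
    t = np.arange(n) / track_rate
    dt = 1.0 / track_rate
    speed = np.zeros(n)
    for state, a, b, mean_speed in epochs:
        sel = (t >= a) & (t < b)
        jitter = 0.02 * mean_speed if mean_speed > 0 else 0.0
        speed[sel] = np.maximum(mean_speed + rng.normal(0, jitter, sel.sum()), 0.0)

    turn = rng.normal(1.0, 0.2) * rng.choice([-1.0, 1.0])  # rad/s meander
    noise = rng.normal(0, 0.05, n)
    cx = cy = ARENA_CM / 2
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = cx, cy
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, n):
        dx, dy = cx - x[i - 1], cy - y[i - 1]
        dist = np.hypot(dx, dy)
        if dist > 0.3 * ARENA_CM:
            # steer gently toward the center before reaching a wall
            want = np.arctan2(dy, dx)
            delta = (want - heading + np.pi) % (2 * np.pi) - np.pi
            heading += 0.25 * delta
        heading += turn * dt + noise[i]
        x[i] = np.clip(x[i - 1] + speed[i] * dt * np.cos(heading), 0, ARENA_CM)
        y[i] = np.clip(y[i - 1] + speed[i] * dt * np.sin(heading), 0, ARENA_CM)
    return pd.DataFrame({"time_s": t, "x_cm": x, "y_cm": y})


# --------------------------------------------------------------------------
# puncta images
# --------------------------------------------------------------------------

@dataclass
class PunctaImageSimConfig:
    """Gaussian-spot puncta on a soma + dendrite mask.

    ``puncta`` entries are ((x_um, y_um), area_um2, peak_intensity); area is
    the spot footprint above half maximum, so sigma_px =
    sqrt(area_px / (2 pi ln 2)). ``dendrite_spec`` is a list of
    (polyline_um, width_um) pairs; a soma disk of ``soma_radius_um`` is
    always part of the mask.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # um / pixel
    soma_center: tuple[float, float] = (12.8, 12.8)  # um
    soma_radius_um: float = 5.0
    dendrite_spec: list = field(default_factory=list)
    puncta: list = field(default_factory=list)
    background_level: float = 20.0
    background_gradient: float = 0.0  # intensity per pixel along x
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, area, _ in self.puncta:
            if area <= 0:
                raise ValueError("punctum area must be positive")
            if area / self.pixel_size ** 2 < 4.0:
                raise ValueError(
                    f"area {area} um^2 not resolvable at {self.pixel_size} um/px")


def spot_sigma_px(area_um2: float, pixel_size: float) -> float:
    """Gaussian sigma (pixels) whose half-maximum footprint has this area."""
    area_px = area_um2 / pixel_size ** 2
    return float(np.sqrt(area_px / (2 * np.pi * np.log(2))))


def build_mask(config: PunctaImageSimConfig) -> np.ndarray:
    """Boolean cell mask: soma disk plus dilated dendrite polylines."""
    from skimage.draw import disk, line
    from skimage.morphology import dilation, disk as disk_se

    h, w = config.image_shape
    mask = np.zeros((h, w), dtype=bool)
    cy = config.soma_center[1] / config.pixel_size
    cx = config.soma_center[0] / config.pixel_size
    rr, cc = disk((cy, cx), config.soma_radius_um / config.pixel_size, shape=(h, w))
    mask[rr, cc] = True
    for polyline, width_um in config.dendrite_spec:
        seg = np.zeros((h, w), dtype=bool)
        pts = [(int(round(y / config.pixel_size)), int(round(x / config.pixel_size)))
               for x, y in polyline]
        for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            seg[rr[ok], cc[ok]] = True
        r = max(int(round(width_um / 2 / config.pixel_size)), 1)
        mask |= dilation(seg, disk_se(r))
    return mask


def gen_puncta_image(config: PunctaImageSimConfig
                     ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render the image, the cell mask, and the ground-truth puncta table.

    Raises ValueError when a punctum centroid falls outside the mask.
    Returns (image float64, mask bool, truth DataFrame with columns
    x_um, y_um, area_um2, peak).
    """
    h, w = config.image_shape
    mask = build_mask(config)
    yy, xx = np.mgrid[0:h, 0:w]
    img = config.background_level + config.background_gradient * xx

    rows = []
    for (x_um, y_um), area, peak in config.puncta:
        px = x_um / config.pixel_size
        py = y_um / config.pixel_size
        iy, ix = int(round(py)), int(round(px))
        if not (0 <= iy < h and 0 <= ix < w) or not mask[iy, ix]:
            raise ValueError(f"punctum centroid ({x_um}, {y_um}) um outside mask")
        sigma = spot_sigma_px(area, config.pixel_size)
        # render on a local window only (8 sigma) for speed
        r = int(np.ceil(8 * sigma))
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        sub_y = yy[y0:y1, x0:x1]
        sub_x = xx[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += peak * np.exp(
            -((sub_x - px) ** 2 + (sub_y - py) ** 2) / (2 * sigma ** 2))
        rows.append({"x_um": x_um, "y_um": y_um, "area_um2": area, "peak": peak})

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, img.shape)

    truth = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2", "peak"])
    return img, mask, truth


def random_puncta_config(density: float, area_range: tuple[float, float],
                         peak: float, seed: int,
                         base: PunctaImageSimConfig | None = None,
                         min_separation_sigma: float = 3.5,
                         interior_only: bool = False
                         ) -> PunctaImageSimConfig:
    """Puncta placed uniformly at random inside the mask at a target density.

    The count is Poisson(density x mask area); placements keep a minimum
    separation of ``min_separation_sigma`` x the largest spot sigma so
    detection is limited by the pipeline, not by spot merging. With
    ``interior_only`` centroids keep a half-maximum footprint's clearance
    from the mask edge (no clipping; shrinks the usable area, so only
    suitable at low densities).
    """
    base = base or default_neuron_image_config()
    rng = np.random.default_rng(seed)
    mask = build_mask(base)
    area_um2 = mask.sum() * base.pixel_size ** 2
    n = rng.poisson(density * area_um2)
    region = mask
    if interior_only:
        from skimage.morphology import erosion, disk as disk_se
        rim = int(np.ceil(spot_sigma_px(area_range[1], base.pixel_size)
                          * np.sqrt(2 * np.log(2)))) + 1
        interior = erosion(mask, disk_se(rim))
        if interior.any():
            region = interior
    ys, xs = np.nonzero(region)
    sep_px = min_separation_sigma * spot_sigma_px(area_range[1], base.pixel_size)

    chosen: list[tuple[float, float]] = []
    puncta = []
    attempts = 0
    while len(puncta) < n and attempts < 300 * n + 100:
        attempts += 1
        k = rng.integers(len(ys))
        py, px = float(ys[k]), float(xs[k])
        if any((py - cy) ** 2 + (px - cx) ** 2 < sep_px ** 2 for cy, cx in chosen):
            continue
        chosen.append((py, px))
        area = rng.uniform(*area_range)
        puncta.append(((px * base.pixel_size, py * base.pixel_size), area, peak))
    cfg = PunctaImageSimConfig(
        image_shape=base.image_shape, pixel_size=base.pixel_size,
        soma_center=base.soma_center, soma_radius_um=base.soma_radius_um,
        dendrite_spec=base.dendrite_spec, puncta=puncta,
        background_level=base.background_level,
        background_gradient=base.background_gradient,
        noise_sd=base.noise_sd, seed=int(rng.integers(2 ** 31)))
    return cfg


def default_neuron_image_config(noise_sd: float = 0.0,
                                seed: int = 0) -> PunctaImageSimConfig:
    """A 25.6 um square field: central soma with four dendrites."""
    c = 12.8
    arms = [
        [(c, c), (25.0, c + 3.0)],
        [(c, c), (0.6, c - 3.0)],
        [(c, c), (c - 3.0, 25.0)],
        [(c, c), (c + 3.0, 0.6)],
    ]
    return PunctaImageSimConfig(
        image_shape=(256, 256), pixel_size=0.1, soma_center=(c, c),
        soma_radius_um=5.0, dendrite_spec=[(a, 2.0) for a in arms],
        background_level=20.0, background_gradient=0.02,
        noise_sd=noise_sd, seed=seed)


# --------------------------------------------------------------------------
# intensity profiles
# --------------------------------------------------------------------------

def gen_intensity_profile(mode: str, length_px: int = 150,
                          pixel_size: float = 0.1, baseline: float = 10.0,
                          bump_amplitude: float = 50.0, bump_sigma_px: float = 4.0,
                          n_bumps: int = 5, noise_sd: float = 0.0,
                          seed: int = 0) -> IntensityProfile:
    """1-D dendritic intensity profile in clustered or diffuse mode.

    ``clustered`` — baseline plus ``n_bumps`` Gaussian bumps at random
    positions (punctate localization); ``diffuse`` — near-constant at a
    level matching the clustered mode's mean, plus noise. The default
    length corresponds to the study's 15 um segment at 0.1 um/px.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(length_px, dtype=float)
    bump_mass = bump_amplitude * bump_sigma_px * np.sqrt(2 * np.pi)
    if mode == "clustered":
        y = np.full(length_px, baseline)
        centers = rng.uniform(0, length_px, n_bumps)
        for c in centers:
            y += bump_amplitude * np.exp(-((x - c) ** 2) / (2 * bump_sigma_px ** 2))
    elif mode == "diffuse":
        # same expected mean as the clustered mode, spread uniformly
        y = np.full(length_px, baseline + n_bumps * bump_mass / length_px)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, length_px)
    return IntensityProfile(intensities=y, pixel_size=pixel_size)
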