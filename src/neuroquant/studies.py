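"""Simulation studies: ground-truth recovery under the study's conditions.

Each routine builds synthetic data at the effect sizes reported for the
InSyn1-type loss-of-function phenotypes — elevated calcium event rates in
vivo, depleted inhibitory-synapse puncta after scaffold knockdown, elevated
burst frequency on MEAs — runs the corresponding quantification chain from
this package, and returns the recovered quantities. They are the backbone of
the numbered analysis scripts and the acceptance checks.

The ground-truth constants below are the printed study values used as
simulation inputs (rates in Hz; depletion/elevation as fractions).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import calcium as ca
from . import mea, puncta, synth

#: per-cell calcium event rates (Hz) by genotype and behavioral state
CALCIUM_RATES = {
    "wt_total": 0.044, "ko_total": 0.098,
    "wt_movement": 0.050, "ko_movement": 0.121,
    "wt_stationary": 0.041, "ko_stationary": 0.075,
}

#: puncta-density depletion after scaffold knockdown (fraction of control lost)
PUNCTA_DEPLETION = {"gephyrin": 0.81, "adg": 0.89}

#: burst-frequency elevation of knockout over wild-type cultures (DIV8)
BURST_ELEVATION_DIV8 = 0.26

#: c-Fos-positive cell-density elevation in knockout dentate gyrus
CFOS_ELEVATION = 0.26


# --------------------------------------------------------------------------
# calcium event-rate recovery
# --------------------------------------------------------------------------

def calcium_total_rate_study(event_rate: float, n_cells: int = 160,
                             duration: float = 300.0, seed: int = 0) -> dict:
    """Detected mean total event rate for cells simulated at ``event_rate``.

    Traces use the study's imaging conditions: 20 frames/s, transient decay
    0.5 s, amplitude 10x the noise MAD. Returns mean/SEM of per-cell
    detected rates plus the per-cell values.
    """
    cfg = synth.CalciumSimConfig(n_cells=n_cells, duration=duration,
                                 event_rate=event_rate, decay_tau=0.5,
                                 amplitude=0.2, noise_sd=0.03, seed=seed)
    traces, _, truth = synth.gen_calcium_session(cfg)
    events = ca.detect_events_table(traces)
    rates = np.array([e.total_rate for e in events])
    return {
        "rate_hz": float(rates.mean()),
        "sem": float(sps.sem(rates)),
        "rates": rates,
        "true_rate_hz": float(np.mean([len(t) for t in truth.event_times])
                              / duration),
    }


def calcium_state_rate_study(movement_rate: float, stationary_rate: float,
                             n_cells: int = 100, n_blocks: int = 5,
                             seed: int = 0) -> dict:
    """State-resolved rate recovery on alternating movement/stationary blocks.

    Sessions alternate 30 s movement (15 cm/s) with 30 s stationary (2 cm/s);
    events are injected per state at the given rates, and the full chain
    (dF/F, event detection, track-based epoch segmentation, state
    normalization) recovers them.
    """
    plan = [("movement", 30.0, 15.0), ("stationary", 30.0, 2.0)] * n_blocks
    duration = sum(d for _, d, _ in plan)
    cfg = synth.CalciumSimConfig(
        n_cells=n_cells, duration=duration,
        event_rate={"movement": movement_rate, "stationary": stationary_rate},
        decay_tau=0.5, amplitude=0.2, noise_sd=0.03,
        epoch_plan=plan, seed=seed)
    traces, track, truth = synth.gen_calcium_session(cfg)
    df = ca.session_state_rates(traces, track)

    def realized(state: str) -> float:
        total = sum(b - a for s, a, b in truth.epochs if s == state)
        count = sum(int(np.sum((t >= a) & (t < b)))
                    for t in truth.event_times
                    for s, a, b in truth.epochs if s == state)
        return count / (total * len(truth.event_times))

    return {
        "movement_rate_hz": float(df.movement_rate_hz.mean()),
        "movement_sem": float(sps.sem(df.movement_rate_hz)),
        "stationary_rate_hz": float(df.stationary_rate_hz.mean()),
        "stationary_sem": float(sps.sem(df.stationary_rate_hz)),
        "true_movement_rate_hz": realized("movement"),
        "true_stationary_rate_hz": realized("stationary"),
        "per_cell": df,
    }


# --------------------------------------------------------------------------
# puncta depletion recovery
# --------------------------------------------------------------------------

def measure_image_density(density: float, seed: int, noise_sd: float = 3.0,
                          peak: float = 60.0,
                          area_range: tuple[float, float] = (0.3, 0.8)) -> dict:
    """Generate one neuron image at a target puncta density and quantify it.

    The detection threshold is fixed at half the nominal spot peak, shared
    across conditions (the groups being compared are always thresholded
    identically).
    """
    base = synth.default_neuron_image_config(noise_sd=noise_sd)
    cfg = synth.random_puncta_config(density, area_range, peak=peak,
                                     seed=seed, base=base)
    img, mask, truth = synth.gen_puncta_image(cfg)
    pconf = puncta.PunctaConfig(threshold=peak / 2)
    sub = puncta.subtract_background(img, pconf.background_radius)
    ps = puncta.detect_puncta(sub, mask, pconf)
    ps = puncta.partition_regions(ps, cfg.soma_center, pconf)
    stats = puncta.compute_density_area(ps, mask, cfg.soma_center, pconf)
    return {
        "density": stats.density["overall"],
        "true_density": len(truth) / stats.mask_area["overall"],
        "stats": stats,
    }


def puncta_depletion_study(depletion: float, n_images: int = 20,
                           control_density: float = 0.3, seed: int = 0) -> dict:
    """Percent density reduction recovered from control vs depleted images.

    ``depletion`` is the ground-truth fraction lost (0.81 means the depleted
    set is generated at 19% of the control density).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=2 * n_images)
    control = [measure_image_density(control_density, int(s))["density"]
               for s in seeds[:n_images]]
    depleted = [measure_image_density(control_density * (1 - depletion),
                                      int(s))["density"]
                for s in seeds[n_images:]]
    reduction = 100.0 * (1.0 - np.mean(depleted) / np.mean(control))
    return {
        "percent_reduction": float(reduction),
        "control_densities": np.asarray(control),
        "depleted_densities": np.asarray(depleted),
    }


# --------------------------------------------------------------------------
# MEA burst-frequency elevation recovery
# --------------------------------------------------------------------------

def well_burst_frequency(burst_rate: float, duration: float = 600.0,
                         background_rate: float = 1.0, seed: int = 0) -> float:
    """Detected per-well burst frequency for one simulated well (Hz)."""
    cfg = synth.bursty_well_config(duration, burst_rate,
                                   background_rate=background_rate, seed=seed)
    well, _ = synth.gen_spike_well(cfg)
    bursts = [b for e, t in enumerate(well.trains)
              for b in mea.detect_bursts(t, electrode=e)]
    return len(bursts) / duration


def burst_elevation_study(elevation: float = BURST_ELEVATION_DIV8,
                          n_wells: int = 40, duration: float = 600.0,
                          wt_burst_rate: float = 0.1, seed: int = 0) -> dict:
    """Recover the knockout burst-frequency elevation after WT normalization.

    Simulates ``n_wells`` wells per genotype (16 electrodes, Poisson
    background at 1 Hz, injected bursts at ``wt_burst_rate`` per electrode
    for WT, scaled by 1 + elevation for KO), detects bursts, normalizes to
    the WT mean, and reports 100 x (KO normalized mean - 1).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=2 * n_wells)
    wt = [well_burst_frequency(wt_burst_rate, duration, seed=int(s))
          for s in seeds[:n_wells]]
    ko = [well_burst_frequency(wt_burst_rate * (1 + elevation), duration,
                               seed=int(s))
          for s in seeds[n_wells:]]
    norm_ko = mea.normalize_group(ko, wt)
    return {
        "percent_elevation": float(100.0 * (np.mean(norm_ko) - 1.0)),
        "wt": np.asarray(wt),
        "ko": np.asarray(ko),
    }
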