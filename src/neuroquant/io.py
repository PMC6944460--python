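"""Readers and writers for the package's on-disk formats.

Spike wells travel as long-format CSV (well_id, electrode_id, spike_time_s);
calcium traces and position tracks as wide CSV; images and masks as 16-bit
TIFF with the soma center in a sidecar JSON; ground truth and stats as JSON.
Configs are YAML mapping directly onto the dataclass fields.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .mea import WellRecording


# ---- spikes ---------------------------------------------------------------

def write_spike_csv(path, wells: list[WellRecording]) -> None:
    rows = []
    for well in wells:
        for e, train in enumerate(well.trains):
            for t in train:
                rows.append((well.well_id, e, t))
    df = pd.DataFrame(rows, columns=["well_id", "electrode_id", "spike_time_s"])
    df.to_csv(path, index=False)


def read_spike_csv(path, duration: float, n_electrodes: int = 16
                   ) -> list[WellRecording]:
    df = pd.read_csv(path)
    wells = []
    for well_id, grp in df.groupby("well_id", sort=True):
        trains = [np.sort(grp.loc[grp.electrode_id == e, "spike_time_s"].to_numpy())
                  for e in range(n_electrodes)]
        wells.append(WellRecording(trains=trains, duration=duration,
                                   well_id=str(well_id)))
    return wells


# ---- calcium --------------------------------------------------------------

def write_traces_csv(path, traces: pd.DataFrame) -> None:
    traces.to_csv(path, index=False)


def read_traces_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("traces CSV needs a time_s column")
    return df


def write_track_csv(path, track: pd.DataFrame) -> None:
    track.to_csv(path, index=False)


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_s", "x_cm", "y_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    return df


# ---- images ---------------------------------------------------------------

def write_image_tiff(path, image: np.ndarray, scale_to_uint16: bool = True) -> None:
    if scale_to_uint16:
        lo, hi = float(image.min()), float(image.max())
        scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        image = (scaled * 65535).astype(np.uint16)
    tifffile.imwrite(path, image)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8) * 255)


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_soma_json(path, soma_center_um, pixel_size: float) -> None:
    Path(path).write_text(json.dumps({
        "soma_center_um": list(soma_center_um), "pixel_size_um": pixel_size}))


def read_soma_json(path) -> tuple[tuple[float, float], float]:
    d = json.loads(Path(path).read_text())
    return tuple(d["soma_center_um"]), float(d["pixel_size_um"])


# ---- generic --------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def load_config(path, cls):
    """Instantiate a config dataclass from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return cls(**data)
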