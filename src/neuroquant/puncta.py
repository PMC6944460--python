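"""Fluorescent puncta quantification inside masked cell regions.

Pipeline: rolling-ball background subtraction, thresholding inside the cell
mask (default Otsu on the in-mask histogram), 8-connected component labeling,
a size gate (0.2–1.0 um^2 by default), partition of puncta into perisomatic
(within 30 um diameter of the soma center) and neurite (30–100 um diameter
annulus) zones, and density/area statistics per zone. The same module also
provides the c-Fos-positive cell density (count / region area) used for
histological sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball
from skimage.transform import rescale, resize

REGIONS = ("perisomatic", "neurite", "outside")


@dataclass
class PunctaConfig:
    background_radius: int = 50          # px, rolling ball
    min_area: float = 0.2                # um^2
    max_area: float = 1.0                # um^2
    threshold: float | str = "otsu"      # "otsu" | "q<quantile>" | fixed value
    pixel_size: float = 0.1              # um / px
    perisomatic_diameter: float = 30.0   # um
    neurite_outer_diameter: float = 100.0  # um

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not 0 < self.perisomatic_diameter < self.neurite_outer_diameter:
            raise ValueError("perisomatic diameter must be positive and "
                             "smaller than the neurite outer diameter")


@dataclass
class Punctum:
    centroid: tuple[float, float]  # (x, y) um
    area: float                    # um^2
    mean_intensity: float
    region: str = "unassigned"


@dataclass
class PunctaSet:
    puncta: list[Punctum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"x_um": p.centroid[0], "y_um": p.centroid[1], "area_um2": p.area,
              "mean_intensity": p.mean_intensity, "region": p.region}
             for p in self.puncta],
            columns=["x_um", "y_um", "area_um2", "mean_intensity", "region"])


@dataclass
class PunctaStats:
    """Per-region and overall puncta summaries.

    density is puncta count per um^2 of mask area in the same region;
    mean_area is NaN when the region holds no puncta.
    """

    n: dict
    density: dict
    mean_area: dict
    total_area: dict
    mask_area: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in list(self.n):
            rows.append({"region": region, "n": self.n[region],
                         "mask_area_um2": self.mask_area[region],
                         "density_per_um2": self.density[region],
                         "mean_area_um2": self.mean_area[region],
                         "total_area_um2": self.total_area[region]})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# background subtraction
# --------------------------------------------------------------------------

def subtract_background(image: np.ndarray, radius: int = 50,
                        downscale_threshold: int = 16) -> np.ndarray:
    """Rolling-ball background subtraction.

    Estimates the background as the surface traced by a ball of the given
    radius rolled under the image and subtracts it, clipping at zero.
    For radii above ``downscale_threshold`` the estimate is computed on a
    downscaled copy and resized back (the ImageJ strategy for large radii);
    the background is smooth, so the approximation error is negligible.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError("radius larger than the image")
    if radius > downscale_threshold:
        factor = max(int(radius // downscale_threshold), 1)
        small = rescale(image, 1.0 / factor, anti_aliasing=True)
        bg_small = rolling_ball(small, radius=radius / factor)
        background = resize(bg_small, image.shape)
        # the ball must stay under the image everywhere
        background = np.minimum(background, image)
    else:
        background = rolling_ball(image, radius=radius)
    return np.clip(image - background, 0, None)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _resolve_threshold(values: np.ndarray, spec) -> float:
    if isinstance(spec, str):
        if spec == "otsu":
            return float(threshold_otsu(values))
        if spec.startswith("q"):
            return float(np.quantile(values, float(spec[1:])))
        raise ValueError(f"unknown threshold spec {spec!r}")
    return float(spec)


def detect_puncta(image: np.ndarray, mask: np.ndarray,
                  config: PunctaConfig | None = None) -> PunctaSet:
    """Threshold inside the mask, label 8-connected components, gate by size.

    The image should already be background-subtracted. Components with area
    in [min_area, max_area] um^2 are kept; centroids are reported in um.
    An empty mask is an error; no pixel above threshold yields an empty set.
    """
    config = config or PunctaConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")

    thr = _resolve_threshold(image[mask], config.threshold)
    binary = (image > thr) & mask
    if not binary.any():
        return PunctaSet()

    labels = measure.label(binary, connectivity=2)  # 8-connectivity
    px_area = config.pixel_size ** 2
    out = []
    for rp in measure.regionprops(labels, intensity_image=image):
        area_um2 = rp.area * px_area
        if config.min_area <= area_um2 <= config.max_area:
            cy, cx = rp.centroid
            out.append(Punctum(
                centroid=(cx * config.pixel_size, cy * config.pixel_size),
                area=area_um2,
                mean_intensity=float(rp.intensity_mean)))
    return PunctaSet(out)


def partition_regions(puncta: PunctaSet, soma_center_um,
                      config: PunctaConfig | None = None) -> PunctaSet:
    """Label each punctum perisomatic / neurite / outside by soma distance.

    Boundary ties go to the inner region (perisomatic is the closed disk of
    radius perisomatic_diameter / 2).
    """
    config = config or PunctaConfig()
    r_in = config.perisomatic_diameter / 2
    r_out = config.neurite_outer_diameter / 2
    for p in puncta:
        d = float(np.hypot(p.centroid[0] - soma_center_um[0],
                           p.centroid[1] - soma_center_um[1]))
        if d <= r_in:
            p.region = "perisomatic"
        elif d <= r_out:
            p.region = "neurite"
        else:
            p.region = "outside"
    return puncta


def region_mask_areas(mask: np.ndarray, soma_center_um,
                      config: PunctaConfig | None = None) -> dict:
    """Mask area (um^2) within each distance zone, plus overall."""
    config = config or PunctaConfig()
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx * config.pixel_size - soma_center_um[0],
                 yy * config.pixel_size - soma_center_um[1])
    px_area = config.pixel_size ** 2
    r_in = config.perisomatic_diameter / 2
    r_out = config.neurite_outer_diameter / 2
    return {
        "perisomatic": float(np.sum(mask & (d <= r_in)) * px_area),
        "neurite": float(np.sum(mask & (d > r_in) & (d <= r_out)) * px_area),
        "outside": float(np.sum(mask & (d > r_out)) * px_area),
        "overall": float(mask.sum() * px_area),
    }


def compute_density_area(puncta: PunctaSet, mask: np.ndarray, soma_center_um,
                         config: PunctaConfig | None = None) -> PunctaStats:
    """Puncta density (count / mask area) and area stats per region.

    Density uses the cell-mask area inside the same distance zone as the
    denominator; a region with puncta but zero mask area is an error.
    """
    config = config or PunctaConfig()
    areas = region_mask_areas(mask, soma_center_um, config)
    groups = {r: [p for p in puncta if p.region == r] for r in REGIONS}
    groups["overall"] = list(puncta)

    n, density, mean_area, total_area = {}, {}, {}, {}
    for region, members in groups.items():
        n[region] = len(members)
        if areas[region] == 0:
            if members:
                raise ValueError(f"region {region!r} has puncta but zero mask area")
            density[region] = 0.0
        else:
            density[region] = len(members) / areas[region]
        sizes = [p.area for p in members]
        mean_area[region] = float(np.mean(sizes)) if sizes else float("nan")
        total_area[region] = float(np.sum(sizes)) if sizes else 0.0
    return PunctaStats(n=n, density=density, mean_area=mean_area,
                       total_area=total_area, mask_area=areas)


def quantify_image(image: np.ndarray, mask: np.ndarray, soma_center_um,
                   config: PunctaConfig | None = None) -> tuple[PunctaSet, PunctaStats]:
    """Full pipeline: background subtraction, detection, partition, stats."""
    config = config or PunctaConfig()
    sub = subtract_background(image, config.background_radius)
    ps = detect_puncta(sub, mask, config)
    ps = partition_regions(ps, soma_center_um, config)
    return ps, compute_density_area(ps, mask, soma_center_um, config)


def cfos_density(cell_points, region_area_um2: float) -> float:
    """c-Fos-positive cell density: count divided by region area (um^-2)."""
    if region_area_um2 <= 0:
        raise ValueError("region area must be positive")
    return len(cell_points) / region_area_um2
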