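"""Puncta quantification: background, detection, partition, densities."""

import numpy as np
import pytest
from scipy import ndimage

from neuroquant import puncta, synth
from neuroquant.puncta import PunctaConfig


@pytest.fixture
def clean_image():
    """Ten well-separated in-range puncta, flat background, no noise."""
    base = synth.default_neuron_image_config(noise_sd=0.0)
    base.background_gradient = 0.0
    cfg = synth.random_puncta_config(0.05, (0.4, 0.7), peak=60.0, seed=11,
                                     base=base, interior_only=True)
    cfg.puncta = cfg.puncta[:10]
    img, mask, truth = synth.gen_puncta_image(cfg)
    return img, mask, truth.iloc[:10], cfg


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = puncta.subtract_background(np.full((64, 64), 13.0), radius=10)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_narrow_peak_preserved(self):
        img = np.full((64, 64), 10.0)
        img[30:33, 30:33] += 100.0
        out = puncta.subtract_background(img, radius=10)
        assert out[31, 31] == pytest.approx(100.0, rel=0.05)
        assert abs(out[5, 5]) < 1.0

    def test_shallow_gradient_removed(self):
        xx = np.arange(128)
        img = 50.0 + 0.05 * np.tile(xx, (128, 1))  # slope << range/radius
        out = puncta.subtract_background(img, radius=20)
        assert out.max() - out.min() < 0.05 * (img.max() - img.min())

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            puncta.subtract_background(np.ones((32, 32)), radius=40)

    def test_matches_grayscale_opening_on_smooth_background(self):
        # independent oracle: opening with a disk bounds the background
        rng = np.random.default_rng(0)
        img = 20.0 + 0.1 * np.arange(96)[None, :] + rng.normal(0, 0.1, (96, 96))
        img[40:43, 40:43] += 50
        out = puncta.subtract_background(img, radius=12)
        opened = ndimage.grey_opening(img, footprint=np.ones((25, 25)))
        alt = np.clip(img - opened, 0, None)
        # both methods must agree on the spike amplitude
        assert out[41, 41] == pytest.approx(alt[41, 41], rel=0.1)


class TestDetectPuncta:
    def test_round_trip_count(self, clean_image):
        img, mask, truth, cfg = clean_image
        ps = puncta.detect_puncta(img - 20.0, mask, PunctaConfig(threshold=30.0))
        assert len(ps) == len(truth)

    def test_generated_areas_within_15_percent(self, clean_image):
        img, mask, truth, cfg = clean_image
        ps = puncta.detect_puncta(img - 20.0, mask, PunctaConfig(threshold=30.0))
        got = sorted(p.area for p in ps)
        want = sorted(truth.area_um2)
        assert np.allclose(got, want, rtol=0.15)

    def test_oversized_component_filtered(self):
        base = synth.default_neuron_image_config()
        cfg = synth.PunctaImageSimConfig(
            image_shape=base.image_shape, pixel_size=0.1,
            soma_center=base.soma_center, dendrite_spec=base.dendrite_spec,
            puncta=[((12.8, 12.8), 1.5, 60.0)], background_level=0.0)
        img, mask, _ = synth.gen_puncta_image(cfg)
        ps = puncta.detect_puncta(img, mask, PunctaConfig(threshold=30.0))
        assert len(ps) == 0

    def test_punctum_outside_mask_excluded(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img += 60 * np.exp(-((xx - 80) ** 2 + (yy - 80) ** 2) / (2 * 3.0 ** 2))
        mask = np.zeros((100, 100), dtype=bool)
        mask[:40, :40] = True
        ps = puncta.detect_puncta(img, mask, PunctaConfig(threshold=30.0))
        assert len(ps) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            puncta.detect_puncta(np.ones((10, 10)), np.zeros((10, 10), bool))

    def test_no_pixels_above_threshold_returns_empty(self):
        ps = puncta.detect_puncta(np.zeros((20, 20)), np.ones((20, 20), bool),
                                  PunctaConfig(threshold=5.0))
        assert len(ps) == 0

    def test_two_spots_separated_by_three_sigma_resolved(self):
        base = synth.default_neuron_image_config()
        sigma_um = synth.spot_sigma_px(0.5, 0.1) * 0.1
        gap = 3.5 * sigma_um
        cfg = synth.PunctaImageSimConfig(
            image_shape=base.image_shape, pixel_size=0.1,
            soma_center=base.soma_center, dendrite_spec=base.dendrite_spec,
            puncta=[((12.8, 12.8), 0.5, 60.0),
                    ((12.8 + gap, 12.8), 0.5, 60.0)],
            background_level=0.0)
        img, mask, _ = synth.gen_puncta_image(cfg)
        ps = puncta.detect_puncta(img, mask, PunctaConfig(threshold=30.0))
        assert len(ps) == 2

    def test_count_matches_flood_fill_oracle(self, clean_image):
        img, mask, truth, cfg = clean_image
        binary = (img - 20.0 > 30.0) & mask
        labels, n = ndimage.label(binary, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n + 1)) * 0.1 ** 2
        expected = int(np.sum((sizes >= 0.2) & (sizes <= 1.0)))
        ps = puncta.detect_puncta(img - 20.0, mask, PunctaConfig(threshold=30.0))
        assert len(ps) == expected

    def test_quantile_threshold_scale_invariant(self, clean_image):
        img, mask, truth, cfg = clean_image
        conf = PunctaConfig(threshold="q0.9")
        d1 = puncta.detect_puncta(img, mask, conf)
        d2 = puncta.detect_puncta(img * 10.0, mask, conf)
        assert len(d1) == len(d2)


class TestPartitionAndDensity:
    def _mk(self, dists):
        return puncta.PunctaSet([
            puncta.Punctum(centroid=(50.0 + d, 50.0), area=0.5,
                           mean_intensity=1.0) for d in dists])

    def test_region_assignment_rules(self):
        ps = puncta.partition_regions(self._mk([10.0, 40.0, 15.0, 50.0, 60.0]),
                                      (50.0, 50.0))
        regions = [p.region for p in ps]
        assert regions == ["perisomatic", "neurite", "perisomatic",
                           "neurite", "outside"]

    def test_partition_exhaustive_exclusive(self, rng):
        dists = rng.uniform(0, 80, 100)
        ps = puncta.partition_regions(self._mk(list(dists)), (50.0, 50.0))
        assert all(p.region in puncta.REGIONS for p in ps)

    def test_density_arithmetic(self):
        # 20 puncta over a 100 um^2 mask -> 0.2 per um^2
        mask = np.zeros((200, 200), dtype=bool)
        mask[:100, :100] = True  # 10000 px * 0.01 um^2 = 100 um^2
        ps = puncta.PunctaSet([
            puncta.Punctum(centroid=(x, 5.0), area=0.5, mean_intensity=1.0)
            for x in np.linspace(2.0, 8.0, 20)])
        ps = puncta.partition_regions(ps, (5.0, 5.0))
        stats = puncta.compute_density_area(ps, mask, (5.0, 5.0))
        assert stats.density["overall"] == pytest.approx(20 / 100.0)
        assert stats.density["perisomatic"] == pytest.approx(20 / 100.0)
        assert stats.n["overall"] == 20

    def test_empty_set_flags_mean_area(self):
        mask = np.ones((50, 50), dtype=bool)
        stats = puncta.compute_density_area(puncta.PunctaSet(), mask, (2.5, 2.5))
        assert stats.density["overall"] == 0.0
        assert np.isnan(stats.mean_area["overall"])

    def test_region_counts_sum_to_total(self, rng):
        ps = puncta.partition_regions(self._mk(rng.uniform(0, 80, 50)),
                                      (50.0, 50.0))
        mask = np.ones((1200, 1200), dtype=bool)
        stats = puncta.compute_density_area(ps, mask, (50.0, 50.0))
        assert stats.n["overall"] == sum(stats.n[r] for r in puncta.REGIONS)


class TestCfosDensity:
    def test_basic_density(self):
        assert puncta.cfos_density([(0, 0)] * 50, 10_000.0) == pytest.approx(0.005)

    def test_empty_counts_zero(self):
        assert puncta.cfos_density([], 100.0) == 0.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            puncta.cfos_density([(0, 0)], -5.0)

    def test_ko_over_wt_ratio_recovered(self, rng):
        # KO sections generated with 1.26x WT point density
        area = 50_000.0
        wt = [len(rng.uniform(size=rng.poisson(0.005 * area))) / area
              for _ in range(30)]
        ko = [len(rng.uniform(size=rng.poisson(0.005 * 1.26 * area))) / area
              for _ in range(30)]
        assert np.mean(ko) / np.mean(wt) == pytest.approx(1.26, abs=0.05)


def test_noiseless_full_pipeline_density_exact():
    base = synth.default_neuron_image_config(noise_sd=0.0)
    cfg = synth.random_puncta_config(0.2, (0.3, 0.8), peak=60.0, seed=21,
                                     base=base)
    img, mask, truth = synth.gen_puncta_image(cfg)
    ps, stats = puncta.quantify_image(img, mask, cfg.soma_center,
                                      PunctaConfig(threshold=30.0))
    true_density = len(truth) / stats.mask_area["overall"]
    assert stats.density["overall"] == pytest.approx(true_density)
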