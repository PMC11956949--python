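"""DAPI-map construction and region statistics."""

import numpy as np
import pytest
from skimage import draw, morphology

from newsecm import (ChannelImage, DapiMap, DapiMapParams, build_dapi_map,
                     normalized_marker_intensity, region_channel_stats,
                     simulate_tissue_image)


def rgb(h=64, w=64, dtype=np.uint8):
    return np.zeros((h, w, 3), dtype=dtype)


class TestBuildDapiMap:
    def test_all_black_blue_channel_empty_map(self):
        img = ChannelImage(rgb())
        with pytest.warns(UserWarning, match="empty"):
            dmap = build_dapi_map(img)
        assert dmap.area == 0

    def test_specks_removed_by_size_filter(self):
        px = rgb()
        px[5, 5, 2] = px[5, 6, 2] = px[6, 5, 2] = 255       # 3-px speck
        px[40, 40, 2] = px[40, 41, 2] = px[41, 40, 2] = 255  # another
        dmap = build_dapi_map(ChannelImage(px),
                              DapiMapParams(min_component_area=30))
        assert dmap.area == 0

    def test_single_disk_matches_morphological_oracle(self):
        px = rgb(128, 128)
        rr, cc = draw.disk((64, 64), 20)
        px[rr, cc, 2] = 255
        params = DapiMapParams(min_component_area=30, disk_radius=3)
        dmap = build_dapi_map(ChannelImage(px), params)
        # independent oracle: closing of the same raster disk
        ref = np.zeros((128, 128), bool)
        ref[rr, cc] = True
        selem = morphology.disk(3)
        ref = morphology.erosion(morphology.dilation(ref, selem), selem)
        assert np.array_equal(dmap.mask, ref)
        disk_area = len(rr)
        assert disk_area <= dmap.area <= disk_area + 100

    def test_deterministic_on_identical_bytes(self):
        img, _ = simulate_tissue_image(seed=9)
        m1 = build_dapi_map(img)
        m2 = build_dapi_map(ChannelImage(img.pixels.copy()))
        assert np.array_equal(m1.mask, m2.mask)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DapiMapParams(threshold_fraction=0.0)
        with pytest.raises(ValueError):
            DapiMapParams(disk_radius=0)

    def test_recovers_truth_mask_on_fixture(self):
        img, truth = simulate_tissue_image(seed=2)
        dmap = build_dapi_map(img)
        jacc = (dmap.mask & truth).sum() / (dmap.mask | truth).sum()
        assert jacc >= 0.8


class TestRegionStats:
    def test_hand_arithmetic_inside_outside(self):
        px = rgb()
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        px[mask, 0] = 128  # red inside only
        stats = region_channel_stats(ChannelImage(px),
                                     DapiMap(mask, DapiMapParams()))
        assert stats.inside_mean["red"] == pytest.approx(128 / 255, abs=1e-12)
        assert stats.outside_mean["red"] == 0.0

    def test_areas_partition_image(self):
        img, truth = simulate_tissue_image(seed=1)
        stats = region_channel_stats(img, DapiMap(truth, DapiMapParams()))
        assert stats.inside_area + stats.outside_area == truth.size

    def test_all_zero_channel_zero_means(self):
        px = rgb()
        mask = np.zeros((64, 64), bool)
        mask[:10] = True
        stats = region_channel_stats(ChannelImage(px),
                                     DapiMap(mask, DapiMapParams()))
        assert stats.inside_mean["green"] == 0.0
        assert stats.outside_mean["green"] == 0.0

    def test_full_mask_outside_missing(self):
        px = rgb()
        stats = region_channel_stats(
            ChannelImage(px), DapiMap(np.ones((64, 64), bool), DapiMapParams()))
        assert stats.outside_area == 0
        assert np.isnan(stats.outside_mean["red"])

    def test_16bit_scaling(self):
        px = rgb(dtype=np.uint16)
        mask = np.zeros((64, 64), bool)
        mask[0, 0] = True
        px[0, 0, 0] = 65535
        stats = region_channel_stats(ChannelImage(px),
                                     DapiMap(mask, DapiMapParams()))
        assert stats.inside_mean["red"] == pytest.approx(1.0)

    def test_recovers_generating_levels_within_2pct(self):
        img, truth = simulate_tissue_image(marker_inside_level=180,
                                           marker_outside_level=40, seed=3)
        dmap = build_dapi_map(img)
        stats = region_channel_stats(img, dmap)
        assert stats.inside_mean["red"] == pytest.approx(180 / 255, rel=0.02)
        assert stats.outside_mean["red"] == pytest.approx(40 / 255, rel=0.02)


class TestNormalizedMarker:
    def _stats(self, marker=100, costain=50):
        px = rgb()
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        px[mask, 0] = marker
        px[mask, 1] = costain
        return region_channel_stats(ChannelImage(px),
                                    DapiMap(mask, DapiMapParams()))

    def test_uniform_marker_area_normalized(self):
        stats = self._stats(marker=100)
        score = normalized_marker_intensity(stats, "red", "dapi_area")
        assert score == pytest.approx(100 / 255, abs=1e-12)

    def test_channel_normalizer_scale_invariance(self):
        s1 = self._stats(marker=60, costain=30)
        s2 = self._stats(marker=120, costain=60)
        a = normalized_marker_intensity(s1, "red", "green")
        b = normalized_marker_intensity(s2, "red", "green")
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_marker_zero_score(self):
        stats = self._stats(marker=0, costain=50)
        assert normalized_marker_intensity(stats, "red", "green") == 0.0

    def test_zero_normalizer_raises(self):
        stats = self._stats(marker=10, costain=0)
        with pytest.raises(ValueError):
            normalized_marker_intensity(stats, "red", "green")


def test_image_io_roundtrip(tmp_path):
    img, _ = simulate_tissue_image(seed=6)
    for name in ("img.png", "img.tif"):
        path = tmp_path / name
        img.write(path)
        back = ChannelImage.read(path)
        assert np.array_equal(back.pixels, img.pixels)
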