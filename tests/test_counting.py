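"""Connected-component extraction, geometry and the four filter stages."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from leafless import counting, masks, occlusion

import oracles
from conftest import random_mask


def _component(area, major, minor, edge_surround=1.0):
    """Fabricated component with prescribed geometry (for predicate tests)."""
    return counting.BerryComponent(label=1, pixels=np.zeros((area, 2), dtype=int),
                                   area=area, centroid=(0.0, 0.0),
                                   major_axis=major, minor_axis=minor,
                                   edge_surround=edge_surround)


def _round_component(area, edge_surround=1.0):
    """Round component whose axes are consistent with its area, so only the
    size stage can reject it."""
    d = 2.0 * math.sqrt(area / math.pi)
    return _component(area, d, d, edge_surround)


class TestExtraction:
    def test_two_ringed_disks(self):
        m = np.zeros((30, 30), dtype=np.uint8)
        for center in [(8, 8), (20, 20)]:
            rr, cc = draw_disk(center, 6, shape=m.shape)
            m[rr, cc] = masks.BERRY_EDGE
            rr, cc = draw_disk(center, 4, shape=m.shape)
            m[rr, cc] = masks.BERRY
        assert len(counting.extract_components(m)) == 2

    def test_empty_mask(self):
        assert counting.extract_components(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_partition_matches_flood_fill(self, rng):
        for _ in range(40):
            m = random_mask(rng, (12, 12), p=(0.5, 0.1, 0.4))
            got = {frozenset(map(tuple, c.pixels))
                   for c in counting.extract_components(m)}
            want = {frozenset(c) for c in oracles.flood_fill_components(m)}
            assert got == want

    def test_4_connectivity_splits_diagonals(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[0, 0] = m[1, 1] = masks.BERRY
        assert len(counting.extract_components(
            m, counting.FilterConfig(connectivity=8))) == 1
        assert len(counting.extract_components(
            m, counting.FilterConfig(connectivity=4))) == 2


class TestGeometry:
    def test_digital_disk_is_round(self):
        m = np.zeros((30, 30), dtype=np.uint8)
        rr, cc = draw_disk((15, 15), 10, shape=m.shape)
        m[rr, cc] = masks.BERRY
        (c,) = counting.extract_components(m)
        assert c.axis_ratio == pytest.approx(1.0, abs=0.05)
        assert c.major_axis == pytest.approx(20.0, rel=0.08)

    def test_line_is_extremely_elongated(self):
        m = np.zeros((3, 24), dtype=np.uint8)
        m[1, 2:22] = masks.BERRY
        (c,) = counting.extract_components(m)
        assert c.axis_ratio < 0.1

    def test_ellipse_axis_ratio(self):
        m = np.zeros((60, 60), dtype=np.uint8)
        rr, cc = draw_ellipse(30, 30, 6, 20)
        m[rr, cc] = masks.BERRY
        (c,) = counting.extract_components(m)
        assert c.axis_ratio == pytest.approx(0.3, abs=0.03)

    def test_single_pixel_degenerate(self):
        m = np.zeros((3, 3), dtype=np.uint8)
        m[1, 1] = masks.BERRY
        (c,) = counting.extract_components(m)
        assert c.major_axis == c.minor_axis == 1.0
        assert c.axis_ratio == 1.0

    def test_axes_match_moment_oracle(self, rng):
        for _ in range(20):
            m = random_mask(rng, (10, 10), p=(0.5, 0.0, 0.5))
            for c in counting.extract_components(m):
                major, minor = oracles.axes_from_moments(
                    set(map(tuple, c.pixels)))
                assert c.major_axis == pytest.approx(major)
                assert c.minor_axis == pytest.approx(minor)


class TestFilterStages:
    def test_size_cutoff_is_exactly_25(self):
        verdicts = {a: counting.filter_components([_round_component(a)]).count
                    for a in range(1, 61)}
        assert all(v == 0 for a, v in verdicts.items() if a < 25)
        assert all(v == 1 for a, v in verdicts.items() if a >= 25)

    def test_axis_ratio_cutoff_is_exactly_03(self):
        for ratio in np.round(np.arange(0.05, 1.001, 0.05), 3).tolist() + [0.29, 0.3, 0.31]:
            major = 50.0
            minor = ratio * major
            area = int(math.ceil(math.pi * ((major + minor) / 4.0) ** 2))
            res = counting.filter_components([_component(area, major, minor)])
            assert res.count == (1 if ratio >= 0.3 else 0), ratio
            if ratio < 0.3:
                assert res.rejected[0].rejected_by == "shape"

    def test_fill_stage_rejects_sparse_components(self):
        # big bounding ellipse but few pixels: actual area far below expected
        c = _component(area=100, major=50.0, minor=40.0)
        res = counting.filter_components([c])
        assert res.count == 0 and res.rejected[0].rejected_by == "fill"

    def test_edge_stage_requires_surround(self):
        good = _round_component(300, edge_surround=0.9)
        bad = _round_component(300, edge_surround=0.2)
        res = counting.filter_components([good, bad])
        assert res.count == 1
        assert res.rejected[0].rejected_by == "edge"

    def test_first_failing_stage_recorded(self):
        c = _component(area=10, major=50.0, minor=5.0, edge_surround=0.0)
        res = counting.filter_components([c])
        assert res.rejected[0].rejected_by == "size"

    def test_tightening_is_monotone(self, rng):
        comps = [_round_component(int(a), edge_surround=float(e))
                 for a, e in zip(rng.integers(5, 400, 30), rng.random(30))]
        base = counting.filter_components(
            comps, counting.FilterConfig(edge_surround_fraction=0.3)).count
        tighter = counting.filter_components(
            comps, counting.FilterConfig(min_area=40,
                                         edge_surround_fraction=0.6)).count
        assert tighter <= base <= len(comps)


class TestCountBerries:
    def test_matches_full_oracle_on_random_masks(self, rng):
        for _ in range(120):
            m = random_mask(rng, (16, 16), p=(0.35, 0.15, 0.5))
            got = counting.count_berries(m).count
            assert got == oracles.count_with_predicates(m)

    def test_empty_mask_counts_zero(self):
        assert counting.count_berries(np.zeros((8, 8), dtype=np.uint8)).count == 0

    def test_toy_scene_parameter_recovery(self):
        spec = occlusion.ToySceneSpec(noise_sd=0.0)
        for seed in range(20):
            _, mask, planted = occlusion.generate_toy_scene(
                spec, np.random.default_rng(seed))
            assert counting.count_berries(mask).count == planted

    def test_translation_invariance(self, rng):
        m = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = draw_disk((12, 12), 7, shape=m.shape)
        m[rr, cc] = masks.BERRY_EDGE
        rr, cc = draw_disk((12, 12), 5, shape=m.shape)
        m[rr, cc] = masks.BERRY
        shifted = np.roll(m, (9, 11), axis=(0, 1))
        assert counting.count_berries(m).count == \
            counting.count_berries(shifted).count == 1

    def test_count_never_exceeds_component_count(self, rng):
        for _ in range(20):
            m = random_mask(rng, (16, 16), p=(0.4, 0.1, 0.5))
            res = counting.count_berries(m)
            assert res.count == len(res.retained)
            assert res.count + len(res.rejected) == \
                len(counting.extract_components(m))


class TestSizeStats:
    def test_equivalent_circle_diameter(self):
        res = counting.CountResult(count=1, retained=[_round_component(100)])
        [(area, diameter)] = counting.berry_size_stats(res)
        assert area == 100
        assert diameter == pytest.approx(2 * math.sqrt(100 / math.pi))

    def test_single_pixel_closed_form(self):
        res = counting.CountResult(count=1, retained=[_component(1, 1.0, 1.0)])
        [(_, diameter)] = counting.berry_size_stats(res)
        assert diameter == pytest.approx(2 / math.sqrt(math.pi))

    def test_aggregate_matches_per_record(self, rng):
        spec = occlusion.ToySceneSpec()
        _, mask, _ = occlusion.generate_toy_scene(spec, rng)
        res = counting.count_berries(mask)
        stats = counting.berry_size_stats(res)
        assert len(stats) == res.count
        for comp, (area, diameter) in zip(res.retained, stats):
            assert area == comp.area
            assert diameter == pytest.approx(2 * math.sqrt(comp.area / math.pi))


class TestBerryCounterEstimator:
    def test_get_set_params_roundtrip(self):
        counter = counting.BerryCounter()
        params = counter.get_params()
        assert params["min_area"] == 25 and params["min_axis_ratio"] == 0.3
        counter.set_params(min_area=10)
        assert counter.config.min_area == 10

    def test_predict_maps_masks_to_counts(self):
        spec = occlusion.ToySceneSpec(noise_sd=0.0)
        scenes = [occlusion.generate_toy_scene(spec, np.random.default_rng(s))
                  for s in range(4)]
        counter = counting.BerryCounter().fit()
        pred = counter.predict([m for _, m, _ in scenes])
        assert pred.tolist() == [planted for _, _, planted in scenes]
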