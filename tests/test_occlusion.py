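"""Synthetic leaf overlay, admissibility, dataset building, toy scenes."""

import numpy as np
import pytest

from leafless import counting, masks, occlusion


@pytest.fixture
def leaf(rng):
    return occlusion.make_toy_leaf("L0", rng, size=24)


@pytest.fixture
def scene(rng):
    gray, mask, planted = occlusion.generate_toy_scene(
        occlusion.ToySceneSpec(), rng)
    return gray, mask, planted


def _spec(leaf, offset=(20, 20), angle=0, width=3):
    return occlusion.OcclusionSpec(leaf_id=leaf.id, angle=angle, offset=offset,
                                   edge_closure_width=width)


class TestApplyLeaf:
    def test_outside_footprint_untouched(self, leaf, scene):
        gray, _, _ = scene
        spec = _spec(leaf)
        fp = occlusion.footprint_on_patch(gray.shape, leaf, spec)
        out = occlusion.apply_leaf_to_gray(gray, leaf, spec)
        assert np.array_equal(out[~fp], gray[~fp])
        assert not np.array_equal(out, gray)

    def test_full_cover_leaf(self, rng):
        gray = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        big = occlusion.LeafTemplate(
            id="full", texture=np.full((20, 20), 77, dtype=np.uint8),
            alpha=np.ones((20, 20), dtype=bool))
        out = occlusion.apply_leaf_to_gray(gray, big, _spec(big, offset=(0, 0)))
        assert (out == 77).all()

    def test_off_patch_rejected(self, leaf, scene):
        gray, _, _ = scene
        with pytest.raises(ValueError):
            occlusion.apply_leaf_to_gray(gray, leaf, _spec(leaf, offset=(500, 500)))

    def test_rotation_angles_preserve_binary_alpha(self, leaf):
        for angle in occlusion.ROTATION_ANGLES:
            rotated = occlusion.rotate_leaf(leaf, angle)
            assert rotated.alpha.dtype == bool
            assert rotated.alpha.any()


class TestDeriveOccludedMask:
    def test_leaf_over_background_only_clears_footprint(self, leaf):
        mask = np.zeros((64, 64), dtype=np.uint8)
        out = occlusion.derive_occluded_mask(mask, leaf, _spec(leaf))
        assert np.array_equal(out, mask)

    def test_berry_area_never_increases(self, leaf, rng):
        for seed in range(10):
            _, mask, _ = occlusion.generate_toy_scene(
                occlusion.ToySceneSpec(), np.random.default_rng(seed))
            spec = _spec(leaf, offset=(int(rng.integers(0, 40)),
                                       int(rng.integers(0, 40))))
            out = occlusion.derive_occluded_mask(mask, leaf, spec)
            assert masks.class_area(out, masks.BERRY) <= \
                masks.class_area(mask, masks.BERRY)

    def test_outside_footprint_identical(self, leaf, scene):
        _, mask, _ = scene
        spec = _spec(leaf)
        fp = occlusion.footprint_on_patch(mask.shape, leaf, spec)
        out = occlusion.derive_occluded_mask(mask, leaf, spec)
        assert np.array_equal(out[~fp], mask[~fp])

    def test_bisected_berry_gets_closure_band(self):
        # one berry; a half-plane leaf cuts straight through it
        mask = np.zeros((40, 40), dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        d2 = (yy - 20) ** 2 + (xx - 20) ** 2
        mask[d2 <= 100] = masks.BERRY_EDGE
        mask[d2 <= 64] = masks.BERRY
        half = occlusion.LeafTemplate(
            id="half", texture=np.full((40, 40), 60, dtype=np.uint8),
            alpha=np.ones((40, 40), dtype=bool))
        spec = occlusion.OcclusionSpec(leaf_id="half", angle=0, offset=(0, 20),
                                       edge_closure_width=3)
        out = occlusion.derive_occluded_mask(mask, half, spec)
        fp = occlusion.footprint_on_patch(mask.shape, half, spec)
        band = (out == masks.BERRY_EDGE) & fp
        assert band.any()
        # band hugs the cut: entirely within closure width of surviving berry
        surv = (out == masks.BERRY) & ~fp
        from scipy import ndimage
        near = ndimage.binary_dilation(surv, np.ones((3, 3), bool), iterations=3)
        assert (band <= near).all()
        # surviving half-berry has a closed contour: it survives counting
        assert counting.count_berries(out).count == 1


class TestAdmissibility:
    def test_all_background_pair_inadmissible(self):
        z = np.zeros((24, 24), dtype=np.uint8)
        assert not occlusion.patch_admissible(z, z)

    def test_bulk_berry_pair_admissible(self, scene, leaf):
        _, mask, _ = scene
        occluded = occlusion.derive_occluded_mask(mask, leaf, _spec(leaf))
        assert occlusion.patch_admissible(mask, occluded)

    def test_threshold_is_strict(self):
        # non-background fraction exactly 1/24 -> inadmissible
        mask = np.zeros((24, 24), dtype=np.uint8)
        mask[0] = masks.BERRY  # 24 of 576 pixels = 1/24
        occluded = mask.copy()
        assert not occlusion.patch_admissible(mask, occluded)
        mask[1, 0] = masks.BERRY  # now strictly above
        assert occlusion.patch_admissible(mask, mask)

    def test_occluded_mask_must_keep_signal(self):
        mask = np.zeros((24, 24), dtype=np.uint8)
        mask[:4] = masks.BERRY
        gone = np.zeros_like(mask)
        assert not occlusion.patch_admissible(mask, gone)

    def test_literal_variant_uses_background_fraction(self):
        mostly_berry = np.full((24, 24), masks.BERRY, dtype=np.uint8)
        mostly_berry[0, 0] = masks.BACKGROUND
        assert occlusion.patch_admissible(mostly_berry, mostly_berry)
        assert not occlusion.patch_admissible(mostly_berry, mostly_berry,
                                              literal=True)


class TestToyScenes:
    def test_zero_berries(self):
        spec = occlusion.ToySceneSpec(n_bunches=(0, 0))
        _, mask, planted = occlusion.generate_toy_scene(spec, 3)
        assert planted == 0 and (mask == 0).all()

    def test_count_recovery_and_consistency(self):
        spec = occlusion.ToySceneSpec()
        for seed in range(10):
            gray, mask, planted = occlusion.generate_toy_scene(spec, seed)
            assert counting.count_berries(mask).count == planted
            berry = mask == masks.BERRY
            if planted:
                assert gray[berry].mean() > gray[mask == 0].mean() + 50

    def test_same_seed_identical(self):
        spec = occlusion.ToySceneSpec()
        g1, m1, n1 = occlusion.generate_toy_scene(spec, 17)
        g2, m2, n2 = occlusion.generate_toy_scene(spec, 17)
        assert np.array_equal(g1, g2) and np.array_equal(m1, m2) and n1 == n2

    def test_strict_packing_raises_when_infeasible(self):
        spec = occlusion.ToySceneSpec(height=32, width=32,
                                      berries_per_bunch=(60, 60),
                                      strict_packing=True)
        with pytest.raises(ValueError):
            occlusion.generate_toy_scene(spec, 0)


class TestBuildDataset:
    def test_manifest_structure(self, toy_dataset):
        manifest, _ = toy_dataset
        assert set(manifest.train_leaves).isdisjoint(manifest.test_leaves)
        assert len(manifest.train_leaves) == 18
        assert len(manifest.test_leaves) == 6
        train = manifest.split_records("train")
        test = manifest.split_records("test")
        assert 0 < len(train) <= 8 * 4   # 8 train patches x multiplicity 4
        assert 0 < len(test) <= 2 * 3
        for rec in manifest.records:
            assert rec.spec.angle in occlusion.ROTATION_ANGLES
            pool = manifest.train_leaves if rec.split == "train" \
                else manifest.test_leaves
            assert rec.spec.leaf_id in pool

    def test_pairs_on_disk_are_admissible_and_aligned(self, toy_dataset):
        manifest, _ = toy_dataset
        n_checked = 0
        for rec, og, om, ng, nm in occlusion.load_pairs(manifest, "test"):
            assert occlusion.patch_admissible(nm, om)
            assert masks.class_area(om, masks.BERRY) <= \
                masks.class_area(nm, masks.BERRY)
            assert og.shape == om.shape == ng.shape == nm.shape
            n_checked += 1
        assert n_checked

    def test_same_seed_byte_identical_manifest(self, tmp_path, toy_leaves):
        rng = np.random.default_rng(5)
        patches = []
        for _ in range(4):
            gray, mask, _ = occlusion.generate_toy_scene(
                occlusion.ToySceneSpec(), rng)
            patches.append((gray, mask))
        m1 = occlusion.build_dataset(patches, toy_leaves, tmp_path / "a", seed=3)
        m2 = occlusion.build_dataset(patches, toy_leaves, tmp_path / "b", seed=3)
        assert m1.to_json() == m2.to_json()

    def test_empty_leaf_set_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            occlusion.build_dataset([(np.zeros((8, 8), np.uint8),) * 2], [],
                                    tmp_path)

    def test_leaf_roundtrip_on_disk(self, tmp_path, toy_leaves):
        occlusion.save_leaves(toy_leaves[:3], tmp_path)
        loaded = occlusion.load_leaves(tmp_path)
        assert [l.id for l in loaded] == [l.id for l in toy_leaves[:3]]
        assert np.array_equal(loaded[0].alpha, toy_leaves[0].alpha)
        assert np.array_equal(loaded[0].texture, toy_leaves[0].texture)


class TestReconstruction:
    def test_perfect_copy_reproduces_baseline(self, scene, leaf):
        _, mask, _ = scene
        spec = _spec(leaf)
        baseline = occlusion.derive_occluded_mask(mask, leaf, spec)
        rec = occlusion.reconstruct_generated_input(mask, leaf, spec)
        assert np.array_equal(rec, baseline)
        assert masks.pearson_correlation(baseline, rec) == pytest.approx(1.0)

    def test_outside_footprint_equals_generated(self, scene, leaf, rng):
        _, mask, _ = scene
        spec = _spec(leaf)
        generated = mask.copy()
        # arbitrary generated mask: corrupt some pixels
        generated[rng.integers(0, 64, 40), rng.integers(0, 64, 40)] = masks.BERRY
        rec = occlusion.reconstruct_generated_input(generated, leaf, spec)
        fp = occlusion.footprint_on_patch(mask.shape, leaf, spec)
        assert np.array_equal(rec[~fp], generated[~fp])
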