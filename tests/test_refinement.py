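"""Morphological refinement cascade: labelling, filters, masks, audit."""

import numpy as np
import pytest

from midas.refinement import (
    ArtefactMask,
    apply_artefact_mask,
    binarise_posterior,
    cleaned_posterior_map,
    components_to_mask,
    exclude_csf_neighbours,
    filter_by_size,
    label_components,
    mask_skull,
    refine_candidates,
)

AFF_1p5 = np.diag([1.5, 1.5, 1.5, 1.0])
VOXVOL = 1.5**3 / 1000.0  # cm^3 per working voxel


def flood_fill_oracle(mask, connectivity):
    """Brute-force component partition by breadth-first flood fill."""
    mask = np.asarray(mask, bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and (connectivity == 26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                n = tuple(np.add(v, off))
                if all(0 <= n[d] < mask.shape[d] for d in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        stack.append(n)
        comps.append(frozenset(comp))
    return set(comps)


class TestBinarise:
    def test_empty_and_single_voxel(self):
        vol = np.zeros((6, 6, 6))
        assert not binarise_posterior(vol, 0.2).any()
        vol[2, 3, 4] = 0.9
        assert binarise_posterior(vol, 0.2).sum() == 1

    def test_threshold_is_inclusive(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = 0.2
        assert binarise_posterior(vol, 0.2)[1, 1, 1]

    def test_random_map_equals_elementwise_oracle(self, rng):
        vol = rng.random((8, 8, 8))
        out = binarise_posterior(vol, 0.2)
        expected = np.array(
            [[[v >= 0.2 for v in row] for row in plane] for plane in vol]
        )
        np.testing.assert_array_equal(out, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarise_posterior(np.full((3, 3, 3), 1.5))


class TestLabelComponents:
    def test_corner_touching_voxels_one_component_at_26(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        assert len(label_components(mask, AFF_1p5, connectivity=26)) == 1
        assert len(label_components(mask, AFF_1p5, connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_sparse_mask_matches_flood_fill(self, rng, connectivity):
        mask = rng.random((10, 10, 10)) < 0.18
        comps = label_components(mask, AFF_1p5, connectivity=connectivity)
        got = {
            frozenset(map(tuple, c.voxels.tolist())) for c in comps
        }
        assert got == flood_fill_oracle(mask, connectivity)

    def test_world_measurements(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 3, 3] = True
        post = np.zeros((6, 6, 6))
        post[2, 3, 3], post[3, 3, 3] = 0.4, 0.7
        (comp,) = label_components(mask, AFF_1p5, posterior=post)
        assert comp.volume_cm3 == pytest.approx(2 * VOXVOL)
        np.testing.assert_allclose(comp.centroid_mm, [2.5 * 1.5, 4.5, 4.5])
        assert comp.peak_posterior == 0.7


class TestSizeFilter:
    def _component(self, n_voxels):
        mask = np.zeros((3, 3, n_voxels + 2), bool)
        mask[1, 1, :n_voxels] = True  # a line of contiguous voxels
        return label_components(mask, AFF_1p5)[0]

    def test_single_voxel_component_too_small(self):
        comp = self._component(1)
        assert comp.volume_cm3 == pytest.approx(0.003375)
        (out,) = filter_by_size([comp])
        assert out.discard_reason == "too_small"

    def test_component_above_cutoff_volume_too_large(self):
        n = int(np.ceil(0.70 / VOXVOL))  # ~0.70 cm^3 worth of voxels
        comp = self._component(n)
        assert comp.volume_cm3 > 0.675
        (out,) = filter_by_size([comp])
        assert out.discard_reason == "too_large"

    def test_ten_voxel_component_kept(self):
        comp = self._component(10)
        assert comp.volume_cm3 == pytest.approx(0.034, abs=0.001)
        (out,) = filter_by_size([comp])
        assert out.kept

    def test_exactly_at_cutoff_kept(self):
        # exclusion is strict: volume must exceed 0.675 cm^3
        comp = self._component(200)  # 0.675 cm^3 exactly
        assert comp.volume_cm3 == pytest.approx(0.675)
        (out,) = filter_by_size([comp])
        assert out.kept


class TestMasking:
    def _two_components(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:4, 2, 2] = True  # component A
        mask[7:9, 7, 7] = True  # component B
        return mask, label_components(mask, AFF_1p5)

    def test_component_inside_skull_discarded(self):
        mask, comps = self._two_components()
        skull = np.zeros(mask.shape)
        skull[2:4, 2, 2] = 0.9
        out = mask_skull(comps, skull, AFF_1p5)
        reasons = {c.id: c.discard_reason for c in out}
        assert "skull" in reasons.values()
        assert sum(c.kept for c in out) == 1

    def test_half_overlap_remeasured(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:6, 2, 2] = True
        comps = label_components(mask, AFF_1p5)
        skull = np.zeros(mask.shape)
        skull[2:4, 2, 2] = 0.9
        out = mask_skull(comps, skull, AFF_1p5)
        (surv,) = [c for c in out if c.kept]
        assert surv.n_voxels == 2
        assert surv.volume_cm3 == pytest.approx(2 * VOXVOL)

    def test_csf_below_threshold_no_change(self):
        _, comps = self._two_components()
        out = exclude_csf_neighbours(comps, np.full((10, 10, 10), 0.4), AFF_1p5)
        assert all(c.kept for c in out)

    def test_csf_neighbour_face_voxel_removed(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:5, 2, 2] = True
        comps = label_components(mask, AFF_1p5)
        csf = np.zeros(mask.shape)
        csf[1, 2, 2] = 0.9  # face-adjacent to voxel (2,2,2)
        out = exclude_csf_neighbours(comps, csf, AFF_1p5)
        (surv,) = [c for c in out if c.kept]
        assert surv.n_voxels == 2
        assert (2, 2, 2) not in set(map(tuple, surv.voxels.tolist()))

    def test_csf_exclusion_matches_morphology_oracle(self, rng):
        from scipy import ndimage

        cand = rng.random((12, 12, 12)) < 0.15
        csf = rng.random((12, 12, 12))
        comps = label_components(cand, AFF_1p5)
        out = exclude_csf_neighbours(comps, csf, AFF_1p5)
        surviving = components_to_mask(out, cand.shape)
        removal = ndimage.binary_dilation(
            csf > 0.5, ndimage.generate_binary_structure(3, 1)
        )
        np.testing.assert_array_equal(surviving, cand & ~removal)


class TestArtefactMask:
    def _comps(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:3, 1, 1] = True
        mask[5:7, 5, 5] = True
        return label_components(mask, AFF_1p5)

    def test_single_voxel_overlap_discards_whole_component(self):
        comps = self._comps()
        am = np.zeros((8, 8, 8), bool)
        am[1, 1, 1] = True
        out = apply_artefact_mask(comps, ArtefactMask(am, AFF_1p5))
        assert [c.discard_reason for c in out] == ["artefact_mask", None]

    def test_empty_mask_keeps_everything(self):
        comps = self._comps()
        out = apply_artefact_mask(
            comps, ArtefactMask.empty((8, 8, 8), AFF_1p5)
        )
        assert all(c.kept for c in out)

    def test_union_is_monotone(self):
        base = ArtefactMask.empty((8, 8, 8), AFF_1p5)
        m1 = np.zeros((8, 8, 8), bool)
        m1[1, 1, 1] = True
        step1 = base.union(m1, "c1")
        m2 = np.zeros((8, 8, 8), bool)
        m2[5, 5, 5] = True
        step2 = step1.union(m2, "c2")
        assert step1.mask.sum() == 1 and step2.mask.sum() == 2
        assert np.all(step2.mask >= step1.mask)
        assert step2.provenance == ["c1", "c2"]

    def test_nested_masks_monotone_in_survivors(self):
        comps = self._comps()
        small = np.zeros((8, 8, 8), bool)
        small[1, 1, 1] = True
        large = small.copy()
        large[5, 5, 5] = True
        n_small = sum(
            c.kept
            for c in apply_artefact_mask(comps, ArtefactMask(small, AFF_1p5))
        )
        n_large = sum(
            c.kept
            for c in apply_artefact_mask(comps, ArtefactMask(large, AFF_1p5))
        )
        assert n_large <= n_small


class TestCascade:
    def test_fixed_order_and_unique_discard_reasons(self, rng):
        shape = (16, 16, 16)
        post = np.zeros(shape)
        post[2:4, 2, 2] = 0.8  # survivor
        post[8, 8, 8] = 0.9  # too small (single voxel)
        post[12:14, 12, 12] = 0.7  # inside skull
        skull = np.zeros(shape)
        skull[12:14, 12, 12] = 0.9
        csf = np.zeros(shape)
        comps, cleaned = refine_candidates(post, skull, csf, AFF_1p5)
        assert len(comps) == 3
        reasons = sorted(
            (c.discard_reason or "kept") for c in comps
        )
        assert reasons == ["kept", "skull", "too_small"]
        # each discarded component has exactly one reason; survivors none
        for c in comps:
            assert (c.discard_reason is None) == c.kept

    def test_cleaned_map_keeps_probabilities_of_survivors_only(self):
        shape = (12, 12, 12)
        post = np.zeros(shape)
        post[2:4, 2, 2] = 0.8
        post[8, 8, 8] = 0.9
        comps, cleaned = refine_candidates(
            post, np.zeros(shape), np.zeros(shape), AFF_1p5
        )
        assert cleaned[2, 2, 2] == pytest.approx(0.8)
        assert cleaned[8, 8, 8] == 0.0  # too-small candidate zeroed

    def test_no_survivor_outside_size_bounds(self, rng):
        shape = (20, 20, 20)
        post = (rng.random(shape) < 0.25) * rng.uniform(0.3, 1.0, shape)
        comps, _ = refine_candidates(
            post, np.zeros(shape), np.zeros(shape), AFF_1p5
        )
        for c in comps:
            if c.kept:
                assert 2 <= c.n_voxels
                assert c.volume_cm3 <= 0.675
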