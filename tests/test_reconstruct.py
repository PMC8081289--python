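"""Reduced-dictionary inpainting and weighted patch aggregation."""

import numpy as np
import pytest

from octinpaint import (Dictionary, InpaintConfig, PatchGrid, SaturationMask,
                        UnrecoverablePatchError, aggregate, extract_patches,
                        inpaint_patch, inject_saturation, low_coherence_frame,
                        patch_weight, process_image, reduce_problem,
                        standardize_patches)


@pytest.fixture(scope="module")
def dict64x96():
    atoms = low_coherence_frame(64, 96, seed=2, max_coherence=0.5)
    # include a constant (DC) atom so patch-mean offsets over partial
    # valid sets are exactly representable
    atoms[:, 0] = 1.0 / 8.0
    return Dictionary(atoms, (8, 8))


class TestPatchWeight:
    def test_eight_by_eight_values(self):
        wm = patch_weight(8, 8)
        assert wm.factor_row[0] == pytest.approx(1 / 8)    # edge
        assert wm.factor_row[3] == pytest.approx(7 / 8)    # near center
        assert wm.weights[0, 0] == pytest.approx(1 / 64)   # corner
        assert (wm.weights > 0).all()

    def test_180_degree_symmetry(self):
        wm = patch_weight(6, 9)
        np.testing.assert_allclose(wm.weights, wm.weights[::-1, ::-1])

    def test_degenerate_single_pixel(self):
        assert patch_weight(1, 1).weights[0, 0] == pytest.approx(1.0)

    def test_zero_edge_variant_vanishes_at_edges(self):
        wm = patch_weight(8, 8, zero_edges=True)
        assert wm.factor_row[0] == 0.0
        assert wm.factor_row[7] == 0.0


class TestReduceProblem:
    def test_fully_valid_patch_is_identity(self, dict64x96, rng):
        img = rng.uniform(0, 255, (8, 8))
        ps = standardize_patches(
            extract_patches(img, None, PatchGrid((8, 8), (8, 8))))
        rp = reduce_problem(ps[0], dict64x96)
        assert rp.n_removed == 0
        np.testing.assert_array_equal(rp.X_prime, dict64x96.atoms)
        np.testing.assert_array_equal(rp.y_prime, ps[0].vector)

    def test_fully_saturated_patch_unrecoverable(self, dict64x96, rng):
        img = rng.uniform(0, 255, (8, 8))
        pm = np.ones((8, 8), dtype=bool)
        ps = extract_patches(img, pm, PatchGrid((8, 8), (8, 8)))
        with pytest.raises(UnrecoverablePatchError):
            reduce_problem(ps[0], dict64x96, min_valid=8)

    def test_one_saturated_column_removes_eight_rows(self, dict64x96, rng):
        img = rng.uniform(0, 255, (8, 8))
        pm = np.zeros((8, 8), dtype=bool)
        pm[:, 3] = True
        ps = standardize_patches(
            extract_patches(img, pm, PatchGrid((8, 8), (8, 8))))
        rp = reduce_problem(ps[0], dict64x96)
        assert rp.n_removed == 8
        assert rp.X_prime.shape == (56, 96)
        assert rp.kept_indices.size == 56


class TestInpaintPatch:
    def test_exact_sparse_patch_recovers_masked_pixels(self, dict64x96):
        """A patch that is exactly mean + 2·atom_j must be reproduced at
        the masked pixels to near machine precision."""
        m = 100.0
        full = m + 2.0 * dict64x96.atoms[:, 17]
        valid = np.ones(64, dtype=bool)
        valid[[5, 13, 21, 40, 63]] = False
        from octinpaint import Patch, standardize_patch
        p = standardize_patch(Patch((0, 0), (8, 8), full.copy(), valid))
        rp = reduce_problem(p, dict64x96)
        z = inpaint_patch(rp, dict64x96, p.mean, p=2)
        np.testing.assert_allclose(z[~valid], full[~valid], atol=1e-6)

    def test_zero_signal_reconstructs_the_mean(self, dict64x96):
        from octinpaint import Patch
        p = Patch((0, 0), (8, 8), np.zeros(64), np.ones(64, dtype=bool))
        rp = reduce_problem(p, dict64x96)
        z = inpaint_patch(rp, dict64x96, 42.0, p=2)
        np.testing.assert_allclose(z, 42.0)


class TestAggregate:
    def test_constant_predictions_average_to_the_constant(self):
        grid = PatchGrid((12, 12), (4, 4))
        Z = np.full((grid.n_patches, 16), 9.0)
        out, covered = aggregate(grid.coords(), Z, patch_weight(4, 4),
                                 (12, 12))
        assert covered.all()
        np.testing.assert_allclose(out, 9.0)

    def test_two_estimate_weighted_mean(self):
        coords = np.array([[0, 0], [0, 0]])
        Z = np.array([[1.0], [5.0]])
        wm = patch_weight(1, 1)
        out, _ = aggregate(coords, Z, wm, (1, 1))
        assert out[0, 0] == pytest.approx(3.0)  # equal weights

    def test_identity_processing_round_trips_the_image(self, rng):
        img = rng.uniform(0, 255, (25, 31))
        grid = PatchGrid((25, 31), (8, 8))
        ps = extract_patches(img, None, grid)
        out, covered = aggregate(ps.coords, ps.vectors, patch_weight(8, 8),
                                 (25, 31))
        assert covered.all()
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_empty_estimate_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.empty((0, 2)), np.empty((0, 16)),
                      patch_weight(4, 4), (8, 8))


class TestProcessImage:
    def test_empty_mask_passthrough_is_exact_identity(self, dict64x96, rng):
        img = rng.uniform(0, 255, (32, 32))
        mask = SaturationMask(np.zeros(32, dtype=bool))
        cfg = InpaintConfig(process_all_patches=False)
        np.testing.assert_array_equal(
            process_image(img, mask, dict64x96, cfg), img)

    def test_empty_mask_full_processing_denoises(self, dict64x96, rng):
        img = rng.uniform(0, 255, (32, 32))
        mask = SaturationMask(np.zeros(32, dtype=bool))
        out = process_image(img, mask, dict64x96, InpaintConfig())
        assert out.shape == img.shape
        assert not np.array_equal(out, img)       # 2-sparse approximation
        assert out.min() >= 0 and out.max() <= 255

    def test_far_pixels_bit_identical_in_passthrough(self, phantom_dict,
                                                     small_phantom):
        noisy, _ = small_phantom
        cols = np.zeros(96, dtype=bool)
        cols[40:44] = True
        mask = SaturationMask(cols)
        corrupted = inject_saturation(noisy, mask)
        cfg = InpaintConfig(process_all_patches=False)
        out = process_image(corrupted, mask, phantom_dict, cfg)
        far = np.zeros(96, dtype=bool)
        far[:32] = far[52:] = True   # > patch width away from the run
        np.testing.assert_array_equal(out[:, far], corrupted[:, far])
        assert not np.array_equal(out[:, 40:44], corrupted[:, 40:44])

    def test_exact_sparse_image_inpainted_to_high_precision(self, dict64x96):
        """Non-overlapping 8x8 tiles built from single atoms; a masked
        column must be recovered almost exactly."""
        tile = (120.0 + 40.0 * dict64x96.atoms[:, 11]).reshape(8, 8)
        img = np.tile(tile, (4, 4))
        cols = np.zeros(32, dtype=bool)
        cols[10] = True
        mask = SaturationMask(cols)
        corrupted = inject_saturation(img, mask)
        cfg = InpaintConfig(sparsity=2, stride=(8, 8),
                            process_all_patches=False)
        out = process_image(corrupted, mask, dict64x96, cfg)
        np.testing.assert_allclose(out[:, 10], img[:, 10], atol=1e-4)

    def test_runs_up_to_seven_columns_leave_valid_pixels(self, dict64x96,
                                                         rng):
        """With 8-wide patches at stride 1, a 7-wide saturated run still
        leaves every covering patch at least one valid column."""
        img = rng.uniform(0, 255, (16, 40))
        cols = np.zeros(40, dtype=bool)
        cols[16:23] = True
        pm = SaturationMask(cols).to_pixel_mask(16)
        ps = extract_patches(img, pm, PatchGrid((16, 40), (8, 8)))
        assert ps.valid.sum(axis=1).min() >= 8

    def test_patch_shape_mismatch_rejected(self, dict64x96, rng):
        img = rng.uniform(0, 255, (32, 32))
        mask = SaturationMask(np.zeros(32, dtype=bool))
        with pytest.raises(ValueError):
            process_image(img, mask, dict64x96,
                          InpaintConfig(patch_size=(4, 4)))
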