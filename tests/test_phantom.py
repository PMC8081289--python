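"""Phantom simulator: speckle statistics, mask protocol, clipped spectra."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octinpaint import (MaskPattern, PhantomSpec, generate_phantom,
                        generate_random_mask, inject_saturation,
                        simulate_spectra)


def _spec(**kw):
    base = dict(height=64, width=64, layer_boundaries=(10, 25, 45),
                layer_reflectivities=(180.0, 120.0, 80.0), seed=0)
    base.update(kw)
    return PhantomSpec(**base)


class TestGeneratePhantom:
    def test_speckle_free_limit_noisy_equals_reference(self):
        noisy, ref = generate_phantom(_spec(speckle_shape=np.inf))
        np.testing.assert_array_equal(noisy, ref)

    def test_single_average_reference_is_the_noisy_frame(self):
        noisy, ref = generate_phantom(_spec(n_average=1))
        np.testing.assert_array_equal(noisy, ref)

    def test_five_frame_averaging_cuts_variance_fivefold(self):
        """Monte-Carlo: per-pixel variance of the 5-average reference is
        about a fifth of the single-frame variance."""
        noisies, refs = [], []
        for seed in range(120):
            n, r = generate_phantom(_spec(seed=seed, n_average=5,
                                          boundary_wobble=0.0))
            noisies.append(n)
            refs.append(r)
        # interior block well inside one layer, away from clipping
        sl = (slice(30, 40), slice(20, 44))
        v_noisy = np.var(np.stack([x[sl] for x in noisies]), axis=0)
        v_ref = np.var(np.stack([x[sl] for x in refs]), axis=0)
        ratio = (v_ref / v_noisy).mean()
        assert 0.14 < ratio < 0.28

    def test_intensity_range_and_shapes(self):
        noisy, ref = generate_phantom(_spec())
        assert noisy.shape == ref.shape == (64, 64)
        for img in (noisy, ref):
            assert img.min() >= 0 and img.max() <= 255

    @pytest.mark.parametrize("kw", [
        dict(layer_boundaries=(25, 10, 45)),            # not increasing
        dict(layer_boundaries=(10, 25, 70)),            # beyond height
        dict(layer_reflectivities=(180.0, -1.0, 80.0)),
        dict(n_average=0),
        dict(speckle_shape=0.0),
    ])
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)


class TestRandomMask:
    @pytest.mark.parametrize("x,y", [(30, 2), (20, 3), (15, 4), (12, 5),
                                     (10, 6)])
    def test_benchmark_patterns_have_sixty_saturated_alines(self, x, y):
        for seed in (0, 1, 2):
            mask = generate_random_mask(1500, MaskPattern(x, y), seed)
            assert mask.n_saturated == 60
            runs = mask.runs()
            assert len(runs) == x
            assert all(length == y for _, length in runs)

    def test_same_seed_reproduces_mask(self):
        a = generate_random_mask(500, MaskPattern(5, 4), 11)
        b = generate_random_mask(500, MaskPattern(5, 4), 11)
        np.testing.assert_array_equal(a.columns, b.columns)

    def test_infeasible_pattern_rejected(self):
        with pytest.raises(ValueError):
            generate_random_mask(20, MaskPattern(5, 4), 0)

    @settings(derandomize=True, max_examples=60)
    @given(x=st.integers(1, 12), y=st.integers(1, 8),
           seed=st.integers(0, 10_000))
    def test_exact_run_structure_for_any_feasible_pattern(self, x, y, seed):
        width = 200
        if width - y - (x - 1) * (y + 1) + 1 < x:
            return  # infeasible, covered by the rejection test
        mask = generate_random_mask(width, MaskPattern(x, y), seed)
        assert mask.n_saturated == x * y
        assert [length for _, length in mask.runs()] == [y] * x


class TestInjectSaturation:
    def test_empty_mask_leaves_image_unchanged(self, rng):
        img = rng.uniform(0, 200, (30, 40))
        mask = generate_random_mask(40, MaskPattern(1, 1), 0)
        mask.columns[:] = False
        np.testing.assert_array_equal(inject_saturation(img, mask), img)

    def test_all_columns_saturated_gives_constant_image(self, rng):
        img = rng.uniform(0, 200, (30, 40))
        mask = generate_random_mask(40, MaskPattern(1, 1), 0)
        mask.columns[:] = True
        out = inject_saturation(img, mask, 255.0)
        assert np.all(out == 255.0)

    def test_changed_pixel_count_matches_pattern(self, rng):
        img = rng.uniform(0, 200, (50, 300))
        mask = generate_random_mask(300, MaskPattern(30, 2), 3)
        out = inject_saturation(img, mask, 255.0)
        assert np.count_nonzero(out != img) == 60 * 50

    def test_idempotent(self, rng):
        img = rng.uniform(0, 200, (20, 100))
        mask = generate_random_mask(100, MaskPattern(4, 3), 1)
        once = inject_saturation(img, mask)
        twice = inject_saturation(once, mask)
        np.testing.assert_array_equal(once, twice)

    def test_dimension_mismatch_rejected(self, rng):
        img = rng.uniform(0, 200, (20, 99))
        mask = generate_random_mask(100, MaskPattern(4, 3), 1)
        with pytest.raises(ValueError):
            inject_saturation(img, mask)


class TestSimulateSpectra:
    def test_no_clip_columns_stay_below_capacity(self):
        frame = simulate_spectra(512, 40, clip_columns=(), seed=0)
        assert frame.charges.max() < frame.capacity

    def test_clipped_column_reaches_capacity_others_do_not(self):
        frame = simulate_spectra(512, 40, clip_columns=[7], seed=1)
        at_cap = frame.charges == frame.capacity
        assert at_cap[:, 7].any()
        assert not at_cap[:, np.arange(40) != 7].any()

    def test_clipped_column_has_consecutive_capacity_run(self):
        frame = simulate_spectra(512, 40, clip_columns=[3], seed=2)
        col = frame.charges[:, 3] == frame.capacity
        # longest run of capacity-valued points
        run = best = 0
        for v in col:
            run = run + 1 if v else 0
            best = max(best, run)
        assert best >= 2

    def test_invalid_capacity_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectra(512, 10, capacity=0.0)

    def test_h5_round_trip(self, tmp_path):
        from octinpaint import SpectralFrame
        frame = simulate_spectra(256, 16, clip_columns=[2, 3], seed=4)
        path = tmp_path / "spectra.h5"
        frame.save_h5(path)
        back = SpectralFrame.load_h5(path)
        np.testing.assert_array_equal(back.charges, frame.charges)
        assert back.capacity == frame.capacity
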