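"""Phantom generator: geometry, motion averaging, degradation, masks."""

import numpy as np
import pytest
from dataclasses import replace

from petseg_consensus import (
    PhantomSpec,
    VoxelVolume,
    apply_motion,
    build_phantom,
    cohort_specs,
    degrade,
    gen_masks,
)


class TestBuildPhantom:
    def test_same_seed_is_bitwise_identical(self, small_spec):
        a = build_phantom(small_spec)
        b = build_phantom(small_spec)
        assert np.array_equal(a.activity.data, b.activity.data)
        assert np.array_equal(a.gt_static, b.gt_static)

    def test_different_seed_changes_shape(self, small_spec):
        a = build_phantom(small_spec)
        b = build_phantom(replace(small_spec, seed=small_spec.seed + 1))
        assert not np.array_equal(a.gt_static, b.gt_static)

    def test_volume_close_to_target(self, small_spec):
        case = build_phantom(small_spec)
        vol = case.gt_static.sum() * case.activity.voxel_volume_cm3
        assert vol == pytest.approx(small_spec.lesion_volume_cm3, rel=0.05)

    def test_level_partition_counts_and_values(self, small_spec):
        case = build_phantom(small_spec)
        n = case.gt_static.sum()
        counts = [m.sum() for m in case.level_masks]
        assert sum(counts) == n
        for c, f in zip(counts, small_spec.level_fractions):
            assert abs(c - f * n) <= 1.0
        lesion_vals = np.unique(case.activity.data[case.gt_static])
        assert lesion_vals.size == 3  # one activity per level
        # core is the hottest level, rim the coldest
        v1 = case.activity.data[case.level_masks[0]]
        v3 = case.activity.data[case.level_masks[2]]
        assert v1.min() > v3.max()

    def test_homogeneous_lesion_with_degenerate_fractions(self, small_spec):
        spec = replace(small_spec, level_fractions=(1.0, 0.0, 0.0))
        case = build_phantom(spec)
        assert np.unique(case.activity.data[case.gt_static]).size == 1
        assert case.level_masks[0].sum() == case.gt_static.sum()

    def test_lesion_too_large_for_grid_rejected(self):
        spec = PhantomSpec(shape=(10, 16, 16), lesion_volume_cm3=55.0)
        with pytest.raises(ValueError):
            build_phantom(spec)

    def test_background_is_unity(self, small_spec):
        case = build_phantom(small_spec)
        assert np.all(case.activity.data[~case.gt_static] == 1.0)


class TestMotion:
    def test_zero_amplitude_is_identity(self, small_spec):
        spec = replace(small_spec, diaphragm_cm=0.0, ap_cm=0.0)
        case = build_phantom(spec)
        moved = apply_motion(case, spec)
        assert np.array_equal(moved.activity.data, case.activity.data)
        assert np.array_equal(moved.gt_motion, moved.gt_static)

    def test_union_strictly_grows_and_contains_static(self, small_spec):
        case = build_phantom(small_spec)
        moved = apply_motion(case, small_spec)
        assert moved.gt_motion.sum() > moved.gt_static.sum()
        assert not np.any(moved.gt_static & ~moved.gt_motion)

    def test_total_activity_conserved(self, small_spec):
        # rigid shifts with linear interpolation preserve interior mass
        case = build_phantom(small_spec)
        moved = apply_motion(case, small_spec)
        rel = abs(moved.activity.data.sum() - case.activity.data.sum()) \
            / case.activity.data.sum()
        assert rel < 1e-3


class TestDegrade:
    def test_deterministic_given_seed(self, small_spec):
        case = build_phantom(small_spec)
        a = degrade(case.activity, small_spec, seed=42)
        b = degrade(case.activity, small_spec, seed=42)
        assert np.array_equal(a.data, b.data)
        c = degrade(case.activity, small_spec, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_never_negative(self, small_spec):
        case = build_phantom(small_spec)
        out = degrade(case.activity, small_spec, seed=1)
        assert np.all(out.data >= 0)

    def test_high_count_limit_recovers_blurred_image(self, small_spec):
        from scipy.ndimage import gaussian_filter
        case = build_phantom(small_spec)
        spec = replace(small_spec, noise_scale=1e8)
        out = degrade(case.activity, spec, seed=0)
        psf = [spec.psf_fwhm_mm / 10 / 2.3548 / s for s in case.activity.spacing]
        post = [spec.post_filter_fwhm_mm / 10 / 2.3548 / s
                for s in case.activity.spacing]
        ref = gaussian_filter(gaussian_filter(case.activity.data, psf), post)
        assert np.allclose(out.data, ref, rtol=5e-3, atol=5e-3)

    def test_unbiased_in_uniform_region(self):
        """Monte-Carlo: noisy mean equals the noise-free value within 3 SE."""
        spec = PhantomSpec(shape=(16, 16, 16), noise_scale=30.0,
                           psf_fwhm_mm=4.0, post_filter_fwhm_mm=2.0)
        flat = VoxelVolume(np.full((16, 16, 16), 2.0), spec.spacing)
        region = (slice(5, 11),) * 3
        means = [
            degrade(flat, spec, seed=1000 + i).data[region].mean()
            for i in range(200)
        ]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 2.0) < 3 * se + 1e-9

    def test_negative_activity_rejected(self, small_spec):
        bad = VoxelVolume(-np.ones((4, 4, 4)), small_spec.spacing)
        with pytest.raises(ValueError):
            degrade(bad, small_spec, seed=0)


class TestGenMasks:
    def test_single_voxel_gives_expanded_box(self):
        gt = np.zeros((15, 15, 15), dtype=bool)
        gt[7, 7, 7] = True
        rect, irr = gen_masks(gt, seed=0, margin=3)
        assert rect.sum() == 7 ** 3
        assert rect[4:11, 4:11, 4:11].all()
        assert irr[gt].all()

    def test_containment_over_random_cases(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            gt = np.zeros((12, 12, 12), dtype=bool)
            z, y, x = rng.integers(3, 9, size=3)
            gt[z - 2:z + 2, y - 2:y + 2, x - 2:x + 2] = True
            rect, irr = gen_masks(gt, seed=int(trial))
            assert not np.any(gt & ~rect)
            assert not np.any(gt & ~irr)

    def test_seed_changes_irregular_not_rectangle(self, small_spec):
        gt = build_phantom(small_spec).gt_static
        r1, i1 = gen_masks(gt, seed=1)
        r2, i2 = gen_masks(gt, seed=2)
        assert np.array_equal(r1, r2)
        assert not np.array_equal(i1, i2)

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            gen_masks(np.zeros((5, 5, 5), dtype=bool), seed=0)


class TestCohort:
    def test_volumes_span_range_reproducibly(self):
        specs = cohort_specs(13, base_seed=3)
        vols = [s.lesion_volume_cm3 for s in specs]
        assert vols[0] == pytest.approx(3.5)
        assert vols[-1] == pytest.approx(55.0)
        assert np.all(np.diff(vols) > 0)
        again = cohort_specs(13, base_seed=3)
        assert [s.seed for s in again] == [s.seed for s in specs]
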