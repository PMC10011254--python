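"""The four delineation methods on controlled phantoms and toy images."""

import numpy as np
import pytest

from petseg_consensus import (
    SegConfig,
    dsc,
    seg_41max,
    seg_ap,
    seg_masac,
    seg_st,
    segment,
)
from petseg_consensus.segmentation import _ap_cluster


class TestFixedThreshold:
    def test_recovers_homogeneous_object(self, two_level_image):
        img, obj, init = two_level_image
        res = seg_41max(img, init)
        assert np.array_equal(res.mask, obj)

    def test_scale_invariance(self, two_level_image):
        img, obj, init = two_level_image
        base = seg_41max(img, init).mask
        for c in (0.01, 3.7, 1e4):
            assert np.array_equal(seg_41max(c * img, init).mask, base)

    def test_profile_selection(self):
        # threshold 4.1 on [1,2,5,10,9,4,1] keeps exactly {5, 10, 9}
        img = np.array([1, 2, 5, 10, 9, 4, 1], dtype=float).reshape(1, 1, -1)
        init = np.ones_like(img, dtype=bool)
        res = seg_41max(img, init)
        assert np.flatnonzero(res.mask).tolist() == [2, 3, 4]

    def test_zero_image_flags_failure(self):
        init = np.ones((3, 3, 3), dtype=bool)
        res = seg_41max(np.zeros((3, 3, 3)), init)
        assert res.failed and not res.mask.any()


class TestContrastThreshold:
    def test_threshold_formula(self):
        # mSUV70 = 10, BG = 2, a = b = 0.5 -> T = 6: only values >= 6 stay
        img = np.full((1, 1, 6), 2.0)
        img[0, 0, :3] = [10.0, 10.0, 7.0]
        init = np.zeros_like(img, dtype=bool)
        init[0, 0, :4] = True
        bg = np.zeros_like(init)
        bg[0, 0, 4:] = True
        res = seg_st(img, init, bg=bg)
        assert np.flatnonzero(res.mask).tolist() == [0, 1, 2]

    def test_homogeneous_object_on_flat_background(self, two_level_image):
        img, obj, init = two_level_image
        res = seg_st(img, init)
        assert np.array_equal(res.mask, obj)

    def test_reduces_to_41max_with_matched_coefficients(self):
        rng = np.random.default_rng(4)
        from scipy.ndimage import gaussian_filter
        for trial in range(5):
            img = gaussian_filter(rng.random((10, 12, 12)), 1.0)
            img[3:7, 4:8, 4:8] += 1.0
            init = np.zeros(img.shape, dtype=bool)
            init[1:9, 2:10, 2:10] = True
            vals = img[init]
            vmax = vals.max()
            msuv70 = vals[vals >= 0.7 * vmax].mean()
            cfg = SegConfig(st_a=0.41 * vmax / msuv70, st_b=0.0)
            a = seg_st(img, init, cfg=cfg, bg=None)
            b = seg_41max(img, init)
            assert np.array_equal(a.mask, b.mask)

    def test_overlapping_background_rejected(self, two_level_image):
        img, obj, init = two_level_image
        with pytest.raises(ValueError):
            seg_st(img, init, bg=init)


class TestAffinityPropagation:
    def test_separable_populations(self):
        rng = np.random.default_rng(0)
        img = np.ones((6, 6, 6)) + rng.normal(0, 0.01, (6, 6, 6))
        hot = np.zeros_like(img, dtype=bool)
        hot[2:4, 2:4, 2:4] = True
        img[hot] += 9.0
        res = seg_ap(img, np.ones_like(hot))
        assert np.array_equal(res.mask, hot)

    def test_constant_image_is_single_cluster(self):
        init = np.zeros((5, 5, 5), dtype=bool)
        init[1:4, 1:4, 1:4] = True
        res = seg_ap(np.ones((5, 5, 5)), init)
        assert np.array_equal(res.mask, init)

    def test_matches_exhaustive_exemplar_oracle(self):
        """Partition equals brute-force maximization of the AP objective."""
        from itertools import combinations
        values = np.array([1.0, 1.05, 1.1, 1.15, 1.2, 5.0, 5.1, 5.2,
                           9.0, 9.05, 9.1, 9.15])
        sim = -(values[:, None] - values[None, :]) ** 2
        pref = np.median(sim[~np.eye(values.size, dtype=bool)])

        best_score, best_labels = -np.inf, None
        n = values.size
        for r in range(1, n + 1):
            for exemplars in combinations(range(n), r):
                ex = np.array(exemplars)
                assign = ex[np.argmax(sim[:, ex], axis=1)]
                assign[ex] = ex  # exemplars represent themselves (s = 0)
                score = sim[np.arange(n), assign].sum() + pref * r
                if score > best_score:
                    best_score, best_labels = score, assign.copy()

        cfg = SegConfig(ap_preference=float(pref))
        labels, exemplars, _ = _ap_cluster(values, cfg)
        # compare as partitions (label ids are arbitrary)
        ours = {tuple(np.flatnonzero(labels == c)) for c in np.unique(labels)}
        oracle = {tuple(np.flatnonzero(best_labels == e)) for e in np.unique(best_labels)}
        assert ours == oracle

    def test_hottest_vs_largest_rule(self):
        img = np.ones((4, 4, 8))
        img[:, :, 6:] = 10.0  # hot minority
        init = np.ones_like(img, dtype=bool)
        hot = seg_ap(img, init, cfg=SegConfig(ap_rule="hottest"))
        big = seg_ap(img, init, cfg=SegConfig(ap_rule="largest"))
        assert np.array_equal(hot.mask, img >= 10.0)
        assert np.array_equal(big.mask, img < 10.0)


class TestActiveContour:
    def test_recovers_sharp_object(self, two_level_image):
        img, obj, init = two_level_image
        res = seg_masac(img, init)
        assert dsc(res.mask, obj) >= 0.99

    def test_deterministic(self, two_level_image):
        img, obj, init = two_level_image
        a = seg_masac(img, init)
        b = seg_masac(img, init)
        assert np.array_equal(a.mask, b.mask)

    def test_large_lambda_approaches_data_partition(self, two_level_image):
        img, obj, init = two_level_image
        res = seg_masac(img, init, cfg=SegConfig(lam=50.0))
        assert dsc(res.mask, obj) >= 0.99


class TestCommonContracts:
    @pytest.mark.parametrize("method", ["masac", "ap", "st", "41max"])
    def test_result_within_initial_mask(self, method):
        rng = np.random.default_rng(9)
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.random((10, 12, 12)), 1.0)
        img[4:7, 5:9, 5:9] += 2.0
        init = np.zeros(img.shape, dtype=bool)
        init[2:9, 3:11, 3:11] = True
        res = segment(method, img, init)
        assert not np.any(res.mask & ~init)

    def test_empty_init_rejected(self, two_level_image):
        img, _, _ = two_level_image
        for fn in (seg_41max, seg_st, seg_ap, seg_masac):
            with pytest.raises(ValueError):
                fn(img, np.zeros_like(img, dtype=bool))

    def test_unknown_method_rejected(self, two_level_image):
        img, _, init = two_level_image
        with pytest.raises(ValueError):
            segment("otsu", img, init)
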