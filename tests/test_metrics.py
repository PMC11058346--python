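"""Image-quality and classification metrics against hand values and
independent straight-line recomputations."""

import math

import numpy as np
import pytest

from tear.metrics import (ROI, ConfusionCounts, DegenerateContrastError,
                          ROIPair, classification_metrics, cnr, enl, psnr,
                          roi_stats, ssim)


def oracle_roi_stats(img, rois):
    """Independent two-pass computation over explicit python loops."""
    out = []
    for roi in (rois.signal, rois.background):
        vals = [img[r][c]
                for r in range(roi.row, roi.row + roi.height)
                for c in range(roi.col, roi.col + roi.width)]
        n = len(vals)
        mu = sum(vals) / n
        var = sum((v - mu) ** 2 for v in vals) / n
        out.extend([mu, math.sqrt(var)])
    return tuple(out)


def random_roi_pair(rng, h, w, box=6):
    r1 = int(rng.integers(0, h // 2 - box))
    r2 = int(rng.integers(h // 2, h - box))
    c1, c2 = (int(rng.integers(0, w - box)) for _ in range(2))
    return ROIPair(signal=ROI(r2, c2, box, box), background=ROI(r1, c1, box, box))


class TestROIStats:
    def test_constant_box(self):
        img = np.full((16, 16), 0.8)
        rois = ROIPair(signal=ROI(8, 8, 4, 4), background=ROI(0, 0, 4, 4))
        mu_s, sig_s, _, _ = roi_stats(img, rois)
        assert mu_s == 0.8 and sig_s == 0.0

    def test_two_by_two_hand_value(self):
        img = np.zeros((8, 8))
        img[0:2, 0:2] = [[0, 1], [0, 1]]
        rois = ROIPair(signal=ROI(0, 0, 2, 2), background=ROI(4, 4, 2, 2))
        mu_s, sig_s, _, _ = roi_stats(img, rois)
        assert mu_s == 0.5 and sig_s == 0.5

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            img = rng.random((24, 20))
            rois = random_roi_pair(rng, 24, 20)
            got = roi_stats(img, rois)
            want = oracle_roi_stats(img.tolist(), rois)
            assert got == pytest.approx(want, abs=1e-12)

    def test_out_of_bounds_roi_raises(self):
        img = np.zeros((8, 8))
        rois = ROIPair(signal=ROI(6, 6, 4, 4), background=ROI(0, 0, 2, 2))
        with pytest.raises(IndexError):
            roi_stats(img, rois)


class TestPSNR:
    def test_known_offset_gives_20db(self):
        ref = np.full((10, 10), 0.4)
        pred = ref + 0.1
        assert psnr(pred, ref) == pytest.approx(20.0, abs=1e-12)

    def test_identical_images_give_inf(self):
        x = np.random.default_rng(0).random((8, 8))
        assert psnr(x, x) == math.inf

    def test_halving_dynamic_range_shifts_by_6db(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        shift = psnr(a, b, 1.0) - psnr(a, b, 0.5)
        assert shift == pytest.approx(20 * math.log10(2), abs=1e-10)

    def test_decreases_with_noise_level(self):
        rng = np.random.default_rng(9)
        ref = rng.random((32, 32))
        pattern = rng.normal(size=(32, 32))
        vals = [psnr(np.clip(ref + s * pattern, 0, 1), ref)
                for s in (0.01, 0.05, 0.1)]
        assert vals[0] > vals[1] > vals[2]


class TestSSIM:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(1).random((16, 16))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_is_negative(self):
        rng = np.random.default_rng(2)
        x = (rng.random((16, 16)) > 0.5).astype(float)
        assert ssim(x, 1.0 - x) < 0

    def test_matches_moment_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p, r = rng.random((10, 10)), rng.random((10, 10))
            mu_p, mu_r = p.mean(), r.mean()
            var_p, var_r = p.var(), r.var()
            cov = (p * r).mean() - mu_p * mu_r
            c1, c2 = 0.01 ** 2, 0.03 ** 2
            want = ((2 * mu_p * mu_r + c1) * (2 * cov + c2)
                    / ((mu_p ** 2 + mu_r ** 2 + c1) * (var_p + var_r + c2)))
            assert ssim(p, r) == pytest.approx(want, abs=1e-12)

    def test_invariant_to_joint_affine_rescale(self):
        # equal-mean pair (one is a shuffle of the other) so the luminance
        # term is exactly 1 and only the stabilizers can drift
        # correlated pair, so neither term is stabilizer-dominated
        rng = np.random.default_rng(4)
        p = rng.random((16, 16))
        r = np.clip(p + 0.02 * rng.standard_normal((16, 16)), 0, 1)
        a = ssim(p, r)
        b = ssim(2.0 * p + 0.1, 2.0 * r + 0.1)
        assert b == pytest.approx(a, abs=1e-3)


class TestCNR:
    def make(self, mu_s, sig_s, mu_b, sig_b):
        """Build an image realizing the four ROI moments exactly."""
        img = np.zeros((12, 12))
        img[8:10, 0:2] = [[mu_s + sig_s, mu_s - sig_s]] * 2
        img[0:2, 0:2] = [[mu_b + sig_b, mu_b - sig_b]] * 2
        rois = ROIPair(signal=ROI(8, 0, 2, 2), background=ROI(0, 0, 2, 2))
        return img, rois

    def test_unit_ratio_is_zero_db(self):
        img, rois = self.make(2.0, 1.0, 1.0, 0.0)
        assert cnr(img, rois) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_ten_is_ten_db(self):
        img, rois = self.make(11.0, 1.0, 1.0, 0.0)
        assert cnr(img, rois) == pytest.approx(10.0, abs=1e-12)

    def test_matches_scalar_recomputation(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            img = rng.random((20, 20)) * 0.2
            img[12:18, 4:10] += 0.6
            rois = ROIPair(signal=ROI(12, 4, 6, 6), background=ROI(2, 2, 6, 6))
            mu_s, sig_s, mu_b, sig_b = roi_stats(img, rois)
            want = 10 * math.log10((mu_s - mu_b)
                                   / math.sqrt(sig_s ** 2 + sig_b ** 2))
            assert cnr(img, rois) == pytest.approx(want, abs=1e-12)

    def test_inverted_contrast_raises(self):
        img, rois = self.make(1.0, 0.5, 2.0, 0.5)
        with pytest.raises(DegenerateContrastError):
            cnr(img, rois)

    def test_flat_rois_raise(self):
        img, rois = self.make(2.0, 0.0, 1.0, 0.0)
        with pytest.raises(DegenerateContrastError):
            cnr(img, rois)

    def test_ignores_pixels_outside_rois(self):
        img, rois = self.make(2.0, 1.0, 1.0, 0.0)
        img2 = img.copy()
        img2[5:7, 5:7] = 123.0
        assert cnr(img, rois) == cnr(img2, rois)


class TestENL:
    def test_hand_value(self):
        img = np.zeros((12, 12))
        img[8:10, 0:2] = [[1.0 + 1.0, 1.0 - 1.0]] * 2  # sigma_s = 1
        img[0:2, 0:2] = 2.0                            # mu_b = 2
        rois = ROIPair(signal=ROI(8, 0, 2, 2), background=ROI(0, 0, 2, 2))
        assert enl(img, rois) == pytest.approx(4.0)

    def test_flat_signal_roi_gives_inf_sentinel(self):
        img = np.full((12, 12), 0.5)
        rois = ROIPair(signal=ROI(8, 0, 2, 2), background=ROI(0, 0, 2, 2))
        assert enl(img, rois) == math.inf

    def test_homogeneous_convention_uses_background_only(self):
        rng = np.random.default_rng(8)
        img = rng.random((16, 16))
        rois = ROIPair(signal=ROI(10, 2, 4, 4), background=ROI(2, 2, 4, 4))
        _, _, mu_b, sig_b = roi_stats(img, rois)
        assert enl(img, rois, convention="homogeneous") == \
            pytest.approx(mu_b ** 2 / sig_b ** 2, abs=1e-12)


class TestClassificationMetrics:
    def test_hand_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["precision"] == pytest.approx(90 / 110)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["f1"] == pytest.approx(2 * (90 / 110) * 0.9 / (90 / 110 + 0.9))

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_f1_algebraic_identity(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 100, size=4))
            m = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn),
                                            rel=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


def test_roi_validation():
    with pytest.raises(ValueError):
        ROI(0, 0, 1, 1)          # area < 4
    with pytest.raises(ValueError):
        ROIPair(signal=ROI(0, 0, 4, 4), background=ROI(2, 2, 4, 4))  # overlap
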