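"""Improved algorithm: kernel distances, spatial term, hesitation, fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyseg import (
    FuzzyCMeans,
    GrayImage,
    IntuitionisticKernelFCM,
    hesitation_correct,
    kernel_distance_sq,
    make_phantom,
    match_labels,
    neighborhood_mean,
    overall_accuracy,
    update_centers,
    update_centers_spatial,
    update_membership,
    update_membership_kernel,
)
from fuzzyseg.exceptions import DomainError
from fuzzyseg.intuitionistic import fuzzify_image


def as_img(values):
    return GrayImage(np.asarray(values, dtype=float).reshape(1, -1))


class TestNeighborhoodMean:
    def test_constant_image_unchanged(self):
        img = GrayImage(np.full((5, 5), 3.0))
        assert np.array_equal(neighborhood_mean(img, 1), img.intensities)

    def test_center_voxel_excluded(self):
        data = np.zeros((3, 3))
        data[1, 1] = 9.0
        assert neighborhood_mean(GrayImage(data), 1)[1, 1] == 0.0

    def test_bounded_by_data_range(self, rng):
        img = GrayImage(rng.normal(0, 1, (10, 12)))
        mbar = neighborhood_mean(img, 2)
        assert mbar.min() >= img.intensities.min() - 1e-12
        assert mbar.max() <= img.intensities.max() + 1e-12

    def test_mask_aware_averaging(self):
        data = np.array([[0.0, 100.0, 2.0],
                         [4.0, 0.0, 6.0],
                         [8.0, 10.0, 12.0]])
        mask = np.ones((3, 3), bool)
        mask[0, 1] = False  # the 100 is outside the brain
        mbar = neighborhood_mean(GrayImage(data, mask=mask), 1)
        assert mbar[1, 1] == pytest.approx((0 + 2 + 4 + 6 + 8 + 10 + 12) / 7)


class TestKernelDistance:
    def test_zero_at_equal_points(self):
        assert kernel_distance_sq(3.0, 3.0, 1.0) == 0.0

    def test_value_at_one_kernel_width(self):
        expected = 2 * (1 - np.exp(-1.0))
        assert kernel_distance_sq(5.0, 4.0, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.26424, abs=1e-5)

    def test_monotone_and_bounded(self):
        d = kernel_distance_sq(np.linspace(0, 100, 200), 0.0, 2.0)
        assert np.all(np.diff(d) >= 0)
        assert d[-1] <= 2.0 and d[-1] == pytest.approx(2.0, abs=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DomainError):
            kernel_distance_sq(1.0, 0.0, 0.0)


class TestSpatialCenters:
    def test_theta_zero_reduces_to_plain_update(self, rng, random_membership):
        m = rng.normal(0, 1, 25)
        B = random_membership(3, 25)
        mbar = rng.normal(0, 1, 25)
        a0 = update_centers_spatial(as_img(m), mbar, B, 2.0, 0.0)
        assert a0 == pytest.approx(update_centers(as_img(m), B, 2.0), abs=1e-14)

    def test_constant_image_fixed_point(self, random_membership):
        m = np.full(10, 4.2)
        a = update_centers_spatial(as_img(m), m, random_membership(2, 10),
                                   2.0, 0.7)
        assert a == pytest.approx([4.2, 4.2])

    def test_matches_scalar_loop_oracle(self, rng, random_membership):
        m = rng.normal(0, 1, 19)
        mbar = rng.normal(0, 1, 19)
        B = random_membership(3, 19)
        l, th = 2.0, 0.5
        expected = [
            sum(B[x, y] ** l * (m[y] + th * mbar[y]) for y in range(19))
            / ((1 + th) * sum(B[x, y] ** l for y in range(19)))
            for x in range(3)
        ]
        got = update_centers_spatial(as_img(m), mbar, B, l, th)
        assert got == pytest.approx(expected, abs=1e-12)


class TestKernelMembership:
    def test_reduces_to_euclidean_for_wide_kernel(self, rng):
        m = rng.normal(0, 1, 40)
        a = np.array([-1.0, 0.5, 2.0])
        B_kernel = update_membership_kernel(as_img(m), m, a, 2.0, 0.0, 1e6)
        B_plain = update_membership(as_img(m), a, 2.0)
        assert np.max(np.abs(B_kernel - B_plain)) < 1e-3

    def test_zero_distance_is_crisp(self):
        B = update_membership_kernel(as_img([1.0, 9.0]), np.array([1.0, 9.0]),
                                     np.array([1.0, 5.0]), 2.0, 0.5, 1.0)
        assert B[:, 0] == pytest.approx([1.0, 0.0])

    def test_symmetric_pixel_splits_evenly(self):
        B = update_membership_kernel(as_img([1.0, 0.0]), np.array([1.0, 0.0]),
                                     np.array([0.0, 2.0]), 2.0, 0.5, 1.3)
        assert B[:, 0] == pytest.approx([0.5, 0.5])

    def test_matches_scalar_loop_oracle(self, rng):
        m = rng.normal(0, 1, 15)
        mbar = rng.normal(0, 1, 15)
        a = np.array([-0.5, 0.3, 1.1])
        l, th, dl = 2.0, 0.4, 0.8

        def kd(u, v):
            return 2 * (1 - np.exp(-((u - v) ** 2) / dl**2))

        D = np.array([[kd(m[y], a[x]) + th * kd(mbar[y], a[x])
                       for y in range(15)] for x in range(3)])
        expected = np.array([
            [1.0 / sum((D[x, y] / D[g, y]) ** (1 / (l - 1)) for g in range(3))
             for y in range(15)] for x in range(3)])
        got = update_membership_kernel(as_img(m), mbar, a, l, th, dl)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_column_sums_one(self, rng):
        m = rng.normal(0, 1, 30)
        B = update_membership_kernel(as_img(m), m, np.array([-1.0, 1.0]),
                                     2.0, 0.5, 0.7)
        assert B.sum(axis=0) == pytest.approx(np.ones(30), abs=1e-10)


class TestHesitationCorrect:
    def test_pi_one_is_identity(self, random_membership):
        B = random_membership(3, 10)
        out = hesitation_correct(B, np.ones(10))
        assert out == pytest.approx(B, abs=1e-14)

    def test_pi_zero_is_crisp(self, random_membership):
        B = random_membership(4, 10)
        out = hesitation_correct(B, np.zeros(10))
        assert set(np.unique(out)) <= {0.0, 1.0}
        assert np.array_equal(np.argmax(out, 0), np.argmax(B, 0))

    def test_hand_example(self):
        B = np.array([[0.6], [0.3], [0.1]])
        out = hesitation_correct(B, np.array([0.5]))
        assert out[:, 0] == pytest.approx([0.8, 0.15, 0.05])

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_preserves_argmax_and_unit_sums(self, seed):
        g = np.random.default_rng(seed)
        B = g.random((g.integers(2, 6), 17))
        B /= B.sum(axis=0)
        pi = g.random(17)
        out = hesitation_correct(B, pi)
        assert np.array_equal(np.argmax(out, 0), np.argmax(B, 0))
        assert out.sum(axis=0) == pytest.approx(np.ones(17), abs=1e-12)
        cols = np.arange(17)
        assert np.all(out[np.argmax(B, 0), cols] >= B[np.argmax(B, 0), cols] - 1e-12)

    def test_out_of_range_hesitation_rejected(self, random_membership):
        with pytest.raises(DomainError):
            hesitation_correct(random_membership(2, 3), np.array([0.1, 1.2, 0.0]))


class TestFit:
    def test_noiseless_phantom_recovered(self, phantom64):
        img = phantom64.image
        res = IntuitionisticKernelFCM(img, 4).fit(seed=0)
        matched = match_labels(res.label_map(), phantom64.labels, img.mask)
        acc = overall_accuracy(matched, phantom64.labels, img.mask)
        assert acc >= 0.999

    def test_same_seed_bit_identical(self, small_phantom):
        img = small_phantom.image
        r1 = IntuitionisticKernelFCM(img, 4).fit(seed=9)
        r2 = IntuitionisticKernelFCM(img, 4).fit(seed=9)
        assert np.array_equal(r1.membership, r2.membership)
        assert np.array_equal(r1.centers, r2.centers)
        assert r1.n_iter == r2.n_iter

    def test_not_worse_than_fcm_on_salt_pepper(self):
        ph = make_phantom((64, 64, 64), noise_model="salt_pepper",
                          noise_level=0.05, seed=3)
        img = ph.image

        def acc(res):
            matched = match_labels(res.label_map(), ph.labels, img.mask)
            return overall_accuracy(matched, ph.labels, img.mask)

        acc_ik = acc(IntuitionisticKernelFCM(img, 4).fit(seed=0))
        acc_f = acc(FuzzyCMeans(img, 4).fit(seed=0))
        assert acc_ik >= acc_f

    def test_accuracy_non_decreasing_in_theta(self):
        # Gaussian noise at 10% of the phantom's intensity range
        base = make_phantom((64, 64, 64))
        spread = np.ptp(base.image.masked_values())
        ph = make_phantom((64, 64, 64), noise_model="gaussian",
                          noise_level=0.1 * spread, seed=11)
        img = ph.image
        accs = []
        for theta in (0.0, 0.5):
            res = IntuitionisticKernelFCM(img, 4, spatial_weight=theta
                                          ).fit(seed=0)
            matched = match_labels(res.label_map(), ph.labels, img.mask)
            accs.append(overall_accuracy(matched, ph.labels, img.mask))
        assert accs[1] >= accs[0]

    def test_centers_gray_monotone_with_working_centers(self, small_phantom):
        res = IntuitionisticKernelFCM(small_phantom.image, 4).fit(seed=0)
        assert np.all(np.diff(res.centers) >= 0)
        assert np.all(np.diff(res.centers_gray) >= 0)
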