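"""Ring detection: DoG response, mask morphology, labelling, circle fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from guvkin import (
    dog_response,
    extract_membrane,
    fit_circle,
    label_guvs,
    max_project,
    segment_channel,
    union_masks,
)
from guvkin.pipeline import segment_movie
from guvkin.simulate import rasterize_annulus


# --- independent pixel-enumeration oracle for the morphology pipeline -----

def _disk_offsets(radius):
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def _dilate(mask, radius):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            out[y, x] = any(
                0 <= y + dy < h and 0 <= x + dx < w and mask[y + dy, x + dx]
                for dy, dx in _disk_offsets(radius)
            )
    return out


def _erode(mask, radius):
    # out-of-bounds counts as background, matching border_value=0
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            out[y, x] = all(
                0 <= y + dy < h and 0 <= x + dx < w and mask[y + dy, x + dx]
                for dy, dx in _disk_offsets(radius)
            )
    return out


def _fill_holes(mask):
    # flood the complement from the border, 4-connected
    h, w = mask.shape
    outside = np.zeros_like(mask)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if not mask[y, x] and (y in (0, h - 1) or x in (0, w - 1))
    ]
    for y, x in stack:
        outside[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    return mask | ~outside


def membrane_oracle(union, k, smooth_radius=0, smooth_operator="none"):
    if smooth_radius > 0 and smooth_operator == "close":
        smoothed = _erode(_dilate(union, smooth_radius), smooth_radius)
    elif smooth_radius > 0 and smooth_operator == "open":
        smoothed = _dilate(_erode(union, smooth_radius), smooth_radius)
    else:
        smoothed = union
    filled = _fill_holes(smoothed)
    gradient = filled & ~_erode(filled, k)
    return gradient & union, filled


class TestDogResponse:
    def test_constant_input_cancels(self):
        resp = dog_response(np.full((16, 16), 9.0), 1.0, 3.0)
        assert np.abs(resp).max() < 1e-9

    def test_impulse_gives_dog_kernel(self):
        # response to a unit impulse is the difference of the two
        # (discrete, truncated) Gaussian kernels
        n = 65
        frame = np.zeros((n, n))
        frame[n // 2, n // 2] = 1.0
        resp = dog_response(frame, 1.0, 3.0)

        def kernel(sigma):
            r = int(4 * sigma + 0.5)  # default truncation
            x = np.arange(-r, r + 1)
            g = np.exp(-(x**2) / (2 * sigma**2))
            g /= g.sum()
            k = np.zeros(n)
            k[n // 2 - r : n // 2 + r + 1] = g
            return np.outer(k, k)

        np.testing.assert_allclose(resp, kernel(1.0) - kernel(3.0), atol=1e-12)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError, match="sigma"):
            dog_response(np.zeros((8, 8)), 1.0, 0.5)


class TestSegmentChannel:
    def test_blank_frame_empty_mask(self):
        assert not segment_channel(np.zeros((32, 32)), 1.0, 3.0).any()

    def test_single_ring_recall(self):
        annulus = rasterize_annulus((96, 96), (48, 48), 24, 2)
        frame = np.where(annulus, 100.0, 0.0)
        mask = segment_channel(frame, 1.0, 3.0)
        recall = (mask & annulus).sum() / annulus.sum()
        assert recall >= 0.9

    def test_two_rings_both_hit(self):
        a = rasterize_annulus((128, 128), (32, 32), 16, 2)
        b = rasterize_annulus((128, 128), (90, 90), 20, 2)
        mask = segment_channel(np.where(a | b, 80.0, 0.0), 1.0, 3.0)
        assert (mask & a).sum() / a.sum() > 0.5
        assert (mask & b).sum() / b.sum() > 0.5


class TestUnionMasks:
    def test_identity_idempotence_counting(self):
        a = np.zeros((5, 5), bool)
        a[1, 1] = a[2, 2] = True
        b = np.zeros((5, 5), bool)
        b[3, 3] = b[4, 4] = True
        empty = np.zeros((5, 5), bool)
        np.testing.assert_array_equal(union_masks(a, empty), a)
        np.testing.assert_array_equal(union_masks(a, a), a)
        assert union_masks(a, b).sum() == 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            union_masks(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestExtractMembrane:
    def test_filled_square_border_ring(self):
        mask = np.zeros((9, 9), bool)
        mask[1:8, 1:8] = True  # 7x7 filled square
        membrane, filled = extract_membrane(
            mask, thickness_um=1.0, pixel_size_um=1.0, smooth_radius_px=0
        )
        assert membrane.sum() == 24  # 49 - 25 one-pixel border
        np.testing.assert_array_equal(filled, mask)

    def test_empty_mask_empty_outputs(self):
        membrane, filled = extract_membrane(np.zeros((9, 9), bool), 0.5, 0.25)
        assert not membrane.any() and not filled.any()

    def test_membrane_disjoint_from_eroded_interior(self, rng):
        from scipy.ndimage import binary_erosion
        from skimage.morphology import disk

        for _ in range(20):
            mask = rng.random((15, 15)) < 0.4
            membrane, filled = extract_membrane(mask, 0.5, 0.25)
            k = 2
            assert not (membrane & binary_erosion(filled, structure=disk(k))).any()
            assert not (membrane & ~mask).any()  # subset of the input mask

    @given(
        mask=arrays(bool, (9, 9)),
        k=st.integers(1, 2),
        smooth=st.sampled_from([(0, "none"), (1, "close"), (1, "open")]),
    )
    def test_matches_pixel_enumeration_oracle(self, mask, k, smooth):
        radius, op = smooth
        membrane, filled = extract_membrane(
            mask, thickness_um=float(k), pixel_size_um=1.0,
            smooth_radius_px=radius, smooth_operator=op,
        )
        exp_membrane, exp_filled = membrane_oracle(mask, k, radius, op)
        np.testing.assert_array_equal(membrane, exp_membrane)
        np.testing.assert_array_equal(filled, exp_filled)


class TestLabelGuvs:
    @staticmethod
    def _disc(shape, center, radius):
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    def test_disc_radius_recovered(self):
        filled = self._disc((64, 64), (32, 32), 10)
        regions = label_guvs(filled, np.zeros_like(filled), pixel_size_um=1.0)
        assert len(regions) == 1
        assert abs(regions[0].radius_px - 10) <= 0.5

    def test_two_discs_two_regions(self):
        filled = self._disc((64, 64), (16, 16), 8) | self._disc((64, 64), (48, 48), 8)
        regions = label_guvs(filled, np.zeros_like(filled), pixel_size_um=1.0)
        assert len(regions) == 2

    def test_small_disc_filtered(self):
        filled = self._disc((64, 64), (32, 32), 3)
        regions = label_guvs(
            filled, np.zeros_like(filled), pixel_size_um=1.0, min_radius_um=5.0
        )
        assert regions == []


class TestFitCircle:
    def test_symmetric_points(self):
        (cy, cx), r = fit_circle([(0, 1), (1, 0), (0, -1), (-1, 0)])
        assert (cy, cx) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_circumcircle_of_right_triangle(self):
        (cy, cx), r = fit_circle([(0, 0), (2, 0), (0, 2)])
        assert (cy, cx) == pytest.approx((1.0, 1.0), abs=1e-9)
        assert r == pytest.approx(math.sqrt(2), rel=1e-9)

    def test_exact_on_sampled_circle(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 25)
        pts = np.column_stack([5 + 3 * np.sin(theta), 7 + 3 * np.cos(theta)])
        (cy, cx), r = fit_circle(pts)
        assert (cy, cx) == pytest.approx((5.0, 7.0), abs=1e-9)
        assert r == pytest.approx(3.0, rel=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestMaxProject:
    def test_single_slice_identity(self):
        a = np.arange(9.0).reshape(3, 3)
        np.testing.assert_array_equal(max_project([a]), a)

    def test_elementwise_maximum(self):
        a = np.array([[1, 5], [3, 2]])
        b = np.array([[2, 1], [0, 9]])
        np.testing.assert_array_equal(max_project([a, b]), [[2, 5], [3, 9]])

    def test_projection_dominates_slices(self, rng):
        slices = [rng.random((8, 8)) for _ in range(10)]
        proj = max_project(slices)
        for s in slices:
            assert (proj >= s).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            max_project([np.zeros((2, 2)), np.zeros((3, 3))])


class TestOnSimulatedScenes:
    def test_noiseless_jaccard_and_radius(self, noiseless_movie):
        stack, gt = noiseless_movie
        regions, membrane_masks, _ = segment_movie(stack)
        assert len(regions) == len(gt.masks)
        for reg in regions:
            d = [
                math.hypot(reg.centroid[0] - cy, reg.centroid[1] - cx)
                for cy, cx in gt.centers_px
            ]
            i = int(np.argmin(d))
            true_mask = gt.masks[i]
            rows, cols = reg.membrane_pixels[0]
            detected = np.zeros_like(true_mask)
            detected[rows, cols] = True
            jacc = (detected & true_mask).sum() / (detected | true_mask).sum()
            assert jacc >= 0.6
            assert abs(reg.radius_um / gt.radii_um[i] - 1) <= 0.05

    def test_segmentation_is_deterministic(self, noisy_movie):
        stack, _ = noisy_movie
        state = np.random.get_state()[1][:5].copy()
        first, masks_a, _ = segment_movie(stack)
        second, masks_b, _ = segment_movie(stack)
        np.testing.assert_array_equal(masks_a, masks_b)
        assert [r.label for r in first] == [r.label for r in second]
        np.testing.assert_array_equal(state, np.random.get_state()[1][:5])
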