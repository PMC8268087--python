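"""Structure-tensor orientation: phantoms, masks, quadrants, equivariance."""

import numpy as np
import pytest
from scipy import ndimage

from ivdmech.orientation import (
    AxisConvention,
    apply_masks,
    axial_difference,
    circular_summary,
    max_project,
    orientation_field,
    split_quadrants,
)
from ivdmech.synthetic import FiberImageSpec, generate_fiber_image

from conftest import grating


def masked_mean(image, **kwargs):
    fld = apply_masks(image, orientation_field(image, **kwargs))
    return circular_summary(fld.theta[fld.valid_mask]).circular_mean


class TestMaxProject:
    def test_single_slice_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        assert np.array_equal(max_project(img[None]), img)

    def test_disjoint_spots_union(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[3, 3], b[10, 12] = 1.0, 1.0
        proj = max_project(np.stack([a, b]))
        assert proj[3, 3] == 1.0 and proj[10, 12] == 1.0

    def test_projection_dominates_every_slice(self):
        stack = np.random.default_rng(1).random((5, 20, 20))
        proj = max_project(stack)
        assert np.all(proj[None] >= stack)


class TestOrientationField:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 87.0, 120.0, 7.0])
    def test_grating_orientation_recovered(self, angle):
        mean = masked_mean(grating(angle))
        assert abs(axial_difference(mean, angle)) < 1.0

    def test_uniform_image_zero_coherency_no_exception(self):
        fld = orientation_field(np.full((128, 128), 3.7))
        assert np.all(fld.coherency == 0.0)
        assert not fld.valid_mask.any()

    def test_coherency_bounded(self):
        phantom = generate_fiber_image(FiberImageSpec(n_fibers=100, seed=2, noise_sd=0.05))
        fld = orientation_field(phantom.image)
        assert np.all((fld.coherency >= 0.0) & (fld.coherency <= 1.0))

    def test_rotation_equivariance(self):
        phantom = generate_fiber_image(
            FiberImageSpec(n_fibers=300, angle_mean=40.0, angle_sd=10.0, seed=5,
                           noise_sd=0.02)
        )
        rotated = ndimage.rotate(phantom.image, 20.0, reshape=False, order=3)

        def interior_mean(image):
            fld = apply_masks(image, orientation_field(image))
            mask = fld.valid_mask.copy()
            mask[:128, :] = mask[-128:, :] = False
            mask[:, :128] = mask[:, -128:] = False
            return circular_summary(fld.theta[mask]).circular_mean

        shift = axial_difference(interior_mean(rotated), interior_mean(phantom.image))
        assert shift == pytest.approx(20.0, abs=1.0)

    def test_intensity_rescaling_invariance(self):
        img = grating(57.0)
        fld1 = orientation_field(img)
        fld2 = orientation_field(4.0 * img + 10.0)
        common = fld1.valid_mask & fld2.valid_mask
        dev = np.array(
            [axial_difference(a, b)
             for a, b in zip(fld1.theta[common].ravel()[::251],
                             fld2.theta[common].ravel()[::251])]
        )
        assert np.max(np.abs(dev)) < 1e-6

    def test_finite_difference_fallback_agrees(self):
        img = grating(33.0)
        m_spline = masked_mean(img, gradient_method="cubic-spline")
        m_fd = masked_mean(img, gradient_method="finite-difference")
        assert abs(axial_difference(m_spline, m_fd)) < 2.0

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            orientation_field(np.zeros((50, 50)), window_sigma_px=10.0)


class TestMasks:
    def test_intensity_threshold_strict(self):
        img = np.zeros((128, 128))
        img[:64] = 200.0
        img[64:] = 10.0  # exactly 5 % of max: must be excluded
        fld = orientation_field(img)
        masked = apply_masks(img, fld, intensity_frac=0.05, coherency_min=-1.0)
        assert not masked.valid_mask[120:, :].any()

    def test_coherency_threshold_strict(self):
        img = grating(10.0)
        fld = orientation_field(img)
        boundary = np.isclose(fld.coherency, 0.05)
        masked = apply_masks(img, fld, coherency_min=0.05)
        assert not (masked.valid_mask & boundary).any()

    def test_all_zero_image_empty_mask(self):
        img = np.zeros((128, 128))
        masked = apply_masks(img, orientation_field(img))
        assert not masked.valid_mask.any()

    def test_masks_monotone_in_thresholds(self):
        phantom = generate_fiber_image(FiberImageSpec(n_fibers=80, seed=6, noise_sd=0.05))
        fld = orientation_field(phantom.image)
        loose = apply_masks(phantom.image, fld, 0.02, 0.02).valid_mask
        tight = apply_masks(phantom.image, fld, 0.10, 0.10).valid_mask
        assert not (tight & ~loose).any()

    def test_background_only_image_empty_after_coherency_mask(self):
        with pytest.warns(UserWarning):
            phantom = generate_fiber_image(
                FiberImageSpec(n_fibers=0, noise_sd=0.0, seed=1)
            )
        masked = apply_masks(phantom.image, orientation_field(phantom.image))
        assert not masked.valid_mask.any()


class TestQuadrants:
    def test_even_split(self):
        part = split_quadrants((0, 100, 0, 80))
        for rows, cols in part.regions.values():
            assert rows.stop - rows.start == 50
            assert cols.stop - cols.start == 40

    def test_odd_rows_extra_pixel_to_caudal(self):
        part = split_quadrants((0, 101, 0, 80))
        cr = part.regions["cranial-dorsal"][0]
        ca = part.regions["caudal-dorsal"][0]
        assert cr.stop - cr.start == 50
        assert ca.stop - ca.start == 51

    def test_regions_tile_disjointly(self):
        part = split_quadrants((5, 104, 3, 80))
        cover = np.zeros((110, 90), dtype=int)
        for rows, cols in part.regions.values():
            cover[rows, cols] += 1
        r0, r1, c0, c1 = part.bbox
        assert np.all(cover[r0:r1, c0:c1] == 1)
        cover[r0:r1, c0:c1] = 0
        assert not cover.any()

    def test_flipping_polarity_swaps_labels_only(self):
        a = split_quadrants((0, 100, 0, 100))
        b = split_quadrants((0, 100, 0, 100), AxisConvention(dorsal_at_left=False))
        assert a.regions["cranial-dorsal"] == b.regions["cranial-ventral"]
        assert a.regions["caudal-dorsal"] == b.regions["caudal-ventral"]

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            split_quadrants((0, 1, 0, 10))


class TestEndToEndPhantoms:
    def test_single_orientation_recovered_within_two_degrees(self):
        phantom = generate_fiber_image(
            FiberImageSpec(n_fibers=200, angle_mean=30.0, angle_sd=0.0, seed=1)
        )
        assert abs(axial_difference(masked_mean(phantom.image), 30.0)) < 1.0

    def test_per_quadrant_means_recovered_within_three_degrees(self):
        spec = FiberImageSpec(
            n_fibers=400,
            quadrant_angles={
                "cranial-dorsal": (90.0, 0.0),
                "cranial-ventral": (90.0, 0.0),
                "caudal-dorsal": (150.0, 0.0),
                "caudal-ventral": (30.0, 0.0),
            },
            seed=2,
        )
        phantom = generate_fiber_image(spec)
        fld = apply_masks(phantom.image, orientation_field(phantom.image))
        part = split_quadrants((0, 512, 0, 512))
        for label, (mean_true, _) in spec.quadrant_angles.items():
            rows, cols = part.regions[label]
            thetas = fld.theta[rows, cols][fld.valid_mask[rows, cols]]
            got = circular_summary(thetas).circular_mean
            assert abs(axial_difference(got, mean_true)) < 3.0, label
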