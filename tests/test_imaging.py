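"""Image quantification: projection, normalization, masking, DoG blob
detection (with a brute-force scale-space oracle), densities, transects
and Welch's t-test."""

import numpy as np
import pytest
from scipy import stats

import endofish as ef
from endofish.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedDensityError,
)
from endofish.imaging import (
    AdaptiveThresholdParams,
    BlobSet,
    DoGParams,
    ImageStack,
    MycelialMask,
    _disc_overlap_fraction,
    density_per_100um2,
    dog_blob_detect,
    dog_scale_space,
    filter_blobs_by_mask,
    max_z_projection,
    minmax_normalize_set,
    mycelial_mask,
    scale_space_maxima,
    transect_counts,
    welch_t_test,
)


def maxima_oracle(cube: np.ndarray, threshold: float) -> set:
    """Explicit triple loop over pixels and scales testing the strict
    local-maximum condition in the 3x3x3 neighborhood."""
    out = set()
    ny, nx, ns = cube.shape
    for y in range(ny):
        for x in range(nx):
            for s in range(ns):
                v = cube[y, x, s]
                if v <= threshold:
                    continue
                is_max = True
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        for ds in (-1, 0, 1):
                            if dy == dx == ds == 0:
                                continue
                            yy, xx, ss = y + dy, x + dx, s + ds
                            if 0 <= yy < ny and 0 <= xx < nx and 0 <= ss < ns:
                                if cube[yy, xx, ss] >= v:
                                    is_max = False
                if is_max:
                    out.add((y, x, s))
    return out


def make_stack(data, roles=None, px=0.1):
    roles = roles or {"sixteenS": 0, "eighteenS": 1}
    return ImageStack(np.asarray(data, float), roles, px)


# --------------------------------------------------------------------------
# projection & normalization

class TestProjection:
    def test_single_slice_identity(self):
        img = np.random.default_rng(0).random((1, 8, 8))
        stack = make_stack(np.stack([img, img]))
        assert np.array_equal(max_z_projection(stack, "sixteenS"), img[0])

    def test_elementwise_max_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.random((2, 4, 10, 12))
        stack = make_stack(data)
        proj = max_z_projection(stack, "eighteenS")
        for y in range(10):
            for x in range(12):
                assert proj[y, x] == max(data[1, z, y, x] for z in range(4))

    def test_unknown_role_rejected(self):
        stack = make_stack(np.zeros((2, 1, 4, 4)))
        with pytest.raises(InvalidInputError):
            max_z_projection(stack, "nuclei")


class TestMinMaxNormalize:
    def test_global_not_per_image_scaling(self):
        a, b = np.array([[0.0, 5.0]]), np.array([[5.0, 10.0]])
        na, nb = minmax_normalize_set([a, b])
        assert np.allclose(na, [[0.0, 0.5]])
        assert np.allclose(nb, [[0.5, 1.0]])

    def test_identity_on_normalized_input(self):
        a = np.array([[0.0, 0.3], [0.7, 1.0]])
        (out,) = minmax_normalize_set([a])
        assert np.allclose(out, a)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        imgs = [rng.random((6, 6)) for _ in range(3)]
        base = minmax_normalize_set(imgs)
        shifted = minmax_normalize_set([3.2 * im + 1.7 for im in imgs])
        for u, v in zip(base, shifted):
            assert np.allclose(u, v)

    def test_constant_set_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            (out,) = minmax_normalize_set([np.full((3, 3), 7.0)])
        assert np.all(out == 0)


# --------------------------------------------------------------------------
# masking

class TestMycelialMask:
    def test_zero_image_empty_mask(self):
        m = mycelial_mask(np.zeros((64, 64)), pixel_size_um=0.1)
        assert m.mask.sum() == 0 and m.area_um2 == 0

    def test_area_is_exact_pixel_count(self):
        img = np.zeros((100, 100))
        img[20:60, :] = 1.0
        m = mycelial_mask(img, pixel_size_um=0.2)
        assert m.area_um2 == pytest.approx(m.mask.sum() * 0.04)

    def test_tube_recovered_with_high_jaccard(self):
        spec = ef.ImageFixtureSpec(seed=3, noise_sigma=0.0, n_spots_outside=0)
        stack, truth = ef.generate_image(spec)
        img18 = minmax_normalize_set([max_z_projection(stack, "eighteenS")])[0]
        m = mycelial_mask(img18, pixel_size_um=spec.pixel_size_um)
        inter = (m.mask & truth.mask).sum()
        union = (m.mask | truth.mask).sum()
        assert inter / union >= 0.9
        # mask covers the tube interior (one pixel in from the soft edge)
        from scipy import ndimage as ndi

        interior = ndi.binary_erosion(truth.mask, iterations=2)
        assert (m.mask & interior).sum() / interior.sum() >= 0.99

    def test_isolated_bright_pixel_removed(self):
        img = np.zeros((128, 128))
        img[30:60, :] = 1.0  # band wide enough to survive
        img[100, 100] = 1.0
        m = mycelial_mask(img, AdaptiveThresholdParams(min_object_px=64))
        assert not m.mask[100, 100]
        assert m.mask[45, 64]

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            mycelial_mask(np.zeros((8, 8)), pixel_size_um=0.0)

    def test_even_block_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            AdaptiveThresholdParams(block_size=50)


# --------------------------------------------------------------------------
# blob detection

def plant_spots(shape, centers, sigma=2.0, amplitude=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for (y, x) in centers:
        img += amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


class TestDogBlobDetect:
    def test_blank_image_no_blobs(self):
        assert len(dog_blob_detect(np.zeros((64, 64)))) == 0

    def test_single_spot_recovered(self):
        img = plant_spots((64, 64), [(30.0, 33.0)], sigma=2.0)
        blobs = dog_blob_detect(img)
        assert len(blobs) == 1
        y, x, s, r = blobs.blobs[0]
        assert abs(y - 30) <= 1 and abs(x - 33) <= 1
        assert 2.0 / 1.5 <= s <= 2.0 * 1.5

    def test_twenty_five_spots_counted_exactly(self):
        rng = np.random.default_rng(4)
        centers = []
        while len(centers) < 25:
            c = rng.uniform(10, 180, 2)
            if all(np.hypot(*(c - q)) >= 12 for q in centers):
                centers.append(c)
        img = plant_spots((192, 192), centers, sigma=2.0)
        assert len(dog_blob_detect(img)) == 25

    def test_maxima_match_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        img = plant_spots((64, 64), [(20, 20), (45, 30)], sigma=2.0)
        img += 0.05 * rng.random((64, 64))
        params = DoGParams(sigma_min=1.0, sigma_max=3.0, n_scales=4,
                           response_threshold=0.02)
        cube, _ = dog_scale_space(img, params)
        assert cube.shape == (64, 64, 3)
        got = {tuple(m) for m in scale_space_maxima(cube, 0.02)}
        assert got == maxima_oracle(cube, 0.02)

    def test_retained_blobs_respect_overlap_bound(self):
        img = plant_spots((96, 96), [(40, 40), (40, 46), (70, 70)], sigma=2.5)
        blobs = dog_blob_detect(img).blobs
        p = DoGParams()
        for i in range(len(blobs)):
            for j in range(i + 1, len(blobs)):
                ri, rj = np.sqrt(2) * blobs[i, 2], np.sqrt(2) * blobs[j, 2]
                d = np.hypot(blobs[i, 0] - blobs[j, 0], blobs[i, 1] - blobs[j, 1])
                assert _disc_overlap_fraction(ri, rj, d) <= p.overlap

    def test_sigma_and_response_within_declared_bounds(self):
        img = plant_spots((64, 64), [(32, 32)], sigma=2.0)
        p = DoGParams()
        blobs = dog_blob_detect(img, p).blobs
        assert np.all(blobs[:, 2] >= p.sigma_min)
        assert np.all(blobs[:, 2] <= p.sigma_max)
        assert np.all(blobs[:, 3] >= p.response_threshold)

    def test_agrees_with_skimage_reference_on_clean_spots(self):
        """Independent reference detector finds the same count and close
        centers on well-separated clean spots."""
        from skimage.feature import blob_dog

        rng = np.random.default_rng(8)
        centers = []
        while len(centers) < 10:
            c = rng.uniform(12, 116, 2)
            if all(np.hypot(*(c - q)) >= 16 for q in centers):
                centers.append(c)
        img = plant_spots((128, 128), centers, sigma=2.0)
        ours = dog_blob_detect(img).blobs
        ref = blob_dog(img, min_sigma=1.0, max_sigma=4.0, threshold=0.1)
        assert len(ours) == len(ref) == 10
        for y, x, _ in ref:
            assert np.min(np.hypot(ours[:, 0] - y, ours[:, 1] - x)) <= 1.5


class TestFilterBlobsByMask:
    def _mask(self, shape, value):
        m = np.full(shape, value, dtype=bool)
        return MycelialMask(m, float(m.sum()), AdaptiveThresholdParams(), 1.0)

    def test_all_true_identity(self):
        blobs = BlobSet(np.array([[5.0, 5.0, 2.0, 1.0], [9.2, 3.8, 2.0, 0.5]]))
        out = filter_blobs_by_mask(blobs, self._mask((16, 16), True))
        assert np.array_equal(out.blobs, blobs.blobs)

    def test_all_false_empty(self):
        blobs = BlobSet(np.array([[5.0, 5.0, 2.0, 1.0]]))
        assert len(filter_blobs_by_mask(blobs, self._mask((16, 16), False))) == 0

    def test_rounded_center_rule(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 5] = True
        mask = MycelialMask(m, 1.0, AdaptiveThresholdParams(), 1.0)
        inside = BlobSet(np.array([[4.6, 5.4, 1.0, 1.0]]))  # rounds to (5, 5)
        outside = BlobSet(np.array([[4.4, 5.4, 1.0, 1.0]]))  # rounds to (4, 5)
        assert len(filter_blobs_by_mask(inside, mask)) == 1
        assert len(filter_blobs_by_mask(outside, mask)) == 0


# --------------------------------------------------------------------------
# density and transects

class TestDensity:
    def _mask_of_area(self, area_px, px=1.0):
        m = np.zeros((100, 100), dtype=bool)
        m.flat[:area_px] = True
        return MycelialMask(m, area_px * px**2, AdaptiveThresholdParams(), px)

    @pytest.mark.parametrize("n,area,expected", [(10, 100, 10.0), (10, 200, 5.0)])
    def test_linear_scaling(self, n, area, expected):
        blobs = BlobSet(np.tile([1.0, 1.0, 1.0, 1.0], (n, 1)))
        d = density_per_100um2(blobs, self._mask_of_area(area))
        assert d.density_per_100um2 == pytest.approx(expected)
        assert d.density_per_100um2 * d.area_um2 / 100 == pytest.approx(d.count)

    def test_zero_area_raises(self):
        with pytest.raises(UndefinedDensityError):
            density_per_100um2(BlobSet(np.empty((0, 4))), self._mask_of_area(0))

    def test_noise_free_fixture_recovers_planted_density(self, noisefree_image):
        spec, _, truth, result = noisefree_image
        planted = len(truth.centers_inside) / (
            truth.mask.sum() * spec.pixel_size_um**2 / 100
        )
        got = result.density.density_per_100um2
        assert got == pytest.approx(planted, rel=0.15)

    def test_density_invariant_under_consistent_resampling(self, noisefree_image):
        from skimage.transform import rescale

        spec, stack, truth, result = noisefree_image
        factor = 2.0
        up = np.stack(
            [
                rescale(stack.data[c, -1], factor, order=1)[None]
                for c in range(stack.data.shape[0])
            ]
        )
        up_stack = ImageStack(
            np.clip(up, 0, None),
            stack.channel_roles,
            stack.pixel_size_um / factor,
        )
        res_up = ef.quantify_stacks([up_stack])[0]
        assert res_up.density.density_per_100um2 == pytest.approx(
            result.density.density_per_100um2, rel=0.15
        )


class TestTransects:
    def test_single_roi_counts_all(self):
        blobs = BlobSet(np.array([[2.0, 3.0, 1.0, 1.0], [7.0, 9.0, 1.0, 1.0]]))
        assert transect_counts(blobs, [(0, 16, 0, 16)]) == [2]

    def test_empty_roi_zero(self):
        blobs = BlobSet(np.array([[2.0, 3.0, 1.0, 1.0]]))
        assert transect_counts(blobs, [(10, 16, 10, 16)]) == [0]

    def test_disjoint_cover_sums_to_total(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 31.4, size=(40, 2))  # rounds within the grid
        blobs = BlobSet(np.column_stack([pts, np.ones((40, 2))]))
        rois = [(0, 32, x, x + 8) for x in range(0, 32, 8)]
        assert sum(transect_counts(blobs, rois)) == 40

    def test_overlapping_rois_rejected(self):
        blobs = BlobSet(np.empty((0, 4)))
        with pytest.raises(InvalidInputError):
            transect_counts(blobs, [(0, 10, 0, 10), (5, 15, 5, 15)])


# --------------------------------------------------------------------------
# Welch's t-test

class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_stat == 0 and r.p_two_sided == pytest.approx(1.0)

    def test_closed_form_example(self):
        r = welch_t_test([1, 2, 3], [2, 4, 6])
        assert r.t_stat == pytest.approx(-1.5492, abs=1e-3)
        assert r.dof == pytest.approx(50 / 17, abs=1e-3)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.1], [2.0, 4.0, 6.6]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 20))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 20))
            mine = welch_t_test(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert mine.t_stat == pytest.approx(t_ref, abs=1e-9)
            assert mine.p_two_sided == pytest.approx(p_ref, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            welch_t_test([2.0, 2.0], [3.0, 3.0])


# --------------------------------------------------------------------------
# stack validation

class TestImageStack:
    def test_negative_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            make_stack(-np.ones((2, 1, 4, 4)))

    def test_bad_channel_index_rejected(self):
        with pytest.raises(InvalidInputError):
            ImageStack(np.zeros((1, 1, 4, 4)), {"sixteenS": 3}, 0.1)
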