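"""Otsu thresholding, morphology and the five-step lesion extraction."""

import numpy as np
import pytest

from ticcad import (
    DegenerateInputError,
    EmptySegmentationError,
    MaskImage,
    SegmentationConfig,
    StructuringElement,
    binary_dilate,
    binary_erode,
    largest_component_8,
    otsu_threshold,
    segment_lesion,
    subtraction_image,
)

from conftest import make_series


# ----- independent oracles -------------------------------------------------

def otsu_oracle(values, bins):
    """Exhaustive scan of every interior bin edge for max between-class variance."""
    values = np.asarray(values, float)
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_edge = -1.0, None
    for k in range(1, bins):
        c0, c1 = counts[:k], counts[k:]
        if c0.sum() == 0 or c1.sum() == 0:
            continue
        w0, w1 = c0.sum(), c1.sum()
        mu0 = (c0 * centers[:k]).sum() / w0
        mu1 = (c1 * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_var:
            best_var, best_edge = v, edges[k]
    return best_edge


def erode_oracle(mask, offsets):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in offsets
            )
    return out


def dilate_oracle(mask, offsets):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in offsets:
                    if 0 <= r + dr < h and 0 <= c + dc < w:
                        out[r + dr, c + dc] = True
    return out


SE4 = StructuringElement.square(4)


class TestSubtraction:
    def test_constant_offset(self):
        series = make_series([np.full((8, 8), 10.0)] * 3 + [np.full((8, 8), 25.0)])
        np.testing.assert_array_equal(subtraction_image(series), np.full((8, 8), 15.0))

    def test_phase_equal_to_baseline_gives_zero(self):
        series = make_series([np.full((8, 8), 7.0)] * 4)
        assert not subtraction_image(series).any()

    def test_negative_values_preserved(self):
        frames = [np.full((8, 8), 30.0)] + [np.full((8, 8), 20.0)] * 3
        series = make_series(frames)
        assert (subtraction_image(series) == -10.0).all()

    def test_index_out_of_range(self):
        series = make_series([np.full((8, 8), 1.0)] * 4)
        from ticcad import FormatError

        with pytest.raises(FormatError):
            subtraction_image(series, SegmentationConfig(post_phase_index=4))


class TestOtsu:
    def test_perfect_bimodal(self):
        values = np.r_[np.full(50, 10.0), np.full(50, 200.0)]
        t = otsu_threshold(values)
        assert 10 <= t < 200
        assert (values > t).sum() == 50  # the bright class is foreground

    def test_matches_exhaustive_oracle_on_gaussian_clusters(self):
        rng = np.random.default_rng(7)
        values = np.r_[rng.normal(30, 5, 500), rng.normal(180, 10, 500)]
        assert otsu_threshold(values, bins=256) == pytest.approx(
            otsu_oracle(values, 256)
        )

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(10, 3.0))

    def test_se4_offsets(self):
        assert set(SE4.offsets) == {(dr, dc) for dr in (-1, 0, 1, 2) for dc in (-1, 0, 1, 2)}


class TestMorphology:
    def test_erosion_of_corner_block(self):
        """A 5×5 block at rows/cols 0–4 erodes to the 2×2 core at {1,2}."""
        m = np.zeros((12, 12), bool)
        m[0:5, 0:5] = True
        out = binary_erode(MaskImage(m), SE4)
        expected = np.zeros((12, 12), bool)
        expected[1:3, 1:3] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_dilation_restores_opened_block(self):
        core = np.zeros((12, 12), bool)
        core[1:3, 1:3] = True
        out = binary_dilate(MaskImage(core), SE4)
        expected = np.zeros((12, 12), bool)
        expected[0:5, 0:5] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_dilation_of_single_pixel(self):
        m = np.zeros((12, 12), bool)
        m[5, 5] = True
        out = binary_dilate(MaskImage(m), SE4)
        expected = np.zeros((12, 12), bool)
        expected[4:8, 4:8] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_and_isolated_pixel(self):
        empty = MaskImage(np.zeros((8, 8), bool))
        assert not binary_erode(empty, SE4).data.any()
        assert not binary_dilate(empty, SE4).data.any()
        speck = np.zeros((8, 8), bool)
        speck[4, 4] = True
        assert not binary_erode(MaskImage(speck), SE4).data.any()

    def test_matches_set_definition_on_random_masks(self, rng):
        offs = SE4.offsets
        for _ in range(20):
            m = rng.uniform(size=(16, 16)) > 0.5
            np.testing.assert_array_equal(
                binary_erode(MaskImage(m), SE4).data, erode_oracle(m, offs)
            )
            np.testing.assert_array_equal(
                binary_dilate(MaskImage(m), SE4).data, dilate_oracle(m, offs)
            )

    def test_opening_contract(self, rng):
        """dilate(erode(X)) ⊆ X and applying the opening twice is a no-op."""
        for _ in range(20):
            m = MaskImage(rng.uniform(size=(24, 24)) > 0.4)
            opened = binary_dilate(binary_erode(m, SE4), SE4)
            assert not (opened.data & ~m.data).any()
            twice = binary_dilate(binary_erode(opened, SE4), SE4)
            np.testing.assert_array_equal(twice.data, opened.data)


class TestLargestComponent:
    def test_larger_component_wins(self):
        m = np.zeros((10, 10), bool)
        m[0:3, 0:3] = True  # size 9
        m[6:8, 6:8] = True  # size 4
        out = largest_component_8(MaskImage(m))
        assert out.data[0:3, 0:3].all() and not out.data[6:8, 6:8].any()

    def test_tie_broken_by_topmost_left_pixel(self):
        m = np.zeros((10, 10), bool)
        m[0:2, 0:2] = True
        m[5:7, 5:7] = True
        out = largest_component_8(MaskImage(m))
        assert out.data[0, 0] and not out.data[5, 5]

    def test_diagonal_chain_is_one_component(self):
        m = np.zeros((8, 8), bool)
        for i in range(6):
            m[i, i] = True
        out = largest_component_8(MaskImage(m))
        assert out.n_pixels == 6

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            largest_component_8(MaskImage(np.zeros((8, 8), bool)))


class TestSegmentLesion:
    @staticmethod
    def _series_with_block(block_slice, speck=None, shape=(12, 12)):
        """Enhancing block (subtraction 200) on background 10, 4 phases."""
        pre = np.full(shape, 100.0)
        post = pre + 10.0
        post[block_slice] = pre[block_slice] + 200.0
        if speck is not None:
            post[speck] = pre[speck] + 200.0
        return make_series([pre, pre + 1.0, pre + 2.0, post])

    def test_block_recovered_and_speck_removed(self):
        series = self._series_with_block((slice(3, 8), slice(3, 8)), speck=(10, 10))
        roi = MaskImage(np.ones((12, 12), bool), kind="roi")
        lesion = segment_lesion(series, roi)
        expected = np.zeros((12, 12), bool)
        expected[3:8, 3:8] = True
        np.testing.assert_array_equal(lesion.data, expected)

    def test_uniform_roi_rejected(self):
        series = make_series([np.full((12, 12), v) for v in (10.0, 20.0, 30.0, 40.0)])
        roi = MaskImage(np.ones((12, 12), bool), kind="roi")
        with pytest.raises(DegenerateInputError):
            segment_lesion(series, roi)

    def test_block_smaller_than_element_yields_empty_segmentation(self):
        series = self._series_with_block((slice(4, 7), slice(4, 7)))
        roi = MaskImage(np.ones((12, 12), bool), kind="roi")
        with pytest.raises(EmptySegmentationError, match="enlarge ROI"):
            segment_lesion(series, roi)

    def test_output_is_subset_of_roi_and_connected(self, rng):
        from scipy import ndimage

        series = self._series_with_block((slice(2, 9), slice(3, 9)))
        series.data[3] += rng.normal(0, 2.0, size=(12, 12))
        roi = np.zeros((12, 12), bool)
        roi[1:11, 1:11] = True
        lesion = segment_lesion(series, MaskImage(roi, kind="roi"))
        assert not (lesion.data & ~roi).any()
        _, n = ndimage.label(lesion.data, structure=np.ones((3, 3)))
        assert n == 1
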