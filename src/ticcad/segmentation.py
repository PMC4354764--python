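"""Five-step semi-automatic lesion segmentation.

The lesion is extracted from the subtraction image (a post-contrast phase
minus the pre-contrast phase) inside a user ROI:

1. threshold the ROI pixels of the subtraction image with Otsu's method
   (foreground = above threshold, since lesions enhance);
2. erode the binary image with a 4×4 all-ones structuring element;
3. keep the largest 8-connected component;
4. dilate it with the same element (completing a morphological opening);
5. clip back to the ROI.

The even-sized default element has no central pixel; its origin is fixed at
grid position (1, 1), i.e. offsets {-1, 0, 1, 2}², and dilation uses the
same offset set as a Minkowski sum so that dilate(erode(X)) is a true
algebraic opening of X.  Pixels whose translated element leaves the image
are treated as background during erosion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, EmptySegmentationError, FormatError
from .io import DceSeries, MaskImage

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass(frozen=True)
class StructuringElement:
    """A set of (drow, dcol) offsets defining erosion/dilation neighborhoods."""

    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.offsets:
            raise FormatError("structuring element must be non-empty")

    @classmethod
    def square(cls, size: int = 4) -> "StructuringElement":
        """All-ones size×size element with origin at grid position
        ((size-1)//2, (size-1)//2); for size 4 the offsets are {-1..2}²."""
        if size < 1:
            raise FormatError("structuring element size must be >= 1")
        lo = -((size - 1) // 2)
        offs = tuple(
            (dr, dc)
            for dr in range(lo, lo + size)
            for dc in range(lo, lo + size)
        )
        return cls(offsets=offs)


@dataclass
class SegmentationConfig:
    """Tunables of the segmentation pipeline.

    ``post_phase_index`` selects which post-contrast phase is subtracted
    from baseline (default the third, the phase conventionally used to
    visualize lesion margins); ``se_size`` the square structuring element
    side; ``histogram_bins`` the Otsu discretization.
    """

    post_phase_index: int = 3
    se_size: int = 4
    histogram_bins: int = 256


def subtraction_image(series: DceSeries, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Signed difference ``data[post_phase_index] - data[0]``, no clamping."""
    cfg = cfg or SegmentationConfig()
    idx = cfg.post_phase_index
    if not 1 <= idx <= series.n_phases - 1:
        raise FormatError(
            f"post_phase_index {idx} out of range 1..{series.n_phases - 1}"
        )
    return series.data[idx] - series.data[0]


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold on a 1-D sample.

    The sample is histogrammed into ``bins`` equal-width bins over its
    observed range; the returned threshold is the interior bin edge that
    maximizes the between-class variance of the classes {<= t} and {> t},
    with class statistics taken at bin centers.  Ties go to the smallest
    edge.  Because bin centers are an affine function of the bin index, the
    maximizer is found with exact integer arithmetic over indices, so the
    result is free of floating-point tie ambiguity:
    :math:`\\sigma_b^2 \\propto (S_0 w_1 - S_1 w_0)^2 / (w_0 w_1)` with
    integer class weights :math:`w` and index sums :math:`S`.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateInputError("Otsu needs at least two distinct values")
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    counts = [int(c) for c in counts]
    total = sum(counts)
    total_s = sum(k * c for k, c in enumerate(counts))
    best_num, best_den = -1, 1  # compare fractions by cross-multiplication
    best_edge = edges[1]
    w0 = s0 = 0
    for k in range(bins - 1):
        w0 += counts[k]
        s0 += k * counts[k]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (total_s - s0) * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:
            best_num, best_den = num, den
            best_edge = edges[k + 1]
    return float(best_edge)


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """out[p] = mask[p + (dr, dc)] with background (False) padding."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    rs_src = slice(max(dr, 0), h + min(dr, 0))
    cs_src = slice(max(dc, 0), w + min(dc, 0))
    rs_dst = slice(max(-dr, 0), h + min(-dr, 0))
    cs_dst = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def binary_erode(mask: MaskImage, se: StructuringElement) -> MaskImage:
    """Erosion: p is kept iff every p+o is inside the image and set."""
    out = np.ones_like(mask.data)
    for dr, dc in se.offsets:
        out &= _shift(mask.data, dr, dc)
    return MaskImage(out, kind=mask.kind)


def binary_dilate(mask: MaskImage, se: StructuringElement) -> MaskImage:
    """Dilation as the Minkowski sum with the same offsets (clipped to bounds)."""
    out = np.zeros_like(mask.data)
    for dr, dc in se.offsets:
        out |= _shift(mask.data, -dr, -dc)  # place mask[q] at q + o
    return MaskImage(out, kind=mask.kind)


def largest_component_8(mask: MaskImage) -> MaskImage:
    """Largest 8-connected component; size ties go to the component whose
    first pixel in row-major order comes earliest."""
    if not mask.data.any():
        raise EmptySegmentationError("mask is empty; no components to label")
    labels, n = ndimage.label(mask.data, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    max_size = sizes.max()
    candidates = np.flatnonzero(sizes == max_size)
    if len(candidates) > 1:
        flat = labels.ravel()
        first = {lab: int(np.argmax(flat == lab)) for lab in candidates}
        winner = min(candidates, key=lambda lab: first[lab])
    else:
        winner = candidates[0]
    return MaskImage(labels == winner, kind=mask.kind)


def segment_lesion(
    series: DceSeries,
    roi: MaskImage,
    cfg: SegmentationConfig | None = None,
) -> MaskImage:
    """Run the full five-step pipeline; returns a lesion mask within the ROI."""
    cfg = cfg or SegmentationConfig()
    if roi.data.shape != series.shape:
        raise FormatError("ROI shape does not match series")
    if not roi.data.any():
        raise EmptySegmentationError("ROI mask is empty")
    sub = subtraction_image(series, cfg)
    roi_values = sub[roi.data]
    if np.min(roi_values) == np.max(roi_values):
        raise DegenerateInputError("ROI intensities are constant; cannot threshold")
    t = otsu_threshold(roi_values, bins=cfg.histogram_bins)
    fg = MaskImage((sub > t) & roi.data, kind="lesion")
    logger.info("segmentation: threshold=%.4g, foreground=%d px", t, fg.n_pixels)
    se = StructuringElement.square(cfg.se_size)
    eroded = binary_erode(fg, se)
    logger.info("segmentation: after erosion %d px", eroded.n_pixels)
    if not eroded.data.any():
        raise EmptySegmentationError(
            "foreground empty after erosion; enlarge ROI or reduce SE size"
        )
    core = largest_component_8(eroded)
    logger.info("segmentation: largest component %d px", core.n_pixels)
    dilated = binary_dilate(core, se)
    final = MaskImage(dilated.data & roi.data, kind="lesion")
    logger.info("segmentation: final lesion %d px", final.n_pixels)
    return final
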