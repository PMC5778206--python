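"""Slice and fat-particle segmentation.

The processing chain mirrors the acquisition geometry: a bright, roughly
circular salami slice photographed on a near-black backdrop, with whitish
fat particles embedded in a reddish meat matrix.  The chain is

    RGB -> 256-level grayscale -> percentile contrast stretch ->
    median filter -> slice extraction -> fat thresholding inside the
    slice -> morphological closing (square structuring element) ->
    small-object removal -> connected-component labelling.

Everything is deterministic for a fixed :class:`~salamivision.io.PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as morph_closing

from .io import CalibratedImage, PipelineConfig

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for the RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class SliceNotFoundError(RuntimeError):
    """Raised when no slice foreground can be separated from the backdrop."""


@dataclass(frozen=True)
class SliceMask:
    """Binary mask of the salami slice (single filled component)."""

    mask: np.ndarray  # bool raster, True = slice
    area_pixels: int
    area_cm2: float  # A_s

    def __post_init__(self) -> None:
        if int(self.mask.sum()) != self.area_pixels:
            raise ValueError("area_pixels inconsistent with mask")


@dataclass(frozen=True)
class FatMask:
    """Labelled fat particles inside a slice.

    ``labels`` is 0 on background and ``k`` on particle ``k`` (1-based,
    8-connected components); ``mask`` is ``labels > 0``.
    """

    mask: np.ndarray
    labels: np.ndarray
    n_particles: int


def to_grayscale(image: CalibratedImage) -> np.ndarray:
    """Convert RGB to a 256-level gray raster with BT.601 luma weights.

    gray = round(0.299 R + 0.587 G + 0.114 B), clamped to [0, 255].
    """
    px = image.pixels.astype(np.float64)
    gray = px[..., 0] * LUMA_WEIGHTS[0] + px[..., 1] * LUMA_WEIGHTS[1] + px[..., 2] * LUMA_WEIGHTS[2]
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def enhance_contrast(gray: np.ndarray, percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Linear percentile stretch: lower percentile -> 0, upper -> 255.

    Values outside the percentile window are clipped.  A degenerate
    (constant) raster is returned unchanged with a logged notice.
    """
    lo_p, hi_p = percentiles
    lo, hi = np.percentile(gray, [lo_p, hi_p])
    if hi <= lo:
        logger.info("contrast stretch skipped: degenerate histogram (p%g == p%g == %g)", lo_p, hi_p, lo)
        return gray.copy()
    stretched = (gray.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.round(stretched), 0, 255).astype(np.uint8)


def smooth(gray: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter with a square window; ``window=1`` is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be an odd integer >= 1, got {window}")
    if window == 1:
        return gray.copy()
    return ndimage.median_filter(gray, size=window, mode="nearest")


def _backdrop_threshold(gray: np.ndarray) -> float:
    # The histogram is typically trimodal (backdrop / meat / fat); a
    # two-class split can land between meat and fat, so use the lower
    # threshold of a three-class split and fall back to two classes when
    # the histogram is too coarse.
    try:
        return float(threshold_multiotsu(gray, classes=3)[0])
    except ValueError:
        try:
            return float(threshold_otsu(gray))
        except ValueError as exc:  # constant image
            raise SliceNotFoundError("no slice found: constant image") from exc


def extract_slice_mask(gray: np.ndarray, image: CalibratedImage) -> SliceMask:
    """Separate the slice from the dark backdrop.

    Thresholds the gray raster, keeps the largest connected component
    and fills its holes (fat particles and any dark voids belong to the
    slice area A_s).
    """
    thr = _backdrop_threshold(gray)
    fg = gray > thr
    if not fg.any():
        raise SliceNotFoundError("no slice found: empty foreground after thresholding")
    labels = cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = ndimage.binary_fill_holes(labels == sizes.argmax())
    area_px = int(mask.sum())
    return SliceMask(mask=mask, area_pixels=area_px, area_cm2=area_px * image.pixel_area_cm2())


def segment_fat(gray: np.ndarray, slice_mask: SliceMask, config: PipelineConfig) -> FatMask:
    """Threshold fat inside the slice and label the particles.

    The threshold is chosen over slice-interior pixels only, by the
    between-class-variance (Otsu) criterion, or taken from
    ``config.fixed_threshold``.  The binary fat mask is then closed with
    a square structuring element of side ``2*closing_radius + 1``
    (dilation followed by erosion, closing the matrix outlines), holes
    are optionally filled, components below ``min_particle_area_px`` are
    dropped, and the rest are labelled 1..n with 8-connectivity.

    Zero detected particles is a valid outcome.
    """
    if not slice_mask.mask.any():
        raise ValueError("slice mask is empty")
    inside = gray[slice_mask.mask]
    if config.threshold_mode == "fixed":
        # user-supplied level: pixels at or above it count as fat
        fat = (gray >= config.fixed_threshold) & slice_mask.mask
    else:
        try:
            thr = float(threshold_otsu(inside))
        except ValueError:  # uniform slice interior -> nothing brighter
            return _empty_fat_mask(gray.shape)
        if not _bimodal_enough(inside, thr, config.bimodality_min_d):
            # the between-class split of a fat-free (unimodal) interior
            # would just halve the noise; declare zero particles instead
            logger.info("fat threshold rejected: slice interior not bimodal")
            return _empty_fat_mask(gray.shape)
        # Otsu convention: the upper class is strictly above the threshold
        # (on a discrete histogram the threshold can equal the matrix mode)
        fat = (gray > thr) & slice_mask.mask
    if config.closing_radius > 0:
        side = 2 * config.closing_radius + 1
        fat = morph_closing(fat, footprint=np.ones((side, side), bool))
        fat &= slice_mask.mask  # closing must not leak past the slice
    if config.fill_holes:
        fat = ndimage.binary_fill_holes(fat) & slice_mask.mask
    labels = cc_label(fat, connectivity=2)
    if config.min_particle_area_px > 0 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= config.min_particle_area_px
        keep[0] = False
        fat = keep[labels]
        labels = cc_label(fat, connectivity=2)
    return FatMask(mask=labels > 0, labels=labels, n_particles=int(labels.max()))


def _bimodal_enough(values: np.ndarray, thr: float, min_d: float) -> bool:
    """Ashman's D separation of the two classes induced by ``thr``."""
    lo = values[values <= thr].astype(np.float64)
    hi = values[values > thr].astype(np.float64)
    if lo.size == 0 or hi.size == 0:
        return False
    denom = np.sqrt(lo.var() + hi.var())
    if denom == 0:  # two delta peaks: perfectly separated
        return True
    return np.sqrt(2.0) * (hi.mean() - lo.mean()) / denom >= min_d


def _empty_fat_mask(shape: tuple[int, int]) -> FatMask:
    z = np.zeros(shape, dtype=np.int32)
    return FatMask(mask=z > 0, labels=z, n_particles=0)
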