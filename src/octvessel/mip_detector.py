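"""Morphological lumen detector (Gaussian blur → adaptive threshold →
erode/open → component size filter → ROI mask).

Lumens are low-signal pores inside bright speckled tissue, so each frame
is blurred, binarized against its local mean (an adaptive threshold with a
subtractive offset), and inverted so lumens become foreground.  Erosion
and opening with small discs strip speckle-induced debris, per-frame
connected components outside an area band are dropped, and everything is
intersected with a region-of-interest mask that removes the bright
culture-insert edge and the central surface depression.  The one free
parameter that matters — the threshold offset — is calibrated against a
reference ground truth by maximizing mean per-frame Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .evaluation import confusion_counts, cohen_kappa
from .stack_io import BinaryStack, IntensityStack

__all__ = [
    "MipParams",
    "MaskStack",
    "build_roi_mask",
    "segment_mip",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class MipParams:
    """Tunables of the morphological chain.

    ``adaptive_offset`` is on the [0, 1] intensity scale: a pixel is lumen
    candidate when it falls at least this far below its local mean.
    """

    gaussian_sigma_px: float = 1.0
    adaptive_block_px: int = 51
    adaptive_offset: float = 0.05
    erosion_radius_px: int = 2
    opening_radius_px: int = 2
    min_area_px: int = 10
    max_area_px: int = 5000
    roi_radius_px: int = 250

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be >= 0")
        if self.adaptive_block_px < 3 or self.adaptive_block_px % 2 == 0:
            raise ValueError("adaptive_block_px must be an odd integer >= 3")
        if self.erosion_radius_px < 0 or self.opening_radius_px < 0:
            raise ValueError("structuring-element radii must be >= 0")
        if not 0 <= self.min_area_px < self.max_area_px:
            raise ValueError("area bounds must satisfy 0 <= min < max")
        if self.roi_radius_px <= 0:
            raise ValueError("roi_radius_px must be positive")


@dataclass
class MaskStack:
    """Per-frame analyzable-region masks (1 = evaluate this pixel)."""

    frames: np.ndarray  # (n_frames, h, w) bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# intensity below which a blurred frame is considered empty of tissue
_TISSUE_FLOOR = 0.05


def _roi_blur_sigma(shape) -> float:
    # ~1% of the frame diameter: coarse enough to wash out lumens and
    # speckle at full acquisition size without swallowing them on small
    # test frames
    return max(2.0, 0.01 * max(shape))


# enclosed dark holes smaller than this fraction of the frame are filled
# back into the tissue mask (lumens must stay analyzable); the central
# surface depression is far larger and stays excluded
_FILL_HOLE_FRAC = 0.05


def _tissue_mask(frame: np.ndarray) -> np.ndarray:
    """Tissue-presence heuristic for one frame: threshold the blurred frame
    globally (Otsu), fill lumen-sized enclosed holes and keep the largest
    connected region."""
    blurred = ndimage.gaussian_filter(frame, _roi_blur_sigma(frame.shape))
    lo, hi = blurred.min(), blurred.max()
    if hi - lo < 1e-6:  # constant frame: all tissue or no tissue
        return np.full(frame.shape, hi >= _TISSUE_FLOOR)
    thresh = max(filters.threshold_otsu(blurred), _TISSUE_FLOOR)
    tissue = blurred > thresh
    if tissue.mean() < 0.5:
        # Otsu latched onto a small bright structure (the insert-edge ring
        # on frames of uniform tissue); fall back to a median-relative cut
        thresh = max(0.5 * float(np.median(blurred)), _TISSUE_FLOOR)
        tissue = blurred > thresh
    if not tissue.any():
        return tissue
    tissue = morphology.remove_small_holes(
        tissue, max_size=int(_FILL_HOLE_FRAC * frame.size)
    )
    labels, n = ndimage.label(tissue)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        tissue = labels == (1 + int(np.argmax(sizes)))
    return tissue


def _centered_disc(shape: tuple[int, int], radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius**2


def build_roi_mask(stack: IntensityStack, roi_radius_px: int = 250) -> MaskStack:
    """Per-frame region-of-interest mask: the centered disc that excludes
    the bright insert edge, intersected with a tissue-presence mask that
    drops the central vacancy of the surface frames."""
    h, w = stack.frame_shape
    max_r = 0.5 * float(np.hypot(h, w))
    if roi_radius_px > max_r:
        import warnings

        warnings.warn(
            f"roi_radius_px={roi_radius_px} exceeds half the frame diagonal; clipping",
            stacklevel=2,
        )
        roi_radius_px = int(max_r)
    disc = _centered_disc((h, w), roi_radius_px)
    frames = np.stack([disc & _tissue_mask(f) for f in stack.data])
    return MaskStack(frames=frames)


def _disc_selem(radius: int) -> np.ndarray:
    return morphology.disk(radius)


def _filter_area(frame: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    """Drop 8-connected 2D components with area outside [min_area, max_area]."""
    labels, n = ndimage.label(frame, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return frame
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = (areas >= min_area) & (areas <= max_area)
    lut = np.concatenate([[False], keep])
    return lut[labels]


def segment_mip(
    stack: IntensityStack,
    params: MipParams = MipParams(),
    roi: MaskStack | None = None,
) -> BinaryStack:
    """Run the morphological chain on every frame; output 1 = lumen.

    The ROI mask is rebuilt from the stack unless one is supplied (useful
    when calibrating many offsets on the same stack).
    """
    if roi is None:
        roi = build_roi_mask(stack, params.roi_radius_px)
    out = np.empty(stack.data.shape, dtype=bool)
    erode = _disc_selem(params.erosion_radius_px) if params.erosion_radius_px else None
    openr = _disc_selem(params.opening_radius_px) if params.opening_radius_px else None
    for i, frame in enumerate(stack.data):
        blurred = (
            ndimage.gaussian_filter(frame, params.gaussian_sigma_px)
            if params.gaussian_sigma_px > 0
            else frame
        )
        local_mean = filters.threshold_local(
            blurred, block_size=params.adaptive_block_px, method="mean"
        )
        # invert: lumens are darker than their neighbourhood by >= offset
        binary = blurred <= local_mean - params.adaptive_offset
        if erode is not None:
            binary = morphology.erosion(binary, erode)
        if openr is not None:
            binary = morphology.opening(binary, openr)
        binary = _filter_area(binary, params.min_area_px, params.max_area_px)
        out[i] = binary & roi[i]
    return BinaryStack(
        data=out,
        pixel_pitch_um=stack.pixel_pitch_um,
        frame_spacing_um=stack.frame_spacing_um,
    )


def calibrate_threshold(
    stack: IntensityStack,
    truth: BinaryStack,
    offset_grid: "np.ndarray | list[float]",
    params: MipParams = MipParams(),
) -> tuple[MipParams, float]:
    """Pick the adaptive-threshold offset maximizing mean per-frame kappa
    against reference ground truth.

    Ties (within 1e-12) are broken toward the smaller absolute offset, then
    grid order.  Returns the winning parameter set and its mean kappa.
    """
    if stack.data.shape != truth.data.shape:
        raise ValueError(
            f"stack/truth geometry mismatch: {stack.data.shape} vs {truth.data.shape}"
        )
    offsets = list(offset_grid)
    if not offsets:
        raise ValueError("offset grid is empty")
    roi = build_roi_mask(stack, params.roi_radius_px)
    best: tuple[float, float, int] | None = None  # (-kappa, |offset|, index)
    best_offset, best_kappa = offsets[0], -np.inf
    for idx, off in enumerate(offsets):
        pred = segment_mip(stack, replace(params, adaptive_offset=off), roi=roi)
        kappas = [
            cohen_kappa(confusion_counts(pred.data[i], truth.data[i]))
            for i in range(pred.n_frames)
        ]
        mean_kappa = float(np.mean(kappas))
        key = (-round(mean_kappa / 1e-12) * 1e-12, abs(off), idx)
        if best is None or key < best:
            best = key
            best_offset, best_kappa = off, mean_kappa
    return replace(params, adaptive_offset=best_offset), best_kappa
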