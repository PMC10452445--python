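"""Image-stack containers, geometry conversion and contrast preprocessing.

OCT acquires the blood-brain-barrier construct as a *y*-stack of x-z
cross-sections (B-scans).  All downstream analysis works on the converted
geometry: a *z*-stack of x-y frames in which frame 0 is the bottom surface
of the fibrin gel (the side seeded with the endothelial monolayer, nearest
the OCT probe).  Voxels are never interpolated: conversion is a pure axis
transpose, depth truncation drops whole frames, and histogram equalization
is a per-frame intensity remap.

Intensities are held internally as floats in [0, 1]; the source bit depth
is remembered so that TIFF round-trips are voxel exact.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "AxisOrder",
    "StackGeometry",
    "IntensityStack",
    "BinaryStack",
    "read_stack",
    "read_mask",
    "write_stack",
    "convert_axes",
    "convert_to_acquisition",
    "truncate_depth",
    "equalize_histogram",
]

#: Default lateral sampling of the OCT system, µm per pixel.
DEFAULT_PIXEL_PITCH_UM = 10.0
#: Default frame-to-frame spacing, µm.
DEFAULT_FRAME_SPACING_UM = 10.0


class AxisOrder(str, enum.Enum):
    """Stack geometry tag.

    ``XZ_YSTACK``: as acquired — each frame is an x-z cross-section, frames
    stacked along y.  ``XY_ZSTACK``: converted — each frame is an x-y plane,
    frames stacked along depth z, frame 0 at the gel bottom.
    """

    XZ_YSTACK = "xz_ystack"
    XY_ZSTACK = "xy_zstack"


@dataclass(frozen=True)
class StackGeometry:
    """Pixel dimensions and physical calibration of a stack."""

    width_px: int
    height_px: int
    n_frames: int
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_spacing_um: float = DEFAULT_FRAME_SPACING_UM

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.pixel_pitch_um <= 0 or self.frame_spacing_um <= 0:
            raise ValueError("physical calibration must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """(width, height, depth) physical extents in µm."""
        return (
            self.width_px * self.pixel_pitch_um,
            self.height_px * self.pixel_pitch_um,
            self.n_frames * self.frame_spacing_um,
        )


def _check_frames(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"stack data must be 3D (frames, rows, cols), got shape {data.shape}")
    if data.shape[0] == 0 or data.shape[1] == 0 or data.shape[2] == 0:
        raise ValueError("stack must be non-empty")


@dataclass
class IntensityStack:
    """Ordered 3D grayscale volume with axis-order tag and calibration.

    ``data`` is ``(n_frames, rows, cols)`` float in [0, 1].  ``source_dtype``
    records the integer type the stack was loaded from (or should be saved
    as); it controls quantization on write so that read/write round-trips
    are exact.
    """

    data: np.ndarray
    axis_order: AxisOrder = AxisOrder.XY_ZSTACK
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_spacing_um: float = DEFAULT_FRAME_SPACING_UM
    source_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint8))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_frames(self.data)
        if self.pixel_pitch_um <= 0 or self.frame_spacing_um <= 0:
            raise ValueError("physical calibration must be positive")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("intensity data must lie in [0, 1]")
        self.axis_order = AxisOrder(self.axis_order)
        self.source_dtype = np.dtype(self.source_dtype)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def geometry(self) -> StackGeometry:
        return StackGeometry(
            width_px=self.data.shape[2],
            height_px=self.data.shape[1],
            n_frames=self.data.shape[0],
            pixel_pitch_um=self.pixel_pitch_um,
            frame_spacing_um=self.frame_spacing_um,
        )

    def frame_depth_um(self, index: int) -> float:
        """Depth of a frame below the gel bottom (XY_ZSTACK stacks)."""
        return index * self.frame_spacing_um


@dataclass
class BinaryStack:
    """Lumen/background labelling with the geometry of its source stack."""

    data: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_spacing_um: float = DEFAULT_FRAME_SPACING_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_frames(self.data)
        if self.pixel_pitch_um <= 0 or self.frame_spacing_um <= 0:
            raise ValueError("physical calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def geometry(self) -> StackGeometry:
        return StackGeometry(
            width_px=self.data.shape[2],
            height_px=self.data.shape[1],
            n_frames=self.data.shape[0],
            pixel_pitch_um=self.pixel_pitch_um,
            frame_spacing_um=self.frame_spacing_um,
        )


# ---------------------------------------------------------------------------
# reading / writing


_INT_SCALE = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def _frames_to_float(raw: np.ndarray) -> tuple[np.ndarray, np.dtype]:
    if raw.ndim == 4:
        raise ValueError("unsupported bit depth: color frames are not grayscale stacks")
    dtype = raw.dtype
    if dtype in _INT_SCALE:
        return raw.astype(np.float64) / _INT_SCALE[dtype], dtype
    if np.issubdtype(dtype, np.floating):
        data = raw.astype(np.float64)
        if data.min() < 0 or data.max() > 1:
            raise ValueError("floating-point stacks must be scaled to [0, 1]")
        return data, np.dtype(np.float32)
    raise ValueError(f"unsupported bit depth: {dtype}")


_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


def read_stack(
    path: str | Path,
    pixel_pitch_um: float | None = None,
    frame_spacing_um: float | None = None,
    axis_order: AxisOrder = AxisOrder.XY_ZSTACK,
) -> IntensityStack:
    """Read a multi-page TIFF, or a directory of single-frame images in
    lexicographic order, into an :class:`IntensityStack`.

    Calibration metadata embedded by :func:`write_stack` is honoured;
    explicit ``pixel_pitch_um`` / ``frame_spacing_um`` arguments override
    it, and the 10 µm / 10 µm system defaults apply when neither is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")

    meta: dict = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise ValueError(f"no frame images found in directory {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames of unequal size: {sorted(shapes)}")
        raw = np.stack(frames)
    else:
        with tifffile.TiffFile(path) as tif:
            raw = tif.asarray()
            desc = tif.pages[0].description
        if raw.ndim == 2:
            raw = raw[None]
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}

    data, src_dtype = _frames_to_float(raw)
    pitch = pixel_pitch_um or meta.get("pixel_pitch_um") or DEFAULT_PIXEL_PITCH_UM
    spacing = frame_spacing_um or meta.get("frame_spacing_um") or DEFAULT_FRAME_SPACING_UM
    if "axis_order" in meta:
        axis_order = AxisOrder(meta["axis_order"])
    return IntensityStack(
        data=data,
        axis_order=axis_order,
        pixel_pitch_um=float(pitch),
        frame_spacing_um=float(spacing),
        source_dtype=src_dtype,
    )


def read_mask(
    path: str | Path,
    pixel_pitch_um: float | None = None,
    frame_spacing_um: float | None = None,
) -> BinaryStack:
    """Read a binary mask stack; any nonzero voxel is foreground."""
    stack = read_stack(path, pixel_pitch_um, frame_spacing_um)
    return BinaryStack(
        data=stack.data > 0,
        pixel_pitch_um=stack.pixel_pitch_um,
        frame_spacing_um=stack.frame_spacing_um,
    )


def write_stack(stack: IntensityStack | BinaryStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF.

    Binary stacks are written as 8-bit {0, 255} for viewer compatibility.
    Intensity stacks are quantized back to their source dtype, so
    ``read_stack(write_stack(s))`` reproduces voxel values exactly for
    integer sources.  Calibration is embedded as a JSON description tag.
    """
    path = Path(path)
    meta = {
        "pixel_pitch_um": stack.pixel_pitch_um,
        "frame_spacing_um": stack.frame_spacing_um,
    }
    if isinstance(stack, BinaryStack):
        raw = np.where(stack.data, 255, 0).astype(np.uint8)
    else:
        meta["axis_order"] = stack.axis_order.value
        if stack.source_dtype in _INT_SCALE:
            raw = np.rint(stack.data * _INT_SCALE[stack.source_dtype]).astype(stack.source_dtype)
        else:
            raw = stack.data.astype(np.float32)
    tifffile.imwrite(path, raw, photometric="minisblack", description=json.dumps(meta))


# ---------------------------------------------------------------------------
# geometry


def convert_axes(stack: IntensityStack) -> IntensityStack:
    """Convert the acquisition y-stack of x-z cross-sections into the
    analysis z-stack of x-y frames.

    A cross-section frame ``y`` is an array indexed ``[z, x]`` with row 0 at
    the gel bottom; the converted frame ``z`` is indexed ``[y, x]``.  The
    operation is the pure transpose ``out[z, y, x] = in[y, z, x]`` — voxel
    values are conserved exactly and frame 0 of the output is the bottom
    surface of the gel.
    """
    if stack.axis_order is not AxisOrder.XZ_YSTACK:
        raise ValueError(f"expected axis order XZ_YSTACK, got {stack.axis_order.value}")
    return replace(
        stack,
        data=np.ascontiguousarray(stack.data.transpose(1, 0, 2)),
        axis_order=AxisOrder.XY_ZSTACK,
    )


def convert_to_acquisition(stack: IntensityStack) -> IntensityStack:
    """Inverse of :func:`convert_axes`; round-trips are voxel exact."""
    if stack.axis_order is not AxisOrder.XY_ZSTACK:
        raise ValueError(f"expected axis order XY_ZSTACK, got {stack.axis_order.value}")
    return replace(
        stack,
        data=np.ascontiguousarray(stack.data.transpose(1, 0, 2)),
        axis_order=AxisOrder.XZ_YSTACK,
    )


def truncate_depth(stack: IntensityStack, max_depth_um: float) -> IntensityStack:
    """Drop frames at or beyond ``max_depth_um`` below the gel bottom.

    Keeps frames with ``index * frame_spacing_um < max_depth_um``, i.e.
    ``floor(max_depth_um / frame_spacing_um)`` frames (capped at the frames
    available).  Microvessels are rarely visible beyond 300–350 µm, so
    350 µm is the pipeline default.
    """
    if stack.axis_order is not AxisOrder.XY_ZSTACK:
        raise ValueError("truncate_depth operates on converted (XY_ZSTACK) stacks")
    if max_depth_um <= 0:
        raise ValueError("max_depth_um must be positive")
    keep = min(stack.n_frames, math.floor(max_depth_um / stack.frame_spacing_um))
    if keep == 0:
        raise ValueError(
            f"max_depth_um={max_depth_um} retains no frames at "
            f"{stack.frame_spacing_um} µm spacing"
        )
    return replace(stack, data=stack.data[:keep].copy())


# ---------------------------------------------------------------------------
# contrast preprocessing


def _equalize_frame(frame: np.ndarray, n_levels: int) -> np.ndarray:
    # classic CDF remap on n_levels quantization bins:
    #   out = (cdf(v) - cdf_min) / (1 - cdf_min), scaled to [0, 1]
    levels = np.minimum((frame * (n_levels - 1)).round().astype(np.int64), n_levels - 1)
    hist = np.bincount(levels.ravel(), minlength=n_levels)
    cdf = np.cumsum(hist) / levels.size
    cdf_min = cdf[levels.min()]
    if cdf_min >= 1.0:  # constant frame: nothing to equalize
        return frame.copy()
    mapped = (cdf - cdf_min) / (1.0 - cdf_min)
    return mapped[levels]


def equalize_histogram(
    stack: IntensityStack, n_levels: int = 256, per_frame: bool = True
) -> IntensityStack:
    """Histogram-equalize to boost global contrast before segmentation.

    Each frame is remapped by its own cumulative intensity distribution
    (``out = (cdf(v) − cdf_min) / (1 − cdf_min)``), which preserves the
    monotone intensity ordering within a frame and stretches the output to
    the full [0, 1] range.  Per-frame equalization is the default because
    OCT contrast decays with depth, so a single stack-wide map would trade
    deep-frame contrast for surface-frame contrast; ``per_frame=False``
    applies one map computed from the pooled stack histogram instead.
    Constant frames are returned unchanged (degenerate CDF).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if per_frame:
        out = np.stack([_equalize_frame(f, n_levels) for f in stack.data])
    else:
        pooled = _equalize_frame(stack.data.reshape(1, -1), n_levels)
        out = pooled.reshape(stack.data.shape)
    return replace(stack, data=out)
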