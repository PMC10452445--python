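"""Patch-based plumbing for externally trained image-translation detectors.

A 600 × 600 OCT frame is too large for typical 256 × 256 image-to-image
translation networks, so frames are split into the minimal uniform grid of
overlapping patches covering the frame (3 × 3 for the 600/256 geometry,
per-axis offsets 0, 172, 344), translated patch-by-patch, and stitched
back by averaging overlaps.  ``stitch(split(frame)) == frame`` exactly.

The network itself (training, weights) lives outside this package;
:func:`external_segment` accepts any producer of per-frame probability
maps — a directory of files, a multipage TIFF, or a Python callable — and
turns them into a :class:`~octvessel.stack_io.BinaryStack` with the
``>= 0.5`` foreground rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .stack_io import BinaryStack, IntensityStack, read_stack

__all__ = [
    "PatchGrid",
    "split_patches",
    "stitch_patches",
    "augment_flips",
    "external_segment",
]

DEFAULT_PATCH_SIZE_PX = 256


def _axis_offsets(dim: int, patch: int) -> np.ndarray:
    """Evenly spaced patch offsets covering an axis of length ``dim``."""
    n = int(np.ceil(dim / patch))
    if n == 1:
        return np.array([0], dtype=int)
    return np.rint(np.linspace(0, dim - patch, n)).astype(int)


@dataclass(frozen=True)
class PatchGrid:
    """Layout of overlapping patches over one frame."""

    patch_size_px: int
    frame_size_px: tuple[int, int]  # (height, width)
    row_offsets: tuple[int, ...]
    col_offsets: tuple[int, ...]

    @property
    def grid(self) -> tuple[int, int]:
        return (len(self.row_offsets), len(self.col_offsets))

    @property
    def offsets(self) -> list[tuple[int, int]]:
        """Per-patch (row, col) top-left corners in row-major order."""
        return [(r, c) for r in self.row_offsets for c in self.col_offsets]

    @property
    def n_patches(self) -> int:
        return len(self.row_offsets) * len(self.col_offsets)


def split_patches(
    frame: np.ndarray, patch_size_px: int = DEFAULT_PATCH_SIZE_PX
) -> tuple[list[np.ndarray], PatchGrid]:
    """Split a frame into the minimal uniform grid of overlapping
    ``patch_size_px``-square patches covering every pixel.

    Per-axis patch counts are ``ceil(dim / patch)`` and offsets are evenly
    spaced from 0 to ``dim − patch`` (rounded), which reproduces the
    3 × 3 / {0, 172, 344} layout for 600-px frames and 256-px patches.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single 2D frame")
    h, w = frame.shape
    if h < patch_size_px or w < patch_size_px:
        raise ValueError(
            f"frame {h}×{w} smaller than patch size {patch_size_px}"
        )
    grid = PatchGrid(
        patch_size_px=patch_size_px,
        frame_size_px=(h, w),
        row_offsets=tuple(_axis_offsets(h, patch_size_px)),
        col_offsets=tuple(_axis_offsets(w, patch_size_px)),
    )
    patches = [
        frame[r : r + patch_size_px, c : c + patch_size_px].copy()
        for r, c in grid.offsets
    ]
    return patches, grid


def stitch_patches(
    patches: Sequence[np.ndarray], grid: PatchGrid, binary: bool = False
) -> np.ndarray:
    """Recombine patches into a frame, averaging overlapping pixels.

    With ``binary=True`` the averaged frame is thresholded at 0.5
    (ties count as foreground).  Stitching the unmodified output of
    :func:`split_patches` reproduces the original frame exactly.
    """
    if len(patches) != grid.n_patches:
        raise ValueError(
            f"expected {grid.n_patches} patches for grid {grid.grid}, got {len(patches)}"
        )
    p = grid.patch_size_px
    acc = np.zeros(grid.frame_size_px, dtype=np.float64)
    cnt = np.zeros(grid.frame_size_px, dtype=np.int64)
    for patch, (r, c) in zip(patches, grid.offsets):
        patch = np.asarray(patch, dtype=np.float64)
        if patch.shape != (p, p):
            raise ValueError(f"patch shape {patch.shape} does not match {p}×{p}")
        acc[r : r + p, c : c + p] += patch
        cnt[r : r + p, c : c + p] += 1
    if (cnt == 0).any():
        raise ValueError("patch grid does not cover the frame")
    out = acc / cnt
    if binary:
        return out >= 0.5
    return out


def augment_flips(
    frames: Sequence[np.ndarray], include_double: bool = False
) -> list[np.ndarray]:
    """Flip augmentation for training image pairs: for each input frame
    emit the original, its horizontal (left-right) flip and its vertical
    (up-down) flip, in that stable order — 3× the input count, or 4× with
    ``include_double=True`` which appends the 180° rotation as well."""
    if len(frames) == 0:
        raise ValueError("no frames to augment")
    out: list[np.ndarray] = []
    for f in frames:
        f = np.asarray(f)
        out.append(f.copy())
        out.append(np.fliplr(f))
        out.append(np.flipud(f))
        if include_double:
            out.append(np.flipud(np.fliplr(f)))
    return out


ProbMapProducer = Callable[[IntensityStack], np.ndarray]


def external_segment(
    stack: IntensityStack,
    producer: str | Path | ProbMapProducer,
    threshold: float = 0.5,
) -> BinaryStack:
    """Adapt an external probability-map producer into the pipeline.

    ``producer`` is either a path to per-frame probability maps (multipage
    TIFF or frame directory, values in [0, 1]) or a callable receiving the
    stack and returning an ``(n_frames, h, w)`` float array.  Probabilities
    ``>= threshold`` become lumen foreground.
    """
    if callable(producer):
        maps = np.asarray(producer(stack), dtype=np.float64)
    else:
        maps = read_stack(
            producer,
            pixel_pitch_um=stack.pixel_pitch_um,
            frame_spacing_um=stack.frame_spacing_um,
        ).data
    if maps.shape != stack.data.shape:
        raise ValueError(
            f"probability-map geometry {maps.shape} does not match stack {stack.data.shape}"
        )
    if maps.min() < 0 or maps.max() > 1:
        raise ValueError("probability maps must lie in [0, 1]")
    return BinaryStack(
        data=maps >= threshold,
        pixel_pitch_um=stack.pixel_pitch_um,
        frame_spacing_um=stack.frame_spacing_um,
    )
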