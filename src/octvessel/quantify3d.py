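"""3D quantification of segmented lumen structures.

Binary lumen stacks are labelled into 3D connected components; components
touching the bottom surface of the gel (frame 0) are *open* vascular
structures — the ones perfusable in a permeability assay — and all others
are *closed*.  For each open structure the pipeline reports its mean
minimum-caliper (min Feret) diameter and its lateral surface area, both in
physical units, and the totals feed the effective-permeability formula
Pe = PSe / A.

Measurement conventions
-----------------------
diameter
    Per occupied frame, the minimum caliper width of the component's 2D
    cross-section: pixel centers are projected onto a fan of directions,
    the smallest (max − min) projection span is taken, and one pixel is
    added for the pixel footprint (so a single pixel measures 1 px and
    digitized discs track their continuous diameter to within a pixel).
    Frame values are averaged over the frames the component spans and
    scaled by the pixel pitch.
surface area
    Per occupied frame, a perimeter estimate of the cross-section (default:
    the mean of the Crofton 4-direction intercept estimate and the weighted
    pixel-edge count, whose discretization biases largely cancel), scaled
    to µm and multiplied by the frame spacing; summed over frames.  This is
    a Riemann sum of the lateral (side-wall) area of the tube — the
    per-frame generalization of "circumference × number of frames".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter, perimeter_crofton

from .stack_io import BinaryStack, StackGeometry

__all__ = [
    "LabelVolume",
    "VesselRecord",
    "VesselTable",
    "label_components",
    "classify_open_closed",
    "remove_closed",
    "measure_diameter",
    "measure_surface_area",
    "summarize",
    "effective_permeability",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabelVolume:
    """3D component labelling of a binary stack (0 = background)."""

    labels: np.ndarray
    n_components: int
    connectivity: int
    geometry: StackGeometry

    @property
    def ids(self) -> range:
        return range(1, self.n_components + 1)

    def component_mask(self, component_id: int) -> np.ndarray:
        if not 1 <= component_id <= self.n_components:
            raise KeyError(f"unknown component id {component_id}")
        return self.labels == component_id


def label_components(mask: BinaryStack, connectivity: int = 26) -> LabelVolume:
    """Label 3D connected components of a lumen mask.

    ``connectivity`` is the 3D neighbourhood: 6 (faces), 18 (faces+edges)
    or 26 (faces+edges+corners, the default).  Labels are assigned in scan
    order, so the labelling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    labels, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    return LabelVolume(
        labels=labels,
        n_components=int(n),
        connectivity=connectivity,
        geometry=mask.geometry,
    )


def classify_open_closed(volume: LabelVolume, anchor_frames: int = 1) -> dict[int, bool]:
    """Flag each component as open (True) or closed (False).

    A structure is open iff it has at least one voxel within the first
    ``anchor_frames`` frames (default: frame 0 only, the gel bottom where
    the endothelial monolayer seals the tube openings).  Widening the
    anchor tolerates segmentation dropout at the very bottom frame.
    """
    if anchor_frames < 1:
        raise ValueError("anchor_frames must be >= 1")
    bottom = volume.labels[:anchor_frames]
    open_ids = set(np.unique(bottom[bottom > 0]).tolist())
    return {cid: cid in open_ids for cid in volume.ids}


def remove_closed(volume: LabelVolume, anchor_frames: int = 1) -> LabelVolume:
    """Drop closed components and renumber the open ones 1..K_open,
    preserving scan order."""
    flags = classify_open_closed(volume, anchor_frames)
    open_ids = [cid for cid in volume.ids if flags[cid]]
    remap = np.zeros(volume.n_components + 1, dtype=volume.labels.dtype)
    for new_id, old_id in enumerate(open_ids, start=1):
        remap[old_id] = new_id
    return LabelVolume(
        labels=remap[volume.labels],
        n_components=len(open_ids),
        connectivity=volume.connectivity,
        geometry=volume.geometry,
    )


def _min_caliper_px(rows: np.ndarray, cols: np.ndarray, n_angles: int = 180) -> float:
    """Minimum caliper width (px) of a 2D pixel set.

    Pixel centers are projected onto ``n_angles`` directions over a
    half-turn; the smallest projection span, plus one pixel for the pixel
    footprint, is the width.  The +1 px correction keeps digitized discs of
    every whole-pixel radius within one pixel of their continuous diameter
    (a bare center span reads a radius-2 disc as 2.83 px instead of 4) and
    makes a single pixel measure 1 px without a separate floor rule.
    """
    if rows.size == 1:
        return 1.0
    pts = np.column_stack([rows, cols]).astype(np.float64)
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = pts @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()) + 1.0


def measure_diameter(volume: LabelVolume, component_id: int) -> float:
    """Mean minimum-caliper diameter of a component, in µm.

    The min Feret width is computed for the component's 2D cross-section in
    every frame it occupies, averaged over those frames, and scaled by the
    lateral pixel pitch.
    """
    mask = volume.component_mask(component_id)
    widths = []
    for frame in mask:
        rows, cols = np.nonzero(frame)
        if rows.size:
            widths.append(_min_caliper_px(rows, cols))
    return float(np.mean(widths)) * volume.geometry.pixel_pitch_um


def _perimeter_px(frame: np.ndarray, estimator: str) -> float:
    """Cross-section perimeter in pixels.

    ``crofton`` is the 4-direction Crofton intercept estimate; ``edge`` the
    classical weighted pixel-edge count; ``hybrid`` (default) their mean.
    On digitized convex sections the two pure estimators err in opposite
    directions — Crofton over-reads the staircase inflation, the edge count
    under-reads cut corners — and averaging cancels most of both (within
    ~7% of the true circumference for discs down to 2 px radius, where
    either alone can exceed 10%).
    """
    if estimator == "crofton":
        return float(perimeter_crofton(frame, directions=4))
    if estimator == "edge":
        return float(perimeter(frame, neighborhood=4))
    if estimator == "hybrid":
        return 0.5 * (
            float(perimeter_crofton(frame, directions=4))
            + float(perimeter(frame, neighborhood=4))
        )
    raise ValueError(f"unknown perimeter estimator {estimator!r}")


def measure_surface_area(
    volume: LabelVolume, component_id: int, estimator: str = "hybrid"
) -> float:
    """Lateral surface area of a component, in µm².

    Sum over occupied frames of (cross-section perimeter × pixel pitch ×
    frame spacing) — circumference integrated along depth.  See
    :func:`_perimeter_px` for the estimator choices.
    """
    mask = volume.component_mask(component_id)
    g = volume.geometry
    perim_px = sum(
        _perimeter_px(frame, estimator) for frame in mask if frame.any()
    )
    return float(perim_px) * g.pixel_pitch_um * g.frame_spacing_um


@dataclass(frozen=True)
class VesselRecord:
    """Measurements of one 3D lumen structure."""

    id: int
    open: bool
    n_voxels: int
    frames_spanned: int
    mean_min_caliper_diameter_um: float
    lateral_surface_area_um2: float


@dataclass
class VesselTable:
    """Per-structure records plus stack-level totals."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_RECORD_COLUMNS)
    )

    @property
    def n_open(self) -> int:
        return int(self.records["open"].sum()) if len(self.records) else 0

    @property
    def n_closed(self) -> int:
        return len(self.records) - self.n_open

    @property
    def total_open_surface_area_um2(self) -> float:
        if not len(self.records):
            return 0.0
        open_rows = self.records[self.records["open"]]
        return float(open_rows["lateral_surface_area_um2"].sum())

    @property
    def mean_diameter_um(self) -> float:
        if not len(self.records):
            return 0.0
        return float(self.records["mean_min_caliper_diameter_um"].mean())

    @property
    def totals(self) -> dict:
        return {
            "n_open": self.n_open,
            "n_closed": self.n_closed,
            "total_open_surface_area_um2": self.total_open_surface_area_um2,
            "mean_diameter_um": self.mean_diameter_um,
        }


_RECORD_COLUMNS = [
    "id",
    "open",
    "n_voxels",
    "frames_spanned",
    "mean_min_caliper_diameter_um",
    "lateral_surface_area_um2",
]


def summarize(
    volume: LabelVolume, open_only: bool = False, anchor_frames: int = 1
) -> VesselTable:
    """Measure every (open) component and assemble the vessel table."""
    flags = classify_open_closed(volume, anchor_frames)
    rows = []
    for cid in volume.ids:
        if open_only and not flags[cid]:
            continue
        mask = volume.labels == cid
        frames_occupied = np.flatnonzero(mask.any(axis=(1, 2)))
        rows.append(
            VesselRecord(
                id=cid,
                open=flags[cid],
                n_voxels=int(mask.sum()),
                frames_spanned=int(frames_occupied.size),
                mean_min_caliper_diameter_um=measure_diameter(volume, cid),
                lateral_surface_area_um2=measure_surface_area(volume, cid),
            )
        )
    records = pd.DataFrame([r.__dict__ for r in rows], columns=_RECORD_COLUMNS)
    return VesselTable(records=records)


def effective_permeability(pse: float, area_um2: float) -> float:
    """Effective permeability coefficient Pe = PSe / A.

    ``pse`` is the permeability–surface-area product of the tracer across
    the endothelial barrier and ``area_um2`` the total open-vessel surface
    area; Pe carries the units of pse / µm².
    """
    if area_um2 <= 0:
        raise ValueError("surface area must be positive")
    return pse / area_um2
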