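"""Synthetic OCT phantom: a hydrogel volume with tubular lumens and truth.

No public OCT datasets of the 3D blood-brain-barrier construct exist, so
every detector and the quantification stage are exercised on synthetic
stacks that emulate the acquisition: 600 × 600-px x-y frames at 10 µm/px
and 10 µm frame spacing, bright speckled tissue whose mean level decays
exponentially with depth, dark pore-like lumen cross-sections, a bright
culture-insert edge ring, a central surface depression in the first few
frames, and depth-increasing Gaussian blur.  Open tubes are anchored at
frame 0 (the gel bottom) and never reach past ``max_extent_um``; closed
lumens float fully inside the gel.

The generator records exact analytic truth per tube — noise-free voxel
mask, radius, centerline, cylinder diameter 2r and lateral area
pi * d * length — so parameter-recovery tests have a closed-form oracle.

Modelling choices (free where real OCT physics is out of scope): speckle
is multiplicative log-normal with unit mean, the standard appearance model
for coherent imaging; tube centerlines are monotone in z (one cross-section
per frame, no branching); tube radii are snapped to whole pixels so the
rasterized truth represents the analytic cylinder at the sampling
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .quantify3d import VesselTable, _RECORD_COLUMNS
from .stack_io import AxisOrder, BinaryStack, IntensityStack, StackGeometry

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "truth_summary"]

MAX_OPEN_EXTENT_UM = 350.0  # open tubes rarely extend deeper than this


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic acquisition.

    Defaults mirror the imaged construct: 600 × 600-px frames, 10 µm
    lateral pitch and frame spacing, 35 frames (350 µm visible depth),
    a handful of 20–40 µm-radius lumens, contrast e-folding over 150 µm,
    insert ring at r = 250 px and a ~5-frame central depression.
    """

    geometry: StackGeometry = field(
        default_factory=lambda: StackGeometry(600, 600, 35)
    )
    n_open: int = 5
    n_closed: int = 2
    radius_um_range: tuple[float, float] = (20.0, 40.0)
    tortuosity: float = 1.0  # per-frame lateral centerline jitter, px
    max_extent_um: float = MAX_OPEN_EXTENT_UM
    speckle_sigma: float = 0.3
    depth_decay_um: float = 150.0
    blur_sigma0_px: float = 1.0
    blur_gain_per_frame: float = 0.05
    ring_radius_px: int = 250
    ring_width_px: float = 2.0
    depression_frames: int = 5
    depression_radius_px: int = 120
    tissue_level: float = 0.85
    lumen_level: float = 0.02
    bright_lumens: bool = False  # invert polarity (lumens bright on dark)
    quantize_radius_to_px: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_open < 0 or self.n_closed < 0:
            raise ValueError("tube counts must be non-negative")
        lo, hi = self.radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("radius range must be positive and ordered")
        if self.max_extent_um > MAX_OPEN_EXTENT_UM:
            raise ValueError(
                f"max_extent_um must not exceed {MAX_OPEN_EXTENT_UM} µm"
            )
        if self.speckle_sigma < 0 or self.tortuosity < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom.

    ``mask`` holds the noise-free lumen voxels; ``tube_table`` one row per
    tube (id, open flag, radius, span, analytic cylinder diameter and
    lateral area); ``centerlines`` maps tube id to an array of
    (frame, row, col) centerline samples.
    """

    mask: BinaryStack
    tube_table: pd.DataFrame
    centerlines: dict[int, np.ndarray]


def _place_centers(
    rng: np.random.Generator,
    spec: PhantomSpec,
    radii_px: np.ndarray,
    max_attempts: int = 500,
) -> np.ndarray:
    """Rejection-sample non-overlapping tube anchor positions inside the
    analyzable annulus (outside the depression, inside the insert ring)."""
    g = spec.geometry
    cy, cx = (g.height_px - 1) / 2.0, (g.width_px - 1) / 2.0
    # random-walk drift scale of the jittered centerline over the stack
    jitter_margin = spec.tortuosity * math.sqrt(g.n_frames) * 1.5 + 2.0
    ring_standoff = max(3.0, 0.03 * spec.ring_radius_px)
    outer = min(spec.ring_radius_px, min(cy, cx)) - ring_standoff
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        inner = spec.depression_radius_px + r + jitter_margin
        if inner >= outer - r:
            raise RuntimeError("no room between depression and insert ring")
        for _ in range(max_attempts):
            rho = math.sqrt(rng.uniform(inner**2, (outer - r) ** 2))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            # anchors snap to the pixel grid so cross-sections digitize
            # identically in every frame
            y = float(round(cy + rho * math.sin(phi)))
            x = float(round(cx + rho * math.cos(phi)))
            ok = all(
                math.hypot(y - yc, x - xc)
                > r + radii_px[j] + 2.0 * jitter_margin + 2.0
                for j, (yc, xc) in enumerate(centers)
            )
            if ok:
                centers.append((y, x))
                break
        else:
            raise RuntimeError(
                f"could not place tube {i} without overlap after {max_attempts} attempts"
            )
    return np.asarray(centers, dtype=float)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityStack, PhantomTruth]:
    """Render a synthetic OCT stack and its exact truth.

    Identical specs (including seed) produce bit-identical output.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    n_tubes = spec.n_open + spec.n_closed

    # -- sample tube parameters -------------------------------------------
    radii_um = rng.uniform(*spec.radius_um_range, size=n_tubes)
    if spec.quantize_radius_to_px:
        radii_um = np.maximum(
            np.rint(radii_um / g.pixel_pitch_um), 1.0
        ) * g.pixel_pitch_um
    radii_px = radii_um / g.pixel_pitch_um

    max_open_frames = min(g.n_frames, math.floor(spec.max_extent_um / g.frame_spacing_um))
    spans: list[tuple[int, int]] = []  # (start_frame, end_frame) inclusive
    for i in range(n_tubes):
        if i < spec.n_open:
            length = int(rng.integers(max(3, max_open_frames // 2), max_open_frames + 1))
            spans.append((0, length - 1))
        else:
            length = int(rng.integers(3, max(4, g.n_frames // 3) + 1))
            start = int(rng.integers(1, max(2, g.n_frames - length)))
            spans.append((start, min(start + length - 1, g.n_frames - 1)))

    centers = _place_centers(rng, spec, radii_px)

    # -- rasterize lumens and record truth --------------------------------
    mask = np.zeros((g.n_frames, g.height_px, g.width_px), dtype=bool)
    yy, xx = np.mgrid[0 : g.height_px, 0 : g.width_px].astype(np.float64)
    centerlines: dict[int, np.ndarray] = {}
    rows = []
    for i in range(n_tubes):
        z0, z1 = spans[i]
        n_span = z1 - z0 + 1
        # whole-pixel jitter: off-grid cross-sections would digitize
        # differently frame to frame and blur the analytic truth
        steps = np.rint(
            rng.uniform(-spec.tortuosity, spec.tortuosity, size=(n_span, 2))
        )
        steps[0] = 0.0
        path = centers[i] + np.cumsum(steps, axis=0)
        samples = np.column_stack([np.arange(z0, z1 + 1), path])
        centerlines[i + 1] = samples
        n_vox = 0
        for (z, cyl, cxl) in samples:
            disc = (yy - cyl) ** 2 + (xx - cxl) ** 2 <= radii_px[i] ** 2
            mask[int(z)] |= disc
            n_vox += int(disc.sum())
        d_um = 2.0 * radii_um[i]
        length_um = n_span * g.frame_spacing_um
        rows.append(
            {
                "id": i + 1,
                "open": i < spec.n_open,
                "radius_um": radii_um[i],
                "start_frame": z0,
                "end_frame": z1,
                "frames_spanned": n_span,
                "n_voxels": n_vox,
                "analytic_diameter_um": d_um,
                "analytic_lateral_area_um2": math.pi * d_um * length_um,
            }
        )
    tube_table = pd.DataFrame(
        rows,
        columns=[
            "id", "open", "radius_um", "start_frame", "end_frame",
            "frames_spanned", "n_voxels", "analytic_diameter_um",
            "analytic_lateral_area_um2",
        ],
    )

    # -- render intensity --------------------------------------------------
    cy, cx = (g.height_px - 1) / 2.0, (g.width_px - 1) / 2.0
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    ring = np.abs(dist - spec.ring_radius_px) <= spec.ring_width_px
    depression = dist < spec.depression_radius_px

    frames = np.empty((g.n_frames, g.height_px, g.width_px), dtype=np.float64)
    for z in range(g.n_frames):
        depth_um = z * g.frame_spacing_um
        level = spec.tissue_level * math.exp(-depth_um / spec.depth_decay_um)
        frame = np.full((g.height_px, g.width_px), level)
        frame[mask[z]] = spec.lumen_level
        if z < spec.depression_frames:
            frame[depression] = spec.lumen_level
        frame[ring] = 1.0
        if spec.speckle_sigma > 0:
            noise = rng.standard_normal(frame.shape)
            frame *= np.exp(spec.speckle_sigma * noise - spec.speckle_sigma**2 / 2.0)
        sigma = spec.blur_sigma0_px + spec.blur_gain_per_frame * z
        if sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma)
        frames[z] = np.clip(frame, 0.0, 1.0)

    if spec.bright_lumens:
        frames = 1.0 - frames

    stack = IntensityStack(
        data=frames,
        axis_order=AxisOrder.XY_ZSTACK,
        pixel_pitch_um=g.pixel_pitch_um,
        frame_spacing_um=g.frame_spacing_um,
    )
    truth = PhantomTruth(
        mask=BinaryStack(
            data=mask,
            pixel_pitch_um=g.pixel_pitch_um,
            frame_spacing_um=g.frame_spacing_um,
        ),
        tube_table=tube_table,
        centerlines=centerlines,
    )
    return stack, truth


def truth_summary(truth: PhantomTruth) -> VesselTable:
    """Analytic tube truth in the shape produced by the quantification
    stage, for direct table-vs-table comparison."""
    t = truth.tube_table
    records = pd.DataFrame(
        {
            "id": t["id"],
            "open": t["open"],
            "n_voxels": t["n_voxels"],
            "frames_spanned": t["frames_spanned"],
            "mean_min_caliper_diameter_um": t["analytic_diameter_um"],
            "lateral_surface_area_um2": t["analytic_lateral_area_um2"],
        },
        columns=_RECORD_COLUMNS,
    )
    return VesselTable(records=records)
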