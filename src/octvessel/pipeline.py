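"""End-to-end runs: convert → truncate → equalize → segment → quantify,
with optional evaluation against ground truth.

A run is described by a :class:`RunConfig` (loadable from TOML); outputs —
intermediate stacks, the vessel table, the kappa profile and a JSON report
with every parameter and the seed — land in one output directory, and the
same config and seed always reproduce them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


from . import __version__
from .evaluation import kappa_profile, summarize_kappa
from .mip_detector import MipParams, calibrate_threshold, segment_mip
from .patchwork import external_segment
from .quantify3d import label_components, remove_closed, summarize
from .rf_detector import (
    FeatureSpec,
    LabelEntry,
    SparseLabels,
    rf_segment,
    train_rf,
)
from .stack_io import (
    AxisOrder,
    BinaryStack,
    IntensityStack,
    convert_axes,
    equalize_histogram,
    read_mask,
    read_stack,
    truncate_depth,
    write_stack,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

METHODS = ("mip", "rf", "external")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str
    output_dir: str
    method: str = "mip"
    truth_path: str | None = None
    seed: int = 0
    pixel_pitch_um: float = 10.0
    frame_spacing_um: float = 10.0
    input_is_acquisition: bool = False  # input is an x-z y-stack needing conversion
    max_depth_um: float = 350.0
    equalize: bool = True
    connectivity: int = 26
    open_only: bool = True
    anchor_frames: int = 1
    mip: MipParams = field(default_factory=MipParams)
    calibrate_offsets: list[float] | None = None  # requires truth
    rf_labels_path: str | None = None  # CSV frame,row,col,class
    rf_n_trees: int = 100
    rf_closing_radius_px: int = 2
    external_probmaps: str | None = None

    def validate(self) -> None:
        if self.method not in METHODS:
            raise PipelineError("config", f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "rf" and not self.rf_labels_path:
            raise PipelineError("config", "method 'rf' requires rf_labels_path")
        if self.method == "external" and not self.external_probmaps:
            raise PipelineError("config", "method 'external' requires external_probmaps")
        if self.calibrate_offsets and not self.truth_path:
            raise PipelineError("config", "offset calibration requires truth_path")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file; the [mip] table maps onto
    :class:`MipParams`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    mip = MipParams(**raw.pop("mip", {}))
    try:
        return RunConfig(mip=mip, **raw)
    except TypeError as exc:
        raise PipelineError("config", str(exc)) from exc


def _read_labels_csv(path: str | Path) -> SparseLabels:
    import csv

    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                LabelEntry(
                    frame=int(row["frame"]),
                    row=int(row["row"]),
                    col=int(row["col"]),
                    cls=row["class"].strip(),
                )
            )
    return SparseLabels(entries=entries)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns (and writes) the JSON-able run report."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "octvessel_version": __version__,
        "seed": config.seed,
        "method": config.method,
        "config": _config_dict(config),
    }

    try:
        stack = read_stack(
            config.input_path,
            pixel_pitch_um=config.pixel_pitch_um,
            frame_spacing_um=config.frame_spacing_um,
            axis_order=AxisOrder.XZ_YSTACK
            if config.input_is_acquisition
            else AxisOrder.XY_ZSTACK,
        )
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    if config.input_is_acquisition:
        stack = convert_axes(stack)
    stack = truncate_depth(stack, config.max_depth_um)
    if config.equalize:
        stack = equalize_histogram(stack)
    write_stack(stack, out_dir / "preprocessed.tif")

    truth: BinaryStack | None = None
    if config.truth_path:
        truth = read_mask(
            config.truth_path,
            pixel_pitch_um=config.pixel_pitch_um,
            frame_spacing_um=config.frame_spacing_um,
        )
        truth.data = truth.data[: stack.n_frames]

    try:
        pred = _segment(stack, truth, config, report)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("segment", str(exc)) from exc
    write_stack(pred, out_dir / "segmented.tif")

    try:
        volume = label_components(pred, connectivity=config.connectivity)
        if config.open_only:
            volume = remove_closed(volume, anchor_frames=config.anchor_frames)
        table = summarize(volume, anchor_frames=config.anchor_frames)
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    table.records.to_csv(out_dir / "vessels.csv", index=False)
    report["vessel_totals"] = table.totals

    if truth is not None:
        try:
            profile = kappa_profile(pred, truth, dataset_id=Path(config.input_path).stem)
            profile.entries.to_csv(out_dir / "kappa.csv", index=False)
            summary = summarize_kappa([profile])
            report["kappa"] = {
                "mean": summary.mean,
                "min": summary.min,
                "max": summary.max,
            }
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _segment(
    stack: IntensityStack,
    truth: BinaryStack | None,
    config: RunConfig,
    report: dict,
) -> BinaryStack:
    if config.method == "mip":
        params = config.mip
        if config.calibrate_offsets:
            assert truth is not None
            params, best_kappa = calibrate_threshold(
                stack, truth, config.calibrate_offsets, params
            )
            report["calibrated_offset"] = params.adaptive_offset
            report["calibration_mean_kappa"] = best_kappa
        return segment_mip(stack, params)
    if config.method == "rf":
        labels = _read_labels_csv(config.rf_labels_path)
        clf = train_rf(
            stack, labels, n_trees=config.rf_n_trees, seed=config.seed
        )
        return rf_segment(stack, clf, closing_radius_px=config.rf_closing_radius_px)
    return external_segment(stack, config.external_probmaps)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
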