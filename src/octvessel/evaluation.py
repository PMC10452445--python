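"""Agreement scoring of detector output against ground truth.

Detector performance is judged pixel-wise per frame with Cohen's kappa, the
chance-corrected agreement between two binary raters:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement and p_e the agreement expected from the
raters' marginal foreground rates.  For binary frames this reduces to the
closed form

    kappa = 2 (TP·TN - FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)).

Frames where both raters are constant (denominator 0) score kappa = 0 by
convention and are flagged, not dropped.  Per-frame kappas are assembled
into depth profiles (depth = frame index × frame spacing) and summarized
across datasets; detector-vs-truth equivalence of stack-level measurements
is tested with a two-sided paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stack_io import BinaryStack

__all__ = [
    "ConfusionCounts",
    "KappaProfile",
    "confusion_counts",
    "cohen_kappa",
    "kappa_profile",
    "summarize_kappa",
    "KappaSummary",
    "paired_equivalence_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of one predicted/truth frame pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def observed_agreement(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def chance_agreement(self) -> float:
        n = self.total
        return ((self.tp + self.fp) * (self.tp + self.fn) + (self.fn + self.tn) * (self.fp + self.tn)) / (n * n)


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, roi: np.ndarray | None = None
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN between two binary frames, optionally inside a ROI.

    TP = predicted lumen pixels overlapping truth lumen; FP = predicted
    lumen on truth background; FN = truth lumen missed; TN = agreement on
    background.  The four counts always sum to the number of evaluated
    pixels (the whole frame, or the ROI area when a mask is given).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"frame dimension mismatch: {pred.shape} vs {truth.shape}")
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != pred.shape:
            raise ValueError(f"ROI dimension mismatch: {roi.shape} vs {pred.shape}")
        pred, truth = pred[roi], truth[roi]
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def cohen_kappa(c: ConfusionCounts, printed_variant: bool = False) -> float:
    """Cohen's kappa of one frame pair.

    Returns 0 when both raters are constant (degenerate denominator).
    ``printed_variant=True`` drops the factor 2 from the numerator — an
    alternative normalization that scores 0.5 for perfect agreement — and
    exists only for auditing against sources that print that form.
    """
    if c.total <= 0:
        raise ValueError("confusion counts are all zero")
    num = 2.0 * (c.tp * c.tn - c.fn * c.fp)
    den = (c.tp + c.fp) * (c.fp + c.tn) + (c.tp + c.fn) * (c.fn + c.tn)
    if den == 0:
        return 0.0
    if printed_variant:
        num /= 2.0
    return num / den


@dataclass
class KappaProfile:
    """Per-frame kappa as a function of depth for one dataset."""

    entries: pd.DataFrame  # columns: depth_um, kappa, degenerate
    dataset_id: str = ""

    @property
    def depths_um(self) -> np.ndarray:
        return self.entries["depth_um"].to_numpy()

    @property
    def kappas(self) -> np.ndarray:
        return self.entries["kappa"].to_numpy()

    def mean_kappa(self, depth_min_um: float | None = None, depth_max_um: float | None = None) -> float:
        """Mean kappa over all frames, optionally restricted to a depth band
        (inclusive bounds)."""
        sel = np.ones(len(self.entries), dtype=bool)
        if depth_min_um is not None:
            sel &= self.depths_um >= depth_min_um
        if depth_max_um is not None:
            sel &= self.depths_um <= depth_max_um
        if not sel.any():
            raise ValueError("no frames in the requested depth band")
        return float(self.kappas[sel].mean())


def kappa_profile(
    pred: BinaryStack,
    truth: BinaryStack,
    roi: Sequence[np.ndarray] | np.ndarray | None = None,
    dataset_id: str = "",
) -> KappaProfile:
    """Score every frame of a predicted stack against truth by depth."""
    if pred.data.shape != truth.data.shape:
        raise ValueError(
            f"stack geometry mismatch: {pred.data.shape} vs {truth.data.shape}"
        )
    rows = []
    for i in range(pred.n_frames):
        roi_frame = None if roi is None else np.asarray(roi[i])
        c = confusion_counts(pred.data[i], truth.data[i], roi_frame)
        num_den = (c.tp + c.fp) * (c.fp + c.tn) + (c.tp + c.fn) * (c.fn + c.tn)
        rows.append(
            {
                "depth_um": i * pred.frame_spacing_um,
                "kappa": cohen_kappa(c),
                "degenerate": num_den == 0,
            }
        )
    return KappaProfile(entries=pd.DataFrame(rows), dataset_id=dataset_id)


@dataclass(frozen=True)
class KappaSummary:
    """Grand mean over frames with min/max of per-dataset means."""

    mean: float
    min: float
    max: float
    per_dataset: dict[str, float]


def summarize_kappa(profiles: Sequence[KappaProfile]) -> KappaSummary:
    """Aggregate depth profiles: grand mean over all frames of all
    datasets, with min and max taken over the per-dataset means (the error
    bars of a detector-comparison plot)."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    all_kappas = np.concatenate([p.kappas for p in profiles])
    per_dataset = {
        p.dataset_id or f"dataset_{i}": float(p.kappas.mean())
        for i, p in enumerate(profiles)
    }
    means = list(per_dataset.values())
    return KappaSummary(
        mean=float(all_kappas.mean()),
        min=min(means),
        max=max(means),
        per_dataset=per_dataset,
    )


def paired_equivalence_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Two-sided paired t-test p-value between matched summary measurements
    (e.g. per-dataset vessel counts from ground truth vs a detector).

    Degenerate inputs — identical sequences, or constant differences with
    zero variance — return p = 1 with a warning: no evidence against
    equality can be extracted from them.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        warnings.warn(
            "zero-variance differences: paired t-test undefined, returning p = 1",
            stacklevel=2,
        )
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)
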