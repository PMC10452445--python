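"""Trainable random-forest pixel classifier for lumen segmentation.

Re-implements the interactive pixel-classification workflow as a library:
a bank of multi-scale image features is computed per pixel, a random
forest is trained on sparsely labelled lumen/background pixels, the rest
of the stack is classified, and misclassified regions can be corrected by
appending labels and retraining.  Predicted lumen probability is
thresholded at 0.5 and post-processed with morphological closing to fuse
small gaps.

The feature bank (Gaussian smoothing, gradient magnitude, Laplacian of
Gaussian, difference of Gaussians and local variance at scales 1–8 px,
plus raw intensity) follows the common trainable-segmentation recipe;
everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from sklearn.ensemble import RandomForestClassifier

from .stack_io import BinaryStack, IntensityStack

__all__ = [
    "FeatureSpec",
    "SparseLabels",
    "LabelEntry",
    "PixelClassifier",
    "extract_features",
    "train_rf",
    "rf_segment",
    "refine_labels",
]

FEATURE_NAMES = (
    "gaussian",
    "gradient_magnitude",
    "laplacian",
    "difference_of_gaussians",
    "local_variance",
)

LUMEN = "lumen"
BACKGROUND = "background"


@dataclass(frozen=True)
class FeatureSpec:
    """Which filters at which Gaussian scales make up the feature bank."""

    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    features: tuple[str, ...] = FEATURE_NAMES
    include_raw: bool = True

    def __post_init__(self) -> None:
        if not self.sigmas or not self.features:
            raise ValueError("need at least one sigma and one feature")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return len(self.sigmas) * len(self.features) + int(self.include_raw)


@dataclass(frozen=True)
class LabelEntry:
    frame: int
    row: int
    col: int
    cls: str  # LUMEN or BACKGROUND


@dataclass
class SparseLabels:
    """Sparse pixel annotations: (frame, row, col, class) entries."""

    entries: list[LabelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.cls not in (LUMEN, BACKGROUND):
                raise ValueError(f"class must be '{LUMEN}' or '{BACKGROUND}', got {e.cls!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, stack: IntensityStack) -> None:
        n, h, w = stack.data.shape
        for e in self.entries:
            if not (0 <= e.frame < n and 0 <= e.row < h and 0 <= e.col < w):
                raise ValueError(f"label out of range: {e}")

    @property
    def classes(self) -> set[str]:
        return {e.cls for e in self.entries}

    def merged_with(self, other: "SparseLabels") -> "SparseLabels":
        return SparseLabels(entries=list(self.entries) + list(other.entries))


def _frame_features(frame: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Feature planes of one frame, shape (h, w, n_features)."""
    planes: list[np.ndarray] = []
    if spec.include_raw:
        planes.append(frame)
    for s in spec.sigmas:
        smooth = ndimage.gaussian_filter(frame, s)
        for name in spec.features:
            if name == "gaussian":
                planes.append(smooth)
            elif name == "gradient_magnitude":
                planes.append(ndimage.gaussian_gradient_magnitude(frame, s))
            elif name == "laplacian":
                planes.append(ndimage.gaussian_laplace(frame, s))
            elif name == "difference_of_gaussians":
                planes.append(smooth - ndimage.gaussian_filter(frame, 1.6 * s))
            elif name == "local_variance":
                mean_sq = ndimage.gaussian_filter(frame**2, s)
                planes.append(np.maximum(mean_sq - smooth**2, 0.0))
    return np.stack(planes, axis=-1)


def extract_features(stack: IntensityStack, spec: FeatureSpec = FeatureSpec()) -> np.ndarray:
    """Per-pixel feature vectors, shape (n_frames, h, w, n_features).

    Deterministic: all filters are linear/deterministic in the input.
    """
    return np.stack([_frame_features(f, spec) for f in stack.data])


@dataclass
class PixelClassifier:
    """A trained forest bundled with its feature spec and training labels."""

    forest: RandomForestClassifier
    feature_spec: FeatureSpec
    labels: SparseLabels
    seed: int

    def predict_proba_stack(self, stack: IntensityStack) -> np.ndarray:
        """Per-voxel lumen probability, shape matching ``stack.data``."""
        feats = extract_features(stack, self.feature_spec)
        n, h, w, k = feats.shape
        proba = self.forest.predict_proba(feats.reshape(-1, k))
        lumen_col = list(self.forest.classes_).index(1)
        return proba[:, lumen_col].reshape(n, h, w)


def _training_matrix(
    stack: IntensityStack, labels: SparseLabels, spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray]:
    labels.validate_against(stack)
    by_frame: dict[int, list[LabelEntry]] = {}
    for e in labels.entries:
        by_frame.setdefault(e.frame, []).append(e)
    xs, ys = [], []
    for frame_idx, entries in sorted(by_frame.items()):
        planes = _frame_features(stack.data[frame_idx], spec)
        for e in entries:
            xs.append(planes[e.row, e.col])
            ys.append(1 if e.cls == LUMEN else 0)
    return np.asarray(xs), np.asarray(ys)


def train_rf(
    stack: IntensityStack,
    labels: SparseLabels,
    feature_spec: FeatureSpec = FeatureSpec(),
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Train a random forest on sparse lumen/background pixel labels."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if labels.classes != {LUMEN, BACKGROUND}:
        raise ValueError("labels must contain both lumen and background pixels")
    x, y = _training_matrix(stack, labels, feature_spec)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    return PixelClassifier(forest=forest, feature_spec=feature_spec, labels=labels, seed=seed)


def rf_segment(
    stack: IntensityStack,
    classifier: PixelClassifier,
    closing_radius_px: int = 2,
    threshold: float = 0.5,
) -> BinaryStack:
    """Classify every pixel and post-process with morphological closing.

    Closing (dilation then erosion) with a disc fuses speckle-induced
    pinholes in detected lumens; radius 0 returns the raw thresholded
    probabilities.
    """
    if closing_radius_px < 0:
        raise ValueError("closing_radius_px must be >= 0")
    proba = classifier.predict_proba_stack(stack)
    binary = proba >= threshold
    if closing_radius_px > 0:
        selem = morphology.disk(closing_radius_px)
        binary = np.stack([morphology.closing(f, selem) for f in binary])
    return BinaryStack(
        data=binary,
        pixel_pitch_um=stack.pixel_pitch_um,
        frame_spacing_um=stack.frame_spacing_um,
    )


def refine_labels(
    stack: IntensityStack,
    classifier: PixelClassifier,
    corrections: SparseLabels,
) -> PixelClassifier:
    """One round of interactive label correction: retrain on the union of
    the classifier's training labels and the new corrections (same seed,
    feature spec and forest size)."""
    if len(corrections) == 0:
        raise ValueError("corrections are empty")
    corrections.validate_against(stack)
    merged = classifier.labels.merged_with(corrections)
    return train_rf(
        stack,
        merged,
        feature_spec=classifier.feature_spec,
        n_trees=classifier.forest.n_estimators,
        seed=classifier.seed,
    )
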