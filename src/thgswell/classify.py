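"""Sparse-annotation trainable pixel classification for non-myelin maps.

A small multiscale filter bank (smoothed intensity, gradient magnitude,
Laplacian of Gaussian, Hessian eigenvalues — computed 2D per z-slice) feeds
a random forest trained on a handful of annotated voxels per class, in the
spirit of interactive trainable-segmentation tools.  The trained model
yields a per-voxel probability of the "non-myelin" class, the input to
swelling detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .io import ProbabilityMap

__all__ = [
    "DEFAULT_SCALES_PX",
    "FEATURE_KINDS",
    "SparseLabels",
    "PixelModel",
    "compute_features",
    "train_pixel_classifier",
    "predict_probability",
    "sample_sparse_labels",
]

DEFAULT_SCALES_PX = (0.7, 1.0, 1.6, 3.5, 5.0)
FEATURE_KINDS = ("gaussian", "gradient", "log", "hessian_max", "hessian_min")

SIGNAL = "signal"
NON_MYELIN = "non-myelin"
CLASS_ORDER = (SIGNAL, NON_MYELIN)


@dataclass
class SparseLabels:
    """Sparse voxel annotations: (z, y, x) coordinates with class names."""

    coords: np.ndarray  # (n, 3) int
    classes: np.ndarray  # (n,) str, values in CLASS_ORDER

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.classes = np.asarray(self.classes)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.classes) != len(self.coords):
            raise ValueError("one class per coordinate required")
        unknown = set(np.unique(self.classes)) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes: {unknown}")

    def validate_bounds(self, shape):
        if np.any(self.coords < 0) or np.any(self.coords >= np.asarray(shape)):
            raise ValueError("annotation coordinates outside the volume")


@dataclass
class PixelModel:
    """Trained voxel classifier with its feature recipe."""

    scales_px: tuple
    kinds: tuple
    forest: RandomForestClassifier
    class_order: tuple = CLASS_ORDER
    seed: int = 0
    feature_names: list = field(default_factory=list)


def _slice_gaussian(volume, sigma, order_yx=(0, 0)):
    # sigma 0 along z keeps the filters strictly 2D per slice
    return ndi.gaussian_filter(
        volume, sigma=(0.0, sigma, sigma), order=(0, *order_yx), mode="nearest"
    )


def compute_features(volume: np.ndarray, scales_px=DEFAULT_SCALES_PX) -> np.ndarray:
    """Multiscale per-slice filter bank: (z, y, x, n_features) float32.

    Per scale σ: Gaussian-smoothed intensity, Gaussian gradient magnitude,
    Laplacian of Gaussian, and the largest/smallest eigenvalue of the 2D
    Hessian — five kinds × len(scales) channels, ordered scale-major.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    half_extent = min(volume.shape[1], volume.shape[2]) / 2.0
    if max(scales_px) > half_extent:
        raise ValueError("largest scale exceeds half the lateral extent")
    channels = []
    for s in scales_px:
        smoothed = _slice_gaussian(volume, s)
        gy = _slice_gaussian(volume, s, (1, 0))
        gx = _slice_gaussian(volume, s, (0, 1))
        grad = np.sqrt(gy * gy + gx * gx)
        hyy = _slice_gaussian(volume, s, (2, 0))
        hxx = _slice_gaussian(volume, s, (0, 2))
        hxy = _slice_gaussian(volume, s, (1, 1))
        log = hyy + hxx
        mean = 0.5 * (hyy + hxx)
        delta = np.sqrt(np.maximum(0.25 * (hyy - hxx) ** 2 + hxy * hxy, 0.0))
        channels.extend([smoothed, grad, log, mean + delta, mean - delta])
    return np.stack(channels, axis=-1)


def feature_names(scales_px=DEFAULT_SCALES_PX) -> list[str]:
    return [f"{kind}@{s}" for s in scales_px for kind in FEATURE_KINDS]


def train_pixel_classifier(
    features: np.ndarray,
    labels: SparseLabels,
    seed: int,
    scales_px=DEFAULT_SCALES_PX,
    n_trees: int = 100,
) -> PixelModel:
    """Fit a random forest on the annotated voxels' feature vectors.

    Bootstrap sampling with √d features per split; deterministic for a
    fixed seed.  Both classes must be represented.
    """
    labels.validate_bounds(features.shape[:3])
    present = set(np.unique(labels.classes))
    if present != set(CLASS_ORDER):
        raise ValueError(
            f"training requires voxels of both classes {CLASS_ORDER}; got {present}"
        )
    z, y, x = labels.coords.T
    X = features[z, y, x]
    target = (labels.classes == NON_MYELIN).astype(int)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, target)
    return PixelModel(
        scales_px=tuple(scales_px),
        kinds=FEATURE_KINDS,
        forest=forest,
        seed=int(seed),
        feature_names=feature_names(scales_px),
    )


def predict_probability(model: PixelModel, features: np.ndarray) -> ProbabilityMap:
    """Per-voxel non-myelin probability (mean tree leaf probability)."""
    expected = len(model.scales_px) * len(model.kinds)
    if features.shape[-1] != expected:
        raise ValueError(
            f"feature recipe mismatch: model expects {expected} channels, "
            f"got {features.shape[-1]}"
        )
    shape = features.shape[:3]
    flat = features.reshape(-1, expected)
    col = list(model.forest.classes_).index(1)
    prob = model.forest.predict_proba(flat)[:, col]
    return ProbabilityMap(prob.reshape(shape), class_name=NON_MYELIN)


# ---------------------------------------------------------------------------
# Annotation fixture: auto-generated scribbles from generator truth


def sample_sparse_labels(
    label_volume: np.ndarray,
    n_per_class: int,
    seed: int,
    signal_labels=(1, 2, 4),
    non_myelin_labels=(0, 3, 5),
) -> SparseLabels:
    """Sample sparse annotations from a ground-truth label volume.

    Stands in for human scribbles: myelin sheaths, axoplasm and lipid bodies
    annotate the "signal" class; background, swelling cavities and cell
    holes the "non-myelin" class.  Sampling is proportional within each
    class and deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    coords, classes = [], []
    for name, members in ((SIGNAL, signal_labels), (NON_MYELIN, non_myelin_labels)):
        mask = np.isin(label_volume, members)
        candidates = np.argwhere(mask)
        if len(candidates) == 0:
            raise ValueError(f"no voxels available for class {name!r}")
        idx = rng.choice(len(candidates), size=min(n_per_class, len(candidates)),
                         replace=False)
        coords.append(candidates[idx])
        classes.extend([name] * len(idx))
    return SparseLabels(np.concatenate(coords), np.asarray(classes))
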