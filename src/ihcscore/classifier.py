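"""Per-pixel five-class tissue classification (tumour +/-, stroma,
lymphocytes, background).

The original pattern-recognition step used an undisclosed commercial texture
classifier; its contract — a five-class tissue map validated by pixel
accuracy — is reproduced here with a random-forest over colour and local
texture features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import footprint_rectangle
from skimage.util import img_as_ubyte

from .stain import CLASS_NAMES, deconvolve_stains

FEATURE_NAMES = (
    "r", "g", "b",
    "h_od", "d_od",
    "h_mean", "h_std", "h_entropy",
    "d_mean", "d_std", "d_entropy",
)


@dataclass
class TissueMap:
    """Five-class label raster plus per-class pixel counts."""

    labels: np.ndarray
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            vals, cnts = np.unique(self.labels, return_counts=True)
            self.counts = {int(c): 0 for c in CLASS_NAMES}
            self.counts.update(dict(zip(vals.astype(int).tolist(), cnts.tolist())))


@dataclass
class ClassifierModel:
    """Fitted per-pixel classifier with its feature specification."""

    window: int
    feature_names: tuple[str, ...]
    estimator: RandomForestClassifier
    n_train_per_class: dict[int, int]
    seed: int

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, ClassifierModel):
            raise TypeError("file does not contain a ClassifierModel")
        return model


def _local_mean_std(channel: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    mean = ndi.uniform_filter(channel, size=window, mode="reflect")
    sq = ndi.uniform_filter(channel * channel, size=window, mode="reflect")
    var = np.clip(sq - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def _local_entropy(channel: np.ndarray, window: int) -> np.ndarray:
    scaled = img_as_ubyte(np.clip(channel / 2.0, 0.0, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank filters warn on bit depth
        return rank_entropy(scaled, footprint_rectangle((window, window)))


def extract_features(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel feature stack of shape (H, W, n_features).

    Features: raw RGB, deconvolved hematoxylin/DAB OD, and local mean,
    standard deviation and entropy of each OD channel over a ``window`` x
    ``window`` neighbourhood (reflected padding at the edges).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h_od, d_od = deconvolve_stains(image)
    rgb = image.astype(np.float64)
    feats = [rgb[..., 0], rgb[..., 1], rgb[..., 2], h_od, d_od]
    for ch in (h_od, d_od):
        mean, std = _local_mean_std(ch, window)
        feats.extend([mean, std, _local_entropy(ch, window)])
    return np.stack(feats, axis=-1)


def train_classifier(
    images,
    annotations,
    window: int = 5,
    max_pixels_per_class: int = 2000,
    n_estimators: int = 30,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the per-pixel classifier on annotated cores.

    Pixels are sampled balanced across classes (down-sampling the majority);
    every one of the five classes must appear in the annotations.
    """
    label_stack = [np.asarray(getattr(a, "class_mask", a)) for a in annotations]
    present = set()
    for lab in label_stack:
        present |= set(np.unique(lab).astype(int).tolist())
    missing = sorted(set(CLASS_NAMES) - present)
    if missing:
        names = ", ".join(CLASS_NAMES[m] for m in missing)
        raise ValueError(f"annotations are missing classes: {names}")

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    feats = [extract_features(img, window) for img in images]
    flat_x = np.concatenate([f.reshape(-1, f.shape[-1]) for f in feats])
    flat_y = np.concatenate([lab.ravel() for lab in label_stack])
    counts: dict[int, int] = {}
    for cls in sorted(CLASS_NAMES):
        idx = np.flatnonzero(flat_y == cls)
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        counts[cls] = int(idx.size)
        xs.append(flat_x[idx])
        ys.append(flat_y[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    est = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    est.fit(x, y)
    return ClassifierModel(
        window=window,
        feature_names=FEATURE_NAMES,
        estimator=est,
        n_train_per_class=counts,
        seed=seed,
    )


def classify_tissue(image: np.ndarray, model: ClassifierModel) -> TissueMap:
    """Label every pixel of ``image`` with one of the five tissue classes."""
    feats = extract_features(image, model.window)
    if feats.shape[-1] != len(model.feature_names):
        raise ValueError("feature stack does not match the model's specification")
    pred = model.estimator.predict(feats.reshape(-1, feats.shape[-1]))
    labels = pred.reshape(image.shape[:2]).astype(np.uint8)
    return TissueMap(labels=labels)


def evaluate_pixel_accuracy(predicted, truth) -> tuple[float, pd.DataFrame]:
    """Pixel accuracy plus a truth-by-prediction confusion table."""
    pred = np.asarray(getattr(predicted, "labels", predicted))
    true = np.asarray(getattr(truth, "class_mask", truth))
    if pred.shape != true.shape:
        raise ValueError("dimension mismatch between prediction and truth")
    classes = sorted(CLASS_NAMES)
    table = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for i, t in enumerate(classes):
        row_mask = true == t
        for j, p in enumerate(classes):
            table[i, j] = int((row_mask & (pred == p)).sum())
    names = [CLASS_NAMES[c] for c in classes]
    confusion = pd.DataFrame(table, index=names, columns=names)
    accuracy = float(np.trace(table) / table.sum())
    return accuracy, confusion
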