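"""Whole-slide tissue classification and prediction-map assembly.

The first pipeline step tiles a slide into patches, classifies each patch as
PanNET, NNPP, or stroma, and assembles the labels into a prediction map — a
grid with one tissue label per patch position — from which the largest tumor
region of interest is later extracted. Patches with too little tissue are
mapped to background.

The classifier is a contract (`TissueClassifier`): anything that maps a
patch to a (label, probability-triple) pair works. The reference
implementation reduces each patch image to color/texture summary features
and fits a multinomial logistic regression with inverse-frequency sample
weights; it also accepts precomputed feature vectors directly, so the
pipeline runs on either pixels or feature tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .labels import BACKGROUND, NNPP, PANNET, STROMA, TISSUE_NAMES

__all__ = [
    "PredictionMap",
    "TissueClassifier",
    "FeatureTissueClassifier",
    "patch_features",
    "tile_slide",
    "normalize_stain",
    "train_tissue_classifier",
    "build_prediction_map",
    "write_prediction_map",
    "read_prediction_map",
]

TISSUE_CLASSES = (PANNET, NNPP, STROMA)


@dataclass
class PredictionMap:
    """Grid of per-patch tissue labels for one slide."""

    grid: np.ndarray  # (rows, cols) int labels
    patch_size: int
    slide_id: str = ""
    probabilities: Optional[np.ndarray] = None  # (rows, cols, 3) over tissue classes

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (*self.grid.shape, 3):
                raise ValueError("probabilities shape mismatch")
            sums = p.sum(axis=-1)
            fg = self.grid != BACKGROUND
            if fg.any() and np.max(np.abs(sums[fg] - 1.0)) > 1e-6:
                raise ValueError("probability triples must sum to 1")
            self.probabilities = p

    @property
    def shape(self) -> Tuple[int, int]:
        return tuple(self.grid.shape)


class TissueClassifier:
    """Contract for the three-class patch classifier.

    ``predict`` maps one patch (image array or feature vector) to a
    (label, probability triple) pair with labels restricted to PanNET,
    NNPP, stroma; inference is deterministic for a fixed fitted state.
    """

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[int]):
        raise NotImplementedError

    def predict(self, patch: np.ndarray) -> Tuple[int, np.ndarray]:
        raise NotImplementedError


def patch_features(patch: np.ndarray) -> np.ndarray:
    """Reduce an RGB patch to an 8-dim color/texture summary.

    Per-channel mean and std, luminance mean, and mean absolute local
    luminance gradient. A 1-D input is passed through unchanged, so feature
    tables satisfy the same interface as pixel patches.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 1:
        return patch
    lum = patch.mean(axis=-1) if patch.ndim == 3 else patch
    chans = patch.reshape(-1, patch.shape[-1]) if patch.ndim == 3 \
        else patch.reshape(-1, 1)
    grad = np.abs(np.diff(lum, axis=0)).mean() if lum.shape[0] > 1 else 0.0
    return np.concatenate([
        chans.mean(axis=0), chans.std(axis=0), [lum.mean()], [grad]
    ])


class FeatureTissueClassifier(TissueClassifier):
    """Logistic-regression tissue classifier over patch summary features.

    Class imbalance is handled with inverse-frequency sample weights; the
    fit is seeded and deterministic.
    """

    def __init__(self, seed: int = 0, max_iter: int = 500):
        self.seed = seed
        self.max_iter = max_iter
        self._model: Optional[LogisticRegression] = None
        self._classes: Optional[np.ndarray] = None

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[int]):
        X = np.stack([patch_features(p) for p in patches])
        y = np.asarray(labels)
        uniq, counts = np.unique(y, return_counts=True)
        if len(uniq) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if not set(uniq) <= set(TISSUE_CLASSES):
            raise ValueError(f"labels must be tissue classes, got {uniq}")
        inv = {u: len(y) / (len(uniq) * c) for u, c in zip(uniq, counts)}
        w = np.array([inv[v] for v in y])
        self._model = LogisticRegression(max_iter=self.max_iter,
                                         random_state=self.seed)
        self._model.fit(X, y, sample_weight=w)
        self._classes = self._model.classes_
        return self

    def predict(self, patch: np.ndarray) -> Tuple[int, np.ndarray]:
        if self._model is None:
            raise RuntimeError("classifier not fitted")
        x = patch_features(patch)[None, :]
        proba = self._model.predict_proba(x)[0]
        # expand to the full 3-class triple in TISSUE_CLASSES order
        triple = np.zeros(3)
        for p, cls in zip(proba, self._classes):
            triple[TISSUE_CLASSES.index(int(cls))] = p
        label = TISSUE_CLASSES[int(np.argmax(triple))]
        return label, triple


def tile_slide(
    image: np.ndarray,
    patch_size: int,
    tissue_threshold: float = 0.1,
    white_luminance: float = 0.9,
) -> List[Tuple[Tuple[int, int], np.ndarray]]:
    """Cut a slide image into a patch grid, keeping tissue-bearing tiles.

    Trailing partial tiles are dropped. A tile is emitted only when its
    fraction of non-white pixels (luminance <= ``white_luminance``, on a
    0-1 scale) is at least ``tissue_threshold``; the rest are background.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        warnings.warn("empty slide image", stacklevel=2)
        return []
    if image.max() > 1.5:  # 8-bit input
        image = image / 255.0
    rows = image.shape[0] // patch_size
    cols = image.shape[1] // patch_size
    tiles = []
    for r in range(rows):
        for c in range(cols):
            tile = image[r * patch_size:(r + 1) * patch_size,
                         c * patch_size:(c + 1) * patch_size]
            lum = tile.mean(axis=-1) if tile.ndim == 3 else tile
            if (lum <= white_luminance).mean() >= tissue_threshold:
                tiles.append(((r, c), tile))
    return tiles


def normalize_stain(patch: np.ndarray, reference: Dict[str, np.ndarray]
                    ) -> np.ndarray:
    """Reinhard-style color normalization toward reference LAB statistics.

    ``reference`` holds per-channel "mean" and "std" in CIELAB. Channels
    with (near-)zero variance in the input pass through unchanged, so a
    constant-color patch is returned as-is. Idempotent when the input
    already matches the reference.
    """
    from skimage import color

    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3 or patch.shape[-1] != 3:
        raise ValueError("normalize_stain expects an RGB image")
    scaled = patch / 255.0 if patch.max() > 1.5 else patch
    lab = color.rgb2lab(np.clip(scaled, 0, 1))
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std < 1e-6):
        warnings.warn("zero-variance channel; stain normalization skipped",
                      stacklevel=2)
        return patch
    out = (lab - mean) / std * np.asarray(reference["std"]) \
        + np.asarray(reference["mean"])
    rgb = np.clip(color.lab2rgb(out), 0.0, 1.0)
    return rgb * 255.0 if patch.max() > 1.5 else rgb


def lab_statistics(patch: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-channel CIELAB mean/std of a patch, for use as a stain reference."""
    from skimage import color

    patch = np.asarray(patch, dtype=float)
    scaled = patch / 255.0 if patch.max() > 1.5 else patch
    lab = color.rgb2lab(np.clip(scaled, 0, 1)).reshape(-1, 3)
    return {"mean": lab.mean(axis=0), "std": lab.std(axis=0)}


def train_tissue_classifier(
    patches: Sequence[np.ndarray],
    labels: Sequence[int],
    seed: int = 0,
) -> TissueClassifier:
    """Fit the reference tissue classifier on labeled patches (or features)."""
    return FeatureTissueClassifier(seed=seed).fit(patches, labels)


def build_prediction_map(
    classifier: TissueClassifier,
    tiles: Sequence[Tuple[Tuple[int, int], np.ndarray]],
    grid_shape: Tuple[int, int],
    patch_size: int = 256,
    slide_id: str = "",
) -> PredictionMap:
    """Classify every tile and assemble the slide's prediction map.

    Grid positions without a tile stay background with a zero probability
    triple.
    """
    grid = np.full(grid_shape, BACKGROUND, dtype=np.int64)
    probs = np.zeros((*grid_shape, 3))
    for (r, c), tile in tiles:
        label, triple = classifier.predict(tile)
        grid[r, c] = label
        probs[r, c] = triple
    return PredictionMap(grid=grid, patch_size=patch_size, slide_id=slide_id,
                         probabilities=probs)


# ---------------------------------------------------------------------------
# Lossless TSV + JSON-sidecar round trip


def write_prediction_map(pmap: PredictionMap, tsv_path, sidecar_path=None
                         ) -> None:
    sidecar_path = sidecar_path or str(tsv_path) + ".json"
    np.savetxt(tsv_path, pmap.grid, fmt="%d", delimiter="\t")
    meta = {
        "slide_id": pmap.slide_id,
        "grid_shape": list(pmap.grid.shape),
        "patch_size": pmap.patch_size,
        "label_legend": {str(k): v for k, v in TISSUE_NAMES.items()},
    }
    if pmap.probabilities is not None:
        meta["probabilities"] = pmap.probabilities.tolist()
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh)


def read_prediction_map(tsv_path, sidecar_path=None) -> PredictionMap:
    sidecar_path = sidecar_path or str(tsv_path) + ".json"
    grid = np.loadtxt(tsv_path, dtype=np.int64, delimiter="\t", ndmin=2)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if list(grid.shape) != meta["grid_shape"]:
        raise ValueError("grid shape does not match sidecar")
    probs = meta.get("probabilities")
    return PredictionMap(
        grid=grid, patch_size=int(meta["patch_size"]),
        slide_id=meta.get("slide_id", ""),
        probabilities=np.asarray(probs) if probs is not None else None)
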