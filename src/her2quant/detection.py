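"""Tumor-tile detection: a pluggable patch classifier and probability map.

A slide's tissue tiles are classified tumor vs non-tumor; the per-tile
probabilities form a probability map that is thresholded into a tumor mask.
The classifier is a contract (batch of square 8-bit RGB patches -> tumor
probabilities in [0, 1]) with three backends:

* ``heuristic`` - a fixed logistic over three color statistics (mean
  saturation, mean value, DAB-pixel fraction); dependency-free, no training;
* ``mlp`` - a scikit-learn multilayer perceptron over a richer color/stain
  feature vector, trained with SGD (lr 0.01, momentum 0.9, minibatch 64,
  50 epochs by default);
* ``external`` - any pickled estimator with ``predict_proba`` over the same
  features, loaded from a checkpoint.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cells import BrownRange, extract_dab_mask
from .errors import InvalidInputError
from .stains import deconvolve
from .types import BinaryMask, ProbMap, RgbImage, TileGrid

AUGMENTATIONS = ("identity", "rot90", "rot180", "rot270", "hflip", "vflip")


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the pipeline's reference
    setup: SGD, learning rate 0.01, momentum 0.9, cross-entropy, 50 epochs,
    minibatch 64, 9:1 train/validation split)."""

    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    loss: str = "cross_entropy"
    epochs: int = 50
    batch_size: int = 64
    split_ratio: float = 0.9
    augmentations: tuple[str, ...] = ("rot90", "rot180", "rot270", "hflip", "vflip")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise InvalidInputError("split_ratio must lie in (0, 1)")
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise InvalidInputError(f"unknown augmentations {unknown}")


def split_dataset(
    n_items: int, ratio: float, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled, disjoint, exhaustive train/validation index split.

    ``|train| = round(n_items * ratio)`` (half away from zero), e.g.
    16,000 at 0.9 gives 14,400/1,600.
    """
    if not 0.0 < ratio < 1.0:
        raise InvalidInputError("ratio must lie in (0, 1)")
    if n_items < 2:
        raise InvalidInputError("need at least two items to split")
    n_train = int(math.floor(n_items * ratio + 0.5))
    n_train = min(max(n_train, 1), n_items - 1)
    perm = np.random.default_rng(rng_seed).permutation(n_items)
    return perm[:n_train], perm[n_train:]


def augment_patch(patch: RgbImage | np.ndarray, op: str) -> np.ndarray:
    """Lossless dihedral augmentation (90-degree rotations and axis flips)."""
    pixels = patch.pixels if isinstance(patch, RgbImage) else np.asarray(patch)
    if op not in AUGMENTATIONS:
        raise InvalidInputError(f"unknown augmentation {op!r}")
    if op in ("rot90", "rot270") and pixels.shape[0] != pixels.shape[1]:
        raise InvalidInputError("90/270 rotation requires a square patch")
    if op == "identity":
        return pixels.copy()
    if op == "rot90":
        return np.rot90(pixels, 1).copy()
    if op == "rot180":
        return np.rot90(pixels, 2).copy()
    if op == "rot270":
        return np.rot90(pixels, 3).copy()
    if op == "hflip":
        return pixels[:, ::-1].copy()
    return pixels[::-1, :].copy()  # vflip


# ---------------------------------------------------------------------------
# feature extraction shared by the classifier backends


def _basic_features(pixels: np.ndarray, brown: BrownRange) -> tuple[float, float, float]:
    hsv = rgb2hsv(pixels)
    dab_frac = float(extract_dab_mask(pixels, brown, closing_radius=0).mean())
    return float(hsv[..., 1].mean()), float(hsv[..., 2].mean()), dab_frac


def feature_vector(pixels: np.ndarray, brown: BrownRange | None = None) -> np.ndarray:
    """Color/stain summary features for the trainable backends."""
    brown = brown or BrownRange()
    hsv = rgb2hsv(pixels)
    mean_s, mean_v, dab_frac = _basic_features(pixels, brown)
    maps = deconvolve(pixels)
    h, d = maps.h_map, maps.dab_map
    return np.array(
        [
            mean_s,
            mean_v,
            dab_frac,
            float(hsv[..., 1].std()),
            float(hsv[..., 2].std()),
            float(h.mean()),
            float((h > 0.3).mean()),  # nucleus-pixel fraction
            float(d.mean()),
            float(d.max()),
        ]
    )


class PatchClassifier:
    """Contract: batch of square 8-bit RGB patches -> tumor probabilities."""

    backend = "abstract"
    metadata: dict

    def predict_proba(self, patches, coords=None) -> np.ndarray:
        raise NotImplementedError


class HeuristicClassifier(PatchClassifier):
    """Deterministic logistic over (mean S, mean V, DAB-pixel fraction).

    Coefficients were set from the closed-form color model: nuclei and
    tissue tint carry saturation, DAB carries brown pixels, background is
    white, so tumor-bearing (cell-dense or stained) tiles score high.
    No training; useful as a dependency-free default and test backend.
    """

    backend = "heuristic"

    def __init__(
        self,
        weights: tuple[float, float, float] = (80.0, -2.0, 300.0),
        bias: float = 0.6,
        brown: BrownRange | None = None,
    ):
        self.weights = np.asarray(weights, float)
        self.bias = float(bias)
        self.brown = brown or BrownRange()
        self.metadata = {"backend": self.backend, "weights": list(weights), "bias": bias}

    def predict_proba(self, patches, coords=None) -> np.ndarray:
        out = np.empty(len(patches))
        for i, p in enumerate(patches):
            pixels = p.pixels if isinstance(p, RgbImage) else np.asarray(p)
            f = np.array(_basic_features(pixels, self.brown))
            out[i] = 1.0 / (1.0 + np.exp(-(f @ self.weights + self.bias)))
        return out


class SklearnPatchClassifier(PatchClassifier):
    """Trainable backend: sklearn estimator over :func:`feature_vector`."""

    backend = "mlp"

    def __init__(self, model, metadata: dict | None = None):
        self.model = model
        self.metadata = metadata or {"backend": self.backend}

    def predict_proba(self, patches, coords=None) -> np.ndarray:
        feats = np.vstack(
            [
                feature_vector(p.pixels if isinstance(p, RgbImage) else np.asarray(p))
                for p in patches
            ]
        )
        return self.model.predict_proba(feats)[:, 1]

    def save(self, path) -> None:
        import joblib

        joblib.dump({"model": self.model, "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path) -> "SklearnPatchClassifier":
        import joblib

        payload = joblib.load(Path(path))
        obj = cls(payload["model"], payload.get("metadata"))
        obj.backend = obj.metadata.get("backend", "external")
        return obj


class OracleClassifier(PatchClassifier):
    """Ground-truth lookup by tile origin; for tests and ablations."""

    backend = "oracle"

    def __init__(self, tumor_origins: set[tuple[int, int]], tile_size: int):
        self.tumor_origins = set(tumor_origins)
        self.tile_size = tile_size
        self.metadata = {"backend": self.backend}

    def predict_proba(self, patches, coords=None) -> np.ndarray:
        if coords is None:
            raise InvalidInputError("oracle classifier needs tile coordinates")
        return np.array(
            [1.0 if tuple(c) in self.tumor_origins else 0.0 for c in coords]
        )


def train_classifier(
    patches,
    labels,
    config: TrainConfig | None = None,
) -> SklearnPatchClassifier:
    """Train the MLP backend on labeled patches (1 = tumor).

    Splits 9:1 by default, fits with SGD + momentum, and records the loss
    curve and validation accuracy in ``metadata``.
    """
    config = config or TrainConfig()
    if len(patches) == 0:
        raise InvalidInputError("empty patch list")
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training data must contain both classes")
    feats = np.vstack(
        [
            feature_vector(p.pixels if isinstance(p, RgbImage) else np.asarray(p))
            for p in patches
        ]
    )
    tr, va = split_dataset(len(y), config.split_ratio, config.rng_seed)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(32,),
                    solver="sgd",
                    learning_rate_init=config.learning_rate,
                    momentum=config.momentum,
                    nesterovs_momentum=False,
                    batch_size=min(config.batch_size, len(tr)),
                    max_iter=config.epochs,
                    random_state=config.rng_seed,
                ),
            ),
        ]
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at small epoch counts
        model.fit(feats[tr], y[tr])
    val_acc = float((model.predict(feats[va]) == y[va]).mean())
    meta = {
        "backend": "mlp",
        "train_config": vars(config) | {"augmentations": list(config.augmentations)},
        "n_train": int(len(tr)),
        "n_validation": int(len(va)),
        "validation_accuracy": val_acc,
        "loss_curve": [float(v) for v in model.named_steps["mlp"].loss_curve_],
    }
    return SklearnPatchClassifier(model, meta)


def probability_map(
    slide,
    grid: TileGrid,
    clf: PatchClassifier,
    batch_size: int = 64,
    level: int = 0,
) -> ProbMap:
    """One tumor probability per admissible tile; NaN elsewhere.

    Values are independent of tile evaluation order and batch size.
    """
    nr, nc = grid.index_shape()
    values = np.full((nr, nc), np.nan)
    origins = grid.origins()
    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        patches = [slide.read_region(o, grid.tile_size, level=level) for o in chunk]
        try:
            probs = clf.predict_proba(patches, coords=chunk)
        except InvalidInputError:
            raise
        except Exception as exc:  # attach tile coordinates to backend failures
            raise RuntimeError(f"classifier failed on tiles {chunk}: {exc}") from exc
        for (r, c), p in zip(chunk, probs):
            values[r // grid.tile_size, c // grid.tile_size] = p
    return ProbMap(values=values, tile_size=grid.tile_size)


def binarize_map(pmap: ProbMap, threshold: float = 0.5) -> BinaryMask:
    """Tile-level tumor mask: probability >= threshold (NaN tiles are False)."""
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isnan(pmap.values), False, pmap.values >= threshold)
    return BinaryMask(mask.astype(bool))
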