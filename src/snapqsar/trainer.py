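"""Image-classifier training harness with pluggable backbones.

Training consumes the image-folder layout written by the snapshot stage
(``<split>/<label>/<molid>_<rx>_<ry>_<rz>.png``), runs a fixed number of
epochs (default 30) and records training loss, validation loss and
validation accuracy each epoch; the reporting model is the epoch with the
minimum validation loss (earliest epoch on ties). The backbone sits behind a
named registry: the default, ``mlp-small``, is a small multilayer perceptron
over downscaled pixels sized for CPU-minute training; a large pretrained
convolutional network can be registered under another name without touching
the harness.

Runs are deterministic under a seed: weight initialization, minibatch
shuffling and therefore the whole loss history repeat exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .snapshot import load_image

__all__ = [
    "TrainConfig",
    "TrainRun",
    "BACKBONES",
    "register_backbone",
    "train_classifier",
    "select_best_epoch",
    "predict_images",
    "save_model",
    "load_model",
    "load_image_folder",
    "featurize_images",
]

#: Class-name convention: the "active" folder is the positive class.
POSITIVE_LABEL = "active"

_SOLVERS = {"sgd", "nag", "adam"}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    epochs: full passes over the training set (default 30).
    lr: initial learning rate. batch_size: minibatch size.
    solver: one of sgd / nag (Nesterov momentum) / adam.
    backbone: registry name of the network builder.
    input_px: images are downscaled to input_px x input_px RGB before the
    backbone sees them (the default backbone is a pixel MLP).
    hidden: hidden-layer widths of the default backbone.
    """

    epochs: int = 30
    lr: float = 0.01
    batch_size: int = 16
    solver: str = "sgd"
    backbone: str = "mlp-small"
    input_px: int = 24
    hidden: tuple[int, ...] = (64,)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.solver not in _SOLVERS:
            raise ValueError(
                f"solver {self.solver!r} is not supported by the default "
                f"backbone (choose from {sorted(_SOLVERS)})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "hidden" in raw:
            raw["hidden"] = tuple(raw["hidden"])
        return cls(**raw)


@dataclass
class TrainRun:
    """Per-epoch history and the selected reporting epoch."""

    backbone: str
    epochs: int
    history: list[dict] = field(default_factory=list)
    selected_epoch: int = -1
    seed: int = 0

    def val_losses(self) -> list[float]:
        return [h["val_loss"] for h in self.history]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.history).to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# backbone registry
# ---------------------------------------------------------------------------

BACKBONES: dict[str, Callable[[TrainConfig, int], object]] = {}


def register_backbone(name: str):
    def deco(fn):
        BACKBONES[name] = fn
        return fn

    return deco


@register_backbone("mlp-small")
def _mlp_small(config: TrainConfig, seed: int):
    solver = "adam" if config.solver == "adam" else "sgd"
    return MLPClassifier(
        hidden_layer_sizes=config.hidden,
        solver=solver,
        learning_rate_init=config.lr,
        momentum=0.9,
        nesterovs_momentum=(config.solver == "nag"),
        random_state=int(seed) % (2**31 - 1),
        max_iter=1,
        warm_start=False,
    )


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

def _prep(img: np.ndarray, input_px: int) -> np.ndarray:
    """Downscale an RGB uint8 image and flatten to a [0, 1] float vector."""
    im = Image.fromarray(img, mode="RGB").resize(
        (input_px, input_px), Image.Resampling.BILINEAR
    )
    return np.asarray(im, dtype=np.float64).ravel() / 255.0


def featurize_images(images: Sequence[np.ndarray], config: TrainConfig) -> list[np.ndarray]:
    """Apply the backbone's input preprocessing to raw RGB uint8 images."""
    return [_prep(np.asarray(im, dtype=np.uint8), config.input_px) for im in images]


def load_image_folder(
    folder: str | Path, input_px: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load ``folder/<label>/*.png`` into (X, y, image names).

    The positive class is the ``active`` directory when present, otherwise
    the lexicographically last class directory. All images must share one
    pixel size.
    """
    folder = Path(folder)
    classes = sorted(p.name for p in folder.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"no class directories under {folder}")
    positive = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[-1]
    xs, ys, names = [], [], []
    size_seen: tuple[int, int] | None = None
    for cls in classes:
        for png in sorted((folder / cls).glob("*.png")):
            img = load_image(png)
            if size_seen is None:
                size_seen = img.shape[:2]
            elif img.shape[:2] != size_seen:
                raise ValueError(
                    f"image size mismatch: {png.name} is {img.shape[:2]}, "
                    f"expected {size_seen}"
                )
            xs.append(_prep(img, input_px))
            ys.append(1 if cls == positive else 0)
            names.append(f"{cls}/{png.name}")
    if not xs:
        raise ValueError(f"no images under {folder}")
    return np.vstack(xs), np.asarray(ys, dtype=int), names


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_classifier(
    train_images: str | Path | tuple[np.ndarray, np.ndarray],
    val_images: str | Path | tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[TrainRun, dict]:
    """Train a snapshot classifier and select the min-val-loss epoch.

    ``train_images`` / ``val_images`` are labeled image folders (or
    pre-featurized ``(X, y)`` pairs). Returns the run history and a model
    artifact dict; the artifact holds the weights of the selected epoch and
    can be saved/loaded with :func:`save_model` / :func:`load_model`.
    """
    config = config or TrainConfig()
    X_tr, y_tr = _coerce(train_images, config)
    X_va, y_va = _coerce(val_images, config)
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if len(set(y_tr.tolist())) < 2:
        raise ValueError("training folder contains a single class")
    if config.backbone not in BACKBONES:
        raise KeyError(f"unknown backbone {config.backbone!r}")

    # standardize features on training statistics: pixel vectors are
    # background-dominated and badly conditioned for SGD otherwise
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd[sd < 1e-8] = 1.0
    X_tr = (X_tr - mu) / sd
    X_va = (X_va - mu) / sd

    model = BACKBONES[config.backbone](config, seed)
    rng = np.random.default_rng(seed)
    classes = np.array([0, 1])
    run = TrainRun(backbone=config.backbone, epochs=config.epochs, seed=seed)
    best: tuple[float, int] | None = None
    best_state = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            model.partial_fit(X_tr[idx], y_tr[idx], classes=classes)
        tr_loss = log_loss(y_tr, model.predict_proba(X_tr), labels=classes)
        va_prob = model.predict_proba(X_va)
        va_loss = log_loss(y_va, va_prob, labels=classes)
        va_acc = float(np.mean(np.argmax(va_prob, axis=1) == y_va))
        run.history.append(
            {
                "epoch": epoch,
                "train_loss": float(tr_loss),
                "val_loss": float(va_loss),
                "val_accuracy": va_acc,
            }
        )
        if best is None or va_loss < best[0]:
            best = (va_loss, epoch)
            best_state = (
                copy.deepcopy(model.coefs_),
                copy.deepcopy(model.intercepts_),
            )
    run.selected_epoch = select_best_epoch(run.val_losses())
    model.coefs_, model.intercepts_ = best_state
    artifact = {
        "model": model,
        "config": config,
        "scaler": (mu, sd),
        "selected_epoch": run.selected_epoch,
        "seed": int(seed),
    }
    return run, artifact


def select_best_epoch(val_losses: Sequence[float]) -> int:
    """Index of the minimum validation loss; ties go to the earliest epoch."""
    if len(val_losses) == 0:
        raise ValueError("empty validation-loss history")
    return int(np.argmin(np.asarray(val_losses, dtype=float)))


def predict_images(artifact: dict, images: Sequence) -> list[float]:
    """Active-class probability for each image (arrays or PNG paths)."""
    if len(images) == 0:
        return []
    config: TrainConfig = artifact["config"]
    xs = []
    size_seen = None
    for im in images:
        arr = load_image(im) if isinstance(im, (str, Path)) else np.asarray(im)
        if size_seen is None:
            size_seen = arr.shape[:2]
        elif arr.shape[:2] != size_seen:
            raise ValueError("image size mismatch in prediction batch")
        xs.append(_prep(arr.astype(np.uint8), config.input_px))
    X = np.vstack(xs)
    mu, sd = artifact["scaler"]
    probs = artifact["model"].predict_proba((X - mu) / sd)[:, 1]
    return [float(p) for p in probs]


def save_model(artifact: dict, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(artifact, path)
    return path


def load_model(path: str | Path) -> dict:
    return joblib.load(path)


def _coerce(src, config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(src, (str, Path)):
        X, y, _names = load_image_folder(src, config.input_px)
        return X, y
    X, y = src
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
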