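"""Colony classifier: dataset handling, CNN building, training, persistence.

Maps cropped plate images to species probabilities.  Datasets follow the
one-subdirectory-per-species layout; the label order is the sorted
subdirectory order and fixes the model's output-index mapping.  Training
uses label-preserving augmentation (rotation, shift, zoom, flips,
brightness), monitors validation loss with early stopping, and keeps the
best-validation-loss weights (checkpointing).  Models round-trip through
HDF5 containers that carry the class-label list as metadata.

Two backbones are available: ``small_cnn`` — three conv/pool blocks
(16-32-64 filters) feeding global average pooling and a dense head — and
``vgg16`` — the 13-conv VGG16 topology (64-64 / 128-128 / 256x3 / 512x3 /
512x3) with the same pooled head, randomly initialized, optionally frozen
so only the head trains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from PIL import Image
from scipy import ndimage

from .nn import (
    Adam,
    Conv2D,
    Dense,
    GlobalAveragePooling,
    InputCenter,
    MaxPool2,
    ReLU,
    Sequential,
    load_weights_h5,
    save_weights_h5,
)

__all__ = [
    "DatasetError",
    "ModelFormatError",
    "LabeledDataset",
    "ModelConfig",
    "AugmentationConfig",
    "TrainingConfig",
    "TrainingHistory",
    "ClassProbabilities",
    "SpeciesClassifier",
    "load_dataset",
    "build_model",
    "augment_batch",
    "train_model",
    "train_on_arrays",
    "predict",
    "save_model",
    "load_model",
]


class DatasetError(ValueError):
    """Raised for malformed dataset directory trees."""


class ModelFormatError(ValueError):
    """Raised when a model file is missing, truncated, or inconsistent."""


IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class LabeledDataset:
    """Species-labelled image collection backed by a directory tree."""

    root: Path
    labels: list[str]
    files: dict[str, list[Path]]
    input_size: tuple[int, int]

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.files.values())

    def class_counts(self) -> dict[str, int]:
        return {lab: len(self.files[lab]) for lab in self.labels}

    def all_items(self) -> list[tuple[Path, str]]:
        """(path, label) pairs in deterministic label-then-name order."""
        return [(p, lab) for lab in self.labels for p in self.files[lab]]

    def load_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Load every image resized to ``input_size``, scaled to [0, 1].

        Returns (X, y) with X of shape (n, h, w, 3) float64 and y integer
        label indices in label order.
        """
        h, w = self.input_size
        items = self.all_items()
        x = np.empty((len(items), h, w, 3))
        y = np.empty(len(items), dtype=np.int64)
        index = {lab: i for i, lab in enumerate(self.labels)}
        for i, (path, lab) in enumerate(items):
            x[i] = load_image_array(path, (h, w))
            y[i] = index[lab]
        return x, y


def load_image_array(path: str | Path, size: tuple[int, int]) -> np.ndarray:
    """Read an image file as RGB, resize bilinearly, scale to [0, 1]."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((size[1], size[0]), Image.BILINEAR)
            return np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, SyntaxError) as exc:
        raise DatasetError(f"unreadable image file {path}: {exc}") from exc


def load_dataset(root: str | Path, input_size: tuple[int, int] = (64, 64)) -> LabeledDataset:
    """Scan a one-subdirectory-per-species tree into a LabeledDataset.

    Labels are the sorted subdirectory names; within a class, files are
    sorted by name, so re-loading yields an identical ordering.
    """
    root = Path(root)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise DatasetError(
            f"need at least 2 class subdirectories under {root}, found {len(class_dirs)}"
        )
    files: dict[str, list[Path]] = {}
    for d in class_dirs:
        imgs = sorted(
            p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not imgs:
            raise DatasetError(f"class directory {d} contains no images")
        files[d.name] = imgs
    return LabeledDataset(
        root=root,
        labels=[d.name for d in class_dirs],
        files=files,
        input_size=tuple(input_size),
    )


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    input_size: tuple[int, int] = (64, 64)
    n_classes: int = 2
    backbone_frozen: bool = False  # vgg16 only
    hidden_units: int = 64

    def __post_init__(self) -> None:
        if self.backbone not in ("small_cnn", "vgg16"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if min(self.input_size) < 32:
            raise ValueError("input_size must be at least 32x32")


@dataclass(frozen=True)
class AugmentationConfig:
    """Label-preserving random transforms applied per training sample."""

    rotation_range: float = 20.0  # degrees
    width_shift: float = 0.1  # fraction of width
    height_shift: float = 0.1  # fraction of height
    zoom_range: float = 0.1  # fraction
    horizontal_flip: bool = True
    vertical_flip: bool = True
    brightness_jitter: float = 0.1  # fraction

    def __post_init__(self) -> None:
        if min(self.rotation_range, self.width_shift, self.height_shift,
               self.zoom_range, self.brightness_jitter) < 0:
            raise ValueError("augmentation ranges must be >= 0")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stopping_patience: int | None = None  # None -> never stop early
    checkpoint_path: str | None = None
    seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.early_stopping_patience is None:
            object.__setattr__(self, "early_stopping_patience", self.epochs)
        if not 1 <= self.early_stopping_patience <= self.epochs:
            raise ValueError("patience must be in [1, epochs]")


@dataclass
class TrainingHistory:
    """Per-epoch series; early stopping may leave fewer rows than epochs."""

    accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accuracy)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,accuracy,loss,val_accuracy,val_loss\n")
            for i in range(len(self)):
                fh.write(
                    f"{i + 1},{self.accuracy[i]:.6f},{self.loss[i]:.6f},"
                    f"{self.val_accuracy[i]:.6f},{self.val_loss[i]:.6f}\n"
                )


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax output mapped back to species labels."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-5:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities.values()):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def predicted_label(self) -> str:
        # max probability; ties resolved by label (insertion == label) order
        best, best_p = None, -1.0
        for lab, p in self.probabilities.items():
            if p > best_p:
                best, best_p = lab, p
        return best


@dataclass
class SpeciesClassifier:
    """A trained (or trainable) network plus its label mapping and config."""

    network: Sequential
    labels: list[str]
    config: ModelConfig


def _conv_block(c_in: int, c_out: int, n_convs: int, rng) -> list:
    layers = []
    for i in range(n_convs):
        layers += [Conv2D(c_in if i == 0 else c_out, c_out, 3, rng=rng), ReLU()]
    layers.append(MaxPool2())
    return layers


def build_model(config: ModelConfig, seed: int = 0) -> SpeciesClassifier:
    """Construct an untrained classifier with seeded He initialization.

    ``small_cnn``: conv16-pool / conv32-pool / conv64-pool → GAP → dense →
    softmax head.  ``vgg16``: the standard 13-conv topology; with
    ``backbone_frozen`` the convolutional stack is excluded from updates.
    """
    rng = np.random.default_rng(seed)
    if config.backbone == "small_cnn":
        backbone = (
            _conv_block(3, 16, 1, rng)
            + _conv_block(16, 32, 1, rng)
            + _conv_block(32, 64, 1, rng)
        )
        feat = 64
    else:  # vgg16
        backbone = (
            _conv_block(3, 64, 2, rng)
            + _conv_block(64, 128, 2, rng)
            + _conv_block(128, 256, 3, rng)
            + _conv_block(256, 512, 3, rng)
            + _conv_block(512, 512, 3, rng)
        )
        feat = 512
    if config.backbone_frozen and config.backbone == "vgg16":
        for layer in backbone:
            layer.trainable = False
    head = [
        GlobalAveragePooling(),
        Dense(feat, config.hidden_units, rng=rng),
        ReLU(),
        Dense(config.hidden_units, config.n_classes, rng=rng),
    ]
    return SpeciesClassifier(
        network=Sequential([InputCenter()] + backbone + head),
        labels=[f"class_{i}" for i in range(config.n_classes)],
        config=config,
    )


def _affine_params(acfg: AugmentationConfig, rng: np.random.Generator):
    angle = rng.uniform(-acfg.rotation_range, acfg.rotation_range)
    tx = rng.uniform(-acfg.width_shift, acfg.width_shift)
    ty = rng.uniform(-acfg.height_shift, acfg.height_shift)
    zoom = 1.0 + rng.uniform(-acfg.zoom_range, acfg.zoom_range)
    hflip = acfg.horizontal_flip and rng.random() < 0.5
    vflip = acfg.vertical_flip and rng.random() < 0.5
    bright = 1.0 + rng.uniform(-acfg.brightness_jitter, acfg.brightness_jitter)
    return angle, tx, ty, zoom, hflip, vflip, bright


def augment_batch(
    x: np.ndarray, acfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply an independent random rotation/shift/zoom/flip/brightness to
    each sample.  Labels are untouched by construction — every transform is
    geometric or photometric, never class-changing."""
    out = np.empty_like(x)
    h, w = x.shape[1:3]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    for i in range(x.shape[0]):
        angle, tx, ty, zoom, hflip, vflip, bright = _affine_params(acfg, rng)
        theta = np.deg2rad(angle)
        # output->input mapping: rotate by -theta and unscale about center,
        # then undo the translation
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        ) / zoom
        center = np.array([cy, cx])
        shift = np.array([ty * h, tx * w])
        offset = center - rot @ (center - shift)
        img = x[i]
        if hflip:
            img = img[:, ::-1, :]
        if vflip:
            img = img[::-1, :, :]
        for ch in range(3):
            out[i, :, :, ch] = ndimage.affine_transform(
                img[:, :, ch], rot, offset=offset, order=1, mode="nearest"
            )
        out[i] = np.clip(out[i] * bright, 0.0, 1.0)
    return out


def _stratified_val_split(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_ids, val_ids = [], []
    for cls in np.unique(y):
        ids = np.nonzero(y == cls)[0]
        perm = rng.permutation(ids)
        if len(ids) < 2:
            raise DatasetError(
                f"class {cls} has {len(ids)} item(s); need >= 2 to hold out "
                "a validation sample"
            )
        # at least one validation item per class, and at least one left to train
        n_val = min(len(ids) - 1, max(1, int(round(val_fraction * len(ids)))))
        val_ids.extend(perm[:n_val])
        train_ids.extend(perm[n_val:])
    return np.sort(np.array(train_ids)), np.sort(np.array(val_ids))


def train_model(
    model: SpeciesClassifier,
    dataset: LabeledDataset,
    tcfg: TrainingConfig,
    validation_fraction: float = 0.2,
) -> tuple[SpeciesClassifier, TrainingHistory]:
    """Train with augmented mini-batches, early stopping and checkpointing.

    The cross-entropy objective is minimized with Adam; a stratified
    ``validation_fraction`` of the dataset is held out and its loss is
    monitored every epoch.  Training stops when validation loss fails to
    improve for ``early_stopping_patience`` epochs, and the weights with the
    lowest validation loss are restored (and written to ``checkpoint_path``
    if one is set).  One integer seed drives the split, shuffling, and
    augmentation sampling.
    """
    if dataset.n_classes != model.config.n_classes:
        raise DatasetError(
            f"dataset has {dataset.n_classes} classes but model expects "
            f"{model.config.n_classes}"
        )
    model.labels = list(dataset.labels)
    x, y = dataset.load_arrays()
    return train_on_arrays(model, x, y, tcfg, validation_fraction)


def train_on_arrays(
    model: SpeciesClassifier,
    x: np.ndarray,
    y: np.ndarray,
    tcfg: TrainingConfig,
    validation_fraction: float = 0.2,
) -> tuple[SpeciesClassifier, TrainingHistory]:
    """Array-level core of :func:`train_model` (x in [0,1], y label indices)."""
    rng = np.random.default_rng(tcfg.seed)
    train_ids, val_ids = _stratified_val_split(y, validation_fraction, rng)
    if len(np.unique(y[train_ids])) < model.config.n_classes:
        raise DatasetError("validation split left a class empty in training")
    x_tr, y_tr = x[train_ids], y[train_ids]
    x_val, y_val = x[val_ids], y[val_ids]

    net = model.network
    opt = Adam(lr=tcfg.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = net.get_weights()
    since_best = 0

    for _epoch in range(tcfg.epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb = augment_batch(x_tr[idx], tcfg.augmentation, rng)
            loss, acc = net.loss_and_grad(xb, y_tr[idx])
            opt.step(net.trainable_params_and_grads())
            ep_loss += loss
            ep_acc += acc
            n_batches += 1
        val_loss, val_acc = net.evaluate(x_val, y_val)
        history.accuracy.append(ep_acc / n_batches)
        history.loss.append(ep_loss / n_batches)
        history.val_accuracy.append(val_acc)
        history.val_loss.append(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.early_stopping_patience:
                break

    net.set_weights(best_weights)  # checkpoint restore: lowest val loss
    if tcfg.checkpoint_path:
        save_model(model, tcfg.checkpoint_path)
    return model, history


def predict(model: SpeciesClassifier, image: np.ndarray | str | Path) -> ClassProbabilities:
    """Classify one image (array or file path); returns label→probability."""
    h, w = model.config.input_size
    if isinstance(image, (str, Path)):
        arr = load_image_array(image, (h, w))
    else:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
        if arr.max() > 1.0:  # 8-bit input
            arr = arr / 255.0
        if arr.shape[:2] != (h, w):
            img = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
            arr = np.asarray(img.resize((w, h), Image.BILINEAR), dtype=np.float64) / 255.0
    probs = model.network.predict_proba(arr[None])[0]
    probs = probs / probs.sum()  # guard against float drift
    return ClassProbabilities(
        probabilities={lab: float(p) for lab, p in zip(model.labels, probs)}
    )


def save_model(model: SpeciesClassifier, path: str | Path) -> None:
    """Persist the network, labels, and config in an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "chromoplate-model-v1"
        fh.attrs["labels"] = json.dumps(model.labels)
        cfg = asdict(model.config)
        cfg["input_size"] = list(cfg["input_size"])
        fh.attrs["config"] = json.dumps(cfg)
        save_weights_h5(fh.create_group("network"), model.network)


def load_model(path: str | Path, expected_classes: int | None = None) -> SpeciesClassifier:
    """Load an HDF5 model; corrupt or inconsistent files raise ModelFormatError."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file {path} does not exist")
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "chromoplate-model-v1":
                raise ModelFormatError(f"{path} is not a recognized model container")
            labels = json.loads(fh.attrs["labels"])
            cfg = json.loads(fh.attrs["config"])
            cfg["input_size"] = tuple(cfg["input_size"])
            config = ModelConfig(**cfg)
            network = load_weights_h5(fh["network"])
    except OSError as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"model file {path} is malformed: {exc}") from exc
    if len(labels) != config.n_classes:
        raise ModelFormatError(
            f"label list ({len(labels)}) disagrees with config n_classes "
            f"({config.n_classes})"
        )
    if expected_classes is not None and config.n_classes != expected_classes:
        raise ModelFormatError(
            f"model has {config.n_classes} classes, expected {expected_classes}"
        )
    return SpeciesClassifier(network=network, labels=labels, config=config)
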