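"""Training and evaluation pipeline.

Protocol: images resized bilinearly to a square input, scaled to [0, 1];
random horizontal flips during training; AdamW with cross-entropy and an
exponentially decaying learning rate (initial 0.001, default decay 0.9 per
epoch); stratified k-fold cross-validation over the training split for
variance reporting, with the final model trained on the full training split.

Evaluation accumulates a confusion matrix with smoke as the positive class
and reports accuracy (TP+TN)/(TP+FN+FP+TN) and sensitivity TP/(TP+FN);
sensitivity is NaN (with a warning) when the test split has no positives.
A wall-clock throughput utility is included for information only.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image as PILImage
from sklearn.model_selection import StratifiedKFold

from .head import ModelConfig, SmokeClassifier
from .layers import AdamW, cross_entropy
from .reparam import TOPOLOGY_FUSED, TOPOLOGY_MULTI_BRANCH, deploy_model
from .synthetic_data import DatasetManifest

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "preprocess",
    "exponential_lr",
    "load_split",
    "train",
    "evaluate",
    "evaluate_arrays",
    "measure_throughput",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The reference protocol uses input_size 224, lr 0.001 with exponential
    decay, 10 folds, 50 epochs and depth 10; the defaults here are a reduced
    configuration sized for CPU-scale synthetic runs, with the reference
    values available via :meth:`reference_protocol`.
    """

    input_size: int = 64
    initial_lr: float = 1e-3
    lr_decay: float = 0.9          # per-epoch exponential factor
    epochs: int = 10
    folds: int = 2
    flip_prob: float = 0.5
    batch_size: int = 32
    weight_decay: float = 1e-4
    seed: int = 0
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        input_size=64, embed_dim=64, depth=2))

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr decay factor must be in (0, 1]")
        if self.model.input_size != self.input_size:
            self.model = dataclasses.replace(self.model, input_size=self.input_size)

    @classmethod
    def reference_protocol(cls, seed: int = 0) -> "TrainConfig":
        """224x224 input, lr 0.001, 10-fold CV, 50 epochs, depth 10."""
        return cls(input_size=224, initial_lr=1e-3, epochs=50, folds=10, seed=seed,
                   model=ModelConfig(input_size=224, embed_dim=64, depth=10, seed=seed))

    @classmethod
    def from_yaml(cls, path: str) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ConfusionCounts:
    """Binary confusion matrix with smoke as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    """Accuracy and sensitivity derived from a confusion matrix."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    throughput: float | None = None  # images/s, informational only

    @classmethod
    def from_counts(cls, counts: ConfusionCounts,
                    throughput: float | None = None) -> "MetricsReport":
        total = counts.total
        if total == 0:
            raise ValueError("cannot compute metrics on an empty evaluation set")
        acc = (counts.tp + counts.tn) / total
        pos = counts.tp + counts.fn
        if pos == 0:
            warnings.warn("no positive (smoke) samples: sensitivity undefined",
                          RuntimeWarning, stacklevel=2)
            sens = float("nan")
        else:
            sens = counts.tp / pos
        return cls(counts=counts, accuracy=acc, sensitivity=sens,
                   throughput=throughput)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "throughput": self.throughput,
        }


# ---------------------------------------------------------------------------
# preprocessing and data loading
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, size: int, *, train_mode: bool = False,
               flip_prob: float = 0.5,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, size, size) float32 in [0, 1].

    Bilinear resize; in train mode, horizontal flip with ``flip_prob``.
    """
    pil = PILImage.fromarray(np.asarray(image, dtype=np.uint8))
    resized = np.asarray(pil.resize((size, size), PILImage.BILINEAR), dtype=np.float32)
    if train_mode and flip_prob > 0:
        rng = rng or np.random.default_rng(0)
        if rng.random() < flip_prob:
            resized = resized[:, ::-1, :]
    return np.ascontiguousarray(resized.transpose(2, 0, 1)) / 255.0


def exponential_lr(epoch: int, initial_lr: float, decay: float) -> float:
    """lr at ``epoch`` (0-based): ``initial_lr * decay**epoch``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial_lr * decay**epoch


def load_split(manifest: DatasetManifest, split: str, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load and preprocess one split: (images (N,3,S,S) float32, labels (N,))."""
    sub = manifest.subset(split)
    if not sub.records:
        raise ValueError(f"manifest has no images in split {split!r}")
    images = np.empty((len(sub.records), 3, size, size), dtype=np.float32)
    for i, path in enumerate(sub.paths()):
        try:
            with PILImage.open(path) as im:
                arr = np.asarray(im.convert("RGB"))
        except OSError as exc:
            raise OSError(f"unreadable image {path}: {exc}") from exc
        images[i] = preprocess(arr, size)
    return images, sub.labels()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _train_one(cfg: TrainConfig, x: np.ndarray, y: np.ndarray,
               seed: int, log: list[dict] | None = None,
               val: tuple[np.ndarray, np.ndarray] | None = None) -> SmokeClassifier:
    model = SmokeClassifier(dataclasses.replace(cfg.model, seed=seed))
    opt = AdamW(model, lr=cfg.initial_lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    if n < cfg.batch_size:
        raise ValueError(f"training set ({n}) smaller than batch size ({cfg.batch_size})")
    for epoch in range(cfg.epochs):
        opt.lr = exponential_lr(epoch, cfg.initial_lr, cfg.lr_decay)
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        model.train(True)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x[idx]
            if cfg.flip_prob > 0:
                flip = rng.random(len(idx)) < cfg.flip_prob
                if flip.any():
                    xb = xb.copy()
                    xb[flip] = xb[flip][:, :, :, ::-1]
            logits = model(xb)
            loss, dlogits = cross_entropy(logits, y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            nb += 1
        record = {"epoch": epoch, "lr": opt.lr, "loss": epoch_loss / nb}
        if val is not None:
            report = evaluate_arrays(model, val[0], val[1])
            record["val_accuracy"] = report.accuracy
            record["val_sensitivity"] = report.sensitivity
        if log is not None:
            log.append(record)
    model.eval()
    return model


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold (train_idx, val_idx) pairs."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(y)), y)]


def train(cfg: TrainConfig, manifest: DatasetManifest, out_dir: str | None = None,
          run_cv: bool = True) -> dict:
    """Run the training protocol on the manifest's train split.

    Returns ``{"model": final model, "cv_reports": [...], "log": [...]}``;
    when ``out_dir`` is given, per-fold and final checkpoints plus a JSON
    training log are written there.
    """
    x, y = load_split(manifest, "train", cfg.input_size)
    log: list[dict] = []
    cv_reports: list[MetricsReport] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    if run_cv:
        for fold, (tr, va) in enumerate(stratified_folds(y, cfg.folds, cfg.seed)):
            fold_log: list[dict] = []
            model = _train_one(cfg, x[tr], y[tr], seed=cfg.seed + fold,
                               log=fold_log, val=(x[va], y[va]))
            report = evaluate_arrays(model, x[va], y[va])
            cv_reports.append(report)
            log.append({"fold": fold, "epochs": fold_log,
                        "val_accuracy": report.accuracy,
                        "val_sensitivity": report.sensitivity})
            if out_dir:
                save_checkpoint(os.path.join(out_dir, f"fold{fold}.ckpt.npz"),
                                model, cfg)

    final_log: list[dict] = []
    model = _train_one(cfg, x, y, seed=cfg.seed, log=final_log)
    log.append({"fold": "final", "epochs": final_log})
    if out_dir:
        save_checkpoint(os.path.join(out_dir, "final.ckpt.npz"), model, cfg)
        with open(os.path.join(out_dir, "train_log.json"), "w") as fh:
            json.dump(log, fh, indent=2)
    return {"model": model, "cv_reports": cv_reports, "log": log}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_arrays(model: SmokeClassifier, x: np.ndarray, y: np.ndarray,
                    batch_size: int = 32) -> MetricsReport:
    if x.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty set")
    was_training = model.training
    model.eval()
    pred = model.predict_labels(x, batch_size=batch_size)
    model.train(was_training)
    return MetricsReport.from_counts(ConfusionCounts.from_predictions(y, pred))


def evaluate(model: SmokeClassifier, manifest: DatasetManifest, split: str = "test",
             batch_size: int = 32) -> MetricsReport:
    """Evaluate a model on one manifest split (smoke = positive class)."""
    x, y = load_split(manifest, split, model.cfg.input_size)
    return evaluate_arrays(model, x, y, batch_size=batch_size)


def measure_throughput(model: SmokeClassifier, n_images: int = 64,
                       image_size: int | None = None, warmup: int = 4,
                       repeats: int = 5, seed: int = 0) -> float:
    """Median wall-clock images/second over ``repeats`` timed passes.

    Host-dependent; informational only.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    size = image_size or model.cfg.input_size
    rng = np.random.default_rng(seed)
    x = rng.random((n_images, 3, size, size)).astype(np.float32)
    model.eval()
    for _ in range(warmup):
        model(x[: min(4, n_images)])
    rates = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model.predict_labels(x)
        rates.append(n_images / (time.perf_counter() - t0))
    return float(np.median(rates))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, model: SmokeClassifier,
                    train_cfg: TrainConfig | None = None) -> None:
    meta = {
        "model": model.cfg.to_dict(),
        "topology": model.topology,
        "train": train_cfg.to_dict() if train_cfg else None,
    }
    state = {f"state.{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **state)


def load_checkpoint(path: str) -> SmokeClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("state."):]: data[k] for k in data.files if k.startswith("state.")}
    cfg = ModelConfig.from_dict(meta["model"])
    model = SmokeClassifier(cfg)
    topology = meta.get("topology", TOPOLOGY_MULTI_BRANCH)
    if topology == TOPOLOGY_FUSED:
        model.eval()
        model = deploy_model(model)
        model.topology = TOPOLOGY_FUSED
    model.load_state_dict(state)
    model.eval()
    return model
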