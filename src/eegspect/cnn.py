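"""The three small spectrogram CNNs and their training protocol.

Model 1: three 3x3 conv blocks (16/32/64 filters), each followed by 2x2
max pooling, then a 512-unit ReLU dense layer and a 2-class softmax head.
Model 2: model 1 with 20% dropout after the last pool.
Model 3: four alternating conv/pool pairs (32/32/64/64 filters) with 25%
dropout after every second pair, a 256-unit ReLU dense layer, 50% dropout,
and the softmax head.

Training uses cross-entropy with Adam (default 1e-3), pixel inputs
rescaled to [0, 1], a stratified 70/15/15 train/validation/test split (a
subject-wise variant is available to prevent subject-identity leakage),
and one master seed for split, initialization, dropout and shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ConfusionCounts, MetricsReport, compute_metrics, compute_roc_auc
from .nn import Adam, Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2D, Sequential, softmax_cross_entropy

#: Frozen architecture presets: (op, arg) tuples per model id.
CNN_PRESETS: dict[int, tuple[tuple[str, float | int], ...]] = {
    1: (
        ("conv", 16), ("pool", 2), ("conv", 32), ("pool", 2), ("conv", 64), ("pool", 2),
        ("flatten", 0), ("dense_relu", 512), ("dense", 2),
    ),
    2: (
        ("conv", 16), ("pool", 2), ("conv", 32), ("pool", 2), ("conv", 64), ("pool", 2),
        ("dropout", 0.2),
        ("flatten", 0), ("dense_relu", 512), ("dense", 2),
    ),
    3: (
        ("conv", 32), ("pool", 2), ("conv", 32), ("pool", 2), ("dropout", 0.25),
        ("conv", 64), ("pool", 2), ("conv", 64), ("pool", 2), ("dropout", 0.25),
        ("flatten", 0), ("dense_relu", 256), ("dropout", 0.5), ("dense", 2),
    ),
}


@dataclass
class CNNSpec:
    model_id: int
    input_shape: tuple[int, int, int] = (128, 128, 1)

    def __post_init__(self) -> None:
        if self.model_id not in CNN_PRESETS:
            raise ValueError(f"unknown model_id {self.model_id}; expected 1, 2 or 3")

    @property
    def layers(self) -> tuple[tuple[str, float | int], ...]:
        return CNN_PRESETS[self.model_id]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    grouping: str = "image"  # image | subject
    early_stop_val_acc: float | None = None  # stop once validation accuracy reaches this

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.grouping not in ("image", "subject"):
            raise ValueError("grouping must be 'image' or 'subject'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


def build_cnn(spec: CNNSpec | int, seed: int = 0) -> Sequential:
    """Instantiate one of the frozen presets with seeded initialization."""
    if isinstance(spec, int):
        spec = CNNSpec(model_id=spec)
    streams = np.random.SeedSequence(seed).spawn(len(spec.layers))
    layers: list[Layer] = []
    shape = spec.input_shape
    for (op, arg), ss in zip(spec.layers, streams):
        rng = np.random.default_rng(ss)
        if op == "conv":
            layer = Conv2D(shape[2], int(arg), rng, relu=True)
        elif op == "pool":
            layer = MaxPool2D()
        elif op == "dropout":
            layer = Dropout(float(arg), rng)
        elif op == "flatten":
            layer = Flatten()
        elif op in ("dense", "dense_relu"):
            layer = Dense(shape[0], int(arg), rng, relu=(op == "dense_relu"))
        else:  # pragma: no cover - presets are frozen
            raise ValueError(f"unknown layer op {op!r}")
        shape = layer.out_shape(shape)
        layers.append(layer)
    return Sequential(layers)


def describe_cnn(spec: CNNSpec | int) -> list[dict]:
    """Serializable layer list of a preset (for inspection/regression)."""
    if isinstance(spec, int):
        spec = CNNSpec(model_id=spec)
    out = []
    shape: tuple = spec.input_shape
    model = build_cnn(spec, seed=0)
    for (op, arg), layer in zip(spec.layers, model.layers):
        shape = layer.out_shape(shape)
        out.append({"op": op, "arg": arg, "output_shape": tuple(shape),
                    "n_params": int(sum(p.size for p in layer.params))})
    return out


def make_split(labels, subject_ids, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, seeded, disjoint and exhaustive 70/15/15 index split.

    With grouping="subject", whole subjects are allocated to one partition
    (per class, by cumulative image count closest to the target fractions).
    """
    labels = np.asarray(labels).astype(int)
    subject_ids = np.asarray(subject_ids, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5eed]))
    f_train, f_val, _ = cfg.fractions
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        if cfg.grouping == "subject":
            subjects = np.array(sorted(set(subject_ids[cls_idx])), dtype=object)
            rng.shuffle(subjects)
            counts = {s: int(np.sum(subject_ids[cls_idx] == s)) for s in subjects}
            total = len(cls_idx)
            cum, part = 0, []
            for s in subjects:
                cum += counts[s]
                if cum <= round(f_train * total) or not part:
                    part.append("train")
                elif cum <= round((f_train + f_val) * total) or "val" not in part:
                    part.append("val")
                else:
                    part.append("test")
            if "test" not in part:
                part[-1] = "test"
            for s, where in zip(subjects, part):
                idx = cls_idx[subject_ids[cls_idx] == s]
                {"train": train_idx, "val": val_idx, "test": test_idx}[where].extend(idx)
        else:
            perm = rng.permutation(cls_idx)
            n = len(perm)
            n_train = int(round(f_train * n))
            n_val = int(round(f_val * n))
            train_idx.extend(perm[:n_train])
            val_idx.extend(perm[n_train : n_train + n_val])
            test_idx.extend(perm[n_train + n_val :])
    out = tuple(np.sort(np.array(part, dtype=int)) for part in (train_idx, val_idx, test_idx))
    for part in out:
        if part.size == 0:
            raise ValueError("too few items for a non-empty train/val/test split")
    return out


def train_cnn(model: Sequential, x_train: np.ndarray, y_train: np.ndarray,
              x_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig) -> TrainHistory:
    """Train with mini-batch Adam; records per-epoch history.

    Inputs must already be scaled to [0, 1] (see :func:`prepare_images`).
    Raises on non-finite loss instead of continuing a diverged run.
    """
    x_train = x_train.astype(np.float32)
    y_train = np.asarray(y_train).astype(int)
    # center on the training-set mean; stored on the model for prediction
    model.input_offset = float(x_train.mean())
    optimizer = Adam(model.params, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xba7c4]))
    history = TrainHistory()
    n = x_train.shape[0]
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, grad = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            model.backward(grad)
            optimizer.step(model.grads)
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(idx)
        history.train_loss.append(sum(losses) / seen)
        history.train_accuracy.append(hits / seen)
        val_p = model.predict_proba(x_val)
        vl = float(-np.log(np.clip(val_p[np.arange(len(y_val)), np.asarray(y_val).astype(int)], 1e-12, None)).mean())
        va = float((val_p.argmax(axis=1) == np.asarray(y_val).astype(int)).mean())
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
        if cfg.early_stop_val_acc is not None and va >= cfg.early_stop_val_acc:
            break
    return history


def evaluate_cnn(model: Sequential, x_test: np.ndarray, y_test: np.ndarray) -> MetricsReport:
    """Held-out test metrics; AUC uses the ASD-class softmax score."""
    y_test = np.asarray(y_test).astype(int)
    if x_test.shape[0] == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(x_test.astype(np.float32))
    pred = proba.argmax(axis=1)
    report = compute_metrics(ConfusionCounts.from_labels(y_test, pred))
    if len(np.unique(y_test)) == 2:
        report.auc = compute_roc_auc(proba[:, 1], y_test)[0]
    return report


def prepare_images(images) -> np.ndarray:
    """Stack 8-bit images into a float32 (N, H, W, 1) tensor scaled to [0, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    if arr.ndim == 3:
        arr = arr[..., None]
    return arr / 255.0
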