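"""Dual-branch CNN-LSTM activity classifier.

The time branch runs the filtered 30x12 window through a two-layer
LSTM (384 then 256 units, dropout 20% / 45%).  The image branch runs
the 8x8x12 spectrogram tensor through a 128-filter 3x3 convolution,
2x2 max pooling, 40% dropout, and a 256-unit dense projection applied
position-wise before flattening (a ``cnn_dense_after_flatten`` switch
offers the conventional ordering).  The branch vectors are
concatenated, passed through a 256-unit ReLU fusion layer, and a
softmax over the eight activity classes.  Training minimizes
categorical cross-entropy with Adam, early-stopping on validation
loss and restoring the best-epoch weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from kneeadl.activities import ACTIVITY_LABELS
from kneeadl.nn import (
    Adam,
    Conv2DValid,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    MaxPool2D,
    Param,
    softmax,
    softmax_cross_entropy,
)
from kneeadl.spectrogram import ChannelScaler


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters."""

    lstm_units: tuple[int, int] = (384, 256)
    lstm_dropout: tuple[float, float] = (0.20, 0.45)
    conv_filters: int = 128
    conv_kernel: int = 3
    conv_dropout: float = 0.40
    cnn_dense_units: int = 256
    fusion_units: int = 256
    n_classes: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0
    branch: str = "fused"              # "fused" | "lstm" | "cnn"
    cnn_dense_after_flatten: bool = False
    window_shape: tuple[int, int] = (30, 12)
    tensor_shape: tuple[int, int, int] = (8, 8, 12)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.branch not in ("fused", "lstm", "cnn"):
            raise ValueError("branch must be fused, lstm or cnn")
        for r in (*self.lstm_dropout, self.conv_dropout):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelConfig":
        payload = dict(payload)
        for key in ("lstm_units", "lstm_dropout", "window_shape", "tensor_shape"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


class DualBranchClassifier:
    """Forward/backward network over (window, spectrogram) pairs."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.Generator(np.random.PCG64(config.seed))
        t_len, t_ch = config.window_shape
        s_h, s_w, s_ch = config.tensor_shape
        u1, u2 = config.lstm_units
        d1, d2 = config.lstm_dropout

        self.lstm1 = LSTM(t_ch, u1, rng, return_sequences=True,
                          name="lstm1", dtype=dtype)
        self.drop1 = Dropout(d1)
        self.lstm2 = LSTM(u1, u2, rng, return_sequences=False,
                          name="lstm2", dtype=dtype)
        self.drop2 = Dropout(d2)

        self.conv = Conv2DValid(s_ch, config.conv_filters, config.conv_kernel,
                                rng, name="conv", dtype=dtype)
        self.pool = MaxPool2D(2)
        self.drop_c = Dropout(config.conv_dropout)
        conv_out = s_h - config.conv_kernel + 1
        pooled = conv_out // 2
        if config.cnn_dense_after_flatten:
            cnn_dense_in = pooled * pooled * config.conv_filters
            cnn_vec = config.cnn_dense_units
        else:
            cnn_dense_in = config.conv_filters
            cnn_vec = pooled * pooled * config.cnn_dense_units
        self.cnn_dense = Dense(cnn_dense_in, config.cnn_dense_units, rng,
                               activation="relu", name="cnn_dense", dtype=dtype)
        self.flatten = Flatten()

        lstm_vec = u2
        if config.branch == "fused":
            fusion_in = lstm_vec + cnn_vec
        elif config.branch == "lstm":
            fusion_in = lstm_vec
        else:
            fusion_in = cnn_vec
        self.fusion = Dense(fusion_in, config.fusion_units, rng,
                            activation="relu", name="fusion", dtype=dtype)
        self.head = Dense(config.fusion_units, config.n_classes, rng,
                          name="head", dtype=dtype)
        # zero-initialized head: training starts from the uniform
        # predictive distribution (initial loss = log(n_classes))
        self.head.W.value[...] = 0
        self._dtype = dtype
        self._fusion_split = lstm_vec  # boundary of the concat for backward

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[Param]:
        layers = []
        if self.config.branch in ("fused", "lstm"):
            layers += [self.lstm1, self.lstm2]
        if self.config.branch in ("fused", "cnn"):
            layers += [self.conv, self.cnn_dense]
        layers += [self.fusion, self.head]
        out: list[Param] = []
        for layer in layers:
            out.extend(layer.params())
        return out

    @property
    def param_count(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = weights[p.name]

    # -- forward / backward ------------------------------------------------

    def _lstm_branch(self, windows, train, rng):
        h = self.lstm1.forward(windows, train, rng)
        h = self.drop1.forward(h, train, rng)
        h = self.lstm2.forward(h, train, rng)
        return self.drop2.forward(h, train, rng)

    def _cnn_branch(self, tensors, train, rng):
        h = self.conv.forward(tensors, train, rng)
        h = self.pool.forward(h, train, rng)
        h = self.drop_c.forward(h, train, rng)
        if self.config.cnn_dense_after_flatten:
            h = self.flatten.forward(h, train, rng)
            return self.cnn_dense.forward(h, train, rng)
        h = self.cnn_dense.forward(h, train, rng)
        return self.flatten.forward(h, train, rng)

    def forward(self, windows: np.ndarray, tensors: np.ndarray,
                train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits (N, n_classes)."""
        windows = np.ascontiguousarray(windows, dtype=self._dtype)
        tensors = np.ascontiguousarray(tensors, dtype=self._dtype)
        branch = self.config.branch
        if branch == "fused":
            vec = np.concatenate(
                [self._lstm_branch(windows, train, rng),
                 self._cnn_branch(tensors, train, rng)], axis=1)
        elif branch == "lstm":
            vec = self._lstm_branch(windows, train, rng)
        else:
            vec = self._cnn_branch(tensors, train, rng)
        h = self.fusion.forward(vec, train, rng)
        return self.head.forward(h, train, rng)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head.backward(grad_logits)
        g = self.fusion.backward(g)
        branch = self.config.branch
        if branch == "fused":
            g_lstm, g_cnn = g[:, :self._fusion_split], g[:, self._fusion_split:]
        elif branch == "lstm":
            g_lstm, g_cnn = g, None
        else:
            g_lstm, g_cnn = None, g
        if g_lstm is not None:
            gl = self.drop2.backward(g_lstm)
            gl = self.lstm2.backward(gl)
            gl = self.drop1.backward(gl)
            self.lstm1.backward(gl)
        if g_cnn is not None:
            if self.config.cnn_dense_after_flatten:
                gc = self.cnn_dense.backward(g_cnn)
                gc = self.flatten.backward(gc)
            else:
                gc = self.flatten.backward(g_cnn)
                gc = self.cnn_dense.backward(gc)
            gc = self.drop_c.backward(gc)
            gc = self.pool.backward(gc)
            self.conv.backward(gc)


def build_model(config: ModelConfig) -> DualBranchClassifier:
    """Deterministically initialize a classifier from ``config``."""
    return DualBranchClassifier(config)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _eval_batches(model, windows, tensors, labels, batch: int = 512):
    losses, correct, n = [], 0, len(labels)
    for i in range(0, n, batch):
        logits = model.forward(windows[i:i + batch], tensors[i:i + batch])
        loss, _ = softmax_cross_entropy(logits, labels[i:i + batch])
        losses.append(loss * len(labels[i:i + batch]))
        correct += int((logits.argmax(axis=1) == labels[i:i + batch]).sum())
    return sum(losses) / n, correct / n


def train_model(
    model: DualBranchClassifier,
    train_windows: np.ndarray,
    train_tensors: np.ndarray,
    train_labels: np.ndarray,
    val_windows: np.ndarray,
    val_tensors: np.ndarray,
    val_labels: np.ndarray,
    verbose: bool = False,
) -> TrainingHistory:
    """Adam / cross-entropy training with early stopping.

    Mutates ``model`` in place and restores the best-validation-loss
    weights before returning.  Deterministic under the model config
    seed for fixed data.
    """
    if len(train_labels) == 0 or len(val_labels) == 0:
        raise ValueError("train and validation splits must be non-empty")
    cfg = model.config
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    patience = 0
    n = len(train_labels)
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            logits = model.forward(train_windows[idx], train_tensors[idx],
                                   train=True, rng=rng)
            loss, grad = softmax_cross_entropy(logits, train_labels[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == train_labels[idx]).sum())
        val_loss, val_acc = _eval_batches(model, val_windows, val_tensors,
                                          val_labels)
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss / n:.4f}  "
                  f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}")
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            patience = 0
        else:
            patience += 1
            if patience >= cfg.early_stop_patience:
                break
        history.stopped_epoch = epoch
    model.set_weights(best_weights)
    return history


def predict_proba(model: DualBranchClassifier, windows: np.ndarray,
                  tensors: np.ndarray) -> np.ndarray:
    """Class probabilities (N, n_classes); rows sum to 1."""
    if windows.ndim == 2:
        windows = windows[None]
    if tensors.ndim == 3:
        tensors = tensors[None]
    return softmax(model.forward(windows, tensors).astype(np.float64))


def classify(model: DualBranchClassifier, windows: np.ndarray,
             tensors: np.ndarray) -> np.ndarray:
    """Argmax labels; ties resolve to the lowest class index."""
    return predict_proba(model, windows, tensors).argmax(axis=1)


# ---------------------------------------------------------------------------
# Persistence


@dataclass
class TrainedModel:
    """Everything needed for exact re-inference."""

    model: DualBranchClassifier
    window_scaler: ChannelScaler
    tensor_scaler: ChannelScaler
    label_names: tuple[str, ...] = ACTIVITY_LABELS
    history: TrainingHistory | None = None

    def predict_proba(self, windows, tensors) -> np.ndarray:
        return predict_proba(self.model,
                             self.window_scaler.transform(windows),
                             self.tensor_scaler.transform(tensors))

    def classify(self, windows, tensors) -> np.ndarray:
        return self.predict_proba(windows, tensors).argmax(axis=1)


def save_model(trained: TrainedModel, model_dir: str | Path) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    np.savez(model_dir / "weights.npz", **trained.model.get_weights())
    sidecar = {
        "config": trained.model.config.to_dict(),
        "label_names": list(trained.label_names),
        "window_scaler": trained.window_scaler.to_dict(),
        "tensor_scaler": trained.tensor_scaler.to_dict(),
        "history": trained.history.to_dict() if trained.history else None,
    }
    with open(model_dir / "model.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    with open(model_dir / "model.json") as fh:
        sidecar = json.load(fh)
    config = ModelConfig.from_dict(sidecar["config"])
    model = build_model(config)
    with np.load(model_dir / "weights.npz") as data:
        model.set_weights({k: data[k] for k in data.files})
    history = None
    if sidecar.get("history"):
        history = TrainingHistory(**sidecar["history"])
    return TrainedModel(
        model=model,
        window_scaler=ChannelScaler.from_dict(sidecar["window_scaler"]),
        tensor_scaler=ChannelScaler.from_dict(sidecar["tensor_scaler"]),
        label_names=tuple(sidecar["label_names"]),
        history=history,
    )
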