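"""1-D convolutional spectral classifier.

Used three ways: as a standalone defect classifier on reflectance spectra, as
the objective evaluated by the firefly band search, and as the 1-D feature
branch inside the fusion detectors.

The faithful preset instantiates 13 convolutional layers in 5 pooled blocks
plus 2 fully-connected layers (VGG-style block plan, since only the layer
counts are prescribed); the scaled preset is a small variant for coarse grids
and fast CPU runs.  Band subsets are fed as zero-masked full-length spectra so
one architecture serves every band combination.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    Conv1D,
    Dense,
    Flatten,
    MaxPool1D,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .synthgen import SpectrumDataset, Spectrum


class TrainingError(RuntimeError):
    """Invalid training data or configuration."""


@dataclass
class SpectralNetConfig:
    """Architecture and training hyperparameters.

    ``blocks`` is a list of (channel width, conv count) pairs; each block ends
    with a stride-2 max pool, so the pool count equals the block count.
    """

    input_len: int
    blocks: list[tuple[int, int]]
    fc_widths: tuple[int, int]
    n_classes: int = 3
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.fc_widths) != 2:
            raise ValueError("exactly two fully-connected widths required")
        if len(self.blocks) > int(np.log2(max(self.input_len, 2))):
            raise ValueError("too many pooling blocks for the input length")

    @property
    def n_conv_layers(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def n_pool_layers(self) -> int:
        return len(self.blocks)

    @classmethod
    def faithful(cls, input_len: int = 360, n_classes: int = 3, **kw) -> "SpectralNetConfig":
        """13 conv / 5 pool / 2 fully-connected preset."""
        return cls(
            input_len=input_len,
            blocks=[(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)],
            fc_widths=(128, n_classes),
            n_classes=n_classes,
            **kw,
        )

    @classmethod
    def scaled(cls, input_len: int = 60, n_classes: int = 3, **kw) -> "SpectralNetConfig":
        """Small preset for coarse grids; trains in seconds on one CPU."""
        kw.setdefault("epochs", 30)
        return cls(
            input_len=input_len,
            blocks=[(8, 1), (16, 1)],
            fc_widths=(32, n_classes),
            n_classes=n_classes,
            **kw,
        )


def build_layers(cfg: SpectralNetConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in, length = 1, cfg.input_len
    for width, n_convs in cfg.blocks:
        for _ in range(n_convs):
            layers.append(Conv1D(c_in, width, 3, rng))
            layers.append(ReLU())
            c_in = width
        layers.append(MaxPool1D())
        length //= 2
    layers.append(Flatten())
    layers.append(Dense(c_in * length, cfg.fc_widths[0], rng))
    layers.append(ReLU())
    layers.append(Dense(cfg.fc_widths[0], cfg.fc_widths[1], rng))
    return Sequential(layers)


def layer_census(net: Sequential) -> dict[str, int]:
    """Count layer kinds; used to audit the faithful preset."""
    return {
        "conv": sum(isinstance(l, Conv1D) for l in net.layers),
        "pool": sum(isinstance(l, MaxPool1D) for l in net.layers),
        "fc": sum(isinstance(l, Dense) for l in net.layers),
    }


def apply_band_mask(values: np.ndarray, bands) -> np.ndarray:
    """Zero out all bands not in ``bands``; shape is preserved.

    Works on a single spectrum (1-D) or a stack of spectra (2-D, bands last).
    """
    values = np.asarray(values, dtype=float)
    idx = np.asarray(sorted(bands), dtype=int)
    if idx.size == 0:
        raise ValueError("band combination must be non-empty")
    if idx.size != np.unique(idx).size:
        raise ValueError("band indices must be distinct")
    n_bands = values.shape[-1]
    if idx.min() < 0 or idx.max() >= n_bands:
        raise ValueError(f"band index out of range [0, {n_bands})")
    mask = np.zeros(n_bands)
    mask[idx] = 1.0
    return values * mask


@dataclass
class TrainedSpectralNet:
    """A trained classifier: architecture, parameters, history, label order."""

    cfg: SpectralNetConfig
    net: Sequential
    classes: list[str]
    history: dict[str, list[float]]

    def _check_input(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.cfg.input_len:
            raise ValueError(
                f"spectrum length {values.shape[1]} != model input {self.cfg.input_len}"
            )
        return values

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Class probability rows (sum to 1) for one or many spectra."""
        x = self._check_input(values)[:, None, :]
        return softmax(self.net.forward(x))

    def predict(self, values: np.ndarray) -> np.ndarray:
        p = self.predict_proba(values)
        return np.array(self.classes)[p.argmax(axis=1)]

    def classify_spectrum(self, spectrum: Spectrum | np.ndarray) -> np.ndarray:
        values = spectrum.values if isinstance(spectrum, Spectrum) else spectrum
        return self.predict_proba(values)[0]

    def extract_features(self, spectrum: Spectrum | np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (first fully-connected, post-ReLU)."""
        values = spectrum.values if isinstance(spectrum, Spectrum) else spectrum
        x = self._check_input(values)[:, None, :]
        dense_seen = 0
        for layer in self.net.layers:
            x = layer.forward(x)
            if isinstance(layer, Dense):
                dense_seen += 1
            if dense_seen == 1 and isinstance(layer, ReLU):
                return x[0] if np.asarray(values).ndim == 1 else x
        raise RuntimeError("network has no fully-connected feature layer")

    @property
    def feature_dim(self) -> int:
        return self.cfg.fc_widths[0]

    def validation_score(self, kind: str = "accuracy") -> float:
        return self.history[f"val_{kind}"][-1]

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        cfg = asdict(self.cfg)
        meta = {"config": cfg, "classes": self.classes, "history": self.history}
        prefix.with_suffix(".json").write_text(json.dumps(meta))
        arrays = {f"p{i}": p for i, p in enumerate(self.net.param_arrays())}
        np.savez(prefix.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedSpectralNet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        cfg_d["blocks"] = [tuple(b) for b in cfg_d["blocks"]]
        cfg_d["fc_widths"] = tuple(cfg_d["fc_widths"])
        cfg = SpectralNetConfig(**cfg_d)
        net = build_layers(cfg, np.random.default_rng(cfg.seed))
        with np.load(prefix.with_suffix(".npz")) as data:
            for i, p in enumerate(net.param_arrays()):
                p[...] = data[f"p{i}"]
        return cls(cfg, net, list(meta["classes"]), meta["history"])

    def history_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.history).to_csv(path, index_label="epoch")


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified calibration/validation index split."""
    train_idx, val_idx = [], []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> float:
    f1s = []
    for c in classes:
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def train_classifier(data: SpectrumDataset, cfg: SpectralNetConfig) -> TrainedSpectralNet:
    """Train the 1-D CNN with Adam on a seeded stratified split.

    Deterministic given ``cfg.seed`` and the data.  History records per-epoch
    mean calibration loss, validation loss, and validation accuracy.
    """
    classes = data.classes
    if len(classes) < 2:
        raise TrainingError("training data must contain at least 2 classes")
    if data.X.shape[1] != cfg.input_len:
        raise TrainingError(
            f"data band count {data.X.shape[1]} != configured input {cfg.input_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    tr, va = stratified_split(data.labels, cfg.val_fraction, rng)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[l] for l in data.labels])
    Xtr, ytr = data.X[tr], y[tr]
    Xva, yva = data.X[va], y[va]

    net = build_layers(cfg, rng)
    opt = Adam(net.param_pairs(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [],
        "val_loss": [],
        "val_accuracy": [],
        "val_macro_f1": [],
    }
    n = Xtr.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            logits = net.forward(Xtr[batch][:, None, :])
            loss, dlogits = softmax_cross_entropy(logits, ytr[batch])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        val_logits = net.forward(Xva[:, None, :])
        val_loss, _ = softmax_cross_entropy(val_logits, yva)
        pred = val_logits.argmax(axis=1)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(float((pred == yva).mean()))
        history["val_macro_f1"].append(
            _macro_f1(
                np.array(classes)[yva], np.array(classes)[pred], classes
            )
        )
    return TrainedSpectralNet(cfg, net, classes, history)
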