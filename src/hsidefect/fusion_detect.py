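"""Spectral-spatial fusion detectors.

Two architectures locate defects on pseudo-color renderings of the hypercube:

* ``one_stage_single_scale`` — convolutional backbone + a single-scale anchor
  head emitting objectness, box deltas, and class scores (one detection
  scale only).
* ``two_stage_rpn`` — backbone + region-proposal stage with two decision
  branches (objectness and coordinate adjustment) + a region classification
  head on pooled features.

With fusion enabled, each localized box is re-classified by a fusion head fed
the concatenation of its pooled 2-D region features and the 1-D spectral
branch's penultimate features extracted from the hypercube at the selected
bands.  The fused decision replaces the 2-D-only class scores.  The spectral
branch is trained first on ground-truth region spectra and kept frozen.

Backbones are compact convolutional stacks, not full production backbones:
the arrangement (2-D localization + spectral extraction + feature fusion) is
the point, configurable depth/width is the implementation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    Conv2D,
    Dense,
    MaxPool2D,
    ReLU,
    Sequential,
    bce_with_logits,
    sigmoid,
    smooth_l1,
    softmax,
    softmax_cross_entropy,
)
from .hypercube import BoundingBox, Hypercube
from .spectral_net import (
    SpectralNetConfig,
    TrainedSpectralNet,
    apply_band_mask,
    train_classifier,
)
from .synthgen import AnnotatedScene, SpectrumDataset
from . import hypercube as hc
from .eval_metrics import iou


class ConfigurationError(ValueError):
    """Inconsistent detector configuration."""


ONE_STAGE = "one_stage_single_scale"
TWO_STAGE = "two_stage_rpn"


@dataclass(eq=False)
class Detection:
    """One predicted box with class label and confidence."""

    box: BoundingBox
    label: str
    confidence: float
    probabilities: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("probability vector must be non-negative and sum to 1")
            self.probabilities = p

    def __eq__(self, other) -> bool:
        if not isinstance(other, Detection):
            return NotImplemented
        if (self.probabilities is None) != (other.probabilities is None):
            return False
        probs_equal = self.probabilities is None or np.array_equal(
            self.probabilities, other.probabilities
        )
        return (
            self.box == other.box
            and self.label == other.label
            and self.confidence == other.confidence
            and probs_equal
        )


@dataclass
class DetectorConfig:
    """Architecture, anchors, thresholds, fusion and training settings."""

    render_bands: tuple[int, int, int]
    architecture: str = ONE_STAGE
    class_names: tuple[str, ...] = ("CBC", "CBB", "CBBR")
    backbone_channels: tuple[int, ...] = (16, 32, 32)
    anchor_sizes: tuple[float, ...] = (8.0, 12.0, 18.0)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    nms_iou: float = 0.5
    nms_class_agnostic: bool = True  # one box per defect: the head's objectness is class-shared
    conf_threshold: float = 0.5
    fusion: bool = False
    spectral_bands: tuple[int, ...] | None = None
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    pos_iou: float = 0.5
    neg_iou: float = 0.3
    roi_hidden: int = 64
    rpn_proposals: int = 25
    fusion_hidden: int = 32
    fusion_epochs: int = 60
    fusion_lr: float = 5e-3

    def __post_init__(self):
        if self.architecture not in (ONE_STAGE, TWO_STAGE):
            raise ConfigurationError(f"unknown architecture '{self.architecture}'")
        if len(set(self.render_bands)) != 3:
            raise ConfigurationError("render_bands must be three distinct indices")
        if any(s <= 0 for s in self.anchor_sizes) or any(r <= 0 for r in self.anchor_ratios):
            raise ConfigurationError("anchor sizes and ratios must be positive")
        if not 0.0 < self.nms_iou < 1.0 or not 0.0 < self.conf_threshold < 1.0:
            raise ConfigurationError("thresholds must lie in (0, 1)")
        if self.spectral_bands is not None:
            self.spectral_bands = tuple(int(b) for b in self.spectral_bands)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_sizes) * len(self.anchor_ratios)


# ---------------------------------------------------------------------------
# Box / anchor arithmetic (float, half-open corner convention)


def _anchor_grid(fh: int, fw: int, stride: int, cfg: DetectorConfig) -> np.ndarray:
    """(M, 4) anchors as (cx, cy, w, h), ordered (anchor, row, col)."""
    anchors = []
    for s in cfg.anchor_sizes:
        for r in cfg.anchor_ratios:
            w = s * np.sqrt(r)
            h = s / np.sqrt(r)
            for i in range(fh):
                for j in range(fw):
                    anchors.append(((j + 0.5) * stride, (i + 0.5) * stride, w, h))
    return np.array(anchors)


def _to_corners(cxcywh: np.ndarray) -> np.ndarray:
    cx, cy, w, h = cxcywh.T
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _to_cxcywh(corners: np.ndarray) -> np.ndarray:
    x0, y0, x1, y1 = corners.T
    return np.stack([(x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0], axis=1)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between corner boxes (M, 4) x (N, 4)."""
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def _encode(gt_corners: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    g = _to_cxcywh(gt_corners)
    t = np.empty_like(g)
    t[:, 0] = (g[:, 0] - anchors[:, 0]) / anchors[:, 2]
    t[:, 1] = (g[:, 1] - anchors[:, 1]) / anchors[:, 3]
    t[:, 2] = np.log(g[:, 2] / anchors[:, 2])
    t[:, 3] = np.log(g[:, 3] / anchors[:, 3])
    return t


def _decode(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    out = np.empty_like(deltas)
    out[:, 0] = anchors[:, 0] + deltas[:, 0] * anchors[:, 2]
    out[:, 1] = anchors[:, 1] + deltas[:, 1] * anchors[:, 3]
    out[:, 2] = anchors[:, 2] * np.exp(np.clip(deltas[:, 2], -4.0, 4.0))
    out[:, 3] = anchors[:, 3] * np.exp(np.clip(deltas[:, 3], -4.0, 4.0))
    return _to_corners(out)


def _assign_anchors(
    anchor_corners: np.ndarray, gt_corners: np.ndarray, pos_iou: float, neg_iou: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max-IoU assignment with forced best match per ground truth.

    Returns (positive indices, negative indices, gt index per anchor).
    """
    M = anchor_corners.shape[0]
    if gt_corners.shape[0] == 0:
        return np.array([], dtype=int), np.arange(M), np.full(M, -1, dtype=int)
    ious = _iou_matrix(anchor_corners, gt_corners)
    gt_for_anchor = ious.argmax(axis=1)
    best_iou = ious.max(axis=1)
    pos = best_iou >= pos_iou
    forced = ious.argmax(axis=0)  # best anchor per gt
    pos[forced] = True
    gt_for_anchor[forced] = np.arange(gt_corners.shape[0])
    neg = (best_iou < neg_iou) & ~pos
    return np.flatnonzero(pos), np.flatnonzero(neg), gt_for_anchor


def _objectness_loss(
    obj: np.ndarray, pos: np.ndarray, neg: np.ndarray, neg_ratio: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced BCE with hard-negative mining.

    Positives share unit weight; the ``neg_ratio * n_pos`` highest-scoring
    negatives share unit weight (the rest contribute nothing), which keeps
    background anchors calibrated without drowning the positives.
    Returns (elementwise losses, dlogits, weights).
    """
    targets = np.zeros(obj.shape)
    targets[pos] = 1.0
    losses, dobj = bce_with_logits(obj, targets)
    w = np.zeros(obj.shape)
    n_pos = max(len(pos), 1)
    w[pos] = 1.0 / n_pos
    if len(neg):
        n_hard = min(len(neg), neg_ratio * n_pos)
        hard = neg[np.argsort(-obj[neg], kind="stable")[:n_hard]]
        w[hard] = 1.0 / n_hard
    return losses, dobj, w


def _corners_to_box(c: np.ndarray, width: int, height: int) -> BoundingBox | None:
    x0 = int(np.clip(np.floor(c[0]), 0, width - 1))
    y0 = int(np.clip(np.floor(c[1]), 0, height - 1))
    x1 = int(np.clip(np.ceil(c[2]), x0 + 1, width))
    y1 = int(np.clip(np.ceil(c[3]), y0 + 1, height))
    if x1 <= x0 or y1 <= y0:
        return None
    return BoundingBox(x0, y0, x1, y1)


# ---------------------------------------------------------------------------
# Shared operations


def extract_box_spectra(
    cube: Hypercube, box: BoundingBox, bands: Sequence[int] | None = None
) -> np.ndarray:
    """Mean region spectrum, zero-masked to the configured bands.

    ``bands=None`` keeps the full spectrum (no masking).
    """
    spectrum = hc.extract_roi_spectrum(cube, box)
    if bands is None:
        return spectrum
    return apply_band_mask(spectrum, bands)


def nms(
    detections: Sequence[Detection], iou_threshold: float, class_agnostic: bool = False
) -> list[Detection]:
    """Greedy non-maximum suppression, per class by default.

    Sorted by descending confidence with a stable coordinate tie-break; a kept
    box suppresses boxes of the same class (or of any class when
    ``class_agnostic``) with IoU strictly above the threshold.
    """
    order = sorted(
        detections,
        key=lambda d: (-d.confidence, d.box.x0, d.box.y0, d.box.x1, d.box.y1, d.label),
    )
    kept: list[Detection] = []
    for d in order:
        if any(
            (class_agnostic or k.label == d.label) and iou(k.box, d.box) > iou_threshold
            for k in kept
        ):
            continue
        kept.append(d)
    return kept


def _jitter_box(
    box: BoundingBox, rng: np.random.Generator, width: int, height: int
) -> BoundingBox:
    """Random rescale (0.6-1.4 per axis) and shift (up to 25% of the size),
    clamped to the image: imitates the imperfect boxes seen at inference."""
    bw = max(2, int(round(box.width * rng.uniform(0.6, 1.4))))
    bh = max(2, int(round(box.height * rng.uniform(0.6, 1.4))))
    cx = (box.x0 + box.x1) / 2 + rng.uniform(-0.25, 0.25) * box.width
    cy = (box.y0 + box.y1) / 2 + rng.uniform(-0.25, 0.25) * box.height
    x0 = int(np.clip(round(cx - bw / 2), 0, width - 2))
    y0 = int(np.clip(round(cy - bh / 2), 0, height - 2))
    return BoundingBox(x0, y0, min(x0 + bw, width), min(y0 + bh, height))


def train_spectral_branch(
    scenes: Sequence[AnnotatedScene],
    cfg: DetectorConfig,
    net_cfg: SpectralNetConfig | None = None,
    subboxes_per_truth: int = 8,
) -> TrainedSpectralNet:
    """Train the 1-D spectral branch on ground-truth region spectra.

    Each truth contributes its full-box mean spectrum plus
    ``subboxes_per_truth`` jittered-box spectra (see :func:`_jitter_box`),
    which both enlarges the training set and teaches the branch the
    background dilution of imperfect boxes.  Spectra are masked to
    ``cfg.spectral_bands`` exactly as at inference.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    rows, labels = [], []
    grid = scenes[0].cube.grid
    for scene in scenes:
        H, W = scene.cube.n_rows, scene.cube.n_cols
        for label, box in scene.truths:
            samples = [box] + [
                _jitter_box(box, rng, W, H) for _ in range(subboxes_per_truth)
            ]
            for b in samples:
                rows.append(extract_box_spectra(scene.cube, b, cfg.spectral_bands))
                labels.append(label)
    if not rows:
        raise ValueError("no ground-truth boxes to train the spectral branch on")
    data = SpectrumDataset(np.vstack(rows), np.array(labels), grid)
    if net_cfg is None:
        net_cfg = SpectralNetConfig.scaled(
            input_len=len(grid),
            n_classes=len(set(labels)),
            seed=cfg.seed,
            epochs=60,
            learning_rate=5e-3,
        )
    return train_classifier(data, net_cfg)


def _build_backbone(cfg: DetectorConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in = 3
    for c_out in cfg.backbone_channels:
        layers.append(Conv2D(c_in, c_out, 3, rng))
        layers.append(ReLU())
        layers.append(MaxPool2D())
        c_in = c_out
    return Sequential(layers)


def _pool_region(F: np.ndarray, box: BoundingBox, stride: int) -> tuple[np.ndarray, tuple]:
    """Average-pool feature map cells covered by the (image-space) box."""
    _C, fh, fw = F.shape
    j0 = int(np.clip(box.x0 // stride, 0, fw - 1))
    i0 = int(np.clip(box.y0 // stride, 0, fh - 1))
    j1 = int(np.clip(-(-box.x1 // stride), j0 + 1, fw))
    i1 = int(np.clip(-(-box.y1 // stride), i0 + 1, fh))
    return F[:, i0:i1, j0:j1].mean(axis=(1, 2)), (i0, i1, j0, j1)


class _DetectorBase:
    """State and helpers shared by both architectures."""

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = _build_backbone(cfg, rng)
        self.stride = 2 ** len(cfg.backbone_channels)
        self.feat_channels = cfg.backbone_channels[-1]
        self._build_heads(rng)
        self.spectral_model: TrainedSpectralNet | None = None
        self.fusion_head: Sequential | None = None
        self.loss_history: list[float] = []
        self._anchor_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _build_heads(self, rng: np.random.Generator) -> None:  # pragma: no cover
        raise NotImplementedError

    def _anchors(self, fh: int, fw: int) -> tuple[np.ndarray, np.ndarray]:
        key = (fh, fw)
        if key not in self._anchor_cache:
            cxcywh = _anchor_grid(fh, fw, self.stride, self.cfg)
            self._anchor_cache[key] = (cxcywh, _to_corners(cxcywh))
        return self._anchor_cache[key]

    def _scene_input(self, scene: AnnotatedScene) -> np.ndarray:
        """Three-band composite as (3, H, W) reflectance planes.

        Channel order matches the pseudo-color rendering (descending
        wavelength), but values stay on the absolute [0, 1] reflectance
        scale: the per-image min-max stretch used for display would blow
        background noise up to full range on defect-free scenes.
        """
        cube = scene.cube
        ordered = sorted(
            self.cfg.render_bands,
            key=lambda b: cube.grid.wavelengths_nm[b],
            reverse=True,
        )
        return cube.values[:, :, ordered].transpose(2, 0, 1)

    def _gt_arrays(self, scene: AnnotatedScene) -> tuple[np.ndarray, np.ndarray]:
        boxes = np.array(
            [[b.x0, b.y0, b.x1, b.y1] for _l, b in scene.truths], dtype=float
        ).reshape(-1, 4)
        labels = np.array(
            [self.cfg.class_names.index(l) for l, _b in scene.truths], dtype=int
        )
        return boxes, labels

    # -- fusion -------------------------------------------------------------

    def _fusion_input_dim(self) -> int:
        assert self.spectral_model is not None
        return self.feat_channels + self.spectral_model.feature_dim

    def _fusion_features(self, F: np.ndarray, cube: Hypercube, box: BoundingBox) -> np.ndarray:
        pooled, _ = _pool_region(F, box, self.stride)
        spec = extract_box_spectra(cube, box, self.cfg.spectral_bands)
        return np.concatenate([pooled, self.spectral_model.extract_features(spec)])

    def _train_fusion_head(self, scenes: Sequence[AnnotatedScene]) -> None:
        if self.spectral_model is None:
            raise ConfigurationError("fusion requires a trained spectral branch")
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 2)
        feats, labels = [], []
        for scene in scenes:
            F = self.backbone.forward(self._scene_input(scene)[None])[0]
            H, W = scene.cube.n_rows, scene.cube.n_cols
            for label, box in scene.truths:
                variants = [box] + [_jitter_box(box, rng, W, H) for _ in range(4)]
                for v in variants:
                    feats.append(self._fusion_features(F, scene.cube, v))
                    labels.append(cfg.class_names.index(label))
        X = np.vstack(feats)
        y = np.array(labels)
        head = Sequential(
            [
                Dense(X.shape[1], cfg.fusion_hidden, rng),
                ReLU(),
                Dense(cfg.fusion_hidden, cfg.n_classes, rng),
            ]
        )
        opt = Adam(head.param_pairs(), lr=cfg.fusion_lr)
        n = X.shape[0]
        for _ in range(cfg.fusion_epochs):
            order = rng.permutation(n)
            for start in range(0, n, 32):
                idx = order[start : start + 32]
                logits = head.forward(X[idx])
                _loss, dlogits = softmax_cross_entropy(logits, y[idx])
                head.backward(dlogits)
                opt.step()
        self.fusion_head = head

    def _apply_fusion(
        self, detections: list[Detection], F: np.ndarray, cube: Hypercube
    ) -> list[Detection]:
        out = []
        for d in detections:
            feat = self._fusion_features(F, cube, d.box)
            probs = softmax(self.fusion_head.forward(feat[None]))[0]
            out.append(
                Detection(
                    d.box,
                    self.cfg.class_names[int(probs.argmax())],
                    d.confidence,
                    probabilities=probs,
                )
            )
        return out

    # -- persistence --------------------------------------------------------

    def _all_param_arrays(self) -> list[np.ndarray]:
        arrays = list(self.backbone.param_arrays())
        arrays += self._head_param_arrays()
        if self.fusion_head is not None:
            arrays += self.fusion_head.param_arrays()
        return arrays

    def _head_param_arrays(self) -> list[np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        meta = {
            "config": asdict(self.cfg),
            "loss_history": self.loss_history,
            "has_fusion_head": self.fusion_head is not None,
            "has_spectral_model": self.spectral_model is not None,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta))
        np.savez(
            prefix.with_suffix(".npz"),
            **{f"p{i}": p for i, p in enumerate(self._all_param_arrays())},
        )
        if self.spectral_model is not None:
            self.spectral_model.save(str(prefix) + "_spectral")


def load_detector(prefix: str | Path):
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    cfg_d = meta["config"]
    for key in ("render_bands", "class_names", "backbone_channels", "anchor_sizes", "anchor_ratios"):
        cfg_d[key] = tuple(cfg_d[key])
    if cfg_d.get("spectral_bands") is not None:
        cfg_d["spectral_bands"] = tuple(cfg_d["spectral_bands"])
    cfg = DetectorConfig(**cfg_d)
    model = build_detector(cfg)
    if meta["has_spectral_model"]:
        model.spectral_model = TrainedSpectralNet.load(str(prefix) + "_spectral")
    if meta["has_fusion_head"]:
        rng = np.random.default_rng(cfg.seed + 2)
        model.fusion_head = Sequential(
            [
                Dense(model._fusion_input_dim(), cfg.fusion_hidden, rng),
                ReLU(),
                Dense(cfg.fusion_hidden, cfg.n_classes, rng),
            ]
        )
    with np.load(prefix.with_suffix(".npz")) as data:
        for i, p in enumerate(model._all_param_arrays()):
            p[...] = data[f"p{i}"]
    model.loss_history = list(meta["loss_history"])
    return model


# ---------------------------------------------------------------------------
# One-stage detector


class OneStageDetector(_DetectorBase):
    """Backbone + one single-scale anchor head (objectness, box, class)."""

    def _build_heads(self, rng: np.random.Generator) -> None:
        self.head = Sequential(
            [Conv2D(self.feat_channels, self.cfg.n_anchors * (5 + self.cfg.n_classes), 1, rng)]
        )

    def _head_param_arrays(self) -> list[np.ndarray]:
        return self.head.param_arrays()

    @property
    def n_detection_scales(self) -> int:
        return 1

    def _forward_raw(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
        F = self.backbone.forward(x[None])
        out = self.head.forward(F)
        _n, _c, fh, fw = out.shape
        A, C = self.cfg.n_anchors, self.cfg.n_classes
        flat = out[0].reshape(A, 5 + C, fh, fw).transpose(0, 2, 3, 1).reshape(-1, 5 + C)
        return F, flat, (fh, fw)

    def _loss_and_grad(
        self, flat: np.ndarray, fh: int, fw: int, gt_boxes: np.ndarray, gt_labels: np.ndarray
    ) -> tuple[float, np.ndarray]:
        cfg = self.cfg
        A, C = cfg.n_anchors, cfg.n_classes
        anchors, corners = self._anchors(fh, fw)
        pos, neg, gt_for = _assign_anchors(corners, gt_boxes, cfg.pos_iou, cfg.neg_iou)
        dflat = np.zeros_like(flat)
        obj = flat[:, 0]
        total = 0.0

        n_pos = max(len(pos), 1)
        losses, dobj, w = _objectness_loss(obj, pos, neg)
        total += float((losses * w).sum())
        dflat[:, 0] = dobj * w

        if len(pos):
            t = _encode(gt_boxes[gt_for[pos]], anchors[pos])
            diff = flat[pos, 1:5] - t
            l1, dl1 = smooth_l1(diff)
            total += float(l1.sum() / n_pos)
            dflat[pos, 1:5] = dl1 / n_pos

            cls_loss, dcls = softmax_cross_entropy(flat[pos, 5:], gt_labels[gt_for[pos]])
            total += cls_loss
            dflat[pos, 5:] = dcls
        return total, dflat

    def train(self, scenes: Sequence[AnnotatedScene]) -> list[float]:
        cfg = self.cfg
        if not any(scene.truths for scene in scenes):
            raise ValueError("no ground-truth boxes in any training scene")
        prepared = [
            (self._scene_input(s), *self._gt_arrays(s), s) for s in scenes
        ]
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.backbone.param_pairs() + self.head.param_pairs(), lr=cfg.learning_rate)
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(prepared))
            epoch_losses = []
            for idx in order:
                x, gt_boxes, gt_labels, _scene = prepared[idx]
                _F, flat, (fh, fw) = self._forward_raw(x)
                loss, dflat = self._loss_and_grad(flat, fh, fw, gt_boxes, gt_labels)
                A, C = cfg.n_anchors, cfg.n_classes
                dout = (
                    dflat.reshape(A, fh, fw, 5 + C)
                    .transpose(0, 3, 1, 2)
                    .reshape(1, A * (5 + C), fh, fw)
                )
                dF = self.head.backward(dout)
                self.backbone.backward(dF)
                opt.step()
                epoch_losses.append(loss)
            self.loss_history.append(float(np.mean(epoch_losses)))
        if cfg.fusion:
            self._train_fusion_head(scenes)
        return self.loss_history

    def detect(
        self, scene: AnnotatedScene | Hypercube, use_fusion: bool | None = None
    ) -> list[Detection]:
        """Localize and classify; ``use_fusion`` overrides the config flag
        (useful for ablations on one trained model)."""
        use_fusion = self.cfg.fusion if use_fusion is None else use_fusion
        cube = scene.cube if isinstance(scene, AnnotatedScene) else scene
        if use_fusion and not cube.calibrated:
            raise ValueError("fusion inference requires a calibrated cube")
        x = self._scene_input(scene if isinstance(scene, AnnotatedScene) else AnnotatedScene(cube, []))
        F, flat, (fh, fw) = self._forward_raw(x)
        anchors, _ = self._anchors(fh, fw)
        obj_p = sigmoid(flat[:, 0])
        keep = np.flatnonzero(obj_p >= self.cfg.conf_threshold)
        keep = keep[np.argsort(-obj_p[keep], kind="stable")][:100]
        corners = _decode(flat[keep, 1:5], anchors[keep])
        cls_probs = softmax(flat[keep, 5:])
        detections = []
        H, W = cube.n_rows, cube.n_cols
        for k, idx in enumerate(keep):
            box = _corners_to_box(corners[k], W, H)
            if box is None:
                continue
            probs = cls_probs[k]
            detections.append(
                Detection(
                    box,
                    self.cfg.class_names[int(probs.argmax())],
                    float(obj_p[idx]),
                    probabilities=probs,
                )
            )
        detections = nms(
            detections, self.cfg.nms_iou, class_agnostic=self.cfg.nms_class_agnostic
        )
        if use_fusion and self.fusion_head is not None:
            detections = self._apply_fusion(detections, F[0], cube)
        return detections


# ---------------------------------------------------------------------------
# Two-stage detector


class TwoStageDetector(_DetectorBase):
    """Backbone + RPN (objectness + coordinate adjustment) + region head."""

    def _build_heads(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        self.rpn = Sequential([Conv2D(self.feat_channels, cfg.n_anchors * 5, 1, rng)])
        self.roi_trunk = Sequential([Dense(self.feat_channels, cfg.roi_hidden, rng), ReLU()])
        self.roi_cls = Dense(cfg.roi_hidden, cfg.n_classes + 1, rng)  # + background
        self.roi_box = Dense(cfg.roi_hidden, 4, rng)

    def _head_param_arrays(self) -> list[np.ndarray]:
        return (
            self.rpn.param_arrays()
            + self.roi_trunk.param_arrays()
            + list(self.roi_cls.params)
            + list(self.roi_box.params)
        )

    @property
    def n_decision_branches(self) -> int:
        return 2  # RPN objectness + coordinate adjustment

    def _rpn_forward(self, F: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        out = self.rpn.forward(F)
        _n, _c, fh, fw = out.shape
        A = self.cfg.n_anchors
        flat = out[0].reshape(A, 5, fh, fw).transpose(0, 2, 3, 1).reshape(-1, 5)
        return flat, (fh, fw)

    def _sample_rois(
        self, scene: AnnotatedScene, rng: np.random.Generator
    ) -> tuple[list[BoundingBox], np.ndarray, np.ndarray]:
        """GT + jittered positives and random negatives, with class targets
        (background = last index) and box-refinement targets for positives."""
        cfg = self.cfg
        H, W = scene.cube.n_rows, scene.cube.n_cols
        gt_boxes, gt_labels = self._gt_arrays(scene)
        rois: list[BoundingBox] = []
        labels: list[int] = []
        refine_targets: list[np.ndarray] = []
        for g, lab in zip(gt_boxes, gt_labels):
            gt_bb = BoundingBox(*g.astype(int))
            candidates = [gt_bb]
            for _ in range(2):
                dx, dy = rng.integers(-3, 4, size=2)
                sw = int(np.clip(gt_bb.x1 + dx, gt_bb.x0 + dx + 2, W))
                sh = int(np.clip(gt_bb.y1 + dy, gt_bb.y0 + dy + 2, H))
                x0 = int(np.clip(gt_bb.x0 + dx, 0, sw - 2))
                y0 = int(np.clip(gt_bb.y0 + dy, 0, sh - 2))
                candidates.append(BoundingBox(x0, y0, sw, sh))
            for c in candidates:
                rois.append(c)
                labels.append(int(lab))
                anchor = _to_cxcywh(np.array([[c.x0, c.y0, c.x1, c.y1]], dtype=float))
                refine_targets.append(_encode(g[None, :], anchor)[0])
        # random negatives
        n_neg = 0
        attempts = 0
        while n_neg < 3 and attempts < 50:
            attempts += 1
            bw = int(rng.integers(6, max(7, W // 3)))
            bh = int(rng.integers(6, max(7, H // 3)))
            x0 = int(rng.integers(0, W - bw))
            y0 = int(rng.integers(0, H - bh))
            cand = np.array([[x0, y0, x0 + bw, y0 + bh]], dtype=float)
            if gt_boxes.shape[0] and _iou_matrix(cand, gt_boxes).max() >= 0.1:
                continue
            rois.append(BoundingBox(x0, y0, x0 + bw, y0 + bh))
            labels.append(cfg.n_classes)  # background
            refine_targets.append(np.zeros(4))
            n_neg += 1
        return rois, np.array(labels), np.vstack(refine_targets)

    def train(self, scenes: Sequence[AnnotatedScene]) -> list[float]:
        cfg = self.cfg
        if not any(scene.truths for scene in scenes):
            raise ValueError("no ground-truth boxes in any training scene")
        prepared = [(self._scene_input(s), *self._gt_arrays(s), s) for s in scenes]
        rng = np.random.default_rng(cfg.seed + 1)
        pairs = (
            self.backbone.param_pairs()
            + self.rpn.param_pairs()
            + self.roi_trunk.param_pairs()
            + list(zip(self.roi_cls.params, self.roi_cls.grads))
            + list(zip(self.roi_box.params, self.roi_box.grads))
        )
        opt = Adam(pairs, lr=cfg.learning_rate)
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(prepared))
            epoch_losses = []
            for idx in order:
                x, gt_boxes, gt_labels, scene = prepared[idx]
                F = self.backbone.forward(x[None])
                flat, (fh, fw) = self._rpn_forward(F)
                anchors, corners = self._anchors(fh, fw)
                pos, neg, gt_for = _assign_anchors(corners, gt_boxes, cfg.pos_iou, cfg.neg_iou)

                dflat = np.zeros_like(flat)
                total = 0.0
                n_pos = max(len(pos), 1)
                losses, dobj, w = _objectness_loss(flat[:, 0], pos, neg)
                total += float((losses * w).sum())
                dflat[:, 0] = dobj * w
                if len(pos):
                    t = _encode(gt_boxes[gt_for[pos]], anchors[pos])
                    l1, dl1 = smooth_l1(flat[pos, 1:5] - t)
                    total += float(l1.sum() / n_pos)
                    dflat[pos, 1:5] = dl1 / n_pos
                A = cfg.n_anchors
                dout = (
                    dflat.reshape(A, fh, fw, 5)
                    .transpose(0, 3, 1, 2)
                    .reshape(1, A * 5, fh, fw)
                )
                dF = self.rpn.backward(dout)

                # region head on sampled proposals
                rois, roi_labels, refine_t = self._sample_rois(scene, rng)
                pooled = np.zeros((len(rois), self.feat_channels))
                regions = []
                for r_i, roi in enumerate(rois):
                    pooled[r_i], region = _pool_region(F[0], roi, self.stride)
                    regions.append(region)
                h = self.roi_trunk.forward(pooled)
                cls_logits = self.roi_cls.forward(h)
                box_deltas = self.roi_box.forward(h)
                cls_loss, dcls = softmax_cross_entropy(cls_logits, roi_labels)
                total += cls_loss
                fg = roi_labels < cfg.n_classes
                dbox = np.zeros_like(box_deltas)
                if fg.any():
                    l1, dl1 = smooth_l1(box_deltas[fg] - refine_t[fg])
                    total += float(l1.sum() / max(fg.sum(), 1))
                    dbox[fg] = dl1 / max(fg.sum(), 1)
                dh = self.roi_cls.backward(dcls) + self.roi_box.backward(dbox)
                dpooled = self.roi_trunk.backward(dh)
                dF_roi = np.zeros_like(F)
                for r_i, (i0, i1, j0, j1) in enumerate(regions):
                    count = (i1 - i0) * (j1 - j0)
                    dF_roi[0, :, i0:i1, j0:j1] += dpooled[r_i][:, None, None] / count

                self.backbone.backward(dF + dF_roi)
                opt.step()
                epoch_losses.append(total)
            self.loss_history.append(float(np.mean(epoch_losses)))
        if cfg.fusion:
            self._train_fusion_head(scenes)
        return self.loss_history

    def _propose(self, flat: np.ndarray, fh: int, fw: int, W: int, H: int) -> list[BoundingBox]:
        anchors, _ = self._anchors(fh, fw)
        scores = sigmoid(flat[:, 0])
        top = np.argsort(-scores, kind="stable")[:100]
        corners = _decode(flat[top, 1:5], anchors[top])
        cands = []
        for k, idx in enumerate(top):
            box = _corners_to_box(corners[k], W, H)
            if box is not None:
                cands.append(Detection(box, "roi", float(scores[idx])))
        kept = nms(cands, 0.7)[: self.cfg.rpn_proposals]
        return [d.box for d in kept]

    def detect(
        self, scene: AnnotatedScene | Hypercube, use_fusion: bool | None = None
    ) -> list[Detection]:
        use_fusion = self.cfg.fusion if use_fusion is None else use_fusion
        cube = scene.cube if isinstance(scene, AnnotatedScene) else scene
        if use_fusion and not cube.calibrated:
            raise ValueError("fusion inference requires a calibrated cube")
        x = self._scene_input(scene if isinstance(scene, AnnotatedScene) else AnnotatedScene(cube, []))
        F = self.backbone.forward(x[None])
        flat, (fh, fw) = self._rpn_forward(F)
        H, W = cube.n_rows, cube.n_cols
        proposals = self._propose(flat, fh, fw, W, H)
        detections = []
        for roi in proposals:
            pooled, _ = _pool_region(F[0], roi, self.stride)
            h = self.roi_trunk.forward(pooled[None])
            probs = softmax(self.roi_cls.forward(h))[0]
            deltas = self.roi_box.forward(h)[0]
            cls_idx = int(probs.argmax())
            if cls_idx == self.cfg.n_classes:  # background
                continue
            if probs[cls_idx] < self.cfg.conf_threshold:
                continue
            anchor = _to_cxcywh(
                np.array([[roi.x0, roi.y0, roi.x1, roi.y1]], dtype=float)
            )
            refined = _decode(deltas[None, :], anchor)[0]
            box = _corners_to_box(refined, W, H)
            if box is None:
                continue
            fg = probs[: self.cfg.n_classes]
            detections.append(
                Detection(
                    box,
                    self.cfg.class_names[cls_idx],
                    float(probs[cls_idx]),
                    probabilities=fg / fg.sum(),
                )
            )
        detections = nms(
            detections, self.cfg.nms_iou, class_agnostic=self.cfg.nms_class_agnostic
        )
        if use_fusion and self.fusion_head is not None:
            detections = self._apply_fusion(detections, F[0], cube)
        return detections


def build_detector(cfg: DetectorConfig):
    """Instantiate an untrained detector for the configured architecture."""
    if cfg.architecture == ONE_STAGE:
        return OneStageDetector(cfg)
    return TwoStageDetector(cfg)


def train_detector(
    scenes: Sequence[AnnotatedScene],
    cfg: DetectorConfig,
    spectral_model: TrainedSpectralNet | None = None,
):
    """Build and train a detector; trains the frozen spectral branch first
    when fusion is enabled and none is supplied."""
    model = build_detector(cfg)
    if cfg.fusion:
        model.spectral_model = spectral_model or train_spectral_branch(scenes, cfg)
    model.train(scenes)
    return model
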