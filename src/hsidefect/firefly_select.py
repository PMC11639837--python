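"""Discrete firefly search over k-band combinations.

Each firefly is a sorted set of k distinct band indices; its luminance is the
hold-out score of the spectral classifier trained on zero-masked spectra
restricted to those bands.  Movement follows the canonical firefly update
(exponential distance-attenuated attraction plus a uniform random step), with
discrete repair: rounding, clamping to the band range, and re-drawing
duplicate indices.  The globally brightest firefly performs a pure random
step each iteration.  Scores are memoized per combination, with per-evaluation
seeds derived from (global seed, combination), so runs are fully
reproducible and identical combinations never retrain.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_net import SpectralNetConfig, apply_band_mask, train_classifier
from .synthgen import SpectrumDataset


@dataclass(frozen=True)
class ObjectiveSettings:
    """How a band combination is scored.

    ``score_kind`` selects the hold-out statistic: "accuracy" (default),
    "macro_f1", or "centroid" (nearest-centroid accuracy, a fast surrogate
    for unit tests).  ``epochs`` caps per-evaluation training cost.
    """

    epochs: int = 15
    score_kind: str = "accuracy"
    learning_rate: float = 5e-3
    batch_size: int = 64
    val_fraction: float = 0.2
    conv_channels: tuple[int, ...] = (8, 16)
    fc_width: int = 32

    def __post_init__(self):
        if self.score_kind not in ("accuracy", "macro_f1", "centroid"):
            raise ValueError(f"unknown score kind '{self.score_kind}'")


@dataclass(frozen=True)
class FireflyParams:
    """Search parameters; defaults n=5, k=3, beta0=0.5, gamma=0.8, alpha=0.6,
    max_iterations=100."""

    n: int = 5
    k: int = 3
    beta0: float = 0.5
    gamma: float = 0.8
    alpha: float = 0.6
    alpha_decay: float = 0.95
    max_iterations: int = 100
    seed: int = 0
    objective: ObjectiveSettings = field(default_factory=ObjectiveSettings)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.k < 1:
            raise ValueError("bands per firefly must be >= 1")
        if not 0.0 < self.beta0 <= 1.0:
            raise ValueError("beta0 must be in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0.0 < self.alpha_decay <= 1.0:
            raise ValueError("alpha_decay must be in (0, 1]")


@dataclass
class Firefly:
    """A band combination (sorted, distinct) with its objective score."""

    bands: tuple[int, ...]
    luminance: float | None = None

    def __post_init__(self):
        b = tuple(int(x) for x in self.bands)
        if len(set(b)) != len(b):
            raise ValueError("band indices must be distinct")
        if tuple(sorted(b)) != b:
            raise ValueError("band indices must be sorted")
        self.bands = b


@dataclass
class SelectionResult:
    """Outcome of a search run."""

    population: list[Firefly]
    history: list[list[float]]
    initial_luminances: list[float]
    best_bands: tuple[int, ...]
    best_luminance: float
    per_firefly_best: list[tuple[tuple[int, ...], float]]
    n_evaluations: int
    n_trainings: int

    def to_json(self, path: str | Path, wavelengths_nm=None) -> None:
        def nm(bands):
            if wavelengths_nm is None:
                return None
            return [float(wavelengths_nm[b]) for b in bands]

        payload = {
            "best_bands": list(self.best_bands),
            "best_bands_nm": nm(self.best_bands),
            "best_luminance": self.best_luminance,
            "population": [
                {"bands": list(f.bands), "bands_nm": nm(f.bands), "luminance": f.luminance}
                for f in self.population
            ],
            "per_firefly_best": [
                {"bands": list(b), "bands_nm": nm(b), "luminance": s}
                for b, s in self.per_firefly_best
            ],
            "initial_luminances": self.initial_luminances,
            "history": self.history,
            "n_evaluations": self.n_evaluations,
            "n_trainings": self.n_trainings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def history_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.history, columns=[f"firefly_{i}" for i in range(len(self.population))]
        )
        df.to_csv(path, index_label="iteration")


def initialize_population(
    params: FireflyParams, num_bands: int, rng: np.random.Generator | None = None
) -> list[Firefly]:
    """n fireflies of k distinct uniform-random band indices each."""
    if num_bands < params.k:
        raise ValueError(f"num_bands={num_bands} < k={params.k}")
    rng = rng or np.random.default_rng(params.seed)
    return [
        Firefly(tuple(sorted(rng.choice(num_bands, size=params.k, replace=False).tolist())))
        for _ in range(params.n)
    ]


def attractiveness(distance: float, beta0: float, gamma: float) -> float:
    """beta = beta0 * exp(-gamma * distance^2)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return beta0 * float(np.exp(-gamma * distance**2))


def _repair(position: np.ndarray, k: int, num_bands: int, rng: np.random.Generator) -> tuple[int, ...]:
    idx = np.clip(np.rint(position), 0, num_bands - 1).astype(int)
    chosen = list(dict.fromkeys(idx.tolist()))  # preserves order, drops dups
    while len(chosen) < k:
        unused = np.setdiff1d(np.arange(num_bands), chosen)
        chosen.append(int(rng.choice(unused)))
    return tuple(sorted(chosen))


def move_firefly(
    dim: Firefly,
    bright: Firefly,
    params: FireflyParams,
    num_bands: int,
    rng: np.random.Generator,
) -> Firefly:
    """Move the dimmer firefly toward the brighter one.

    The continuous update runs in positions normalized to [0, 1] by the band
    range (the canonical O(1) parameter values are meaningless against raw
    band-index distances of tens to hundreds: attraction underflows and the
    random step rounds to zero movement).  The result is mapped back to band
    indices with discrete repair: round, clamp, re-draw duplicates uniformly
    from unused bands, sort.
    """
    scale = max(num_bands - 1, 1)
    z = np.array(dim.bands, dtype=float) / scale
    zb = np.array(bright.bands, dtype=float) / scale
    distance = float(np.linalg.norm(zb - z))
    beta = attractiveness(distance, params.beta0, params.gamma)
    u = rng.random(params.k)
    z_new = z + beta * (zb - z) + params.alpha * (u - 0.5)
    return Firefly(_repair(z_new * scale, params.k, num_bands, rng))


def random_step(
    firefly: Firefly, params: FireflyParams, num_bands: int, rng: np.random.Generator
) -> Firefly:
    """Pure alpha-term random walk (applied to the brightest firefly).

    Runs in the same normalized position space as :func:`move_firefly`.
    """
    scale = max(num_bands - 1, 1)
    z = np.array(firefly.bands, dtype=float) / scale
    u = rng.random(params.k)
    return Firefly(_repair((z + params.alpha * (u - 0.5)) * scale, params.k, num_bands, rng))


def _evaluation_seed(global_seed: int, bands: tuple[int, ...]) -> int:
    payload = ",".join(map(str, bands)).encode()
    return (global_seed * 1000003 + zlib.crc32(payload)) % (2**31 - 1)


def _centroid_score(X, labels, val_fraction, seed) -> float:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    n_val = max(1, int(round(val_fraction * len(labels))))
    va, tr = order[:n_val], order[n_val:]
    classes = sorted(set(labels.tolist()))
    centroids = np.stack([X[tr][labels[tr] == c].mean(axis=0) for c in classes])
    d = ((X[va][:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.array(classes)[d.argmin(axis=1)]
    return float((pred == labels[va]).mean())


class LuminanceEvaluator:
    """Memoized objective: score of the classifier on band-masked spectra."""

    def __init__(self, data: SpectrumDataset, params: FireflyParams):
        self.data = data
        self.params = params
        self.cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0
        self.n_trainings = 0

    def __call__(self, bands: tuple[int, ...]) -> float:
        bands = tuple(sorted(int(b) for b in bands))
        self.n_evaluations += 1
        if bands in self.cache:
            return self.cache[bands]
        obj = self.params.objective
        seed = _evaluation_seed(self.params.seed, bands)
        Xm = apply_band_mask(self.data.X, bands)
        self.n_trainings += 1
        if obj.score_kind == "centroid":
            score = _centroid_score(Xm, self.data.labels, obj.val_fraction, seed)
        else:
            cfg = SpectralNetConfig(
                input_len=self.data.X.shape[1],
                blocks=[(c, 1) for c in obj.conv_channels],
                fc_widths=(obj.fc_width, len(self.data.classes)),
                n_classes=len(self.data.classes),
                learning_rate=obj.learning_rate,
                epochs=obj.epochs,
                batch_size=obj.batch_size,
                val_fraction=obj.val_fraction,
                seed=seed,
            )
            masked = SpectrumDataset(Xm, self.data.labels, self.data.grid)
            model = train_classifier(masked, cfg)
            score = model.validation_score(obj.score_kind)
        self.cache[bands] = score
        return score


def evaluate_luminance(
    firefly: Firefly, data: SpectrumDataset, params: FireflyParams,
    evaluator: LuminanceEvaluator | None = None,
) -> float:
    evaluator = evaluator or LuminanceEvaluator(data, params)
    return evaluator(firefly.bands)


def run_selection(data: SpectrumDataset, params: FireflyParams) -> SelectionResult:
    """Full firefly search; deterministic under ``params.seed``.

    Per iteration: every firefly moves toward each brighter one (using the
    previous iteration's luminances), the brightest takes a random step, then
    all luminances are re-evaluated and recorded.  The step coefficient alpha
    shrinks by ``alpha_decay`` each iteration, shifting the search from
    exploration to exploitation.
    """
    num_bands = data.X.shape[1]
    rng = np.random.default_rng(params.seed)
    evaluator = LuminanceEvaluator(data, params)
    pop = initialize_population(params, num_bands, rng)
    for f in pop:
        f.luminance = evaluator(f.bands)
    initial = [f.luminance for f in pop]

    best_per_firefly: list[tuple[tuple[int, ...], float]] = [
        (f.bands, f.luminance) for f in pop
    ]
    history: list[list[float]] = []
    for it in range(params.max_iterations):
        effective = replace(params, alpha=params.alpha * params.alpha_decay**it)
        lums = [f.luminance for f in pop]
        brightest = int(np.argmax(lums))
        for i in range(params.n):
            for j in range(params.n):
                if lums[j] > lums[i]:
                    moved = move_firefly(pop[i], Firefly(pop[j].bands), effective, num_bands, rng)
                    pop[i] = Firefly(moved.bands, luminance=None)
        pop[brightest] = random_step(pop[brightest], effective, num_bands, rng)
        for i, f in enumerate(pop):
            f.luminance = evaluator(f.bands)
            if f.luminance > best_per_firefly[i][1]:
                best_per_firefly[i] = (f.bands, f.luminance)
        history.append([f.luminance for f in pop])

    best_bands, best_luminance = max(evaluator.cache.items(), key=lambda kv: (kv[1], kv[0]))
    return SelectionResult(
        population=pop,
        history=history,
        initial_luminances=initial,
        best_bands=best_bands,
        best_luminance=best_luminance,
        per_firefly_best=best_per_firefly,
        n_evaluations=evaluator.n_evaluations,
        n_trainings=evaluator.n_trainings,
    )


def random_search(
    data: SpectrumDataset, params: FireflyParams, n_combinations: int
) -> tuple[tuple[int, ...], float]:
    """Uniform random search baseline at a fixed evaluation budget."""
    num_bands = data.X.shape[1]
    rng = np.random.default_rng(params.seed)
    evaluator = LuminanceEvaluator(data, params)
    best_bands, best_score = None, -1.0
    for _ in range(n_combinations):
        bands = tuple(sorted(rng.choice(num_bands, size=params.k, replace=False).tolist()))
        score = evaluator(bands)
        if score > best_score:
            best_bands, best_score = bands, score
    return best_bands, best_score
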