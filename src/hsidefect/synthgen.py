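"""Synthetic labeled spectra and annotated hyperspectral scenes.

Class spectra are flat baselines minus Gaussian absorption features plus
i.i.d. Gaussian noise.  Defect classes carry hemoglobin-like absorption
features in the 420-600 nm range (depth ordered CBC > CBBR > CBB) and a
water-like feature near 962 nm; the background carries no defect features.
Scenes are background cubes with non-overlapping elliptical defect regions
stamped inside their recorded bounding boxes.

All sampling is driven by explicit seeds, so identical specs produce
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hypercube import BoundingBox, Hypercube, WavelengthGrid

DEFECT_CLASSES = ("CBC", "CBB", "CBBR")
BACKGROUND = "background"


class AbsorptionFeature(NamedTuple):
    center_nm: float
    width_nm: float
    depth: float


class PlacementError(RuntimeError):
    """Could not place the requested non-overlapping defects."""


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Parametric reflectance profile for one class.

    reflectance(w) = baseline - sum_i depth_i * exp(-(w - center_i)^2 / (2 width_i^2))
    """

    label: str
    baseline: float
    features: tuple[AbsorptionFeature, ...] = ()
    noise_sd: float = 0.01

    def __post_init__(self):
        feats = tuple(AbsorptionFeature(*f) for f in self.features)
        object.__setattr__(self, "features", feats)
        for f in feats:
            if not 0.0 <= f.depth < 1.0:
                raise ValueError(f"feature depth {f.depth} outside [0, 1)")
            if f.width_nm <= 0:
                raise ValueError("feature width must be positive")
        if not 0.0 < self.baseline < 1.0:
            raise ValueError("baseline must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def curve(self, grid: WavelengthGrid) -> np.ndarray:
        """Noiseless reflectance over the grid."""
        w = grid.wavelengths_nm
        r = np.full(w.shape, self.baseline)
        for c, width, depth in self.features:
            r -= depth * np.exp(-((w - c) ** 2) / (2.0 * width**2))
        return r

    def validate_on(self, grid: WavelengthGrid) -> None:
        r = self.curve(grid)
        if r.min() <= 0 or r.max() >= 1:
            raise ValueError(
                f"profile '{self.label}' leaves (0, 1) on the given grid"
            )


@dataclass(frozen=True)
class Spectrum:
    """1-D reflectance vector aligned to a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.grid):
            raise ValueError("spectrum length must equal grid length")
        object.__setattr__(self, "values", v)


_HEMOGLOBIN_CENTERS = (430.0, 545.0, 576.0)
_WATER_CENTER = 962.0

# depth ordering CBC > CBBR > CBB for hemoglobin features; water-band
# reflectance CBC > CBB > CBBR (i.e. water depth CBC < CBB < CBBR)
_DEFAULT_HEMOGLOBIN_DEPTHS = {
    "CBC": (0.30, 0.27, 0.25),
    "CBBR": (0.21, 0.19, 0.17),
    "CBB": (0.13, 0.11, 0.10),
}
_DEFAULT_WATER_DEPTHS = {"CBC": 0.05, "CBB": 0.09, "CBBR": 0.14}


def default_profiles(
    noise_sd: float = 0.01,
    hemoglobin_depths: dict[str, tuple[float, float, float]] | None = None,
    water_depths: dict[str, float] | None = None,
    baseline: float = 0.62,
    background_baseline: float = 0.72,
    feature_width_nm: float = 12.0,
    water_width_nm: float = 10.0,
) -> list[ClassSpectralProfile]:
    """Profiles for the three defect classes plus background.

    Depth orderings default to hemoglobin CBC > CBBR > CBB and water-band
    absorption CBBR > CBB > CBC, but are plain parameters.
    """
    hemoglobin_depths = hemoglobin_depths or _DEFAULT_HEMOGLOBIN_DEPTHS
    water_depths = water_depths or _DEFAULT_WATER_DEPTHS
    profiles = []
    for label in DEFECT_CLASSES:
        feats = [
            AbsorptionFeature(c, feature_width_nm, d)
            for c, d in zip(_HEMOGLOBIN_CENTERS, hemoglobin_depths[label])
        ]
        feats.append(AbsorptionFeature(_WATER_CENTER, water_width_nm, water_depths[label]))
        profiles.append(
            ClassSpectralProfile(label, baseline, tuple(feats), noise_sd)
        )
    profiles.append(ClassSpectralProfile(BACKGROUND, background_baseline, (), noise_sd))
    return profiles


def planted_band_profiles(
    windows_nm: Sequence[tuple[float, float]] = ((420.0, 450.0), (560.0, 600.0), (950.0, 975.0)),
    depths: dict[str, tuple[float, ...]] | None = None,
    baseline: float = 0.6,
    noise_sd: float = 0.04,
) -> list[ClassSpectralProfile]:
    """Profiles whose class signal lives only inside the given windows.

    Each window contributes one narrow Gaussian feature centred in it; depths
    differ by class, so bands outside every window carry no class
    information.  The default depths make each window separate exactly one
    class from the other two, so no single window resolves all three classes
    and a good band combination must cover at least two windows.  Used for
    band-selection recovery experiments.
    """
    depths = depths or {
        "CBC": (0.30, 0.15, 0.08),
        "CBB": (0.12, 0.30, 0.08),
        "CBBR": (0.12, 0.15, 0.25),
    }
    profiles = []
    for label in DEFECT_CLASSES:
        feats = tuple(
            AbsorptionFeature((lo + hi) / 2.0, max((hi - lo) / 2.0, 12.0), d)
            for (lo, hi), d in zip(windows_nm, depths[label])
        )
        profiles.append(ClassSpectralProfile(label, baseline, feats, noise_sd))
    profiles.append(ClassSpectralProfile(BACKGROUND, baseline, (), noise_sd))
    return profiles


def spectral_only_profiles(
    shared_center_nm: float = 480.0,
    distinct_centers_nm: Sequence[float] = (700.0, 780.0, 860.0),
    baseline: float = 0.62,
    background_baseline: float = 0.72,
    noise_sd: float = 0.01,
) -> list[ClassSpectralProfile]:
    """Defect classes that are identical near ``shared_center_nm`` (where the
    pseudo-color rendering looks) but differ at ``distinct_centers_nm``.

    Renders of the shared band show every defect identically against the
    background, so 2-D appearance carries no class signal while full spectra
    remain separable.
    """
    profiles = []
    for label, center in zip(DEFECT_CLASSES, distinct_centers_nm):
        feats = (
            AbsorptionFeature(shared_center_nm, 14.0, 0.25),
            AbsorptionFeature(center, 12.0, 0.25),
        )
        profiles.append(ClassSpectralProfile(label, baseline, feats, noise_sd))
    profiles.append(ClassSpectralProfile(BACKGROUND, background_baseline, (), noise_sd))
    return profiles


def profiles_by_label(profiles: Sequence[ClassSpectralProfile]) -> dict[str, ClassSpectralProfile]:
    return {p.label: p for p in profiles}


def defect_profiles(profiles: Sequence[ClassSpectralProfile]) -> list[ClassSpectralProfile]:
    return [p for p in profiles if p.label != BACKGROUND]


def sample_spectrum(
    profile: ClassSpectralProfile,
    grid: WavelengthGrid,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Noiseless curve plus Gaussian noise, clipped to [0, 1]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = profile.curve(grid) + rng.normal(0.0, profile.noise_sd, len(grid))
    return Spectrum(np.clip(v, 0.0, 1.0), grid, label=profile.label)


@dataclass
class SpectrumDataset:
    """Labeled spectra as a (n, bands) matrix plus string labels."""

    X: np.ndarray
    labels: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.size:
            raise ValueError("X must be (n, bands) with one label per row")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("band count must equal grid length")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.grid.wavelengths_nm])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumDataset":
        df = pd.read_csv(path)
        grid = WavelengthGrid(np.array([float(c) for c in df.columns[1:]]))
        return cls(df.iloc[:, 1:].to_numpy(float), df["label"].to_numpy(), grid)


def generate_spectrum_dataset(
    profiles: Sequence[ClassSpectralProfile],
    n_per_class: int,
    grid: WavelengthGrid,
    seed: int = 0,
) -> SpectrumDataset:
    """Balanced labeled spectrum set, deterministically shuffled."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for p in profiles:
        curve = p.curve(grid)
        noise = rng.normal(0.0, p.noise_sd, (n_per_class, len(grid)))
        rows.append(np.clip(curve + noise, 0.0, 1.0))
        labels.extend([p.label] * n_per_class)
    X = np.vstack(rows)
    labels = np.array(labels)
    order = rng.permutation(len(labels))
    return SpectrumDataset(X[order], labels[order], grid)


# ---------------------------------------------------------------------------
# Scene generation


@dataclass
class SceneSpec:
    """Parameters of one synthetic annotated scene."""

    height: int = 64
    width: int = 64
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.desk)
    n_defects: tuple[int, int] = (2, 4)
    defect_size: tuple[int, int] = (8, 16)
    class_mix: dict[str, float] | None = None
    seed: int = 0
    max_attempts: int = 200
    margin: int = 2

    def __post_init__(self):
        if self.class_mix is None:
            self.class_mix = {c: 1.0 / len(DEFECT_CLASSES) for c in DEFECT_CLASSES}
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix proportions sum to {total}, not 1")
        if self.n_defects[0] > self.n_defects[1] or self.n_defects[0] < 0:
            raise ValueError("invalid defect count range")
        if self.defect_size[0] < 2 or self.defect_size[0] > self.defect_size[1]:
            raise ValueError("invalid defect size range")


@dataclass
class AnnotatedScene:
    """A hypercube with ground-truth boxes; the detector training unit."""

    cube: Hypercube
    truths: list[tuple[str, BoundingBox]]

    def __post_init__(self):
        for label, box in self.truths:
            if box.x1 > self.cube.n_cols or box.y1 > self.cube.n_rows:
                raise ValueError(f"truth box {box.as_tuple()} out of bounds")


def _boxes_overlap(a: BoundingBox, b: BoundingBox, gap: int = 1) -> bool:
    return not (
        a.x1 + gap <= b.x0
        or b.x1 + gap <= a.x0
        or a.y1 + gap <= b.y0
        or b.y1 + gap <= a.y0
    )


def generate_scene(
    spec: SceneSpec, profiles: Sequence[ClassSpectralProfile]
) -> AnnotatedScene:
    """Stamp elliptical defect regions on a background cube.

    Each defect occupies the ellipse inscribed in its recorded bounding box;
    boxes never overlap.  Raises :class:`PlacementError` when the requested
    defects cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    by_label = profiles_by_label(profiles)
    bg = by_label[BACKGROUND]
    H, W, B = spec.height, spec.width, len(spec.grid)

    cube = bg.curve(spec.grid)[None, None, :] + rng.normal(0.0, bg.noise_sd, (H, W, B))

    n = int(rng.integers(spec.n_defects[0], spec.n_defects[1] + 1))
    class_names = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in class_names])
    truths: list[tuple[str, BoundingBox]] = []
    for _ in range(n):
        label = class_names[int(rng.choice(len(class_names), p=probs))]
        placed = False
        for _attempt in range(spec.max_attempts):
            bw = int(rng.integers(spec.defect_size[0], spec.defect_size[1] + 1))
            bh = int(rng.integers(spec.defect_size[0], spec.defect_size[1] + 1))
            if bw + 2 * spec.margin > W or bh + 2 * spec.margin > H:
                continue
            x0 = int(rng.integers(spec.margin, W - bw - spec.margin + 1))
            y0 = int(rng.integers(spec.margin, H - bh - spec.margin + 1))
            box = BoundingBox(x0, y0, x0 + bw, y0 + bh)
            if any(_boxes_overlap(box, b) for _, b in truths):
                continue
            yy, xx = np.mgrid[y0 : y0 + bh, x0 : x0 + bw]
            cx, cy = x0 + (bw - 1) / 2.0, y0 + (bh - 1) / 2.0
            mask = ((xx - cx) / (bw / 2.0)) ** 2 + ((yy - cy) / (bh / 2.0)) ** 2 <= 1.0
            if not mask.any():
                mask[bh // 2, bw // 2] = True
            prof = by_label[label]
            npix = int(mask.sum())
            patch = prof.curve(spec.grid)[None, :] + rng.normal(
                0.0, prof.noise_sd, (npix, B)
            )
            region = cube[y0 : y0 + bh, x0 : x0 + bw, :]
            region[mask] = patch
            truths.append((label, box))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place defect {len(truths) + 1} of {n} "
                f"after {spec.max_attempts} attempts"
            )
    cube = np.clip(cube, 0.0, 1.0)
    return AnnotatedScene(
        Hypercube(cube, spec.grid, calibrated=True), truths
    )


def generate_scenes(
    spec: SceneSpec,
    profiles: Sequence[ClassSpectralProfile],
    n_scenes: int,
    seed: int | None = None,
) -> list[AnnotatedScene]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from ``seed``."""
    base = spec.seed if seed is None else seed
    scenes = []
    for i in range(n_scenes):
        s = SceneSpec(
            height=spec.height,
            width=spec.width,
            grid=spec.grid,
            n_defects=spec.n_defects,
            defect_size=spec.defect_size,
            class_mix=dict(spec.class_mix),
            seed=base + 7919 * i,
            max_attempts=spec.max_attempts,
            margin=spec.margin,
        )
        scenes.append(generate_scene(s, profiles))
    return scenes


def nearest_centroid_accuracy(
    data: SpectrumDataset, train_fraction: float = 0.8, seed: int = 0
) -> float:
    """Hold-out accuracy of a nearest-centroid classifier on full spectra.

    Independent separability oracle used to validate that learned models have
    a well-posed task.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_train = int(round(train_fraction * len(data)))
    tr, te = order[:n_train], order[n_train:]
    classes = data.classes
    centroids = np.stack(
        [data.X[tr][data.labels[tr] == c].mean(axis=0) for c in classes]
    )
    d = ((data.X[te][:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.array(classes)[d.argmin(axis=1)]
    return float((pred == data.labels[te]).mean())
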