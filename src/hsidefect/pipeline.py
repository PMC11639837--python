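"""End-to-end orchestration: simulate -> select bands -> train -> detect -> evaluate.

A :class:`PipelineConfig` (YAML-friendly dict of plain values) drives every
stage; the global seed propagates to each stage so a run is reproducible from
its manifest.  Stage outputs land in a run directory and completed stages are
skipped on resume.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .hypercube import WavelengthGrid, save_annotations, write_envi
from .synthgen import (
    SceneSpec,
    SpectrumDataset,
    default_profiles,
    defect_profiles,
    generate_scenes,
    generate_spectrum_dataset,
)
from .spectral_net import SpectralNetConfig, train_classifier
from .firefly_select import FireflyParams, ObjectiveSettings, run_selection
from .fusion_detect import DetectorConfig, train_detector, load_detector
from .eval_metrics import evaluate_detections

log = logging.getLogger("hsidefect")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults are desk-scale."""

    seed: int = 0
    grid: str = "desk"  # "desk" (60 bands) or "full" (360 bands)
    n_bands_desk: int = 60
    n_spectra_per_class: int = 300
    n_train_scenes: int = 24
    n_test_scenes: int = 8
    scene_size: int = 64
    defect_size: tuple[int, int] = (8, 16)
    n_defects: tuple[int, int] = (2, 4)
    firefly: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key in ("defect_size", "n_defects"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def make_grid(self) -> WavelengthGrid:
        if self.grid == "full":
            return WavelengthGrid.default()
        return WavelengthGrid.desk(self.n_bands_desk)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Artifacts: scenes (ENVI + JSON annotations), the spectrum dataset CSV,
    band-selection JSON, model checkpoints, detections JSON, the evaluation
    report, and a manifest with the config hash and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.make_grid()
    profiles = default_profiles()
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"hsidefect": __version__, "numpy": np.__version__},
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            marker = out / f".done_{name}"
            if resume and marker.exists():
                log.info("stage %s: already complete, skipping", name)
                manifest["stages"][name] = "skipped"
                return
            log.info("stage %s: running", name)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
            marker.write_text("ok")
            manifest["stages"][name] = "ok"

        return deco

    scenes_dir = out / "scenes"
    state: dict = {}

    def _load_scenes(split: str):
        from .hypercube import read_envi, load_annotations
        from .synthgen import AnnotatedScene

        scenes = []
        for hdr in sorted(scenes_dir.glob(f"{split}_*.hdr")):
            cube = read_envi(hdr)
            truths = load_annotations(hdr.with_suffix(".json"))
            scenes.append(AnnotatedScene(cube, truths))
        if not scenes:
            raise FileNotFoundError(f"no '{split}' scenes under {scenes_dir}")
        return scenes

    @_stage("simulate")
    def _simulate():
        data = generate_spectrum_dataset(
            defect_profiles(profiles), cfg.n_spectra_per_class, grid, seed=cfg.seed
        )
        data.to_csv(out / "spectra.csv")
        spec = SceneSpec(
            height=cfg.scene_size,
            width=cfg.scene_size,
            grid=grid,
            n_defects=cfg.n_defects,
            defect_size=cfg.defect_size,
            seed=cfg.seed,
        )
        scenes_dir.mkdir(exist_ok=True)
        train = generate_scenes(spec, profiles, cfg.n_train_scenes, seed=cfg.seed)
        test = generate_scenes(spec, profiles, cfg.n_test_scenes, seed=cfg.seed + 10_000)
        for split, scenes in (("train", train), ("test", test)):
            for i, s in enumerate(scenes):
                write_envi(s.cube, scenes_dir / f"{split}_{i:03d}.hdr")
                save_annotations(s.truths, scenes_dir / f"{split}_{i:03d}.json")
        state["train"], state["test"] = train, test

    @_stage("select_bands")
    def _select():
        data = SpectrumDataset.from_csv(out / "spectra.csv")
        ff_kwargs = {k: v for k, v in cfg.firefly.items() if k != "objective"}
        objective = ObjectiveSettings(**cfg.firefly.get("objective", {}))
        ff = FireflyParams(seed=cfg.seed, objective=objective, **ff_kwargs)
        result = run_selection(data, ff)
        result.to_json(out / "selection.json", wavelengths_nm=grid.wavelengths_nm)
        result.history_to_csv(out / "selection_history.csv")
        state["bands"] = result.best_bands

    @_stage("train_spectral")
    def _train_spectral():
        data = SpectrumDataset.from_csv(out / "spectra.csv")
        net_cfg = SpectralNetConfig.scaled(
            input_len=len(grid), n_classes=len(data.classes), seed=cfg.seed,
            **cfg.spectral,
        )
        model = train_classifier(data, net_cfg)
        model.save(out / "spectral_model")
        model.history_to_csv(out / "spectral_history.csv")

    @_stage("train_detector")
    def _train_detector():
        bands = state.get("bands")
        if bands is None:
            bands = tuple(json.loads((out / "selection.json").read_text())["best_bands"])
        det_cfg = DetectorConfig(
            render_bands=tuple(bands[:3]),
            spectral_bands=tuple(bands),
            seed=cfg.seed,
            **cfg.detector,
        )
        train_scenes = state.get("train") or _load_scenes("train")
        model = train_detector(train_scenes, det_cfg)
        model.save(out / "detector")
        (out / "detector_losses.json").write_text(json.dumps(model.loss_history))
        state["detector"] = model

    @_stage("detect")
    def _detect():
        model = state.get("detector") or load_detector(out / "detector")
        test_scenes = state.get("test") or _load_scenes("test")
        state["test"] = test_scenes
        records = {}
        for i, scene in enumerate(test_scenes):
            dets = model.detect(scene)
            records[f"test_{i:03d}"] = [
                {
                    "label": d.label,
                    "confidence": d.confidence,
                    "box": list(d.box.as_tuple()),
                    "probabilities": None
                    if d.probabilities is None
                    else d.probabilities.tolist(),
                }
                for d in dets
            ]
        (out / "detections.json").write_text(json.dumps(records, indent=1))
        state["detections"] = records

    @_stage("evaluate")
    def _evaluate():
        from .hypercube import BoundingBox

        records = state.get("detections") or json.loads(
            (out / "detections.json").read_text()
        )
        if "test" not in state:
            state["test"] = _load_scenes("test")
        preds = {
            img: [
                (BoundingBox(*r["box"]), r["label"], r["confidence"]) for r in recs
            ]
            for img, recs in records.items()
        }
        truths = {
            f"test_{i:03d}": scene.truths for i, scene in enumerate(state["test"])
        }
        report = evaluate_detections(
            preds,
            truths,
            classes=sorted({l for t in truths.values() for l, _ in t}),
            **cfg.evaluation,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        (out / "report.txt").write_text(report.to_table())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
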