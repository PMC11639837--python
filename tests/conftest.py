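import numpy as np
import pytest

from hsidefect.fusion_detect import DetectorConfig, train_detector
from hsidefect.hypercube import WavelengthGrid, nearest_band_index
from hsidefect.spectral_net import SpectralNetConfig, train_classifier
from hsidefect.synthgen import (
    SceneSpec,
    default_profiles,
    defect_profiles,
    generate_scenes,
    generate_spectrum_dataset,
    planted_band_profiles,
    spectral_only_profiles,
)


@pytest.fixture(scope="session")
def grid_full():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def grid_desk():
    return WavelengthGrid.desk(60)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def default_dataset(grid_desk, profiles):
    """300 spectra per defect class on the desk grid."""
    return generate_spectrum_dataset(defect_profiles(profiles), 300, grid_desk, seed=1)


@pytest.fixture(scope="session")
def planted_dataset(grid_desk):
    return generate_spectrum_dataset(
        defect_profiles(planted_band_profiles()), 300, grid_desk, seed=2
    )


@pytest.fixture(scope="session")
def trained_scaled_net(default_dataset):
    cfg = SpectralNetConfig.scaled(input_len=60, n_classes=3, seed=0)
    return train_classifier(default_dataset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Detector fixtures: trained once per session and shared between the unit
# suite and the acceptance suite to stay inside the CPU budget.

SCENE_BANDS = 24


@pytest.fixture(scope="session")
def scene_grid():
    return WavelengthGrid.desk(SCENE_BANDS)


@pytest.fixture(scope="session")
def render_bands(scene_grid):
    return tuple(nearest_band_index(scene_grid, nm) for nm in (430.0, 576.0, 962.0))


def _scene_spec(grid, seed=0):
    return SceneSpec(
        height=48, width=48, grid=grid, n_defects=(2, 3), defect_size=(10, 16), seed=seed
    )


@pytest.fixture(scope="session")
def detector_scenes(scene_grid):
    """(train, test) scene lists with the default (visually distinct) classes."""
    profiles = default_profiles()
    spec = _scene_spec(scene_grid)
    return (
        generate_scenes(spec, profiles, 16, seed=100),
        generate_scenes(spec, profiles, 6, seed=20_000),
    )


@pytest.fixture(scope="session")
def spectral_only_scenes(scene_grid):
    """(train, test) scenes whose classes differ only spectrally."""
    profiles = spectral_only_profiles()
    spec = _scene_spec(scene_grid)
    return (
        generate_scenes(spec, profiles, 16, seed=300),
        generate_scenes(spec, profiles, 6, seed=30_000),
    )


def _detector_cfg(render_bands, **kw):
    kw.setdefault("backbone_channels", (16, 32))
    kw.setdefault("epochs", 200)
    kw.setdefault("learning_rate", 2e-3)
    kw.setdefault("pos_iou", 0.35)
    kw.setdefault("neg_iou", 0.35)
    kw.setdefault("nms_iou", 0.35)
    kw.setdefault("seed", 0)
    return DetectorConfig(render_bands=render_bands, **kw)


@pytest.fixture(scope="session")
def trained_one_stage(detector_scenes, render_bands):
    """Fusion-enabled one-stage detector trained on the default scenes."""
    train, _test = detector_scenes
    cfg = _detector_cfg(render_bands, fusion=True, spectral_bands=None)
    return train_detector(train, cfg)


@pytest.fixture(scope="session")
def trained_spectral_only(spectral_only_scenes, render_bands):
    """Fusion-enabled detector for the spectral-only ablation scenes."""
    train, _test = spectral_only_scenes
    cfg = _detector_cfg(render_bands, fusion=True, spectral_bands=None)
    return train_detector(train, cfg)
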