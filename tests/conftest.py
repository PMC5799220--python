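"""Shared fixtures: small synthetic volumes and session-scoped study runs."""

from dataclasses import replace

import numpy as np
import pytest

from faupa.detect import DetectionConfig, detect_faupas
from faupa.synth import SyntheticSpec, calibrate_noise, simulate
from faupa.volume_io import BoldVolume, GridGeometry

SMALL_GEO = GridGeometry(dims=(20, 20, 10), voxel_size=(3.5, 3.5, 3.5),
                         tr=2.5, n_timepoints=160)


@pytest.fixture(scope="session")
def small_geometry() -> GridGeometry:
    return SMALL_GEO


def make_noise_volume(geometry: GridGeometry, seed: int,
                      sd: float = 1.0) -> BoldVolume:
    """Pure white-noise volume (not band-limited): the simplest null."""
    rng = np.random.default_rng(seed)
    data = sd * rng.standard_normal((*geometry.dims, geometry.n_timepoints))
    return BoldVolume(geometry=geometry, data=data,
                      mask=np.ones(geometry.dims, dtype=bool))


def plant_block(geometry: GridGeometry, voxels, course: np.ndarray,
                noise_sd: float = 1.0, seed: int = 0,
                amplitudes=None) -> BoldVolume:
    """Noise volume with a hand-placed set of voxels sharing one course."""
    vol = make_noise_volume(geometry, seed, sd=noise_sd)
    voxels = sorted(voxels)
    amps = np.ones(len(voxels)) if amplitudes is None else np.asarray(amplitudes)
    for (x, y, z), a in zip(voxels, amps):
        vol.data[x, y, z, :] = a * course
    return vol


@pytest.fixture(scope="session")
def calibrated_sd() -> float:
    """Noise sd at which planted within-cluster R-bar is ~0.95 (default spec)."""
    return calibrate_noise(0.95, SyntheticSpec())


@pytest.fixture(scope="session")
def recovery_runs(calibrated_sd):
    """Five seeded simulate+detect runs at the calibrated-R-bar study condition."""
    runs = []
    for seed in range(1, 6):
        spec = SyntheticSpec(noise_sd=calibrated_sd, rng_seed=seed)
        volume, truth = simulate(spec)
        faupas, labelmap = detect_faupas(volume, DetectionConfig())
        runs.append((volume, truth, faupas, labelmap))
    return runs


@pytest.fixture(scope="session")
def null_detection_counts():
    """Detections on 20 seeded cluster-free volumes (specificity check)."""
    counts = []
    for seed in range(100, 120):
        spec = SyntheticSpec(n_clusters=0, rng_seed=seed)
        volume, _ = simulate(spec)
        faupas, _ = detect_faupas(volume, DetectionConfig())
        counts.append(len(faupas))
    return counts
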