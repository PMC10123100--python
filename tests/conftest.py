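"""Shared fixtures: small synthetic fields rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from repliscope.config import OpticsConfig, SimConfig


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    return OpticsConfig(image_shape_px=(64, 256))


@pytest.fixture(scope="session")
def quiet_sim() -> SimConfig:
    """No pauses, fixed rate: the simplest growing-product scenario."""
    return SimConfig(
        mean_rate_bp_s=580.0,
        rate_sd_bp_s=0.0,
        roadblock_occupancy=0.0,
        spontaneous_pause_rate_per_kbp=0.0,
        movie_duration_s=60.0,
        seed=1,
    )


def synth_spot_frame(
    row: float,
    col: float,
    photons: float = 2000.0,
    shape: tuple[int, int] = (64, 64),
    psf_sigma: float = 1.3,
    background: float = 40.0,
    seed: int = 0,
) -> np.ndarray:
    """One rendered emitter with the package's camera model (Poisson + read noise)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    photon_map = np.zeros(shape)
    r0, c0 = int(np.floor(row)), int(np.floor(col))
    fr, fc = row - r0, col - c0
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc), (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        photon_map[r0 + dr, c0 + dc] += photons * w
    expected = ndimage.gaussian_filter(photon_map, psf_sigma) + background
    return rng.poisson(expected).astype(float) + rng.normal(0, 3.0, shape)
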