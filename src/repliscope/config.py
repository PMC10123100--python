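"""Configuration objects for simulation, optics, and analysis.

All experimental constants default to the conditions of the single-molecule
rolling-circle replication assay this package models: an *E. coli* replisome
extruding dsDNA product from a 2,030-bp (or 18-kbp) circular template at a
median rate near 580 bp/s, transient accessory-helicase (Rep) binding at the
fork with ~2 s lifetimes and small integer stoichiometry, ~8 s per-fluorophore
photobleaching, and EMCCD imaging with 200 ms exposures once per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = ["SimConfig", "OpticsConfig", "AnalysisConfig"]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class SimConfig:
    """Ground-truth generator parameters.

    Parameters
    ----------
    template_length_bp
        Circumference of the rolling-circle template; the protein roadblock
        target site recurs once per template length in the linear product.
    mean_rate_bp_s, rate_sd_bp_s
        Elongation-rate distribution across rate segments. Rates are drawn
        from a normal truncated below at the pause threshold (100 bp/s).
    roadblock_site_period_bp, roadblock_occupancy
        Spacing of roadblock sites in the product and the Bernoulli
        probability that a given site passage is actually blocked
        (solution-phase roadblocks rebind stochastically).
    pause_mean_s
        Mean of the exponential roadblock-pause duration.
    spontaneous_pause_rate_per_kbp, spontaneous_pause_mean_s
        Poisson rate (per kbp of product) and exponential mean duration of
        spontaneous replisome pauses.
    rep_binding_freq_per_min, rep_binding_freq_pause_per_min
        Poisson arrival rates of Rep at the fork during elongation and during
        pauses. ``None`` for the pause rate means "same as elongation".
    rep_dwell_mean_s
        Exponential mean of the true (pre-photobleaching) bound dwell.
    rep_stoich_pmf
        Probability mass over the number of labeled monomers per binding
        event (keys are small positive integers).
    photobleach_mean_s
        Per-fluorophore exponential photobleaching time under imaging.
    frame_interval_s, exposure_s, movie_duration_s
        Imaging cadence: one ``exposure_s`` snapshot per ``frame_interval_s``.
    """

    template_length_bp: int = 2030
    mean_rate_bp_s: float = 580.0
    rate_sd_bp_s: float = 60.0
    roadblock_site_period_bp: int = 2030
    roadblock_occupancy: float = 0.25
    pause_mean_s: float = 20.0
    spontaneous_pause_rate_per_kbp: float = 0.06
    spontaneous_pause_mean_s: float = 5.0
    rep_binding_freq_per_min: float = 16.0
    rep_binding_freq_pause_per_min: float | None = 20.0
    rep_dwell_mean_s: float = 2.0
    rep_stoich_pmf: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    photobleach_mean_s: float = 8.0
    frame_interval_s: float = 1.0
    exposure_s: float = 0.2
    movie_duration_s: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(
            template_length_bp=self.template_length_bp,
            mean_rate_bp_s=self.mean_rate_bp_s,
            roadblock_site_period_bp=self.roadblock_site_period_bp,
            pause_mean_s=self.pause_mean_s,
            spontaneous_pause_mean_s=self.spontaneous_pause_mean_s,
            rep_dwell_mean_s=self.rep_dwell_mean_s,
            photobleach_mean_s=self.photobleach_mean_s,
            frame_interval_s=self.frame_interval_s,
            exposure_s=self.exposure_s,
            movie_duration_s=self.movie_duration_s,
        )
        if self.rate_sd_bp_s < 0:
            raise ValueError("rate_sd_bp_s must be non-negative")
        if not 0.0 <= self.roadblock_occupancy <= 1.0:
            raise ValueError("roadblock_occupancy must lie in [0, 1]")
        if self.spontaneous_pause_rate_per_kbp < 0:
            raise ValueError("spontaneous_pause_rate_per_kbp must be non-negative")
        if self.rep_binding_freq_per_min < 0:
            raise ValueError("rep_binding_freq_per_min must be non-negative")
        total = float(sum(self.rep_stoich_pmf.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rep_stoich_pmf must sum to 1 (got {total})")
        if any(int(k) < 1 or p < 0 for k, p in self.rep_stoich_pmf.items()):
            raise ValueError("rep_stoich_pmf keys must be >= 1 with p >= 0")
        if not self.frame_interval_s < self.movie_duration_s:
            raise ValueError("frame_interval_s must be smaller than movie_duration_s")
        if self.exposure_s > self.frame_interval_s:
            raise ValueError("exposure_s cannot exceed frame_interval_s")

    @property
    def pause_binding_freq_per_min(self) -> float:
        if self.rep_binding_freq_pause_per_min is None:
            return self.rep_binding_freq_per_min
        return self.rep_binding_freq_pause_per_min

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rep_stoich_pmf"] = {int(k): float(v) for k, v in self.rep_stoich_pmf.items()}
        return d


@dataclass
class OpticsConfig:
    """Camera / rendering parameters for synthetic movies.

    The camera model is Poisson shot noise on the expected photon image,
    multiplied by a linear gain, plus Gaussian read noise and a constant
    electronic offset (EMCCD excess-noise factor is not modeled). The
    excitation beam profile multiplies both signal and fluorescent
    background, so flat-fielding the offset-subtracted movie restores
    spatial uniformity.
    """

    image_shape_px: tuple[int, int] = (128, 512)
    pixel_size_kbp: float = 0.55
    psf_sigma_px: float = 1.3
    photons_per_fluorophore_per_frame: float = 400.0
    dna_photons_per_px_per_frame: float = 300.0
    background_photons_per_px: float = 40.0
    camera_gain: float = 1.0
    read_noise: float = 3.0
    offset: float = 100.0
    beam_sigma_px: float = 300.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape_px
        if rows < 8 or cols < 8:
            raise ValueError("image_shape_px too small")
        _require_positive(
            pixel_size_kbp=self.pixel_size_kbp,
            psf_sigma_px=self.psf_sigma_px,
            camera_gain=self.camera_gain,
            beam_sigma_px=self.beam_sigma_px,
        )
        if self.background_photons_per_px < 0 or self.read_noise < 0:
            raise ValueError("background and read noise must be non-negative")

    def beam_profile(self) -> np.ndarray:
        """Smooth multiplicative excitation field, peak-normalized to 1."""
        rows, cols = self.image_shape_px
        r = np.arange(rows)[:, None] - (rows - 1) / 2.0
        c = np.arange(cols)[None, :] - (cols - 1) / 2.0
        profile = np.exp(-(r**2 + c**2) / (2.0 * self.beam_sigma_px**2))
        return profile


@dataclass
class AnalysisConfig:
    """Thresholds and switches used across the analysis stages."""

    pause_rate_threshold_bp_s: float = 100.0
    coloc_distance_px: float = 2.0
    rep_half_threshold: float = 0.5
    roi_radius_px: float = 3.0
    detection_threshold_sd: float = 5.0
    fit_window_px: int = 7
    pause_merge_gap_frames: int = 2
    pause_distance_bin_kbp: float = 0.5
    exp_fit_method: str = "mle"  # "mle" (left-truncated) or "histogram_ls"
    bootstrap_n: int = 1000
    bootstrap_seed: int = 12345

    def __post_init__(self) -> None:
        _require_positive(
            pause_rate_threshold_bp_s=self.pause_rate_threshold_bp_s,
            coloc_distance_px=self.coloc_distance_px,
            rep_half_threshold=self.rep_half_threshold,
            roi_radius_px=self.roi_radius_px,
            detection_threshold_sd=self.detection_threshold_sd,
        )
        if self.exp_fit_method not in ("mle", "histogram_ls"):
            raise ValueError("exp_fit_method must be 'mle' or 'histogram_ls'")
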