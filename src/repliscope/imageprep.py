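"""Movie corrections and sub-pixel focus detection.

Preprocessing mirrors the standard single-molecule TIRF chain: subtract the
camera's electronic offset and divide out the excitation-beam profile
(flattening), register frames against frame 0 to remove slow stage drift,
and subtract the first frame so static surface-bound molecules vanish while
growing replication products remain. Foci are local maxima above a robust
threshold refined by 2-D Gaussian fits.

Coordinates are (row, col), 0-based, with pixel centers at integer
coordinates, throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

__all__ = [
    "MovieStack",
    "Focus",
    "flatten",
    "correct_drift",
    "subtract_first_frame",
    "find_peaks",
    "estimate_beam_profile",
    "foci_to_frame",
]


@dataclass
class MovieStack:
    """A time-ordered stack of 2-D frames for one channel."""

    frames: np.ndarray  # (time, rows, cols)
    frame_interval_s: float
    channel: str = "dna"
    pixel_size_kbp: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (time, rows, cols) stack with >= 2 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def save_tiff(self, path) -> None:
        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, metadata={"frame_interval_s": self.frame_interval_s})

    @classmethod
    def load_tiff(cls, path, frame_interval_s: float, **kwargs) -> "MovieStack":
        return cls(tifffile.imread(path).astype(float), frame_interval_s, **kwargs)


@dataclass
class Focus:
    """A detected diffraction-limited spot in one frame."""

    frame_index: int
    row: float
    col: float
    integrated_intensity: float
    fit_sigma_px: float
    fit_ok: bool

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.row, self.col)


def estimate_beam_profile(movie: MovieStack, blur_sigma_px: float = 50.0) -> np.ndarray:
    """Excitation profile estimate: heavy blur of the temporal median frame.

    The temporal median suppresses transient emitters; the wide blur removes
    remaining point structure, leaving the smooth illumination field. The
    result is peak-normalized so flattening preserves peak intensities.
    """
    median_frame = np.median(movie.frames, axis=0)
    offset = float(np.percentile(movie.frames, 0.1))
    smooth = ndimage.gaussian_filter(np.clip(median_frame - offset, 0, None), blur_sigma_px)
    peak = smooth.max()
    if peak <= 0:
        return np.ones(movie.shape)
    profile = smooth / peak
    return np.clip(profile, 1e-3, None)


def flatten(
    movie: MovieStack,
    beam_profile: np.ndarray | None = None,
    offset: float | None = None,
) -> MovieStack:
    """Offset-subtract and divide each frame by the excitation profile.

    ``offset`` defaults to the movie's global intensity floor (0.1th
    percentile), a robust stand-in for the camera's electronic offset when
    it is not supplied from a dark frame.
    """
    if beam_profile is None:
        beam_profile = estimate_beam_profile(movie)
    beam_profile = np.asarray(beam_profile, dtype=float)
    if beam_profile.shape != movie.shape:
        raise ValueError("beam_profile shape must match the frames")
    if np.any(beam_profile <= 0):
        raise ValueError("beam_profile must be strictly positive")
    if offset is None:
        offset = float(np.percentile(movie.frames, 0.1))
    corrected = (movie.frames.astype(float) - offset) / beam_profile[None, :, :]
    return replace(movie, frames=corrected)


def _frame_has_features(frame: np.ndarray, threshold_sd: float = 5.0, min_px: int = 2) -> bool:
    med = np.median(frame)
    sd = 1.4826 * np.median(np.abs(frame - med)) + 1e-12
    return int(np.sum(frame > med + threshold_sd * sd)) >= min_px


def _registration_image(frame: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Median-subtract, clip, and lightly smooth: emphasizes real features
    over the flat background and pixel noise before cross-correlation."""
    out = np.clip(frame - np.median(frame), 0.0, None)
    return ndimage.gaussian_filter(out, smooth_sigma)


def correct_drift(
    movie: MovieStack, upsample_factor: int = 20
) -> tuple[MovieStack, pd.DataFrame]:
    """Register every frame to frame 0 by upsampled cross-correlation.

    Returns the resampled movie and a per-frame drift table with columns
    ``frame, drow, dcol, featureless``. Featureless frames (no pixels well
    above the robust background) get zero shift and a warning flag.
    """
    ref = movie.frames[0].astype(float)
    ref_ok = _frame_has_features(ref)
    ref_reg = _registration_image(ref)
    shifts = np.zeros((movie.n_frames, 2))
    featureless = np.zeros(movie.n_frames, dtype=bool)
    out = movie.frames.astype(float).copy()
    for k in range(1, movie.n_frames):
        frame = movie.frames[k].astype(float)
        if not ref_ok or not _frame_has_features(frame):
            featureless[k] = True
            continue
        shift, _, _ = phase_cross_correlation(
            ref_reg,
            _registration_image(frame),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        shifts[k] = shift
        if np.any(np.abs(shift) > 1e-9):
            out[k] = ndimage.shift(frame, shift, order=1, mode="nearest")
    if featureless.any():
        warnings.warn(
            f"{int(featureless.sum())} featureless frame(s): drift set to zero",
            stacklevel=2,
        )
    trace = pd.DataFrame(
        {
            "frame": np.arange(movie.n_frames),
            "drow": -shifts[:, 0],  # measured displacement of the frame vs frame 0
            "dcol": -shifts[:, 1],
            "featureless": featureless,
        }
    )
    return replace(movie, frames=out), trace


def subtract_first_frame(movie: MovieStack) -> MovieStack:
    """Remove static molecules: frame_t <- max(frame_t - frame_0, 0)."""
    frames = movie.frames.astype(float)
    out = np.clip(frames - frames[0][None, :, :], 0.0, None)
    out[0] = 0.0
    return replace(movie, frames=out)


def _gauss2d(coords, amp, r0, c0, sigma, bg):
    r, c = coords
    return amp * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2 * sigma**2)) + bg


def _fit_gaussian(frame: np.ndarray, row: int, col: int, window: int):
    half = window // 2
    r0, r1 = max(row - half, 0), min(row + half + 1, frame.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, frame.shape[1])
    patch = frame[r0:r1, c0:c1].astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    bg0 = float(np.median(patch))
    amp0 = float(patch.max() - bg0)
    p0 = [max(amp0, 1e-6), float(row), float(col), 1.3, bg0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (rr.ravel(), cc.ravel()),
            patch.ravel(),
            p0=p0,
            maxfev=400,
        )
    except (RuntimeError, ValueError):
        return None
    amp, rf, cf, sigma, bg = popt
    sigma = abs(sigma)
    if not (r0 - 1 <= rf <= r1 and c0 - 1 <= cf <= c1) or amp <= 0 or sigma > window:
        return None
    integrated = 2 * np.pi * amp * sigma**2
    return rf, cf, integrated, sigma


def find_peaks(
    frame: np.ndarray,
    threshold_sd: float = 5.0,
    frame_index: int = 0,
    fit_window: int = 7,
    min_distance: int = 2,
) -> list[Focus]:
    """Detect sub-pixel foci in one frame.

    Candidates are local maxima above ``median + threshold_sd * robust SD``
    of the frame; each is refined by a 2-D Gaussian fit. Fit failures keep
    the integer-pixel candidate with ``fit_ok=False``. Duplicates within
    1 px keep the brighter focus.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    frame = np.asarray(frame, dtype=float)
    med = float(np.median(frame))
    sd = float(1.4826 * np.median(np.abs(frame - med)))
    if sd <= 0:
        sd = float(np.std(frame)) or 1.0
    threshold = med + threshold_sd * sd
    coords = peak_local_max(
        frame, min_distance=min_distance, threshold_abs=threshold, exclude_border=1
    )
    foci: list[Focus] = []
    for row, col in coords:
        fit = _fit_gaussian(frame, int(row), int(col), fit_window)
        if fit is None:
            foci.append(
                Focus(frame_index, float(row), float(col), max(frame[row, col] - med, 0.0), np.nan, False)
            )
        else:
            rf, cf, integrated, sigma = fit
            foci.append(Focus(frame_index, float(rf), float(cf), float(integrated), float(sigma), True))
    # merge duplicates within 1 px, keeping the brighter
    foci.sort(key=lambda f: -f.integrated_intensity)
    kept: list[Focus] = []
    for f in foci:
        if all((f.row - g.row) ** 2 + (f.col - g.col) ** 2 > 1.0 for g in kept):
            kept.append(f)
    return kept


def foci_to_frame(foci: list[Focus]) -> pd.DataFrame:
    """Tidy table of detected foci (frame, row, col, intensity, sigma, fit_ok)."""
    return pd.DataFrame(
        {
            "frame": [f.frame_index for f in foci],
            "row": [f.row for f in foci],
            "col": [f.col for f in foci],
            "intensity": [f.integrated_intensity for f in foci],
            "sigma": [f.fit_sigma_px for f in foci],
            "fit_ok": [f.fit_ok for f in foci],
        }
    )
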