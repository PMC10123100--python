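"""Fluorophore counting, degree of labeling, and colocalization statistics.

The single-fluorophore unit intensity is calibrated from photobleaching
steps of surface-immobilized labeled molecules imaged under the experiment's
own conditions: change-point analysis of each intensity trace yields plateau
drops, and a Gaussian fit of the pooled step-size histogram gives the mean
unit intensity. Stoichiometries follow by dividing a focus's initial
intensity by the unit.

Colocalization uses the centroid rule (two foci colocalize when their
centroids fall within 2 px). The expected rate of coincidental
colocalization for n foci scattered over a field is

    C = (A_R / A_FOV) * n,

the fraction of the field covered by n focus-sized discs (valid while the
discs are sparse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .imageprep import Focus
from .segmentation import detect_steps
from .tracking import IntensityTrace

__all__ = [
    "UnitIntensity",
    "CoincidenceInput",
    "calibrate_unit_intensity",
    "count_fluorophores",
    "initial_intensity",
    "degree_of_labeling",
    "colocalize",
    "chance_coincidence",
]


@dataclass(frozen=True)
class UnitIntensity:
    """Calibrated mean intensity of a single fluorophore (a.u.)."""

    mean: float
    sd: float
    n_steps: int
    source: str = "photobleaching-step Gaussian fit"
    low_confidence: bool = False


@dataclass(frozen=True)
class CoincidenceInput:
    area_focus_px2: float
    area_fov_px2: float
    n_foci: int

    def __post_init__(self) -> None:
        if not 0 < self.area_focus_px2 <= self.area_fov_px2:
            raise ValueError("require 0 < A_R <= A_FOV")
        if self.n_foci < 0:
            raise ValueError("n_foci must be non-negative")


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def bleaching_step_sizes(traces: list[IntensityTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Pool photobleaching step sizes and steps-per-trace across traces."""
    sizes: list[float] = []
    counts: list[int] = []
    for trace in traces:
        fit = detect_steps(trace.times_s, trace.intensity)
        drops = -fit.step_sizes()
        drops = drops[drops > 0]
        sizes.extend(float(d) for d in drops)
        counts.append(int(len(drops)))
    return np.asarray(sizes), np.asarray(counts, dtype=int)


def calibrate_unit_intensity(traces: list[IntensityTrace]) -> UnitIntensity:
    """Single-fluorophore intensity from pooled photobleaching steps.

    Fewer than 20 pooled steps flags the calibration low-confidence.
    The step-size histogram is fit with a Gaussian; when the fit cannot
    converge (few steps, or degenerate histogram) the robust center of the
    pooled steps is used instead.
    """
    sizes, _ = bleaching_step_sizes(traces)
    if sizes.size == 0:
        raise ValueError("no photobleaching steps detected in the calibration traces")
    low_confidence = sizes.size < 20
    if low_confidence:
        warnings.warn(
            f"only {sizes.size} photobleaching steps pooled (< 20): calibration is low-confidence",
            stacklevel=2,
        )
    mean, sd = float(np.median(sizes)), float(1.4826 * np.median(np.abs(sizes - np.median(sizes))))
    if sizes.size >= 10:
        counts, edges = np.histogram(sizes, bins=max(int(np.sqrt(sizes.size) * 2), 8))
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            popt, _ = curve_fit(
                _gaussian,
                centers,
                counts,
                p0=[counts.max(), mean, max(sd, 0.1 * mean)],
                maxfev=2000,
            )
            if 0 < popt[1] < 2 * sizes.max():
                mean, sd = float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            pass
    return UnitIntensity(mean=mean, sd=sd, n_steps=int(sizes.size), low_confidence=low_confidence)


def count_fluorophores(
    initial_intensity: float, unit: UnitIntensity, return_flag: bool = False
):
    """Fluorophores in a focus: round(initial / unit), minimum 0.

    A fractional part in [0.4, 0.6) marks the count ambiguous (returned as
    a second value when ``return_flag`` is set).
    """
    if unit.mean <= 0:
        raise ValueError("unit intensity must be positive")
    ratio = max(initial_intensity, 0.0) / unit.mean
    count = int(round(ratio))
    ambiguous = 0.4 <= (ratio - np.floor(ratio)) < 0.6
    if return_flag:
        return count, bool(ambiguous)
    return count


def initial_intensity(trace: IntensityTrace) -> float:
    """Initial intensity of an event trace: mean of its first plateau.

    Using the first change-point plateau rather than the first frame
    resists single-frame shot noise.
    """
    fit = detect_steps(trace.times_s, trace.intensity)
    return float(fit.levels[0])


def degree_of_labeling(step_counts) -> tuple[pd.DataFrame, int]:
    """Histogram of photobleaching steps per molecule and its modal value.

    Counts are binned over {1, 2, 3+}; molecules with zero detected steps
    are excluded (no evidence of a fluorophore).
    """
    counts = np.asarray(step_counts, dtype=int)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no molecules with detected photobleaching steps")
    binned = np.minimum(counts, 3)
    table = pd.DataFrame(
        {
            "steps": ["1", "2", "3+"],
            "n_molecules": [int(np.sum(binned == k)) for k in (1, 2, 3)],
        }
    )
    mode = int(table.loc[table["n_molecules"].idxmax(), "steps"].rstrip("+"))
    return table, mode


def colocalize(
    foci_a: list[Focus], foci_b: list[Focus], max_dist_px: float = 2.0
) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbor matching of foci across channels.

    Candidate pairs within ``max_dist_px`` are matched in order of
    increasing centroid distance, each focus at most once. Returns
    (index_a, index_b, distance) triples. Symmetric under channel swap.
    """
    pairs = []
    for i, a in enumerate(foci_a):
        for j, b in enumerate(foci_b):
            d = float(np.hypot(a.row - b.row, a.col - b.col))
            if d <= max_dist_px:
                pairs.append((d, i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, d))
    return matches


def chance_coincidence(inp: CoincidenceInput) -> float:
    """Expected chance-coincidence level C = (A_R / A_FOV) * n."""
    return (inp.area_focus_px2 / inp.area_fov_px2) * inp.n_foci
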