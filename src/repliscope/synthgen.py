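"""Ground-truth simulation of rolling-circle replication and Rep binding.

The generator produces, with a single seeded random stream consumed in a
fixed order (trajectory -> binding -> rendering):

1. piecewise-linear product position vs time per molecule, alternating
   elongation segments (rates drawn around the configured mean, truncated
   above the 100 bp/s pause threshold) with roadblock pauses recurring each
   template length and spontaneous pauses arriving as a Poisson process in
   replicated length;
2. Rep binding events arriving as a Poisson process (a distinct rate during
   pauses is supported), each with an integer stoichiometry, an exponential
   bound dwell, and independent exponential photobleaching clocks per
   fluorophore — a fluorophore is visible for min(dwell, bleach);
3. rendered two-channel movies: the DNA channel draws the product as a line
   of uniform emitter density from anchor to leading edge, the Rep channel a
   point emitter at the tip during binding events; frames carry a Gaussian
   PSF, a multiplicative beam profile, Poisson shot noise, gain, read noise,
   an electronic offset, and optional cumulative drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import OpticsConfig, SimConfig
from .imageprep import MovieStack

__all__ = [
    "Segment",
    "PauseRecord",
    "BindingEvent",
    "MoleculeTruth",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_rep_trace",
    "render_movie",
    "default_layout",
    "CalibrationTruth",
    "simulate_calibration_field",
]

ELONGATION = "elongation"
ROADBLOCK = "roadblock_pause"
SPONTANEOUS = "spontaneous_pause"


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    rate_bp_s: float
    kind: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PauseRecord:
    site_bp: float
    start_s: float
    duration_s: float  # observed (truncated at acquisition end if censored)
    kind: str
    censored: bool


@dataclass(frozen=True)
class BindingEvent:
    start_s: float
    dwell_s: float  # true bound dwell (dissociation clock)
    stoichiometry: int
    bleach_times_s: tuple[float, ...]  # per fluorophore, measured from start_s

    @property
    def visible_dwell_s(self) -> float:
        """Time until the event goes dark: min(dissociation, last bleach)."""
        return min(self.dwell_s, max(self.bleach_times_s))

    @property
    def visible_end_s(self) -> float:
        return self.start_s + self.visible_dwell_s

    def n_visible(self, t: float) -> int:
        """Number of emitting fluorophores at absolute time ``t``."""
        dt = t - self.start_s
        if dt < 0 or dt >= self.dwell_s:
            return 0
        return int(sum(1 for b in self.bleach_times_s if b > dt))


@dataclass
class MoleculeTruth:
    molecule_id: int
    segments: list[Segment]
    pauses: list[PauseRecord]
    events: list[BindingEvent] = field(default_factory=list)

    def position_bp(self, t) -> np.ndarray:
        """Piecewise-linear product length in bp at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s.start_s for s in self.segments])
        rates = np.array([s.rate_bp_s for s in self.segments])
        durs = np.array([s.duration_s for s in self.segments])
        seg_start_pos = np.concatenate(([0.0], np.cumsum(rates * durs)))[:-1]
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        pos = seg_start_pos[idx] + rates[idx] * np.clip(t - starts[idx], 0, durs[idx])
        pos[t < starts[0]] = 0.0
        end = self.segments[-1].end_s
        total = seg_start_pos[-1] + rates[-1] * durs[-1]
        pos[t >= end] = total
        return pos

    def replicated_length_bp(self) -> float:
        return float(sum(s.rate_bp_s * s.duration_s for s in self.segments))

    def visible_units(self, window_start: float, window_end: float) -> float:
        """Time-averaged number of emitting fluorophores over a window."""
        width = window_end - window_start
        if width <= 0:
            return 0.0
        total = 0.0
        for ev in self.events:
            if ev.start_s >= window_end or ev.visible_end_s <= window_start:
                continue
            for b in ev.bleach_times_s:
                dark = ev.start_s + min(ev.dwell_s, b)
                lo = max(ev.start_s, window_start)
                hi = min(dark, window_end)
                if hi > lo:
                    total += hi - lo
        return total / width


@dataclass
class GroundTruth:
    cfg: SimConfig
    molecules: list[MoleculeTruth]
    rng: np.random.Generator = field(repr=False, default=None)

    def pause_table(self) -> pd.DataFrame:
        rows = []
        for mol in self.molecules:
            for p in mol.pauses:
                rows.append(
                    {
                        "molecule_id": mol.molecule_id,
                        "site_bp": p.site_bp,
                        "start_s": p.start_s,
                        "duration_s": p.duration_s,
                        "kind": p.kind,
                        "censored": p.censored,
                    }
                )
        return pd.DataFrame(
            rows, columns=["molecule_id", "site_bp", "start_s", "duration_s", "kind", "censored"]
        )

    def segment_table(self) -> pd.DataFrame:
        rows = []
        for mol in self.molecules:
            for s in mol.segments:
                rows.append(
                    {
                        "molecule_id": mol.molecule_id,
                        "start_s": s.start_s,
                        "end_s": s.end_s,
                        "rate_bp_s": s.rate_bp_s,
                        "kind": s.kind,
                    }
                )
        return pd.DataFrame(rows, columns=["molecule_id", "start_s", "end_s", "rate_bp_s", "kind"])

    def event_table(self) -> pd.DataFrame:
        rows = []
        for mol in self.molecules:
            for ev in mol.events:
                rows.append(
                    {
                        "molecule_id": mol.molecule_id,
                        "start_s": ev.start_s,
                        "dwell_s": ev.dwell_s,
                        "visible_dwell_s": ev.visible_dwell_s,
                        "stoichiometry": ev.stoichiometry,
                    }
                )
        return pd.DataFrame(
            rows, columns=["molecule_id", "start_s", "dwell_s", "visible_dwell_s", "stoichiometry"]
        )


def _draw_rate(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Elongation rate ~ Normal(mean, sd) truncated above 100 bp/s."""
    if cfg.rate_sd_bp_s == 0:
        return cfg.mean_rate_bp_s
    for _ in range(1000):
        r = rng.normal(cfg.mean_rate_bp_s, cfg.rate_sd_bp_s)
        if r > 100.0:
            return float(r)
    raise ValueError("rate distribution places essentially no mass above 100 bp/s")


def _simulate_one_trajectory(cfg: SimConfig, rng: np.random.Generator, mol_id: int) -> MoleculeTruth:
    T = cfg.movie_duration_s
    period = float(cfg.roadblock_site_period_bp)
    spont_rate_per_bp = cfg.spontaneous_pause_rate_per_kbp / 1000.0

    segments: list[Segment] = []
    pauses: list[PauseRecord] = []
    t, pos = 0.0, 0.0
    rate = _draw_rate(cfg, rng)

    def next_roadblock(after_bp: float) -> float:
        if cfg.roadblock_occupancy <= 0:
            return np.inf
        site = (np.floor(after_bp / period + 1e-9) + 1.0) * period
        while rng.random() >= cfg.roadblock_occupancy:
            site += period
        return float(site)

    def next_spontaneous(after_bp: float) -> float:
        if spont_rate_per_bp <= 0:
            return np.inf
        return after_bp + float(rng.exponential(1.0 / spont_rate_per_bp))

    nxt_rb = next_roadblock(pos)
    nxt_sp = next_spontaneous(pos)

    while t < T:
        target = min(nxt_rb, nxt_sp)
        dt_to_target = (target - pos) / rate if np.isfinite(target) else np.inf
        if t + dt_to_target >= T:
            segments.append(Segment(t, T, rate, ELONGATION))
            pos += rate * (T - t)
            t = T
            break
        if dt_to_target > 0:
            segments.append(Segment(t, t + dt_to_target, rate, ELONGATION))
            t += dt_to_target
            pos = target
        kind = ROADBLOCK if nxt_rb <= nxt_sp else SPONTANEOUS
        mean = cfg.pause_mean_s if kind == ROADBLOCK else cfg.spontaneous_pause_mean_s
        dur = float(rng.exponential(mean))
        censored = t + dur >= T
        end = min(t + dur, T)
        segments.append(Segment(t, end, 0.0, kind))
        pauses.append(PauseRecord(pos, t, end - t, kind, censored))
        t = end
        if kind == ROADBLOCK:
            nxt_rb = next_roadblock(pos)
        else:
            nxt_sp = next_spontaneous(pos)
        if t >= T:
            break
        rate = _draw_rate(cfg, rng)

    mol = MoleculeTruth(mol_id, segments, pauses)
    if cfg.roadblock_occupancy > 0 and not any(p.kind == ROADBLOCK for p in pauses):
        if period > mol.replicated_length_bp():
            warnings.warn(
                "roadblock period exceeds total replicated length; no roadblock pauses",
                stacklevel=3,
            )
    return mol


def simulate_trajectory(cfg: SimConfig, n_molecules: int = 1) -> GroundTruth:
    """Simulate ``n_molecules`` ground-truth replication trajectories.

    Reproducible given ``cfg.seed``; the returned object carries the live
    random stream so the binding and rendering stages continue it in order.
    """
    rng = np.random.default_rng(cfg.seed)
    molecules = [_simulate_one_trajectory(cfg, rng, i) for i in range(n_molecules)]
    return GroundTruth(cfg, molecules, rng)


def _draw_events_in(
    cfg: SimConfig,
    rng: np.random.Generator,
    t0: float,
    t1: float,
    rate_per_s: float,
) -> list[BindingEvent]:
    if rate_per_s <= 0 or t1 <= t0:
        return []
    stoich_keys = np.array(sorted(cfg.rep_stoich_pmf), dtype=int)
    stoich_p = np.array([cfg.rep_stoich_pmf[k] for k in stoich_keys], dtype=float)
    stoich_p = stoich_p / stoich_p.sum()
    n = rng.poisson(rate_per_s * (t1 - t0))
    starts = np.sort(rng.uniform(t0, t1, n))
    events = []
    for s in starts:
        stoich = int(rng.choice(stoich_keys, p=stoich_p))
        dwell = float(rng.exponential(cfg.rep_dwell_mean_s))
        bleach = tuple(float(b) for b in rng.exponential(cfg.photobleach_mean_s, stoich))
        events.append(BindingEvent(float(s), dwell, stoich, bleach))
    return events


def simulate_rep_trace(cfg: SimConfig, truth: GroundTruth) -> GroundTruth:
    """Augment a GroundTruth with Rep binding events (in place; returned).

    Arrivals are a piecewise-homogeneous Poisson process: the elongation
    rate applies during elongation segments and the (possibly distinct)
    pause rate during pause segments.
    """
    rng = truth.rng if truth.rng is not None else np.random.default_rng(cfg.seed + 1)
    lam_e = cfg.rep_binding_freq_per_min / 60.0
    lam_p = cfg.pause_binding_freq_per_min / 60.0
    for mol in truth.molecules:
        events: list[BindingEvent] = []
        for seg in mol.segments:
            lam = lam_e if seg.kind == ELONGATION else lam_p
            events.extend(_draw_events_in(cfg, rng, seg.start_s, seg.end_s, lam))
        mol.events = sorted(events, key=lambda e: e.start_s)
    return truth


def default_layout(n_molecules: int, shape: tuple[int, int], anchor_col: int = 20):
    """Evenly spaced anchor positions (row, col) along the rows of the field."""
    rows, _ = shape
    margin = 8
    usable = rows - 2 * margin
    if n_molecules == 1:
        return [(rows // 2, anchor_col)]
    step = usable / (n_molecules - 1) if n_molecules > 1 else 0
    if step < 10:
        raise ValueError(f"{n_molecules} molecules do not fit in {rows} rows (needs >=10 px spacing)")
    return [(int(round(margin + i * step)), anchor_col) for i in range(n_molecules)]


def _deposit_bilinear(img: np.ndarray, rows, cols, weights) -> None:
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    weights = np.asarray(weights, dtype=float)
    H, W = img.shape
    inside = (rows > -1) & (rows < H) & (cols > -1) & (cols < W)
    rows, cols, weights = rows[inside], cols[inside], weights[inside]
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        np.add.at(img, (rr[ok], cc[ok]), weights[ok] * w[ok])


def render_movie(
    truth: GroundTruth,
    optics: OpticsConfig,
    channel: str,
    layout: list[tuple[int, int]] | None = None,
) -> MovieStack:
    """Render one channel of the simulated field of view.

    DNA channel: each product is a line of uniform emitter density (the
    intercalating stain binds ~uniformly per kbp) from its anchor to the
    leading edge. Rep channel: a point emitter at the leading edge whose
    brightness is the exposure-averaged number of visible fluorophores.
    Deterministic given the generator's stream; call order is documented as
    DNA first, then Rep.
    """
    if channel not in ("dna", "rep"):
        raise ValueError("channel must be 'dna' or 'rep'")
    cfg = truth.cfg
    rng = truth.rng if truth.rng is not None else np.random.default_rng(cfg.seed + 2)
    shape = optics.image_shape_px
    if layout is None:
        layout = default_layout(len(truth.molecules), shape)
    if len(layout) != len(truth.molecules):
        raise ValueError("layout must give one (row, col) anchor per molecule")
    n_frames = int(np.floor(cfg.movie_duration_s / cfg.frame_interval_s))
    beam = optics.beam_profile()
    px_per_bp = 1.0 / (optics.pixel_size_kbp * 1000.0)
    subsample = 4  # line emitters per pixel of product
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    drift = np.asarray(optics.drift_px_per_frame, dtype=float)
    clipped = False
    for k in range(n_frames):
        t0 = k * cfg.frame_interval_s
        t1 = t0 + cfg.exposure_s
        tm = 0.5 * (t0 + t1)
        photon_map = np.zeros(shape, dtype=float)
        dk = drift * k
        for mol, (arow, acol) in zip(truth.molecules, layout):
            length_px = float(mol.position_bp(tm)[0]) * px_per_bp
            tip_col = acol + length_px
            if tip_col >= shape[1] - 1:
                clipped = True
                tip_col = shape[1] - 1.001
                length_px = tip_col - acol
            if channel == "dna":
                if length_px <= 0:
                    continue
                n_pts = max(int(np.ceil(length_px * subsample)), 1)
                cols = acol + (np.arange(n_pts) + 0.5) * (length_px / n_pts)
                w = np.full(n_pts, optics.dna_photons_per_px_per_frame * length_px / n_pts)
                _deposit_bilinear(photon_map, np.full(n_pts, arow) + dk[0], cols + dk[1], w)
            else:
                units = mol.visible_units(t0, t1)
                if units > 0:
                    _deposit_bilinear(
                        photon_map,
                        [arow + dk[0]],
                        [tip_col + dk[1]],
                        [units * optics.photons_per_fluorophore_per_frame],
                    )
        blurred = ndimage.gaussian_filter(photon_map, optics.psf_sigma_px)
        expected = (blurred + optics.background_photons_per_px) * beam
        counts = rng.poisson(expected).astype(float) * optics.camera_gain
        counts += rng.normal(0.0, optics.read_noise, shape) + optics.offset
        frames[k] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    if clipped:
        warnings.warn("emitters outside the field of view were clipped", stacklevel=2)
    return MovieStack(
        frames,
        cfg.frame_interval_s,
        channel=channel,
        pixel_size_kbp=optics.pixel_size_kbp,
        meta={"layout": layout, "n_frames": n_frames},
    )


@dataclass
class CalibrationTruth:
    """Immobilized-fluorophore field for unit-intensity calibration."""

    positions: np.ndarray  # (n, 2) row, col
    stoichiometries: np.ndarray
    bleach_times_s: list[tuple[float, ...]]


def simulate_calibration_field(
    cfg: SimConfig,
    optics: OpticsConfig,
    n_spots: int,
    stoich_pmf: dict[int, float] | None = None,
    seed: int | None = None,
) -> tuple[CalibrationTruth, MovieStack]:
    """Render surface-immobilized labeled molecules photobleaching stepwise.

    Spots sit at uniform random positions (10-px margin, >= 8 px apart);
    each carries ``stoich`` fluorophores with independent exponential bleach
    clocks and no dissociation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pmf = stoich_pmf if stoich_pmf is not None else {1: 1.0}
    keys = np.array(sorted(pmf), dtype=int)
    p = np.array([pmf[k] for k in keys], dtype=float)
    p = p / p.sum()
    shape = optics.image_shape_px
    margin = 10
    positions = []
    attempts = 0
    while len(positions) < n_spots and attempts < 100 * n_spots:
        attempts += 1
        cand = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if all((cand[0] - q[0]) ** 2 + (cand[1] - q[1]) ** 2 >= 64 for q in positions):
            positions.append(cand)
    positions = np.array(positions)
    stoich = rng.choice(keys, size=len(positions), p=p)
    bleach = [
        tuple(float(b) for b in rng.exponential(cfg.photobleach_mean_s, s)) for s in stoich
    ]
    n_frames = int(np.floor(cfg.movie_duration_s / cfg.frame_interval_s))
    beam = optics.beam_profile()
    drift = np.asarray(optics.drift_px_per_frame, dtype=float)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    for k in range(n_frames):
        t0 = k * cfg.frame_interval_s
        t1 = t0 + cfg.exposure_s
        photon_map = np.zeros(shape, dtype=float)
        units = np.array(
            [
                sum(max(min(b, t1) - t0, 0.0) for b in bl) / (t1 - t0)
                for bl in bleach
            ]
        )
        lit = units > 0
        if lit.any():
            _deposit_bilinear(
                photon_map,
                positions[lit, 0] + drift[0] * k,
                positions[lit, 1] + drift[1] * k,
                units[lit] * optics.photons_per_fluorophore_per_frame,
            )
        blurred = ndimage.gaussian_filter(photon_map, optics.psf_sigma_px)
        expected = (blurred + optics.background_photons_per_px) * beam
        counts = rng.poisson(expected).astype(float) * optics.camera_gain
        counts += rng.normal(0.0, optics.read_noise, shape) + optics.offset
        frames[k] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    movie = MovieStack(frames, cfg.frame_interval_s, channel="rep", pixel_size_kbp=optics.pixel_size_kbp)
    return CalibrationTruth(positions, stoich, bleach), movie
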