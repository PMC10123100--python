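"""Leading-edge tracking and colocalized trace extraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliscope.config import OpticsConfig, SimConfig
from repliscope import imageprep, synthgen, tracking
from repliscope.synthgen import BindingEvent, Segment


def _preprocessed_dna(cfg, optics, n_molecules=1):
    gt = synthgen.simulate_trajectory(cfg, n_molecules)
    movie = synthgen.render_movie(gt, optics, "dna")
    prep = imageprep.subtract_first_frame(
        imageprep.flatten(movie, optics.beam_profile(), offset=optics.offset)
    )
    return gt, prep, movie.meta["layout"]


def test_constant_growth_slope_recovered(quiet_sim, small_optics):
    # 580 bp/s at 0.55 kbp/px is ~1.05 px/frame at 1 s cadence
    gt, prep, layout = _preprocessed_dna(quiet_sim, small_optics)
    traj = tracking.track_leading_edge(prep, layout[0])
    sel = traj.times_s > 5  # skip the sub-resolution early product
    slope = np.polyfit(traj.times_s[sel], traj.edge_position_px[sel], 1)[0]
    expected = 0.58 / small_optics.pixel_size_kbp
    assert slope == pytest.approx(expected, rel=0.05)


def test_stationary_product_has_zero_slope(small_optics):
    cfg = SimConfig(seed=2, movie_duration_s=60.0, rate_sd_bp_s=0.0,
                    roadblock_occupancy=0.0, spontaneous_pause_rate_per_kbp=0.0)
    gt = synthgen.simulate_trajectory(cfg, 1)
    # freeze the molecule at 8 kbp from frame 0 on
    gt.molecules[0].segments = [
        Segment(0.0, 0.01, 800000.0, "elongation"),
        Segment(0.01, 60.0, 0.0, "roadblock_pause"),
    ]
    movie = synthgen.render_movie(gt, small_optics, "dna")
    prep = imageprep.flatten(movie, small_optics.beam_profile(), offset=small_optics.offset)
    traj = tracking.track_leading_edge(prep, movie.meta["layout"][0])
    slope = np.polyfit(traj.times_s, traj.edge_position_px, 1)[0]
    assert abs(slope) < 0.05


def test_pause_mid_movie_is_flat(small_optics):
    cfg = SimConfig(seed=3, movie_duration_s=60.0, rate_sd_bp_s=0.0,
                    roadblock_occupancy=0.0, spontaneous_pause_rate_per_kbp=0.0)
    gt = synthgen.simulate_trajectory(cfg, 1)
    gt.molecules[0].segments = [
        Segment(0.0, 20.0, 580.0, "elongation"),
        Segment(20.0, 40.0, 0.0, "roadblock_pause"),
        Segment(40.0, 60.0, 580.0, "elongation"),
    ]
    movie = synthgen.render_movie(gt, small_optics, "dna")
    prep = imageprep.subtract_first_frame(
        imageprep.flatten(movie, small_optics.beam_profile(), offset=small_optics.offset)
    )
    traj = tracking.track_leading_edge(prep, movie.meta["layout"][0])
    during = traj.edge_position_px[22:40]
    assert during.std() < 0.5


def test_to_kbp_examples_and_linearity():
    traj = tracking.ReplicationTrajectory(
        0, np.arange(3.0), np.array([0.0, 10.0, 4.0]), (10, 10), np.ones(3, bool)
    )
    tracking.to_kbp(traj, 0.55)
    assert traj.edge_position_kbp == pytest.approx([0.0, 5.5, 2.2])
    with pytest.raises(ValueError):
        tracking.to_kbp(traj, -1.0)


@settings(derandomize=True, max_examples=25)
@given(
    a=st.floats(-50, 50),
    b=st.floats(-50, 50),
    px=st.floats(0.01, 5.0),
)
def test_to_kbp_is_linear(a, b, px):
    def convert(x):
        traj = tracking.ReplicationTrajectory(
            0, np.arange(1.0), np.array([x]), (0, 0), np.ones(1, bool)
        )
        return tracking.to_kbp(traj, px).edge_position_kbp[0]

    assert convert(a + b) == pytest.approx(convert(a) + convert(b) - convert(0.0), abs=1e-9)


def test_tracked_rate_in_bp_s_within_ten_percent(quiet_sim, small_optics):
    gt, prep, layout = _preprocessed_dna(quiet_sim, small_optics)
    traj = tracking.to_kbp(
        tracking.track_leading_edge(prep, layout[0]), small_optics.pixel_size_kbp
    )
    sel = traj.times_s > 5
    slope_kbp = np.polyfit(traj.times_s[sel], traj.edge_position_kbp[sel], 1)[0]
    assert slope_kbp * 1000 == pytest.approx(580.0, rel=0.10)


def test_rms_edge_error_below_half_pixel(quiet_sim, small_optics):
    gt, prep, layout = _preprocessed_dna(quiet_sim, small_optics)
    traj = tracking.track_leading_edge(prep, layout[0])
    mid = traj.times_s + quiet_sim.exposure_s / 2  # rendering samples the exposure midpoint
    true_px = gt.molecules[0].position_bp(mid) / 1000.0 / small_optics.pixel_size_kbp
    sel = traj.quality & (true_px > 3)
    rms = np.sqrt(np.mean((traj.edge_position_px[sel] - true_px[sel]) ** 2))
    assert rms < 0.5


# --- Rep trace extraction ---------------------------------------------------


def _rep_scenario(small_optics, events, seed=4):
    cfg = SimConfig(seed=seed, movie_duration_s=40.0, rate_sd_bp_s=0.0,
                    roadblock_occupancy=0.0, spontaneous_pause_rate_per_kbp=0.0,
                    mean_rate_bp_s=580.0)
    gt = synthgen.simulate_trajectory(cfg, 1)
    gt.molecules[0].events = events
    movie = synthgen.render_movie(gt, small_optics, "rep")
    prep = imageprep.flatten(movie, small_optics.beam_profile(), offset=small_optics.offset)
    layout = movie.meta["layout"]
    n = prep.n_frames
    mid = np.arange(n) + 0.5
    true_px = gt.molecules[0].position_bp(mid)[ : ] / 1000.0 / small_optics.pixel_size_kbp
    traj = tracking.ReplicationTrajectory(
        0, prep.times_s(), true_px, layout[0], np.ones(n, bool)
    )
    return gt, prep, traj


def test_no_rep_events_gives_zero_mean_trace(small_optics):
    gt, prep, traj = _rep_scenario(small_optics, [])
    trace = tracking.extract_rep_trace(prep, traj)
    unit = small_optics.photons_per_fluorophore_per_frame
    assert abs(np.nanmean(trace.intensity)) < 0.05 * unit


def test_single_event_intensity_matches_rendered_level(small_optics):
    event = BindingEvent(start_s=10.0, dwell_s=10.0, stoichiometry=1, bleach_times_s=(1e9,))
    gt, prep, traj = _rep_scenario(small_optics, [event])
    trace = tracking.extract_rep_trace(prep, traj)
    # expected integrated intensity: photons x PSF fraction inside r=3 disc
    frac = 1 - np.exp(-(3.0**2) / (2 * small_optics.psf_sigma_px**2))
    expected = small_optics.photons_per_fluorophore_per_frame * frac
    on = trace.intensity[12:19]
    off = np.concatenate([trace.intensity[:9], trace.intensity[22:]])
    assert on.mean() == pytest.approx(expected, rel=0.15)
    assert abs(off.mean()) < 0.1 * expected


def test_emitter_five_px_from_tip_not_colocalized(small_optics):
    event = BindingEvent(start_s=5.0, dwell_s=30.0, stoichiometry=2, bleach_times_s=(1e9, 1e9))
    gt, prep, traj = _rep_scenario(small_optics, [event])
    # shift the trajectory 5 px off the true tip: the focus is detectable in
    # the expanded ROI but fails the 2-px centroid rule
    traj.edge_position_px = traj.edge_position_px - 5.0
    trace = tracking.extract_rep_trace(prep, traj, detect_foci=True)
    mid = slice(10, 30)
    assert trace.foci  # something was found near the ROI
    assert not trace.colocalized[mid].any()


def test_tip_outside_frame_marks_missing(small_optics):
    gt, prep, traj = _rep_scenario(small_optics, [])
    traj.edge_position_px = traj.edge_position_px + 10000.0
    trace = tracking.extract_rep_trace(prep, traj)
    assert trace.missing.all()
    assert np.isnan(trace.intensity).all()
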