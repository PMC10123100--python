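"""Pause classification, periodicity, Rep annotation, and dwell fitting."""

from __future__ import annotations

import numpy as np
import pytest

from repliscope.config import AnalysisConfig, SimConfig
from repliscope import pausekinetics as pk
from repliscope import segmentation, synthgen
from repliscope.segmentation import RateSegment
from repliscope.tracking import IntensityTrace


def _seg(start, end, rate, start_kbp=0.0, i0=0, i1=10):
    return RateSegment(start, end, rate, start_kbp, start_kbp + rate * (end - start) / 1000,
                       0.0, i0, i1)


# --- classification ---------------------------------------------------------


def test_fast_segment_is_not_a_pause():
    pauses = pk.classify_pauses(0, [_seg(0, 30, 580.0)])
    assert pauses == []


def test_slow_segment_becomes_pause_with_duration():
    pauses = pk.classify_pauses(0, [_seg(0, 10, 580.0, 0.0), _seg(10, 22, 50.0, 5.8)],
                                acquisition_end_s=60.0)
    assert len(pauses) == 1
    assert pauses[0].duration_s == pytest.approx(12.0)
    assert pauses[0].site_kbp == pytest.approx(5.8)
    assert not pauses[0].censored


def test_final_segment_at_acquisition_end_is_censored():
    pauses = pk.classify_pauses(0, [_seg(0, 40, 580.0), _seg(40, 60, 10.0, 23.2)],
                                acquisition_end_s=60.0)
    assert pauses[0].censored


def test_adjacent_subthreshold_segments_merge():
    segs = [
        _seg(0, 10, 580.0),
        _seg(10, 20, 20.0, 5.8),
        _seg(21, 30, 30.0, 5.9),  # 1-frame gap: tracking jitter
        _seg(30, 60, 600.0, 5.9),
    ]
    pauses = pk.classify_pauses(0, segs, acquisition_end_s=80.0)
    assert len(pauses) == 1
    assert pauses[0].duration_s == pytest.approx(20.0)


def test_roundtrip_pause_sites_within_300_bp(small_optics):
    """Three >= 5 s pauses inserted at known sites are all recovered."""
    from repliscope import imageprep, tracking

    cfg = SimConfig(seed=5, movie_duration_s=90.0, rate_sd_bp_s=0.0,
                    roadblock_occupancy=0.0, spontaneous_pause_rate_per_kbp=0.0)
    gt = synthgen.simulate_trajectory(cfg, 1)
    sites_bp = []
    segs, t, pos = [], 0.0, 0.0
    for k in range(3):
        segs.append(synthgen.Segment(t, t + 15.0, 580.0, "elongation"))
        pos += 580.0 * 15.0
        t += 15.0
        segs.append(synthgen.Segment(t, t + 10.0, 0.0, "roadblock_pause"))
        sites_bp.append(pos)
        t += 10.0
    segs.append(synthgen.Segment(t, 90.0, 580.0, "elongation"))
    gt.molecules[0].segments = segs
    movie = synthgen.render_movie(gt, small_optics, "dna")
    prep = imageprep.subtract_first_frame(
        imageprep.flatten(movie, small_optics.beam_profile(), offset=small_optics.offset)
    )
    traj = tracking.to_kbp(
        tracking.track_leading_edge(prep, movie.meta["layout"][0]),
        small_optics.pixel_size_kbp,
    )
    rate_segs = segmentation.segment_rates(traj.times_s, traj.edge_position_kbp)
    pauses = pk.classify_pauses(0, rate_segs, acquisition_end_s=90.0)
    assert len(pauses) == 3
    for p, site in zip(pauses, sites_bp):
        assert abs(p.site_kbp - site / 1000.0) < 0.3


# --- pairwise distances -----------------------------------------------------


def test_pairwise_distances_multiset():
    pauses = [
        pk.PauseEvent(0, site, 0.0, 1.0) for site in (2.0, 4.0, 8.0)
    ]
    d, _ = pk.pairwise_pause_distances(pauses)
    assert sorted(d) == pytest.approx([2.0, 4.0, 6.0])


def test_single_pause_per_molecule_gives_empty_result():
    pauses = [pk.PauseEvent(0, 2.0, 0.0, 1.0), pk.PauseEvent(1, 5.0, 0.0, 1.0)]
    d, hist = pk.pairwise_pause_distances(pauses)
    assert len(d) == 0
    assert hist.empty


def test_periodic_sites_histogram_modes_at_multiples():
    rng = np.random.default_rng(0)
    pauses = []
    for mol in range(50):
        ks = np.sort(rng.choice(np.arange(1, 12), size=3, replace=False))
        for k in ks:
            pauses.append(pk.PauseEvent(mol, k * 2.03 + rng.normal(0, 0.1), 0.0, 1.0))
    d, hist = pk.pairwise_pause_distances(pauses, bin_width_kbp=0.5)
    heights = hist.height.to_numpy()
    centers = 0.5 * (hist.bin_left_kbp + hist.bin_right_kbp).to_numpy()
    med = np.median(heights[heights > 0])
    modes = [
        centers[i]
        for i in range(1, len(heights) - 1)
        if heights[i] >= heights[i - 1] and heights[i] >= heights[i + 1] and heights[i] > 2 * med
    ]
    assert modes
    for c in modes:
        k = round(c / 2.03)
        assert k >= 1 and abs(c - k * 2.03) <= 0.5


def test_no_roadblocks_gives_flat_histogram():
    """Uniform (spontaneous) pause sites show no dominant periodic bin."""
    rng = np.random.default_rng(1)
    pauses = []
    for mol in range(60):
        for site in rng.uniform(0, 25, 4):
            pauses.append(pk.PauseEvent(mol, site, 0.0, 1.0))
    _, hist = pk.pairwise_pause_distances(pauses, bin_width_kbp=1.0, max_distance_kbp=20.0)
    heights = hist.height.to_numpy()
    assert heights.max() <= 3 * np.median(heights[heights > 0])


# --- efficiency -------------------------------------------------------------


def test_replication_efficiency_examples():
    assert pk.replication_efficiency(4, 100) == pytest.approx(4.0)
    assert pk.replication_efficiency(0, 100) == 0.0
    with pytest.raises(ValueError):
        pk.replication_efficiency(1, 0)
    with pytest.raises(ValueError):
        pk.replication_efficiency(5, 4)


def test_efficiency_summary_aggregates_replicates():
    mean, se = pk.replication_efficiency_summary([(4, 100), (5, 100), (3, 100)])
    assert mean == pytest.approx(4.0)
    assert se == pytest.approx(1.0 / np.sqrt(3))
    with pytest.raises(ValueError, match="3 replicates"):
        pk.replication_efficiency_summary([(4, 100), (5, 100)])


def test_efficiency_fold_change_between_conditions():
    # mean efficiencies of a weak vs a strong roadblock condition
    assert pk.replication_efficiency(5, 1000) / pk.replication_efficiency(2, 10000) == pytest.approx(25.0)


# --- binding events ---------------------------------------------------------


def _trace(values, dt=1.0):
    values = np.asarray(values, float)
    return IntensityTrace(0, np.arange(len(values)) * dt, values, 3.0)


def test_four_crossings_in_fifteen_seconds_is_sixteen_per_minute():
    y = np.zeros(15)
    y[[2, 5, 9, 13]] = 1.0
    events = pk.binding_events(_trace(y), unit_intensity=1.0)
    assert len(events) == 4
    assert pk.binding_frequency_per_min(events, 15.0) == pytest.approx(16.0)


def test_flat_zero_trace_has_no_events():
    assert pk.binding_events(_trace(np.zeros(30)), unit_intensity=1.0) == []


def test_binding_events_require_positive_unit():
    with pytest.raises(ValueError):
        pk.binding_events(_trace(np.ones(5)), unit_intensity=0.0)


def test_corrected_arrival_rate_recovers_generating_frequency():
    """Dead-time-corrected estimate within 15% of the Poisson arrival rate."""
    cfg = SimConfig(seed=3, movie_duration_s=60.0, roadblock_occupancy=0.0,
                    spontaneous_pause_rate_per_kbp=0.0,
                    rep_binding_freq_per_min=16.0, rep_binding_freq_pause_per_min=16.0)
    gt = synthgen.simulate_rep_trace(cfg, synthgen.simulate_trajectory(cfg, 100))
    traces = []
    for mol in gt.molecules:
        units = np.array([mol.visible_units(k * 1.0, k * 1.0 + cfg.exposure_s) for k in range(60)])
        traces.append(_trace(units))
    lam, tau = pk.estimate_arrival_rate(traces, 1.0, exposure_s=cfg.exposure_s)
    assert lam == pytest.approx(16.0, rel=0.15)


# --- arrival classes --------------------------------------------------------


def _pause(start, end):
    return pk.PauseEvent(0, 1.0, start, end - start)


def _event(start, end):
    return pk.RepEvent(0, start, end, 1.0, 1.0)


def test_spanning_event_is_t0():
    p = pk.annotate_pause_with_rep(_pause(10, 40), [_event(10, 30)])
    assert p.arrival_class == "t0"
    assert p.t_w_s == 0.0
    assert p.t_R_s == pytest.approx(30.0)


def test_late_event_is_t_gt0():
    p = pk.annotate_pause_with_rep(_pause(10, 40), [_event(18, 25)])
    assert p.arrival_class == "t_gt0"
    assert p.t_w_s == pytest.approx(8.0)
    assert p.t_R_s == pytest.approx(22.0)


def test_no_event_is_no_rep():
    p = pk.annotate_pause_with_rep(_pause(10, 40), [_event(50, 60)])
    assert p.arrival_class == "no_rep"
    assert p.t_w_s is None and p.t_R_s is None


def test_arrival_classes_partition_and_time_bounds():
    rng = np.random.default_rng(2)
    classes = {"t0": 0, "t_gt0": 0, "no_rep": 0}
    for _ in range(200):
        p0, p1 = 10.0, 10.0 + rng.exponential(20.0)
        events = [
            _event(s, s + rng.exponential(2.0))
            for s in np.sort(rng.uniform(0, p1 + 10, rng.poisson(5)))
        ]
        p = pk.annotate_pause_with_rep(_pause(p0, p1), events, frame_interval_s=1.0)
        classes[p.arrival_class] += 1
        if p.arrival_class == "t0":
            assert p.t_R_s <= p.duration_s + 1e-9
        if p.arrival_class == "t_gt0":
            assert p.t_w_s + p.t_R_s <= p.duration_s + 1.0 + 1e-9
    assert sum(classes.values()) == 200


def test_median_wait_time_decreases_with_arrival_rate():
    rng = np.random.default_rng(4)
    medians = []
    for rate_per_min in (5.0, 15.0, 45.0):
        waits = []
        for _ in range(300):
            p = _pause(0.0, 60.0)
            starts = np.sort(rng.uniform(0, 60, rng.poisson(rate_per_min)))
            events = [_event(s, s + 1.0) for s in starts]
            ann = pk.annotate_pause_with_rep(p, events, frame_interval_s=0.0)
            if ann.arrival_class == "t_gt0":
                waits.append(ann.t_w_s)
        medians.append(np.median(waits))
    assert medians[0] > medians[1] > medians[2]


# --- distribution fitting ---------------------------------------------------


def test_exponential_mle_is_sample_mean_without_truncation():
    fit = pk.fit_duration_distribution([2.0, 2.0, 2.0, 2.0, 2.0], truncation_s=0.0)
    assert fit.mean == pytest.approx(2.0)
    assert fit.model == "exponential" and fit.method == "mle"


def test_gaussian_fit_mean():
    fit = pk.fit_duration_distribution([1.0, 2.0, 3.0, 2.0, 2.0], model="gaussian")
    assert fit.mean == pytest.approx(2.0)
    assert fit.sd is not None


def test_fit_refuses_small_samples():
    with pytest.raises(ValueError, match=">= 5"):
        pk.fit_duration_distribution([1.0, 2.0, 3.0])


def test_censored_durations_are_excluded_and_counted():
    durations = [5.0, 6.0, 7.0, 8.0, 9.0, 100.0, 100.0]
    fit = pk.fit_duration_distribution(
        durations, censored_flags=[0, 0, 0, 0, 0, 1, 1], truncation_s=0.0
    )
    assert fit.n == 5
    assert fit.n_censored_excluded == 2
    assert fit.mean == pytest.approx(7.0)


@pytest.mark.parametrize("tau", [5.0, 20.0, 80.0])
def test_truncated_mle_recovers_exponential_mean(tau):
    """500 seeded draws: fitted mean within 3 bootstrap SE of the truth."""
    rng = np.random.default_rng(int(tau))
    t0 = 1.0
    draws = t0 + rng.exponential(tau, 500)  # left-truncated observation model
    fit = pk.fit_duration_distribution(draws, truncation_s=t0)
    assert abs(fit.mean - tau) < 3 * fit.se


def test_histogram_ls_method_agrees_roughly_with_mle():
    rng = np.random.default_rng(10)
    draws = rng.exponential(10.0, 2000)
    fit = pk.fit_duration_distribution(draws, method="histogram_ls")
    assert fit.method == "histogram_ls"
    assert fit.mean == pytest.approx(10.0, rel=0.25)
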