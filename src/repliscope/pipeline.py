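"""End-to-end orchestration: simulate -> render -> analyze -> compare to truth.

This module is the executable heart of the analysis scripts, the CLI, and
the acceptance checks: it renders synthetic two-channel movies of
rolling-circle replication with periodic roadblock pauses, runs the full
image-analysis chain (flatten, first-frame subtraction, leading-edge
tracking, change-point segmentation, pause classification, Rep trace
extraction, unit-intensity calibration, arrival-class annotation), and
reports recovered quantities side by side with the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imageprep, pausekinetics, segmentation, stoichcoloc, synthgen, tracking
from .config import AnalysisConfig, OpticsConfig, SimConfig

__all__ = ["EndToEndResult", "run_end_to_end", "calibrate_from_field", "annotate_truth_pauses"]

MOLECULES_PER_FIELD = 8


@dataclass
class EndToEndResult:
    """Recovered vs generating quantities for one synthetic study."""

    n_molecules: int
    truth: list[synthgen.GroundTruth]
    trajectories: list[tracking.ReplicationTrajectory]
    segments: dict[int, list[segmentation.RateSegment]]
    pauses: list[pausekinetics.PauseEvent]
    rep_traces: list[tracking.IntensityTrace]
    unit_intensity: stoichcoloc.UnitIntensity
    metrics: dict = field(default_factory=dict)

    def pause_table(self) -> pd.DataFrame:
        rows = [
            {
                "molecule_id": p.molecule_id,
                "site_kbp": p.site_kbp,
                "start_s": p.start_s,
                "duration_s": p.duration_s,
                "censored": p.censored,
                "arrival_class": p.arrival_class,
                "t_w_s": p.t_w_s,
                "t_R_s": p.t_R_s,
            }
            for p in self.pauses
        ]
        return pd.DataFrame(rows)


def calibrate_from_field(
    cfg: SimConfig,
    optics: OpticsConfig,
    n_spots: int = 60,
    seed: int = 7001,
    stoich_pmf: dict[int, float] | None = None,
):
    """Unit-intensity calibration from an immobilized-fluorophore field.

    Returns ``(UnitIntensity, traces, CalibrationTruth)``; imaging settings
    match the experiment, as the calibration must.
    """
    cal_truth, movie = synthgen.simulate_calibration_field(
        cfg, optics, n_spots, stoich_pmf=stoich_pmf or {1: 1.0}, seed=seed
    )
    flat = imageprep.flatten(movie, optics.beam_profile(), offset=optics.offset)
    traces = []
    for pos in cal_truth.positions:
        anchor = (int(round(pos[0])), int(round(pos[1])))
        traj = tracking.ReplicationTrajectory(
            0,
            flat.times_s(),
            np.zeros(flat.n_frames),
            anchor,
            np.ones(flat.n_frames, bool),
        )
        traces.append(tracking.extract_rep_trace(flat, traj, roi_radius_px=3.0))
    unit = stoichcoloc.calibrate_unit_intensity(traces)
    return unit, traces, cal_truth


def annotate_truth_pauses(truth: synthgen.GroundTruth) -> pd.DataFrame:
    """Arrival classes of the generating process itself (the reference).

    Classes are assigned from the true visible-event intervals with the
    same rules as the analysis, so recovered fractions are compared with
    the ground-truth process rather than re-derived statistics.
    """
    rows = []
    for mol in truth.molecules:
        events = [
            pausekinetics.RepEvent(mol.molecule_id, e.start_s, e.visible_end_s, 0.0, 0.0)
            for e in mol.events
            if e.visible_dwell_s > 0
        ]
        for p in mol.pauses:
            pe = pausekinetics.PauseEvent(
                molecule_id=mol.molecule_id,
                site_kbp=p.site_bp / 1000.0,
                start_s=p.start_s,
                duration_s=p.duration_s,
                censored=p.censored,
            )
            pe = pausekinetics.annotate_pause_with_rep(pe, events, frame_interval_s=0.0)
            rows.append(
                {
                    "molecule_id": mol.molecule_id,
                    "site_kbp": pe.site_kbp,
                    "start_s": pe.start_s,
                    "duration_s": pe.duration_s,
                    "kind": p.kind,
                    "censored": p.censored,
                    "arrival_class": pe.arrival_class,
                    "t_w_s": pe.t_w_s,
                    "t_R_s": pe.t_R_s,
                }
            )
    return pd.DataFrame(rows)


def _event_initial_intensity(trace: tracking.IntensityTrace, event: pausekinetics.RepEvent) -> float:
    """Initial intensity of one binding event.

    Mean of the first change-point plateau of the event's frames; events
    too short for a plateau (< 3 frames) fall back to their peak frame,
    which for a snapshot exposure is the least-diluted sample.
    """
    sel = (trace.times_s >= event.start_s - 1e-9) & (trace.times_s < event.end_s - 1e-9)
    y = trace.intensity[sel]
    t = trace.times_s[sel]
    if len(y) >= 6:
        fit = segmentation.detect_steps(t, y)
        return float(fit.levels.max() if len(fit.levels) > 1 else fit.levels[0])
    return float(np.max(y)) if len(y) else 0.0


def analyze_field(
    dna: imageprep.MovieStack,
    rep: imageprep.MovieStack | None,
    layout: list[tuple[int, int]],
    optics: OpticsConfig,
    analysis: AnalysisConfig | None = None,
    unit_intensity: float | None = None,
):
    """Analyze one rendered/recorded field: track, segment, classify, extract.

    Returns ``(trajectories, segments_by_molecule, pauses, rep_traces)``.
    Pauses are Rep-annotated only when both a Rep movie and a calibrated
    unit intensity are supplied.
    """
    analysis = analysis or AnalysisConfig()
    beam = optics.beam_profile()
    dt = dna.frame_interval_s
    dna_p = imageprep.subtract_first_frame(imageprep.flatten(dna, beam, offset=optics.offset))
    rep_p = imageprep.flatten(rep, beam, offset=optics.offset) if rep is not None else None
    trajectories, rep_traces = [], []
    segments: dict[int, list[segmentation.RateSegment]] = {}
    pauses: list[pausekinetics.PauseEvent] = []
    acquisition_end = dna.n_frames * dt
    for mol_id, anchor in enumerate(layout):
        traj = tracking.track_leading_edge(dna_p, anchor, molecule_id=mol_id)
        traj = tracking.to_kbp(traj, optics.pixel_size_kbp)
        trajectories.append(traj)
        segs = segmentation.segment_rates(traj.times_s, traj.edge_position_kbp)
        segments[mol_id] = segs
        mol_pauses = pausekinetics.classify_pauses(
            mol_id, segs, analysis, acquisition_end_s=acquisition_end, frame_interval_s=dt
        )
        if rep_p is not None:
            trace = tracking.extract_rep_trace(rep_p, traj, roi_radius_px=analysis.roi_radius_px)
            rep_traces.append(trace)
            if unit_intensity is not None:
                events = pausekinetics.binding_events(trace, unit_intensity, analysis)
                mol_pauses = [
                    pausekinetics.annotate_pause_with_rep(p, events, frame_interval_s=dt)
                    for p in mol_pauses
                ]
        pauses.extend(mol_pauses)
    return trajectories, segments, pauses, rep_traces


def run_end_to_end(
    seed: int = 7,
    n_molecules: int = 50,
    cfg: SimConfig | None = None,
    optics: OpticsConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> EndToEndResult:
    """Full synthetic study: periodic roadblock pausing watched by Rep.

    Renders fields of ``MOLECULES_PER_FIELD`` molecules each (two channels,
    default 128 x 512 px), analyzes every molecule blind to the truth, and
    fills ``result.metrics`` with recovered-vs-true summaries:

    - ``rate_true/rate_recovered_bp_s`` — median elongation-segment rate;
    - ``pause distance histogram`` modes vs the template periodicity;
    - ``stoich_accuracy_12`` — 1-vs-2 fluorophore counting on matched events;
    - arrival-class fractions (t0 / t_gt0 / no_rep), recovered and true;
    - ``freq_true/freq_recovered_per_min`` — dead-time-corrected Rep
      arrival rate vs the truth's time-weighted generating rate.
    """
    cfg = cfg or SimConfig(seed=seed)
    optics = optics or OpticsConfig()
    analysis = analysis or AnalysisConfig()
    dt = cfg.frame_interval_s

    # --- simulate and render, field by field -----------------------------
    truths: list[synthgen.GroundTruth] = []
    trajectories: list[tracking.ReplicationTrajectory] = []
    rep_traces: list[tracking.IntensityTrace] = []
    segments: dict[int, list[segmentation.RateSegment]] = {}
    mol_offset = 0
    n_fields = int(np.ceil(n_molecules / MOLECULES_PER_FIELD))
    beam = optics.beam_profile()
    for f in range(n_fields):
        n_here = min(MOLECULES_PER_FIELD, n_molecules - f * MOLECULES_PER_FIELD)
        field_cfg = SimConfig(**{**cfg.to_dict(), "seed": cfg.seed + 1000 * f})
        gt = synthgen.simulate_trajectory(field_cfg, n_here)
        gt = synthgen.simulate_rep_trace(field_cfg, gt)
        for i, mol in enumerate(gt.molecules):
            mol.molecule_id = mol_offset + i
        dna = synthgen.render_movie(gt, optics, "dna")
        rep = synthgen.render_movie(gt, optics, "rep")
        truths.append(gt)
        layout = dna.meta["layout"]
        dna_p = imageprep.subtract_first_frame(
            imageprep.flatten(dna, beam, offset=optics.offset)
        )
        rep_p = imageprep.flatten(rep, beam, offset=optics.offset)
        for mol, anchor in zip(gt.molecules, layout):
            traj = tracking.track_leading_edge(dna_p, anchor, molecule_id=mol.molecule_id)
            traj = tracking.to_kbp(traj, optics.pixel_size_kbp)
            trajectories.append(traj)
            segs = segmentation.segment_rates(traj.times_s, traj.edge_position_kbp)
            segments[mol.molecule_id] = segs
            rep_traces.append(
                tracking.extract_rep_trace(
                    rep_p, traj, roi_radius_px=analysis.roi_radius_px
                )
            )
        mol_offset += n_here

    # --- calibration under matched imaging -------------------------------
    unit, _, _ = calibrate_from_field(cfg, optics, n_spots=60, seed=cfg.seed + 90001)

    # --- pauses, Rep events, annotations ---------------------------------
    all_pauses: list[pausekinetics.PauseEvent] = []
    events_by_mol: dict[int, list[pausekinetics.RepEvent]] = {}
    for traj, trace in zip(trajectories, rep_traces):
        mol_id = traj.molecule_id
        pauses = pausekinetics.classify_pauses(
            mol_id,
            segments[mol_id],
            analysis,
            acquisition_end_s=cfg.movie_duration_s,
            frame_interval_s=dt,
        )
        events = pausekinetics.binding_events(trace, unit.mean, analysis)
        events_by_mol[mol_id] = events
        for p in pauses:
            all_pauses.append(
                pausekinetics.annotate_pause_with_rep(p, events, frame_interval_s=dt)
            )

    # --- metrics ---------------------------------------------------------
    metrics: dict = {}
    truth_segments = pd.concat([gt.segment_table() for gt in truths], ignore_index=True)
    truth_pauses = pd.concat([annotate_truth_pauses(gt) for gt in truths], ignore_index=True)
    truth_events = pd.concat([gt.event_table() for gt in truths], ignore_index=True)

    elong = [
        s.rate_bp_s
        for segs in segments.values()
        for s in segs
        if s.rate_bp_s >= analysis.pause_rate_threshold_bp_s and s.duration_s >= 3 * dt
    ]
    true_elong = truth_segments.query("kind == 'elongation' and end_s - start_s >= @dt")
    metrics["rate_recovered_bp_s"] = float(np.median(elong)) if elong else np.nan
    metrics["rate_true_bp_s"] = float(
        np.average(true_elong.rate_bp_s, weights=true_elong.end_s - true_elong.start_s)
    )

    # pairwise pause-site distances and their periodicity
    total_product_kbp = float(
        sum(gt_mol.replicated_length_bp() for gt in truths for gt_mol in gt.molecules)
    ) / 1000.0
    distances, hist = pausekinetics.pairwise_pause_distances(
        all_pauses,
        total_product_length_kbp=total_product_kbp,
        bin_width_kbp=analysis.pause_distance_bin_kbp,
    )
    metrics["pause_distances_kbp"] = distances
    metrics["pause_distance_hist"] = hist
    metrics["n_pauses_recovered"] = len(all_pauses)
    metrics["n_pauses_true"] = len(truth_pauses)

    # arrival-class fractions (uncensored pauses with known class)
    def _fractions(frame: pd.DataFrame) -> dict[str, float]:
        counts = frame["arrival_class"].value_counts()
        n = int(counts.sum())
        return {
            "t0": float(counts.get("t0", 0)) / max(n, 1),
            "t_gt0": float(counts.get("t_gt0", 0)) / max(n, 1),
            "no_rep": float(counts.get("no_rep", 0)) / max(n, 1),
            "n": n,
        }

    rec_pause_frame = pd.DataFrame(
        [
            {"arrival_class": p.arrival_class}
            for p in all_pauses
            if p.arrival_class is not None and p.duration_s >= 2 * dt
        ]
    )
    true_pause_frame = truth_pauses.query("duration_s >= 2 * @dt")
    metrics["arrival_fractions_recovered"] = (
        _fractions(rec_pause_frame) if len(rec_pause_frame) else {"n": 0}
    )
    metrics["arrival_fractions_true"] = _fractions(true_pause_frame)

    # Rep arrival frequency: dead-time-corrected vs time-weighted truth
    lam_hat, tau_hat = pausekinetics.estimate_arrival_rate(
        rep_traces,
        unit.mean,
        analysis,
        frame_interval_s=dt,
        exposure_s=cfg.exposure_s,
        seed=cfg.seed + 40404,
    )
    pause_time = float(
        truth_segments.query("kind != 'elongation'").eval("end_s - start_s").sum()
    )
    total_time = float(truth_segments.eval("end_s - start_s").sum())
    lam_true = (
        cfg.rep_binding_freq_per_min * (total_time - pause_time)
        + cfg.pause_binding_freq_per_min * pause_time
    ) / total_time
    metrics["freq_recovered_per_min"] = lam_hat
    metrics["freq_true_per_min"] = float(lam_true)
    metrics["visible_dwell_recovered_s"] = tau_hat
    metrics["visible_dwell_true_s"] = float(truth_events.visible_dwell_s.mean())

    # stoichiometry of recovered events matched to true events (1 vs 2)
    n_checked = n_correct = 0
    trace_by_mol = {tr.molecule_id: tr for tr in rep_traces}
    for gt in truths:
        for mol in gt.molecules:
            trace = trace_by_mol.get(mol.molecule_id)
            if trace is None:
                continue
            rec = events_by_mol.get(mol.molecule_id, [])
            for ev in mol.events:
                if ev.stoichiometry > 2 or ev.visible_dwell_s < 1.5 * dt:
                    continue
                overlapping = [
                    r
                    for r in rec
                    if r.start_s < ev.visible_end_s and r.end_s > ev.start_s
                ]
                # require an unambiguous 1:1 match to a recovered event
                if len(overlapping) != 1:
                    continue
                r = overlapping[0]
                others = [
                    e
                    for e in mol.events
                    if e is not ev and e.start_s < r.end_s and e.visible_end_s > r.start_s
                ]
                if others:
                    continue
                n_hat = stoichcoloc.count_fluorophores(
                    _event_initial_intensity(trace, r), unit
                )
                n_checked += 1
                n_correct += int(n_hat == ev.stoichiometry)
    metrics["stoich_n_checked"] = n_checked
    metrics["stoich_accuracy_12"] = n_correct / n_checked if n_checked else np.nan
    metrics["unit_intensity"] = unit.mean

    return EndToEndResult(
        n_molecules=n_molecules,
        truth=truths,
        trajectories=trajectories,
        segments=segments,
        pauses=all_pauses,
        rep_traces=rep_traces,
        unit_intensity=unit,
        metrics=metrics,
    )
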