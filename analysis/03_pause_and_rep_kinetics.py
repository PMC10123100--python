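#!/usr/bin/env python
"""Pause periodicity, arrival classes, wait/resolve times, and dwell fits.

Consumes the tables written by analysis/02: builds the pairwise pause-site
distance histogram (normalized to total product length, first 20 kbp),
summarizes arrival classes (Rep present at stall onset vs arriving later vs
absent), fits exponential models to pause durations and wait times, and
reports the dead-time-corrected Rep arrival frequency.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from repliscope import pausekinetics as pk
from repliscope.config import AnalysisConfig, SimConfig
from repliscope.tracking import IntensityTrace

SEED = 7


def main() -> None:
    results = ROOT / "results"
    pauses_df = pd.read_csv(results / "pauses.csv")
    traces_df = pd.read_csv(ROOT / "scratch" / "cohort" / "rep_traces.csv")
    truth_segments = pd.read_csv(results / "truth_segments.csv")
    unit = json.loads((results / "unit_intensity.json").read_text())
    analysis = AnalysisConfig()
    cfg = SimConfig(seed=SEED)

    pauses = [
        pk.PauseEvent(int(r.molecule_id), r.site_kbp, r.start_s, r.duration_s,
                      censored=bool(r.censored))
        for r in pauses_df.itertuples()
    ]
    total_product_kbp = float(
        ((truth_segments.end_s - truth_segments.start_s) * truth_segments.rate_bp_s).sum()
    ) / 1000.0
    distances, hist = pk.pairwise_pause_distances(
        pauses, total_product_length_kbp=total_product_kbp,
        bin_width_kbp=analysis.pause_distance_bin_kbp, max_distance_kbp=20.0,
    )
    hist.to_csv(results / "pause_distance_hist.csv", index=False)

    classes = pauses_df.query("duration_s >= 2").arrival_class.value_counts(normalize=True)
    durations = pauses_df.query("not censored and duration_s > 0").duration_s
    fit_pause = pk.fit_duration_distribution(
        durations, truncation_s=cfg.frame_interval_s,
        bootstrap_seed=analysis.bootstrap_seed,
    )
    waits = pauses_df.query("arrival_class == 't_gt0'").t_w_s.dropna()
    fit_wait = (
        pk.fit_duration_distribution(waits, truncation_s=0.0,
                                     bootstrap_seed=analysis.bootstrap_seed)
        if len(waits) >= 5
        else None
    )

    traces = [
        IntensityTrace(int(mid), g["t"].to_numpy(), g["intensity"].to_numpy(), 3.0)
        for mid, g in traces_df.groupby("molecule_id")
    ]
    lam, tau = pk.estimate_arrival_rate(
        traces, unit["mean"], analysis,
        frame_interval_s=cfg.frame_interval_s, exposure_s=cfg.exposure_s,
    )

    summary = {
        "n_pauses": int(len(pauses_df)),
        "n_pairwise_distances_first20kbp": int(len(distances)),
        "arrival_class_fractions": {k: float(v) for k, v in classes.items()},
        "pause_duration_exp_mean_s": fit_pause.mean,
        "pause_duration_exp_se_s": fit_pause.se,
        "pause_duration_n_censored_excluded": fit_pause.n_censored_excluded,
        "wait_time_exp_mean_s": fit_wait.mean if fit_wait else None,
        "rep_arrival_rate_per_min": lam,
        "rep_visible_dwell_s": tau,
    }
    with open(results / "pause_kinetics_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    top = hist.sort_values("height", ascending=False).head(3)
    print(
        f"{len(pauses_df)} pauses, {len(distances)} pairwise distances; "
        f"top histogram bins at {[f'{x:.2f}' for x in (0.5*(top.bin_left_kbp+top.bin_right_kbp))]} kbp "
        f"(template period 2.03 kbp); pause duration {fit_pause.mean:.1f} +/- {fit_pause.se:.1f} s; "
        f"Rep arrival {lam:.1f}/min, visible dwell {tau:.2f} s"
    )


if __name__ == "__main__":
    main()
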