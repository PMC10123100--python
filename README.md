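# repliscope

Single-molecule analysis of rolling-circle DNA replication and
accessory-helicase (Rep) dynamics at the fork — as a fully synthetic,
testable pipeline.

## The problem

In flow-stretched rolling-circle assays, an *E. coli* replisome circles a
small circular template (2,030 bp or 18 kbp) and extrudes a long dsDNA
product whose stained length, imaged by near-TIRF microscopy, reads out the
replication rate in real time. A catalytically dead Cas9 (dCas9) bound via a
guide RNA acts as a programmable protein roadblock: the fork stalls each
time it meets the target site, which recurs once per template length in the
product, and the accessory helicase Rep (labeled with a red fluorophore)
removes the block and rescues synthesis. The quantities of interest are the
elongation-rate segments and pauses of each molecule, the spatial
periodicity of pause sites, the stoichiometry and binding kinetics of Rep at
the fork (wait time *t*<sub>w</sub> to arrive at a stalled fork, resolve
time *t*<sub>R</sub> from arrival to restart), and — on the biochemistry
side — SPR binding kinetics of Rep on short ssDNA oligos.

Because raw experimental movies are large and instrument-specific, every
stage here is driven by a synthetic-data generator with known ground truth:
piecewise-linear trajectories with exponential pauses, Poisson Rep arrivals
with competing dissociation/photobleaching clocks, and rendered two-channel
EMCCD-like movies (Gaussian PSF, beam-profile inhomogeneity, shot noise,
read noise, drift). Every analysis stage is validated by recovering the
generating parameters.

## The methods at the core

* **Change-point segmentation** (`segmentation`): exact optimal-partitioning
  dynamic programming minimizing per-segment least-squares cost plus a
  BIC-like penalty `m·σ̂²·log n` per breakpoint — piecewise-linear for
  position traces (rates) and piecewise-constant for intensity traces
  (photobleaching steps, binding events). A pause is a rate segment below
  100 bp/s.
* **Leading-edge tracking** (`tracking`): half-plateau crossing of the
  longitudinal intensity profile, sub-pixel by linear interpolation; ROIs at
  the tip are transposed into the Rep channel for colocalized intensity.
* **Stoichiometry** (`stoichcoloc`): single-fluorophore unit intensity from
  pooled photobleaching steps (Gaussian fit of the step-size histogram);
  fluorophore counts = round(initial intensity / unit). Colocalization uses
  the 2-px centroid rule with chance coincidence `C = (A_R/A_FOV)·n`.
* **Kinetics** (`pausekinetics`): arrival classes (*t* = 0 / *t* > 0 /
  no-Rep), left-truncated exponential MLE with bootstrap SEs for dwell and
  pause durations, and a dead-time-corrected Poisson arrival-rate estimator
  for the Rep binding frequency.
* **SPR** (`spr`): two-compartment 1:1 Langmuir binding with mass-transport
  limitation, global nonlinear fitting over a titration,
  `K_D = k_off / k_on`, and RU-ratio stoichiometry
  `n = (R_Rep/R_DNA)·(Mr_DNA/Mr_Rep)`.

## Worked example

Run the numbered analysis scripts in order (movies land in `scratch/`,
tables in `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_track_and_segment.py
python analysis/03_pause_and_rep_kinetics.py
python analysis/04_stoichiometry.py
python analysis/05_spr_kinetics.py
```

which prints, for the default 24-molecule cohort (seed 7):

```
simulated 24 molecules: 174 pauses (120 at roadblock sites), 1289 Rep binding events; movies in scratch/cohort
tracked 24 molecules; 395 rate segments, 116 pauses; median elongation rate 540 bp/s (generating 580 bp/s); unit intensity 355 a.u. from 57 bleach steps
116 pauses, 252 pairwise distances; top histogram bins at ['1.75', '8.25', '10.25'] kbp (template period 2.03 kbp); pause duration 18.9 +/- 1.8 s; Rep arrival 17.9/min, visible dwell 1.57 s
unit intensity 358 +/- 24 a.u. (60 steps); degree-of-labeling mode 1; 1-vs-2 counting accuracy 85.0% over 60 molecules
K_D fold difference 2.78; max monomers per dT35 footprint: 4
```

Reading these numbers: the tracked median elongation rate (540 bp/s) sits
within 7% of the generating 580 bp/s; the dominant pairwise pause-site
distances fall at 1×, 4×, and 5× the 2.03-kbp template length, i.e. pauses
recur at the roadblock's periodic target site; the fitted pause duration
(18.9 ± 1.8 s) recovers the generating 20 s exponential; the corrected Rep
arrival rate (17.9/min) matches the generating 16–20/min Poisson process;
and most surface-immobilized Rep molecules bleach in a single step (one dye
per monomer). The counting accuracy on *immobilized* molecules (85%) is
lower than on transient binding events (~97%, see the acceptance run)
because long-lived dimers often lose their first fluorophore before the
initial plateau can be resolved.

There is also a CLI for one-off runs:

```bash
repliscope simulate --seed 7 --n-molecules 4 --out scratch/run
repliscope analyze --bundle scratch/run --out scratch/run_analysis
repliscope end-to-end --seed 7 --n-molecules 16 --out scratch/e2e
```

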