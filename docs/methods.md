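# Methods

This note documents the models, estimators, defaults, and numerical choices
behind repliscope, and what the synthetic-data studies do and do not
establish about real data.

## Synthetic-data generator (`synthgen`)

**Trajectories.** Each molecule's product length vs time is piecewise
linear. Elongation rates are drawn per segment from a normal distribution
(default mean 580 bp/s, SD 60 bp/s) truncated above the 100 bp/s pause
threshold, so no "elongation" segment is itself a pause. Two pause processes
interrupt elongation:

* *Roadblock pauses* at product positions that are exact multiples of the
  template length (default 2,030 bp). Each site passage is blocked with an
  independent Bernoulli probability (default occupancy 0.25). The default
  is sub-saturating: with ~2–3 pauses per molecule over products spanning
  many template lengths, the roadblock concentration regime this emulates
  leaves most site passages unblocked; it also keeps elongation runs long
  enough (~10 kbp, ~15 s) to be resolvable as rate segments at a 1-s
  cadence. Occupancy 1.0 with 20 s pauses would leave ~3-frame elongation
  runs, below any change-point resolution. Pause durations are exponential
  (default mean 20 s).
* *Spontaneous pauses* as a Poisson process in replicated length (default
  0.06 per kbp, exponential mean 5 s), at arbitrary positions.

Pauses running into the end of the acquisition are recorded with their
observed (truncated) duration and a censored flag. Replicated length is
conserved exactly: position(t) is the running integral of segment rate over
segment duration.

**Rep binding.** Arrivals are a piecewise-homogeneous Poisson process:
16 min⁻¹ during elongation and 20 min⁻¹ during pauses by default (the
paused-state arrival rate is measurably slightly higher at the same
concentration; both are exposed as independent knobs). Each event draws an
integer stoichiometry from a pmf over {1, 2, 3} (default 0.70/0.25/0.05 —
predominantly monomeric with occasional dimers), an exponential bound dwell
(default mean 2.0 s), and one exponential photobleaching clock per
fluorophore (default mean 8.0 s). A fluorophore is visible for
min(dwell, bleach); for monomers the visible dwell is therefore exponential
with mean 1/(1/2.0 + 1/8.0) = 1.6 s. Bleaching clocks run in wall-clock
time; the sub-unity illumination duty cycle is not modeled as slower
bleaching, because the default bleach constant was itself measured under
the matching imaging cadence.

**Rendering.** One snapshot exposure (200 ms) per frame interval (1 s).
The DNA channel draws each product as a line of uniform emitter density
(intercalative staining is ~uniform per kbp; no sequence bias) from its
anchor to the leading edge, sampled at 4 sub-pixel emitters per pixel with
bilinear deposition; the Rep channel places a point emitter at the tip with
brightness proportional to the exposure-averaged number of visible
fluorophores. Frames are PSF-blurred (Gaussian, σ = 1.3 px), multiplied by
a smooth beam profile (signal *and* fluorescent background, both
excitation-driven), and digitized as Poisson(expected) × gain +
Gaussian read noise + electronic offset, to 16-bit. The EMCCD excess-noise
factor is omitted; at the default photon budget (400 photons per
fluorophore per frame, integrated-spot SNR ≈ 10) its main effect would be a
√2 inflation of shot noise, which the recovery margins tolerate. Drift is a
per-frame constant offset accumulated linearly.

A single seeded stream drives each simulation, consumed in the fixed order
trajectory → binding → rendering (DNA channel, then Rep), so any prefix of
the pipeline is reproducible bit-for-bit.

**What the generator does not emulate:** lagging-strand loop dynamics,
SSB/polymerase exchange, fork collapse, multi-molecule crossing or
entanglement, non-uniform DNA stretching in flow, chromatic offset between
channels, and sCMOS/EMCCD pattern noise. Passing recovery tests therefore
shows the *analysis chain* is unbiased under the stated observation model,
not that these instrument effects are harmless.

## Image preprocessing (`imageprep`)

Flattening subtracts the electronic offset (supplied, or the movie's 0.1th
percentile as a robust floor) and divides by the beam profile (supplied, or
estimated as a σ = 50 px Gaussian blur of the temporal median frame —
common practice when no reference field is recorded). Drift correction
registers every frame to frame 0 by upsampled cross-correlation (×20) on
median-subtracted, clipped, lightly smoothed (σ = 1 px) feature images;
plain (unnormalized) correlation proved markedly more robust than phase
normalization on spot-like images over a flat background. Featureless
frames (< 2 pixels above 5 robust SDs) get zero shift and a warning.
First-frame subtraction clips negatives at zero; frame 0 becomes zeros by
definition.

Focus detection thresholds local maxima at median + 5 robust SDs (MAD ×
1.4826) — no detection threshold is inherited from elsewhere, so it is a
configurable default — and refines each candidate with a 2-D Gaussian fit
in a 7-px window; non-converged fits keep the integer-pixel candidate
flagged `fit_ok=False`; duplicates within 1 px keep the brighter focus.
Coordinates are (row, col), 0-based, pixel centers at integers, everywhere.

## Tracking (`tracking`)

The leading edge is the farthest column (flow axis) where the longitudinal
profile — averaged over ±2 rows around the anchor — exceeds half its local
plateau, localized sub-pixel by linear interpolation. A step edge convolved
with a symmetric PSF crosses half-height exactly at the step, so the
estimator is unbiased for products longer than a few PSF widths; measured
RMS edge error on high-SNR synthetic movies is ≈ 0.4 px. There is no single
standard edge criterion for this assay; the
half-plateau crossing is this package's documented choice. Monotonicity is
not enforced; a window-3 median filter is applied before segmentation. The
pixel-to-kbp calibration is a required input (synthetic data supplies its
true value, 0.55 kbp/px by default; real data must provide its own).

Rep traces integrate a 3-px-radius disc at the tip minus the per-pixel
median of a 5–9 px annulus; the ROI radius covers a PSF at the 2-px
colocalization tolerance. Tips outside the field are marked missing.

## Change-point engine (`segmentation`)

Both trace types share one objective — total per-segment least-squares cost
plus penalty × (number of breakpoints) — minimized *exactly* by optimal
partitioning (dynamic programming over last-breakpoint positions, O(n²)
with O(1) segment costs from prefix sums). Exactness is what makes the
brute-force oracle test possible: on every trace of ≤ 30 samples the DP
provably matches exhaustive enumeration of all breakpoint placements. The
change-point literature spans several variants (likelihood-ratio cascades
among them); numerical identity with any particular implementation is not
claimed.

Defaults: minimum segment length 3 samples; ties broken toward fewer
breakpoints; noise σ̂ estimated as MAD(first differences)/0.6745/√2, shared
across segments; penalty m·σ̂²·log n with m = 2 (linear) and m = 3
(constant). The constant-model multiplier is larger because an extra
plateau buys both a level and a breakpoint-location parameter; m = 2 was
measured to split SNR-5 staircases spuriously ~10% of the time, violating
the ≥ 95% recovery requirement, while m = 3 gives ≥ 98% with no loss on
true steps. Noiseless traces get an infinitesimal effective σ̂ so any real
level change is always split.

## Pause and Rep kinetics (`pausekinetics`)

A pause is any rate segment with |rate| < 100 bp/s; its site is the fitted
position at segment start. Sub-threshold segments separated by < 2 frames
are merged (tracking jitter splits single stalls). The final segment
reaching the acquisition end is censored; censored pauses are excluded from
duration fits by default and counted in the fit record (their durations are
systematically underestimates).

Pairwise pause-site distances are computed within molecules and histogrammed
with heights normalized to the total product length analyzed; the analysis
scripts restrict to the first 20 kbp of distances where the periodicity is
best resolved.

**Arrival classes.** Using the half-molecule intensity threshold: a pause
is *t = 0* when an event already spans its start (within half a frame),
*t > 0* when the first event begins later (wait time t_w = event start −
pause start), else *no-Rep*. The resolve time t_R runs from the relevant
event's first above-threshold time to the pause end; when several events
overlap a pause, the first is used.

**Duration fits.** Exponential fitting defaults to left-truncated MLE
(mean = sample mean − truncation, with the truncation point defaulting to
one frame interval, since sub-frame events are unobservable); a
histogram least-squares option exists for parity with histogram-based
workflows, and the method used is recorded in the fit object. Gaussian fits
are MLE on raw (unbinned) values. SEs come from a 1000-replicate seeded
nonparametric bootstrap.

**Binding frequency.** The thresholding definition — maximal runs of frames
above half a unit intensity, divided by observation time — is implemented
as specified, but it estimates the *excursion* rate, not the arrival rate:
at the default conditions (16 min⁻¹ arrivals, 1.6 s visible dwells, ≈ 45%
duty) overlapping events merge and sub-frame events vanish, and the raw
count runs ≈ 55% low. `estimate_arrival_rate` therefore inverts the
observation model: it finds the (Poisson rate, exponential visible-dwell
mean) pair whose forward-simulated excursion rate and mean excursion
duration — under the same exposure, cadence, and threshold — match the
observed ones (fixed-point iteration, common random numbers). This is a
standard dead-time correction in spirit; it recovers the generating rate
within a few percent on synthetic data, and on real data is exact only
insofar as arrivals are Poisson and visible dwells near-exponential.

## Stoichiometry and colocalization (`stoichcoloc`)

Unit intensity: photobleaching steps of surface-immobilized labeled
molecules, imaged under experiment-matched conditions, are pooled across
traces and their histogram fit with a Gaussian; fewer than 20 steps flags
the calibration low-confidence. Counting divides an initial intensity by
the unit and rounds; fractional parts in [0.4, 0.6) are flagged ambiguous.
The initial intensity of a trace is the mean of its first change-point
plateau (single-frame noise resistance); transient binding events too short
for a plateau fall back to their peak frame, the least exposure-diluted
sample. On immobilized molecules, dimers that lose a fluorophore before the
first plateau resolves are systematically undercounted (measured ≈ 85%
accuracy there vs ≈ 97% on transient events) — an intrinsic limit of
frame-rate-bound step counting, reported rather than corrected.
Discrimination between two and three fluorophores is markedly worse than
one-vs-two at the same SNR, consistent with intensity-based counting being
reliable for monomer-vs-dimer calls only.

Colocalization matches centroids within 2 px greedily by increasing
distance, each focus used once; at the sparse focus densities simulated,
greedy and optimal assignment coincide. Chance coincidence uses
C = (A_R/A_FOV)·n with the focus area defaulting to a disc of the 2-px
colocalization radius;
C is computed per frame and aggregated.

## SPR (`spr`)

The "1:1 with mass transfer" model is the standard two-compartment
quasi-steady formulation: transport k_t·(C_bulk − C_s) balances net binding
k_on·C_s·(R_max − R) − k_off·R, eliminating C_s algebraically and leaving
one ODE in R, integrated with LSODA (rtol 1e-8). As k_t → ∞ it reduces to
pure Langmuir kinetics; the equilibrium response R_max·C/(C + K_D) is
k_t-independent, which the tests verify. Global fitting optimizes
(k_on, k_off, R_max, k_t) in log space, shared across the titration, over
both phases jointly, with data-driven initial guesses (tail log-slope for
k_off, early slope for k_on·R_max) and asymptotic SEs from the Jacobian.
A series with no response above 5× the point-to-point noise floor is
rejected as degenerate.

Recovery studies place the concentration series at 0.5–4 × K_D of each
grid point, as a practitioner designs a titration: far below K_D the
surface barely loads and only k_on·R_max is identifiable; far above,
association curvature saturates. A fixed low-nM series across a K_D grid
spanning three orders of magnitude would make corner cases structurally
unidentifiable — a property of the experiment, not the fitter. The
moderate-affinity "dT15-like" scenario keeps the conventional 1–8 nM
series; the high-affinity "dT35-like" scenario uses a single 20 nM
injection for the same reason. Biphasic/multimeric binding at high analyte
concentration is out of scope: the fitter addresses the low-concentration
1:1 regime only. ATP-stimulated dissociation is representable only as a
refit with faster k_off, not modeled mechanistically.

## Problem sizes and reproducibility

The shipped studies use sizes chosen to make every recovery statistically
decisive at interactive runtimes on one core: 50 rendered molecules
(128 × 512 px, 180 frames) for the end-to-end study, 60-spot calibration
fields, 200 traces for the oracle comparison, 100 replicates × 500 draws
per dwell constant, a 3 × 3 SPR grid, and 10,000 Monte-Carlo placements for
the coincidence check. All randomness flows from explicit integer seeds;
`scripts/acceptance.py --seed N` reseeds every study from N.

## Known limitations

* Tracking assumes one molecule per anchor row and products aligned with
  the flow axis; crossing or overlapping molecules are out of scope
  (molecules are selected, as in the assay this emulates).
* The arrival-rate correction assumes Poisson arrivals with a common rate
  over the trace; strongly state-dependent rates bias it toward the
  time-weighted mean rate.
* The pairwise-distance periodicity readout needs several pauses per
  molecule; at very low roadblock occupancy the modes dilute into the
  spontaneous-pause background.
* Exponential dwell fits ignore the discreteness of frame sampling beyond
  the left-truncation point; at dwells ≲ 2 frames the recovered means carry
  a small (< 5%) discretization bias.
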