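# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `tirffusion` pipeline.

## Imaging model and conventions

All analysis assumes a single adherent cell imaged by TIRF with both color
channels registered pixel-for-pixel. Coordinates are 0-based `(y, x)` (row,
column); frame windows are half-open `[start, stop)`; frame `k` is acquired
at `k * frame_interval_s`. Calibration defaults are 0.109 µm/px and
0.136 s/frame (60× objective with a 2.5× magnifier on an EMCCD), both
overridable. Dual-view frames are split into halves and registered by
integer-pixel normalized cross-correlation; sub-pixel channel registration
is not attempted because all regional statistics operate on ≥ 7 px
footprints.

## Synthetic recordings

The simulator is the source of ground truth for every quantitative claim.
Its noiseless expectation for frame *t* is

    offset + bleach(t) · (autofluor · cellmask + gain · Σ event PSFs)

with `bleach(t) = exp(−t/τ)` applied to all cell-derived photons but not to
the camera offset. Noise is Poisson on photon counts, then amplification by
`gain`, then Gaussian read noise in counts. Defaults: offset 100 counts,
autofluorescence 200 counts, read noise 2 counts, gain 1 count/photon,
τ_bleach 200 s, PSF σ 1.3 px. Event spots are isotropic Gaussians of
integrated brightness `amplitude_photons` (default 1500 photons/frame,
placing event onsets at peak signal-to-noise ≈ 5–7 over the in-cell shot
noise — the regime in which automated detection of single vesicles is
realistic).

Event phenotypes:

- **visiting** — Brownian lateral motion (default D = 0.02 µm²/s) for
  `dwell_frames`, with brightness modulated by `exp(−z/d)` where *z* is a
  reflecting random walk in [0, 300] nm and *d* = 100 nm is the evanescent
  decay length. The walk starts within 40 nm of the membrane: a visitor is
  defined by its arrival into the evanescent field, so its appearance is
  bright and later depth excursions cause the characteristic flicker.
- **docking** — appearance at a fixed position with constant brightness (a
  step to a plateau).
- **fusing** — a dim docked spot from frame 0; at onset the intensity jumps
  by `dequench_factor` (default ×5 — the pH-dequench magnitude is not a
  measured quantity and is a free simulator parameter) and the fluorophores
  then diffuse in the membrane plane: a Gaussian with per-axis variance
  σ_psf² + 2·(D_mem/px²)·t and conserved total, D_mem default 0.1 µm²/s.

The marker channel implements three co-recruitment models: `cargo_like`
(proportional to the vesicle's own photons), `pa_like` (nothing before
docking, a linear ramp while docked — default 0.05 of the amplitude per
second — and a Gaussian-in-time pulse of σ 0.5 s peaking `marker_lag_s`
after the fusion peak, default 1.4 s), and `cytosolic` (uniform fill of the
cell, the null model). All randomness flows from one seed via spawned
sub-streams per event, so identical configurations are bit-identical.

What the simulator does **not** emulate: EMCCD excess-noise statistics,
a structured PSF (Airy rings, aberrations), cell-shape irregularity and
membrane ruffling, stage drift, hemifusion/kiss-and-run kinetics, or
heterogeneous vesicle brightness. Tests passing on these movies therefore
demonstrate the correctness and calibration of the estimators under the
stated model, not performance on arbitrary real recordings.

## Photobleach correction

Each frame is rescaled so the background-subtracted cell mean is constant:

    corrected = (raw − bg_t) · (m_0 / m_t) + bg_0,   m_t = mean(cell) − bg_t

This direct per-frame ratio is the minimal estimator achieving a constant
cell intensity; no exponential model is fitted. The correction is exact on
noiseless input, idempotent, preserves within-frame intensity ratios, and
corrects each channel independently with its own cell mean. An optional
11-frame median filter on `m_t` (off by default) avoids imprinting shot
noise of the cell mean onto the movie. Background is measured per frame
outside the cell, beyond a ≥ 2 px guard band around the Otsu-derived cell
mask (computed once from the temporal mean; adherent cells do not move on
these timescales).

## ΔF/S and object colocalization

The circle is read as 7 px in *diameter* (radius 3.5 px ≈ 0.76 µm at
0.109 µm/px, the size of a diffraction-limited vesicle image); a radius-7
reading would average over 1.5 µm and destroy the locality of the annulus
reference, but the radius is configurable. Regional statistics use means,
not sums, so circle and annulus areas need not match. A spot whose annulus
mean does not exceed the background gives an invalid (flagged, logged)
ΔF/S rather than an exception; batch summaries exclude flagged values.
Spots whose full circle+annulus footprint does not fit inside the cell
mask are excluded — an annulus hanging over the dim cell edge would fake
enrichment. Object-percentage colocalization is centroid-distance-based
(greedy nearest-pair matching, each query spot used once; default match
radius = circle radius); exact parity with ImageJ plugins is not a goal.

## Event detection

The public difference-movie operator is a 3-frame boxcar followed by a
lag-1 forward difference. For candidate detection the pipeline evaluates
the *full-step* variant (lag equal to the boxcar width, i.e. the running
sum of the lag-1 differences): a step change then contributes its entire
amplitude to one difference frame instead of a third of it, which matters
because the detector max-projects over hundreds of frames and the noise
floor of that projection grows with T. Each difference frame is spatially
bandpassed (difference of Gaussians, σ 1 and 4 px) *before* the temporal
max-projection for the same reason. Peaks are local maxima above
`median + k·MAD` of the projection computed over the cell footprint
(k = 14 by default; in-cell shot noise, not the dark surround, sets the
relevant floor), with sub-pixel positions from local intensity-weighted
centroids.

Onsets are refined per candidate on the circle-mean time series of the
smoothed movie: the first frame exceeding the pre-rise baseline mean +
4 SD (baseline: up to 30 frames ending 2 frames before the steepest rise).
Because a moving vesicle can re-brighten more steeply than it appeared,
the onset anchor is the *first* rise within the candidate's neighbourhood
whose step amplitude is at least half the largest one, evaluated on an
enlarged (+3 px) circle, and the position is re-estimated from the step
image at that time. Candidates coincident within 8 px and 10 frames are
grouped; each group is represented by its earliest-onset member with a
competitive (≥ half-maximal) score. Onset estimates inherit a ~1-frame
early bias from the centered temporal smoothing; this is well inside the
±2-frame accuracy the pipeline claims.

## Traces and classification

ΔF/F uses the circle only — the annulus is deliberately excluded because
its intensity changes when fusion occurs. The baseline C_i is the mean
over exactly the 5 frames before onset (at 0.136 s/frame this is 0.68 s;
the 5-frame rule is primary). The peak is the first global maximum after
onset. Events without 50 frames before and 100 after onset are still
traced but carry a `short_window` flag and are excluded from averaged
readouts. The marker trace is normalized by its own extremum (switchable
in principle; normalizing by the vesicle channel's extremum would make
marker amplitudes comparable across channels but destroys the 0–1
contract used everywhere downstream).

Classification is automated with three rules, applied in the order
fusing → docking → visiting:

- **fusing**: rise to peak ≤ 5 frames, ΔF/F ≤ 0.6 one second after the
  peak, and radial spread 0.5–1 s post-peak ≥ 1.3× the pre-peak spread.
- **docking**: median ΔF/F over the last quarter of the window ≥ 0.5 and
  net centroid displacement ≤ 2 px, spread criterion not met.
- **visiting**: otherwise.

The reported confidence is the smallest relative margin to any threshold
used. Manual review of ambiguous movies is replaced by these explicit
thresholds; they are validated against simulator truth (100% on the
standard 20-event benchmark; ≥ 95% across seeds), not against any manual
labelling.

**Radial spread** is the second central moment of the event crop
(21 × 21 px) after per-frame median subtraction, σ = 1 px smoothing, and
trimming at a threshold that is 20% of the frame's peak (never below 4
robust noise SDs — estimated once per event from pre-onset frame
differences, because a per-frame MAD inflates once the spreading spot
covers much of the crop). Trimming at a fixed *fraction of peak* makes the
estimate invariant to spot brightness — essential, since a visiting
vesicle's depth flicker would otherwise masquerade as spread change — and
the trimmed moment is rescaled by the analytic Gaussian trim factor and
corrected for the smoothing variance, so a Gaussian spot of width σ reads
≈ 2σ². Frames whose peak does not clear the noise floor, or where the
noise floor would trim more than half the peak, yield NaN; a fusing label
requires the post-peak window to be essentially complete, which is also
what rejects departed visitors. The net displacement used by the docking
rule is measured between the median centroid just after the rise completes
and the median over the last quarter of the window (the detected onset
frame itself can precede the spot's appearance).

## Event metrics

- The docking "plateau" is the median of the last quarter of the
  post-onset window; the 80%-of-plateau readout takes the first frame
  reaching 0.8× that level.
- Trace integrals are trapezoidal over the frames inside the requested
  window (the 0–4 s integral therefore ends at the last frame ≤ 4 s);
  a plain frame sum would differ by a constant factor only.
- Peak lags compare first argmaxima of boxcar-smoothed traces. The default
  width is 3 frames: the fusion trace peaks sharply and decays slowly, so
  wider boxcars drag its argmax onto the decay side and bias recovered
  lags low by ~2 frames — measured directly in the lag-recovery tests.
- Fast/slow decay binning thresholds the slope histogram by Otsu's
  criterion (median fallback when degenerate); "fast" means more negative.
- Stage-relative marker intensity divides the circle mean by the
  whole-cell mean (cancelling reporter expression level exactly — the
  table is invariant to scaling the marker channel) and subtracts the mean
  pre-event level of visiting vesicles as the zero reference.
- Relative fusion rates divide each cell's events/min by the mean control
  rate of the same batch; zero-event cells are included, and each batch
  must contain a control.
- Group significance testing is left to standard statistical routines
  (`scipy.stats`, statsmodels); only the Pearson correlation used for the
  slope-vs-ΔF/S association is wrapped here, computed per event.

## Tracking

Frame-to-frame linking solves a global minimum-total-distance bipartite
assignment per frame (deterministic and order-independent, unlike greedy
linking), rejecting links beyond 3 px/frame, closing gaps of up to 1 frame
with proportionally scaled limits, and dropping tracks shorter than 10
points. MSD is time-averaged over all pairs at each lag; D comes from an
unweighted least-squares line through the first 4 MSD points with a free
intercept that absorbs the static localization-noise offset. Negative
estimates are reported unclamped (they are part of the estimator's
sampling distribution) and classify as immobile at the 0.0055 µm²/s
mobility threshold. The fit range and linking limits are declared
defaults validated on simulation; with 200-frame tracks at D = 0.02 µm²/s
and 0.3 px localization noise the median estimate is within a few percent
of truth.

## Problem sizes used in the tests

The standard detection benchmark is one 256 × 256 × 600-frame recording
with 20 events (~82 s of imaging); classification adds a 15-event
224 × 224 × 500 recording (35 events total); lag recovery uses two
15-event fusion-only recordings per injected lag (0.5, 1.4, 3.0 s);
diffusion checks use 100 synthetic tracks of 200 frames. These sizes give
stable statistics (binomial SE on a 20-event recall ≈ 0.07; lag medians
over ≥ 25 events) while each recording renders and analyzes in about a
minute.

## Known limitations

- The classifier's thresholds are calibrated on the simulator's event
  phenomenology; recordings with very different SNR, vesicle brightness
  heterogeneity, or motion regimes will need the thresholds revisited
  (all are exposed in `ClassifierParams`).
- Detection assumes events are sparse: two events overlapping within
  ~8 px and ~10 frames merge into one candidate.
- Registration is integer-pixel; chromatic warping is out of scope.
- The spread estimator's Gaussian trim calibration is exact only for
  Gaussian profiles; ring-like intermediates are summarized but not
  modelled.
- Kiss-and-run vs full fusion is not discriminated.
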