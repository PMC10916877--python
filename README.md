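# tirffusion

Analysis of single secretory-vesicle behaviour in two-channel TIRF
microscopy recordings. The package quantifies where and when proteins and
lipids accumulate around vesicles as they **visit** the plasma membrane,
**dock**, and **fuse** — the workflow used to study phospholipase D1 (PLD1)
and its product phosphatidic acid (PA, reported by the PASS biosensor) at
exocytic sites in neuroendocrine cells. It is aimed at cell biologists
quantifying exocytosis with pH-sensitive vesicle reporters (e.g.
VAMP2-pHmScarlet) alongside a GFP-tagged protein or lipid sensor.

## What it computes

**Object-based colocalization (ΔF/S).** Around each spot found in the
vesicle ("red") channel, the marker ("green") channel is summarized as

    ΔF/S = (C − A) / (A − bg)

where *C* is the mean intensity of a 7-pixel-diameter circle, *A* the mean
of a 1-px-wide concentric ring separated by a 1-px gap, and *bg* the mean
extracellular background. ΔF/S is exactly invariant to affine intensity
transforms, hence to reporter expression level. Object-percentage
colocalization (fraction of reference spots with a matching query spot) is
also provided.

**Event detection, traces, classification.** Candidate events are spots
with a rapid intensity rise, found on a temporally smoothed, spatially
bandpassed difference movie. Each event's circle intensity is normalized to

    ΔF/F(t) = (C_t − C_i) / (C_max − C_i)

with *C_i* the mean over the 5 frames before onset, so every trace has
baseline 0 and peak 1. Events are classified as visiting, docking, or
fusing; a fusing label additionally requires the post-peak outward
expansion of fluorescence (radial second moment growing ≥ 1.3× within 1 s)
that verifies membrane merger.

**Event metrics.** Marker ΔF/F at the vesicle peak (or at 80% of the
plateau for docking events), 0–4 s trace integrals, vesicle-to-marker peak
lags, post-peak decay slopes with fast/slow histogram binning,
expression-corrected stage-relative marker intensity, and fusion rates
normalized to same-day control cells.

**Tracking and mobility.** Spots are linked by optimal bipartite
assignment; diffusion coefficients come from a line fit to the first MSD
points (D = slope/4), and vesicles with D > 0.0055 µm²/s are classified
mobile.

**Simulator.** A ground-truthed two-channel movie generator (cell
footprint, diffraction-limited spots, Brownian motion with TIRF-depth
modulation, docking, fusion with pH-dequench and membrane spreading,
marker co-recruitment with configurable lag, photobleaching, shot/read
noise) backs every quantitative test.

## Worked example

```python
from tirffusion import (EventSpec, SimConfig, simulate_movie,
                        estimate_cell_mask, correct_photobleach,
                        run_event_pipeline)

events = [
    EventSpec("fusing",   x0=40, y0=40, onset_frame=80),
    EventSpec("docking",  x0=80, y0=50, onset_frame=100),
    EventSpec("visiting", x0=60, y0=85, onset_frame=120, dwell_frames=15),
]
cfg = SimConfig(image_shape=(128, 128), n_frames=300,
                event_specs=events, rng_seed=3)
vesicle, marker, truth = simulate_movie(cfg)

mask = estimate_cell_mask(vesicle)
vesicle = correct_photobleach(vesicle, mask)
marker = correct_photobleach(marker, mask)
for rec in run_event_pipeline(vesicle, marker, cell_mask=mask.inside):
    c = rec.candidate
    print(f"{rec.kind:9s} y={c.y:5.1f} x={c.x:5.1f} onset={c.onset_frame}")
```

prints

```
fusing    y= 40.0 x= 40.0 onset=79
docking   y= 50.1 x= 80.0 onset=99
visiting  y= 84.7 x= 59.2 onset=120
```

— all three simulated events recovered at their true positions, onsets
within one frame of truth (detection sees the temporally smoothed movie,
so onsets can land one frame early), and correctly classified.

A command-line interface wraps the same library for shell use:
`tirffusion simulate|preprocess|coloc|detect|track --help`.

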