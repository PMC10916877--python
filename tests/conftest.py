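"""Shared fixtures: small synthetic recordings reused across the suite.

Expensive simulations (the 20-event detection benchmark, the classification
and null-control recordings) are session-scoped so they are rendered and
analyzed once.
"""

import numpy as np
import pytest

from tirffusion import (
    EventSpec,
    SimConfig,
    correct_photobleach,
    estimate_cell_mask,
    run_event_pipeline,
    simulate_movie,
)
from tirffusion.synthetic import benchmark_config


def analyze(config):
    """Simulate + mask + bleach-correct + event pipeline for a config."""
    ves, mark, truth = simulate_movie(config)
    mask = estimate_cell_mask(ves)
    ves_c = correct_photobleach(ves, mask)
    mark_c = correct_photobleach(mark, mask)
    records = run_event_pipeline(ves_c, mark_c, cell_mask=mask.inside)
    return dict(vesicle=ves_c, marker=mark_c, mask=mask, truth=truth,
                records=records, config=config)


def match_records_to_truth(records, truth, max_dist_px=1.0, max_dt_frames=2):
    """Greedy truth matching at the stated position/onset tolerances.

    Returns (matched: {truth_index: record}, false_positives: [record]).
    """
    matched, fps = {}, []
    for rec in records:
        best = None
        for j, ev in enumerate(truth.events):
            d = np.hypot(rec.candidate.y - ev["y0"], rec.candidate.x - ev["x0"])
            dt = abs(rec.candidate.onset_frame - ev["onset_frame"])
            if d <= max_dist_px and dt <= max_dt_frames and (
                best is None or d < best[1]
            ):
                best = (j, d)
        if best is None:
            fps.append(rec)
        elif best[0] not in matched:
            matched[best[0]] = rec
        else:
            fps.append(rec)
    return matched, fps


@pytest.fixture(scope="session")
def noiseless_config():
    """Tiny noise-free recording: one event of each kind, no camera noise."""
    events = [
        EventSpec("fusing", x0=40.0, y0=40.0, onset_frame=80),
        EventSpec("docking", x0=80.0, y0=50.0, onset_frame=100),
        EventSpec("visiting", x0=60.0, y0=85.0, onset_frame=120, dwell_frames=15),
    ]
    return SimConfig(
        image_shape=(128, 128), n_frames=300, event_specs=events,
        read_noise_sd=0.0, shot_noise=False, rng_seed=5, bleach_tau_s=1e9,
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_config):
    import dataclasses

    cfg = dataclasses.replace(noiseless_config)
    # zero shot noise too: photon field becomes the expectation
    ves, mark, truth = simulate_movie(cfg)
    return cfg, ves, mark, truth


@pytest.fixture(scope="session")
def small_noisy_run():
    """Small noisy 3-event recording, fully analyzed."""
    events = [
        EventSpec("fusing", x0=40.0, y0=40.0, onset_frame=80),
        EventSpec("docking", x0=80.0, y0=50.0, onset_frame=100),
        EventSpec("visiting", x0=60.0, y0=85.0, onset_frame=120, dwell_frames=15),
    ]
    cfg = SimConfig(image_shape=(128, 128), n_frames=300, event_specs=events,
                    rng_seed=3)
    return analyze(cfg)


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard 20-event 256x256x600 detection benchmark, analyzed."""
    return analyze(benchmark_config(n_events=20, seed=1))


@pytest.fixture(scope="session")
def extra_classification_run():
    """15 further mixed events for the 35-event classification check."""
    return analyze(
        benchmark_config(n_events=15, image_shape=(224, 224), n_frames=500,
                         seed=2)
    )


@pytest.fixture(scope="session")
def cytosolic_run():
    """Recording whose marker is a uniform cytosolic reporter (null model)."""
    return analyze(
        benchmark_config(n_events=12, image_shape=(192, 192), n_frames=400,
                         seed=7, marker_model="cytosolic")
    )
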