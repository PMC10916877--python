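"""Ground-truthed two-channel TIRF movie simulator.

Generates a single adherent cell on a dark background, diffraction-limited
secretory-vesicle spots undergoing visiting (Brownian lateral motion with
TIRF-depth intensity modulation), docking (arrival followed by motion
arrest), and fusion (instantaneous pH-dequench intensity jump followed by
2-D radial spreading of the fluorophores), together with a second "marker"
channel emulating a cargo-like, PA-biosensor-like, or cytosolic reporter.
Whole-cell photobleaching and camera shot/read noise are applied last.

The noiseless expected image of frame t is

    offset + autofluor * cell_mask * exp(-t/tau) + gain * sum_events PSF_photons

and noise is applied as Poisson shot noise on photon counts, amplified by
``gain``, plus Gaussian read noise in counts, plus the camera offset. Every
simulation run emits a :class:`GroundTruth` record used as the oracle in
tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .movie_io import CalibratedMovie, DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM

# TIRF evanescent-field decay length used to modulate visitor intensity.
TIRF_DEPTH_NM = 100.0


@dataclass(frozen=True)
class EventSpec:
    """One simulated vesicle event.

    kind
        ``"visiting"``, ``"docking"`` or ``"fusing"``.
    x0, y0
        Nominal position in pixels (visiting vesicles diffuse around it).
    onset_frame
        Frame at which the vesicle appears (visiting/docking) or fuses
        (fusing; the vesicle is present, dim, from frame 0).
    amplitude_photons
        Integrated spot brightness in photons/frame before dequenching.
    lateral_D_um2_s
        Lateral diffusion coefficient of a visiting vesicle.
    dequench_factor
        Multiplicative intensity jump at fusion (> 1 only for fusing).
    membrane_D_um2_s
        Post-fusion 2-D spreading coefficient of the fluorophores.
    dwell_frames
        Residence time of a visiting vesicle in the evanescent field.
    """

    kind: str
    x0: float
    y0: float
    onset_frame: int
    amplitude_photons: float = 1500.0
    lateral_D_um2_s: float = 0.02
    dequench_factor: float = 5.0
    membrane_D_um2_s: float = 0.1
    dwell_frames: int = 15

    def __post_init__(self):
        if self.kind not in ("visiting", "docking", "fusing"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind != "fusing" and self.dequench_factor != 1.0:
            object.__setattr__(self, "dequench_factor", 1.0)
        if self.kind == "fusing" and self.dequench_factor <= 1.0:
            raise ValueError("fusing events require dequench_factor > 1")


@dataclass
class SimConfig:
    """Full parameterization of one simulated two-channel recording.

    Defaults reproduce the acquisition geometry of an EMCCD TIRF setup
    (0.109 um/px, 136 ms/frame) imaging a single PC12-like cell.
    """

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 300
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    cell_center: tuple[float, float] = (64.0, 64.0)  # (y, x) px
    cell_axes: tuple[float, float] = (50.0, 55.0)  # semi-axes (y, x) px
    psf_sigma_px: float = 1.3
    background_offset: float = 100.0
    cell_autofluor: float = 200.0
    bleach_tau_s: float = 200.0
    read_noise_sd: float = 2.0
    gain: float = 1.0
    shot_noise: bool = True
    rng_seed: int = 0
    event_specs: list[EventSpec] = field(default_factory=list)
    marker_model: str = "pa_like"
    marker_lag_s: float = 1.4
    marker_docking_ramp_slope: float = 0.05  # fraction of amplitude per second
    marker_amplitude_factor: float = 1.0
    marker_pulse_sigma_s: float = 0.5
    cytosolic_level_photons: float = 150.0

    def __post_init__(self):
        for name in (
            "pixel_size_um", "frame_interval_s", "psf_sigma_px",
            "bleach_tau_s", "gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.read_noise_sd < 0 or self.background_offset < 0:
            raise ValueError("noise/offset parameters must be nonnegative")
        if self.marker_model not in ("cargo_like", "pa_like", "cytosolic"):
            raise ValueError(f"unknown marker_model {self.marker_model!r}")
        cy, cx = self.cell_center
        ay, ax = self.cell_axes
        h, w = self.image_shape
        if not (cy - ay >= 8 and cy + ay <= h - 8 and cx - ax >= 8 and cx + ax <= w - 8):
            raise ValueError("cell ellipse must lie inside the image with >= 8 px margin")

    def cell_mask(self) -> np.ndarray:
        """Boolean H x W footprint of the elliptical cell."""
        h, w = self.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = self.cell_center
        ay, ax = self.cell_axes
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Simulator-emitted truth: the acceptance oracle for the pipeline."""

    events: list[dict]  # kind, x0, y0, onset_frame, peak_frame
    tracks: list[dict]  # event_index, frames, y_px, x_px, true_D_um2_s
    marker_lag_s: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def gaussian_spot(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
    total_photons: float,
) -> np.ndarray:
    """Isotropic 2-D Gaussian with the given integrated photon count.

    Rendered by pixel-center sampling of the normalized density; for
    sigma >= 1 px the discrete sum matches the analytic integral to much
    better than 0.1% (Poisson-summation error), so photon conservation
    holds on any grid large enough to contain the tails.
    """
    h, w = shape
    cy, cx = center
    # local window keeps rendering O(sigma^2) rather than O(H*W)
    r = int(np.ceil(5 * sigma_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    out = np.zeros(shape, dtype=np.float64)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2))
    out[y0:y1, x0:x1] = total_photons * g / (2.0 * np.pi * sigma_px**2)
    return out


def fusion_profile(
    t_since_fusion_s: float,
    amplitude_photons: float,
    dequench_factor: float,
    psf_sigma_px: float,
    membrane_D_um2_s: float,
    pixel_size_um: float,
    shape: tuple[int, int] = (41, 41),
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Expected photon image of a fused vesicle ``t`` seconds post-fusion.

    The dequenched fluorophores diffuse in the plane of the membrane, so the
    profile is an isotropic Gaussian with per-axis variance

        sigma_psf^2 + 2 * (membrane_D / pixel_size^2) * t

    and conserved total ``amplitude * dequench`` for all t.
    """
    if t_since_fusion_s < 0:
        raise ValueError("t_since_fusion must be >= 0")
    if membrane_D_um2_s < 0:
        raise ValueError("membrane diffusion coefficient must be >= 0")
    var_px2 = psf_sigma_px**2 + 2.0 * (membrane_D_um2_s / pixel_size_um**2) * t_since_fusion_s
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return gaussian_spot(
        shape, center, float(np.sqrt(var_px2)), amplitude_photons * dequench_factor
    )


def brownian_track(
    n_frames: int,
    D_um2_s: float,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    start: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Seeded 2-D Brownian trajectory in pixels, shape ``(n_frames, 2)``.

    Per-axis increments are i.i.d. Gaussian with variance ``2 * D * dt``
    converted to px^2. Row order is ``(y, x)``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    step_sd_px = np.sqrt(2.0 * D_um2_s * frame_interval_s) / pixel_size_um
    steps = rng.normal(0.0, step_sd_px, size=(n_frames - 1, 2))
    track = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return track + np.asarray(start, dtype=float)


def _reflected_depth_walk(rng, n: int, step_nm: float = 30.0, z_max_nm: float = 300.0):
    """Vesicle axial coordinate: reflecting random walk in [0, z_max].

    The walk starts shallow (within 40 nm of the membrane): a visiting
    vesicle is defined by its arrival into the evanescent field, so its
    appearance is bright, and subsequent depth excursions modulate it.
    """
    z = np.empty(n)
    z[0] = rng.uniform(0.0, 40.0)
    for i in range(1, n):
        zi = z[i - 1] + rng.normal(0.0, step_nm)
        zi = abs(zi)
        if zi > z_max_nm:
            zi = 2 * z_max_nm - zi
        z[i] = zi
    return z


def _event_photon_frames(spec: EventSpec, config: SimConfig, rng):
    """Per-frame vesicle-channel photon images for one event, plus truth.

    Returns ``(frames, positions, peak_frame)`` where ``frames`` maps frame
    index -> photon image contribution and ``positions`` maps frame index ->
    (y, x).
    """
    T = config.n_frames
    dt = config.frame_interval_s
    sigma = config.psf_sigma_px
    shape = config.image_shape
    frames: dict[int, np.ndarray] = {}
    positions: dict[int, tuple[float, float]] = {}

    if spec.kind == "visiting":
        n = min(spec.dwell_frames, T - spec.onset_frame)
        track = brownian_track(
            max(n, 2), spec.lateral_D_um2_s, dt, config.pixel_size_um,
            seed=rng, start=(spec.y0, spec.x0),
        )[:n]
        z = _reflected_depth_walk(rng, n)
        depth_gain = np.exp(-z / TIRF_DEPTH_NM)
        for i in range(n):
            t = spec.onset_frame + i
            y, x = track[i]
            frames[t] = gaussian_spot(
                shape, (y, x), sigma, spec.amplitude_photons * depth_gain[i]
            )
            positions[t] = (float(y), float(x))
        peak_frame = spec.onset_frame + int(np.argmax(depth_gain))

    elif spec.kind == "docking":
        for t in range(spec.onset_frame, T):
            frames[t] = gaussian_spot(
                shape, (spec.y0, spec.x0), sigma, spec.amplitude_photons
            )
            positions[t] = (spec.y0, spec.x0)
        peak_frame = spec.onset_frame

    else:  # fusing: dim docked vesicle from frame 0, dequench + spread at onset
        for t in range(T):
            positions[t] = (spec.y0, spec.x0)
            if t < spec.onset_frame:
                frames[t] = gaussian_spot(
                    shape, (spec.y0, spec.x0), sigma, spec.amplitude_photons
                )
            else:
                frames[t] = fusion_profile(
                    (t - spec.onset_frame) * dt,
                    spec.amplitude_photons,
                    spec.dequench_factor,
                    sigma,
                    spec.membrane_D_um2_s,
                    config.pixel_size_um,
                    shape=shape,
                    center=(spec.y0, spec.x0),
                )
        peak_frame = spec.onset_frame
    return frames, positions, peak_frame


def _marker_photon_frames(spec, config: SimConfig, vesicle_frames, peak_frame):
    """Marker-channel photon contribution of one event, per marker model."""
    T = config.n_frames
    dt = config.frame_interval_s
    shape = config.image_shape
    amp = spec.amplitude_photons * config.marker_amplitude_factor
    frames: dict[int, np.ndarray] = {}

    if config.marker_model == "cytosolic":
        return frames  # uniform fill handled globally

    if config.marker_model == "cargo_like":
        for t, img in vesicle_frames.items():
            frames[t] = config.marker_amplitude_factor * img
        return frames

    # pa_like: nothing pre-docking; linear ramp while docked; Gaussian-in-time
    # pulse peaking marker_lag_s after the fusion peak.
    sigma_sp = config.psf_sigma_px * 1.5  # PA spreads slightly beyond the vesicle
    if spec.kind == "docking":
        for t in range(spec.onset_frame, T):
            level = config.marker_docking_ramp_slope * (t - spec.onset_frame) * dt
            frames[t] = gaussian_spot(
                shape, (spec.y0, spec.x0), sigma_sp, amp * min(level, 2.0)
            )
    elif spec.kind == "fusing":
        t_lag = config.marker_lag_s
        s = config.marker_pulse_sigma_s
        for t in range(spec.onset_frame, T):
            dt_peak = (t - peak_frame) * dt
            pulse = np.exp(-((dt_peak - t_lag) ** 2) / (2.0 * s**2))
            frames[t] = gaussian_spot(shape, (spec.y0, spec.x0), sigma_sp, amp * pulse)
    return frames


def simulate_movie(
    config: SimConfig,
) -> tuple[CalibratedMovie, CalibratedMovie, GroundTruth]:
    """Render the two-channel movie described by ``config`` with its truth.

    Returns ``(vesicle_movie, marker_movie, truth)``. Identical configs
    (including ``rng_seed``) produce bit-identical stacks and truth. Raises
    if any event lies outside the cell footprint.
    """
    mask = config.cell_mask()
    h, w = config.image_shape
    for i, spec in enumerate(config.event_specs):
        iy, ix = int(round(spec.y0)), int(round(spec.x0))
        if not (0 <= iy < h and 0 <= ix < w and mask[iy, ix]):
            raise ValueError(
                f"event {i} at (y={spec.y0}, x={spec.x0}) lies outside the cell mask"
            )

    root = np.random.SeedSequence(config.rng_seed)
    event_seeds = root.spawn(len(config.event_specs))
    noise_rng = np.random.default_rng(root.spawn(1)[0])

    T = config.n_frames
    times = np.arange(T) * config.frame_interval_s
    bleach = np.exp(-times / config.bleach_tau_s)

    autofluor_photons = (config.cell_autofluor / config.gain) * mask.astype(np.float64)
    ves_photons = np.tile(autofluor_photons, (T, 1, 1))
    mark_photons = np.tile(autofluor_photons, (T, 1, 1))
    if config.marker_model == "cytosolic":
        mark_photons += config.cytosolic_level_photons * mask

    truth_events: list[dict] = []
    truth_tracks: list[dict] = []
    for spec, seed in zip(config.event_specs, event_seeds):
        rng = np.random.default_rng(seed)
        frames, positions, peak_frame = _event_photon_frames(spec, config, rng)
        for t, img in frames.items():
            ves_photons[t] += img
        for t, img in _marker_photon_frames(spec, config, frames, peak_frame).items():
            mark_photons[t] += img
        truth_events.append(
            dict(kind=spec.kind, x0=spec.x0, y0=spec.y0,
                 onset_frame=spec.onset_frame, peak_frame=int(peak_frame))
        )
        fr = sorted(positions)
        truth_tracks.append(
            dict(
                event_index=len(truth_events) - 1,
                frames=fr,
                y_px=[positions[t][0] for t in fr],
                x_px=[positions[t][1] for t in fr],
                true_D_um2_s=(spec.lateral_D_um2_s if spec.kind == "visiting" else 0.0),
            )
        )

    def render(photons: np.ndarray) -> np.ndarray:
        # cell-derived photons bleach; the camera offset does not
        photons = photons * bleach[:, None, None]
        if not config.shot_noise and config.read_noise_sd == 0:
            # exact expectation, kept in float: noiseless reference movies
            return config.gain * photons + config.background_offset
        shot = (noise_rng.poisson(photons).astype(np.float64)
                if config.shot_noise else photons)
        counts = (
            config.gain * shot
            + noise_rng.normal(0.0, config.read_noise_sd, size=photons.shape)
            + config.background_offset
        )
        return np.clip(np.round(counts), 0, 65535).astype(np.uint16)

    cal = dict(
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
    )
    vesicle = CalibratedMovie(render(ves_photons), channel_name="vesicle", **cal)
    marker = CalibratedMovie(render(mark_photons), channel_name="marker", **cal)
    truth = GroundTruth(
        events=truth_events, tracks=truth_tracks, marker_lag_s=config.marker_lag_s
    )
    return vesicle, marker, truth


def benchmark_config(
    n_events: int = 20,
    image_shape: tuple[int, int] = (256, 256),
    n_frames: int = 600,
    seed: int = 0,
    kinds: tuple[str, ...] = ("fusing", "docking", "visiting"),
    marker_model: str = "pa_like",
    min_separation_px: float = 22.0,
    **overrides,
) -> SimConfig:
    """Standard synthetic benchmark: mixed events scattered over one cell.

    Event kinds cycle through ``kinds``; positions are drawn inside the
    cell (margin 12 px from its edge) with a minimum pairwise separation so
    event footprints do not overlap, and onsets are uniform over the frame
    range satisfying the 50-pre/100-post inclusion rule. Deterministic in
    ``seed``.
    """
    h, w = image_shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    axes = (h / 2.0 - 10.0, w / 2.0 - 9.0)
    rng = np.random.default_rng(seed)
    positions: list[tuple[float, float]] = []
    while len(positions) < n_events:
        y = rng.uniform(center[0] - axes[0], center[0] + axes[0])
        x = rng.uniform(center[1] - axes[1], center[1] + axes[1])
        inside = (((y - center[0]) / (axes[0] - 12)) ** 2
                  + ((x - center[1]) / (axes[1] - 12)) ** 2) <= 1.0
        if inside and all(np.hypot(y - py, x - px) >= min_separation_px
                          for py, px in positions):
            positions.append((y, x))
    onsets = rng.integers(55, n_frames - 105, size=n_events)
    specs = [
        EventSpec(kinds[i % len(kinds)], x0=float(x), y0=float(y),
                  onset_frame=int(t))
        for i, ((y, x), t) in enumerate(zip(positions, onsets))
    ]
    return SimConfig(
        image_shape=image_shape, n_frames=n_frames, cell_center=center,
        cell_axes=axes, event_specs=specs, rng_seed=seed,
        marker_model=marker_model, **overrides,
    )


def expected_image(config: SimConfig, frame: int) -> np.ndarray:
    """Noiseless expected camera image (counts) of one frame.

    Equals offset + bleach(t) * (autofluor * mask + gain * event photons);
    the closed form against which Monte-Carlo averages are checked.
    """
    mask = config.cell_mask()
    root = np.random.SeedSequence(config.rng_seed)
    event_seeds = root.spawn(len(config.event_specs))
    photons = (config.cell_autofluor / config.gain) * mask.astype(np.float64)
    for spec, seed in zip(config.event_specs, event_seeds):
        rng = np.random.default_rng(seed)
        frames, _, _ = _event_photon_frames(spec, config, rng)
        if frame in frames:
            photons = photons + frames[frame]
    bleach = np.exp(-frame * config.frame_interval_s / config.bleach_tau_s)
    return config.background_offset + config.gain * photons * bleach
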