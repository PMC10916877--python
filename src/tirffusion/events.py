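"""Exocytic-event detection, trace extraction, and classification.

Candidate events are spots where intensity rises rapidly, found on a
temporal-difference movie (boxcar smoothing then lag-1 forward difference,
max-projected and bandpassed). At each candidate the circle-mean intensity
is extracted over a fixed pre/post window and normalized to the per-event
dF/F trace

    dF/F(t) = (C_t - C_i) / (C_max - C_i)

with C_i the mean over the 5 frames immediately before onset, so every
trace has baseline 0 and peak exactly 1. Events are then classified as
visiting, docking, or fusing from the trace shape, the lateral motion of
the intensity centroid, and the radial-spread series; a "fusing" label is
only assigned when the post-peak outward spread of fluorescence confirms
membrane merger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .movie_io import CalibratedMovie
from .spots import SpotGeometry, bandpass, detect_spots, region_pixels

logger = logging.getLogger(__name__)

#: Inclusion rule for event averaging: frames required before/after onset.
PRE_FRAMES = 50
POST_FRAMES = 100
BASELINE_FRAMES = 5
CROP_HALF_PX = 10  # 21x21 px event crop


@dataclass(frozen=True)
class EventCandidate:
    y: float
    x: float
    onset_frame: int
    detection_score: float = 0.0


@dataclass
class Trace:
    """A normalized per-event dF/F intensity trace.

    ``values[k]`` is dF/F at frame ``t0_frame - pre + k`` where ``pre`` is
    the number of pre-onset frames included; ``peak_frame`` indexes into
    the movie (absolute frames).
    """

    values: np.ndarray
    t0_frame: int
    frame_interval_s: float
    c_i: float
    c_max: float
    peak_frame: int
    start_frame: int

    def dff_at_frame(self, frame: int) -> float:
        k = frame - self.start_frame
        if not (0 <= k < len(self.values)):
            raise IndexError(f"frame {frame} outside trace window")
        return float(self.values[k])

    def post_onset(self) -> np.ndarray:
        """dF/F from onset onward."""
        return self.values[self.t0_frame - self.start_frame:]

    def times_since_onset_s(self) -> np.ndarray:
        return (
            np.arange(self.start_frame, self.start_frame + len(self.values))
            - self.t0_frame
        ) * self.frame_interval_s


@dataclass
class EventRecord:
    candidate: EventCandidate
    kind: str
    vesicle_trace: Trace
    marker_trace: Trace | None
    spread_series: np.ndarray
    displacement_series: np.ndarray
    confidence: float = 0.0
    qc_flags: set = field(default_factory=set)


@dataclass
class ClassifierParams:
    """Thresholds of the visiting/docking/fusing decision rules."""

    max_rise_frames: int = 5
    fusing_decay_dff: float = 0.6  # trace at peak + 1 s must fall below this
    spread_ratio: float = 1.3  # post-peak / pre-peak spread for fusion
    docking_plateau_dff: float = 0.5  # median of last quarter of window
    max_docked_displacement_px: float = 2.0


def difference_movie(
    movie: CalibratedMovie | np.ndarray, smooth_frames: int = 3
) -> np.ndarray:
    """Temporal boxcar then lag-1 forward difference, ``(T-1, H, W)``.

    Negative values (departures) are retained; callers that only care
    about appearances clip at zero.
    """
    data = movie.data if isinstance(movie, CalibratedMovie) else np.asarray(movie)
    data = data.astype(np.float32)
    if data.shape[0] < smooth_frames + 1:
        raise ValueError(
            f"movie too short: need > {smooth_frames} frames, got {data.shape[0]}"
        )
    if smooth_frames > 1:
        data = ndimage.uniform_filter1d(data, size=smooth_frames, axis=0,
                                        mode="nearest")
    return np.diff(data, axis=0)


def _circle_series(data: np.ndarray, center, geometry: SpotGeometry) -> np.ndarray:
    """Mean circle intensity at ``center`` for every frame."""
    circle_idx, _ = region_pixels(center, geometry, data.shape[1:])
    return data[:, circle_idx[:, 0], circle_idx[:, 1]].mean(axis=1)


def _refine_onset(series: np.ndarray, t_rise: int, k_sd: float = 4.0) -> int:
    """First frame where the series exceeds baseline mean + k_sd * SD.

    Baseline is up to 30 frames ending 2 frames before the steepest rise
    ``t_rise``; the search runs forward from the baseline end so noise far
    from the event cannot trigger a spurious onset.
    """
    b1 = max(t_rise - 2, 1)
    b0 = max(b1 - 30, 0)
    base = series[b0:b1]
    thr = base.mean() + k_sd * max(base.std(), 1e-9)
    for t in range(b1, min(t_rise + 6, len(series))):
        if series[t] > thr:
            return t
    return t_rise + 1  # first frame after the steepest smoothed rise


def find_event_candidates(
    movie: CalibratedMovie | np.ndarray,
    smooth_frames: int = 3,
    band_sigma_small: float = 1.0,
    band_sigma_large: float = 4.0,
    k_mad: float = 14.0,
    min_separation_px: float = 8.0,
    min_separation_frames: int = 10,
    geometry: SpotGeometry = SpotGeometry(),
    cell_mask: np.ndarray | None = None,
) -> list[EventCandidate]:
    """Detect locations and onsets of rapid intensity increases.

    The positive part of the difference movie is max-projected over time,
    bandpassed, and peak-found as for static spots; the onset at each peak
    is refined on the smoothed circle-mean series. Candidates closer than
    ``min_separation_px`` AND ``min_separation_frames`` are merged keeping
    the higher detection score.
    """
    data = movie.data if isinstance(movie, CalibratedMovie) else np.asarray(movie)
    smoothed = ndimage.uniform_filter1d(
        data.astype(np.float32), size=smooth_frames, axis=0, mode="nearest"
    )
    # full-step temporal difference: lag equal to the boxcar width captures
    # the entire intensity jump (the lag-1 difference_movie splits it over
    # the boxcar support, burying small events under the T-frame max)
    step = smoothed[smooth_frames:] - smoothed[:-smooth_frames]
    # bandpass each difference frame before projecting: max-projecting raw
    # noise over hundreds of frames would otherwise set the floor
    step = ndimage.gaussian_filter(step, (0, band_sigma_small, band_sigma_small))
    step -= ndimage.gaussian_filter(step, (0, band_sigma_large, band_sigma_large))
    proj = np.clip(step, 0, None).max(axis=0)
    spots = detect_spots(
        proj, band_sigma_small, band_sigma_large, k_mad,
        merge_radius_px=min_separation_px, stats_mask=cell_mask,
        prefiltered=True,
    )
    if cell_mask is not None:
        spots = [s for s in spots
                 if cell_mask[int(round(s.y)), int(round(s.x))]]

    cands = []
    h, w = data.shape[1:]
    # onset/localization series use an enlarged circle: a moving vesicle may
    # drift a few px between first entry and its brightest rise, and the
    # event is anchored at first entry
    big = SpotGeometry(circle_radius_px=geometry.circle_radius_px + 3.0,
                       gap_px=geometry.gap_px, ring_px=geometry.ring_px)
    for s in spots:
        try:
            series = _circle_series(smoothed, (s.y, s.x), big)
        except ValueError:
            try:
                series = _circle_series(smoothed, (s.y, s.x), geometry)
            except ValueError:
                continue  # edge spot
        # onset anchored at the FIRST competitive rise (>= half the largest
        # lag-w step): a moving vesicle may re-brighten more steeply later,
        # but its event starts at first entry
        rise_series = series[smooth_frames:] - series[:-smooth_frames]
        t_first = int(np.argmax(rise_series >= 0.5 * rise_series.max()))
        d1 = np.diff(series)
        w0 = max(t_first - 1, 0)
        t_rise = w0 + int(np.argmax(d1[w0:t_first + smooth_frames + 2]))
        onset = _refine_onset(series, t_rise)
        if onset >= data.shape[0]:
            continue
        # re-localize on the step image at that rise: the max-projection
        # position can reflect the later brightening instead
        t_loc = int(np.clip(t_first, 0, step.shape[0] - 1))
        iy, ix = int(round(s.y)), int(round(s.x))
        y0, y1 = max(0, iy - 5), min(h, iy + 6)
        x0, x1 = max(0, ix - 5), min(w, ix + 6)
        win = np.clip(step[t_loc, y0:y1, x0:x1], 0, None)
        if win.sum() > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((win * yy).sum() / win.sum())
            cx = float((win * xx).sum() / win.sum())
        else:
            cy, cx = s.y, s.x
        cands.append(
            EventCandidate(y=cy, x=cx, onset_frame=onset,
                           detection_score=s.peak_snr)
        )
    del step
    # merge candidates coincident in both space and time: group them, then
    # represent each group by its earliest-onset member whose score is
    # competitive (>= half the group's best) — a moving vesicle can score
    # higher on a later re-brightening, but its event starts at first entry
    cands.sort(key=lambda c: -c.detection_score)
    groups: list[list[EventCandidate]] = []
    for c in cands:
        for grp in groups:
            if any(
                np.hypot(c.y - k.y, c.x - k.x) < min_separation_px
                and abs(c.onset_frame - k.onset_frame) < min_separation_frames
                for k in grp
            ):
                grp.append(c)
                break
        else:
            groups.append([c])
    kept = []
    for grp in groups:
        best = max(g.detection_score for g in grp)
        eligible = [g for g in grp if g.detection_score >= 0.5 * best]
        eligible.sort(key=lambda g: (g.onset_frame, -g.detection_score))
        kept.append(eligible[0])
    kept.sort(key=lambda c: (c.onset_frame, c.y, c.x))
    return kept


def extract_trace(
    movie: CalibratedMovie,
    candidate: EventCandidate,
    geometry: SpotGeometry = SpotGeometry(),
    pre_frames: int = PRE_FRAMES,
    post_frames: int = POST_FRAMES,
) -> tuple[Trace, set]:
    """Normalized dF/F trace of the circle-mean intensity around an event.

    The annulus is deliberately not used here: its intensity changes when
    fusion occurs, so only the circle mean enters the trace. The baseline
    C_i is the mean over frames ``[onset-5, onset)``. Events without the
    full ``pre_frames``/``post_frames`` coverage are still traced but
    flagged ``"short_window"`` so averaging steps can exclude them.
    """
    T = movie.n_frames
    onset = candidate.onset_frame
    flags: set = set()
    start = onset - pre_frames
    stop = onset + post_frames
    if start < 0 or stop > T:
        flags.add("short_window")
        start = max(start, 0)
        stop = min(stop, T)
    if onset - BASELINE_FRAMES < 0:
        raise ValueError("onset too early: no baseline frames available")
    series = _circle_series(movie.data[start:stop], (candidate.y, candidate.x),
                            geometry)
    base = _circle_series(
        movie.data[onset - BASELINE_FRAMES:onset], (candidate.y, candidate.x),
        geometry,
    )
    c_i = float(base.mean())
    # peak searched post-onset: first global maximum
    post = series[onset - start:]
    c_max = float(post.max())
    # a non-positive (or numerically negligible) dynamic range cannot be
    # normalized: the trace never rises above its own baseline
    if c_max - c_i <= 1e-9 * max(abs(c_max), abs(c_i), 1.0):
        raise ValueError("flat event: C_max does not exceed baseline C_i")
    peak_frame = onset + int(np.argmax(post))
    values = (series - c_i) / (c_max - c_i)
    return (
        Trace(values=values, t0_frame=onset,
              frame_interval_s=movie.frame_interval_s, c_i=c_i, c_max=c_max,
              peak_frame=peak_frame, start_frame=start),
        flags,
    )


def _event_crop(data: np.ndarray, candidate: EventCandidate):
    iy, ix = int(round(candidate.y)), int(round(candidate.x))
    h, w = data.shape[1:]
    if not (CROP_HALF_PX <= iy < h - CROP_HALF_PX
            and CROP_HALF_PX <= ix < w - CROP_HALF_PX):
        return None
    return data[:, iy - CROP_HALF_PX:iy + CROP_HALF_PX + 1,
                ix - CROP_HALF_PX:ix + CROP_HALF_PX + 1]


def _trim_calibration(f: float) -> float:
    """Moment shrinkage of a 2-D Gaussian trimmed at fraction ``f`` of peak.

    Weighting a unit Gaussian by ``(G - f*G0)+`` gives second moment
    ``2 sigma^2 * c(f)``; this returns ``c(f)`` so the trimmed moment can
    be rescaled back to ``2 sigma^2`` independently of spot brightness.
    """
    if f <= 0:
        return 1.0
    u_c = np.log(1.0 / f)
    den = (1.0 - f) - f * u_c
    num = (1.0 - (1.0 + u_c) * f) - f * u_c**2 / 2.0
    return num / den


def radial_spread(
    event_movie_crop: np.ndarray,
    baseline_img: np.ndarray | None = None,
    smooth_sigma_px: float = 1.0,
    noise_k: float = 4.0,
    rel_threshold: float = 0.2,
    max_trim_fraction: float = 0.5,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Per-frame second central moment (px^2) of the crop's intensity.

    Each frame is background-subtracted (its own median, or a supplied
    baseline image), smoothed by ``smooth_sigma_px``, and trimmed at a
    threshold that is a fixed fraction ``rel_threshold`` of the frame's
    peak (never below ``noise_k`` robust noise SDs): shot noise in the
    empty part of the crop cannot pull the moment toward the crop's
    geometric moment, and — because the trim scales with brightness — the
    estimate is invariant to intensity changes of the spot. The trimmed
    moment is rescaled by the analytic Gaussian trim factor and the
    smoothing variance ``2 * smooth_sigma^2`` removed, so a
    diffraction-limited Gaussian spot of width sigma reads ~2 sigma^2 and
    outward spreading after fusion makes the series rise. Frames whose
    peak does not clear the noise floor yield NaN.

    ``noise_sd`` is the raw per-pixel noise SD if known (e.g. estimated
    from pre-event frames); it is converted to the smoothed image's scale
    internally. When omitted it is estimated per frame from the MAD — which
    overestimates once a spreading spot covers much of the crop.
    """
    crop = np.asarray(event_movie_crop, dtype=np.float64)
    if crop.ndim != 3 or min(crop.shape[1:]) < 15:
        raise ValueError("crop must be T x H x W with H, W >= 15")
    out = np.full(crop.shape[0], np.nan)
    yy, xx = np.mgrid[0:crop.shape[1], 0:crop.shape[2]]
    if noise_sd is not None and smooth_sigma_px:
        # white-noise SD after Gaussian smoothing: 1 / (2 sqrt(pi) sigma)
        noise_sd_s = noise_sd / (2.0 * np.sqrt(np.pi) * smooth_sigma_px)
    else:
        noise_sd_s = noise_sd
    for t in range(crop.shape[0]):
        img = crop[t] - (baseline_img if baseline_img is not None
                         else np.median(crop[t]))
        if smooth_sigma_px:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        sd = (noise_sd_s if noise_sd_s is not None
              else 1.4826 * np.median(np.abs(img - np.median(img))))
        peak = img.max()
        if peak <= noise_k * sd or peak <= 0:
            continue
        thr = max(rel_threshold * peak, noise_k * sd)
        if thr > max_trim_fraction * peak:
            # trim would leave only the very tip of the spot: the rescaling
            # becomes noise-dominated, so the frame is unusable
            continue
        img = np.clip(img - thr, 0, None)
        tot = img.sum()
        if tot <= 0:
            continue
        cy = (img * yy).sum() / tot
        cx = (img * xx).sum() / tot
        moment = (img * ((yy - cy) ** 2 + (xx - cx) ** 2)).sum() / tot
        moment /= _trim_calibration(thr / peak)
        out[t] = max(moment - 2.0 * smooth_sigma_px**2, 0.0)
    return out


def centroid_series(
    event_movie_crop: np.ndarray,
    baseline_img: np.ndarray | None = None,
    smooth_sigma_px: float = 1.0,
    noise_k: float = 3.0,
) -> np.ndarray:
    """Per-frame intensity centroid ``(y, x)`` of the background-subtracted crop.

    Uses the same smoothing + robust noise threshold as
    :func:`radial_spread`; without the threshold, clipped shot noise over
    the whole crop drags the centroid toward the crop centre.
    """
    crop = np.asarray(event_movie_crop, dtype=np.float64)
    yy, xx = np.mgrid[0:crop.shape[1], 0:crop.shape[2]]
    out = np.full((crop.shape[0], 2), np.nan)
    for t in range(crop.shape[0]):
        img = crop[t] - (baseline_img if baseline_img is not None
                         else np.median(crop[t]))
        if smooth_sigma_px:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        noise_sd = 1.4826 * np.median(np.abs(img - np.median(img)))
        img = np.clip(img - noise_k * noise_sd, 0, None)
        tot = img.sum()
        if tot <= 0:
            continue
        out[t] = (img * yy).sum() / tot, (img * xx).sum() / tot
    return out


def classify_event(
    vesicle_trace: Trace,
    spread_series: np.ndarray,
    displacement_series: np.ndarray,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[str, float]:
    """Assign visiting / docking / fusing from trace, spread, and motion.

    Decision order: FUSING if the rise to peak is fast (<= 5 frames), the
    trace has decayed below 0.6 one second after the peak, and the
    radial spread 0.5-1 s post-peak exceeds 1.3x the pre-peak spread
    (outward expansion verifies fusion). DOCKING if the trace plateaus
    (median of the last quarter of the window >= 0.5) with net centroid
    displacement <= 2 px and the spread criterion is not met. VISITING
    otherwise. Returns ``(kind, confidence)`` where confidence is the
    smallest relative margin to any threshold used.
    """
    dt = vesicle_trace.frame_interval_s
    onset = vesicle_trace.t0_frame
    peak = vesicle_trace.peak_frame
    n_post = len(vesicle_trace.post_onset())
    if n_post < 30:
        raise ValueError("trace must cover >= 30 post-onset frames")

    rise_frames = peak - onset
    one_s = int(round(1.0 / dt))
    k_peak1s = peak - vesicle_trace.start_frame + one_s
    dff_peak_1s = (float(vesicle_trace.values[k_peak1s])
                   if k_peak1s < len(vesicle_trace.values) else
                   float(vesicle_trace.values[-1]))

    # spread ratio: mean over peak+0.5..1 s vs mean over pre-peak frames
    k_peak = peak - vesicle_trace.start_frame
    pre = spread_series[max(0, k_peak - one_s):k_peak]
    post = spread_series[k_peak + one_s // 2:k_peak + one_s + 1]
    pre_m = np.nanmedian(pre) if np.isfinite(pre).any() else np.nan
    # a fused spot stays above noise throughout the post window; a visitor
    # that left (or dimmed away) leaves mostly-NaN spread there and cannot
    # verify as fusion
    post_ok = np.isfinite(post).sum() >= max(3, len(post) - 1) if len(post) else False
    post_m = np.nanmedian(post) if post_ok else np.nan
    ratio = post_m / pre_m if (np.isfinite(pre_m) and pre_m > 0
                               and np.isfinite(post_m)) else np.nan

    margins = []
    if (rise_frames <= params.max_rise_frames
            and dff_peak_1s <= params.fusing_decay_dff
            and np.isfinite(ratio) and ratio >= params.spread_ratio):
        margins = [
            (params.max_rise_frames - rise_frames + 1) / (params.max_rise_frames + 1),
            (params.fusing_decay_dff - dff_peak_1s) / params.fusing_decay_dff,
            (ratio - params.spread_ratio) / params.spread_ratio,
        ]
        return "fusing", float(min(margins))

    post_vals = vesicle_trace.post_onset()
    tail = post_vals[-max(1, len(post_vals) // 4):]
    plateau_med = float(np.median(tail))
    disp = displacement_series[np.isfinite(displacement_series)]
    net_disp = float(disp[-1]) if len(disp) else np.inf
    if (plateau_med >= params.docking_plateau_dff
            and net_disp <= params.max_docked_displacement_px):
        margins = [
            (plateau_med - params.docking_plateau_dff) / params.docking_plateau_dff,
            (params.max_docked_displacement_px - net_disp)
            / params.max_docked_displacement_px,
        ]
        return "docking", float(min(margins))

    conf = max(
        (params.docking_plateau_dff - plateau_med) / params.docking_plateau_dff,
        0.0,
    )
    return "visiting", float(conf)


def run_event_pipeline(
    vesicle_movie: CalibratedMovie,
    marker_movie: CalibratedMovie | None = None,
    cell_mask: np.ndarray | None = None,
    geometry: SpotGeometry = SpotGeometry(),
    detection_kwargs: dict | None = None,
    params: ClassifierParams = ClassifierParams(),
    pre_frames: int = PRE_FRAMES,
    post_frames: int = POST_FRAMES,
) -> list[EventRecord]:
    """Detect, trace, and classify every event in a recording.

    Marker traces are extracted at the vesicle-channel coordinates and
    normalized by the marker channel's own extremum. Deterministic given
    its inputs.
    """
    detection_kwargs = detection_kwargs or {}
    cands = find_event_candidates(
        vesicle_movie, geometry=geometry, cell_mask=cell_mask, **detection_kwargs
    )
    records: list[EventRecord] = []
    data = vesicle_movie.data.astype(np.float64)
    for cand in cands:
        qc: set = set()
        try:
            trace, flags = extract_trace(vesicle_movie, cand, geometry,
                                         pre_frames, post_frames)
        except ValueError as exc:
            logger.info("skipping candidate at (%.1f, %.1f): %s", cand.y, cand.x, exc)
            continue
        qc |= flags
        crop = _event_crop(data, cand)
        if crop is None:
            qc.add("crop_out_of_frame")
            continue
        crop = crop[trace.start_frame:trace.start_frame + len(trace.values)]
        n_base = cand.onset_frame - trace.start_frame
        # per-frame median subtraction (not the temporal baseline): a fusing
        # vesicle is present, dim, before fusion, and subtracting it would
        # erase the pre-peak spread reference
        noise_sd = None
        if n_base >= 3:
            d = np.diff(crop[:n_base], axis=0)
            noise_sd = float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))
        spread = radial_spread(crop, noise_sd=noise_sd)
        cent = centroid_series(crop)
        # start reference: median centroid just after the rise completes
        # (the detected onset frame itself may precede the spot)
        head = cent[n_base + 1:n_base + 7]
        head = head[np.isfinite(head).all(axis=1)]
        onset_pos = np.median(head, axis=0) if len(head) else None
        tail = cent[len(cent) - max(1, (len(cent) - n_base) // 4):]
        tail = tail[np.isfinite(tail).all(axis=1)]
        if onset_pos is None or not len(tail):
            disp_series = np.array([np.nan])
        else:
            # distance of the median late-window centroid from the onset position
            late = np.median(tail, axis=0)
            disp_series = np.hypot(cent[:, 0] - onset_pos[0],
                                   cent[:, 1] - onset_pos[1])
            disp_series[-1] = np.hypot(late[0] - onset_pos[0],
                                       late[1] - onset_pos[1])
        try:
            kind, conf = classify_event(trace, spread, disp_series, params)
        except ValueError:
            qc.add("too_short_to_classify")
            kind, conf = "visiting", 0.0
        marker_trace = None
        if marker_movie is not None:
            try:
                marker_trace, mflags = extract_trace(
                    marker_movie, cand, geometry, pre_frames, post_frames
                )
                qc |= {f"marker_{f}" for f in mflags}
            except ValueError:
                qc.add("marker_flat")
        records.append(
            EventRecord(candidate=cand, kind=kind, vesicle_trace=trace,
                        marker_trace=marker_trace, spread_series=spread,
                        displacement_series=disp_series, confidence=conf,
                        qc_flags=qc)
        )
    return records
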