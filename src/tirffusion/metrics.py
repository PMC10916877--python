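"""Per-event and per-group readouts of the event pipeline.

Covers event-triggered average/difference images, the marker dF/F readout
at the stage-appropriate reference time (vesicle peak for fusion/visiting,
80%-of-plateau for docking), 0-4 s trace integrals, vesicle-to-marker peak
lags, post-peak decay slopes with fast/slow histogram binning,
expression-corrected stage-relative marker intensity, and fusion rates
normalized to same-batch controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .events import BASELINE_FRAMES, EventRecord, Trace

logger = logging.getLogger(__name__)


@dataclass
class EventAverage:
    """Across-event mean images at onset ("initial") and at peak ("final")."""

    initial_img: np.ndarray
    final_img: np.ndarray
    diff_img: np.ndarray
    n_events: int
    window_initial: tuple[int, int]
    window_final: tuple[int, int]


@dataclass
class GroupRates:
    table: pd.DataFrame  # cell, group_label, batch_label, rate, relative_rate


def average_event_images(
    crops: list[np.ndarray],
    onset_indices: list[int],
    final_indices: list[int],
    window: int = 5,
) -> EventAverage:
    """Event-triggered 5-frame average images and their difference.

    ``crops[i]`` is an aligned T x H x W crop; the "initial" window is the
    ``window`` frames ending at each event's onset index and the "final"
    window the ``window`` frames ending at its own peak/plateau index.
    Per-event window means are averaged across events; the difference image
    is exactly final - initial.
    """
    if not crops:
        raise ValueError("no event crops supplied")
    initials, finals = [], []
    for crop, i0, i1 in zip(crops, onset_indices, final_indices):
        a0 = max(0, i0 - window)
        a1 = max(1, i0)
        b0 = max(0, i1 - window + 1)
        b1 = i1 + 1
        initials.append(crop[a0:a1].mean(axis=0))
        finals.append(crop[b0:b1].mean(axis=0))
    initial = np.mean(initials, axis=0)
    final = np.mean(finals, axis=0)
    return EventAverage(
        initial_img=initial, final_img=final, diff_img=final - initial,
        n_events=len(crops), window_initial=(-window, 0),
        window_final=(-window + 1, 1),
    )


def plateau_level(trace: Trace) -> float:
    """Plateau of a docking trace: median of the last quarter post-onset."""
    post = trace.post_onset()
    return float(np.median(post[-max(1, len(post) // 4):]))


def marker_at_reference(event: EventRecord) -> float:
    """Marker dF/F at the event's reference time.

    Fusing and visiting events are read at the vesicle-trace peak frame;
    docking events at the first frame where the vesicle trace reaches 80%
    of its plateau. Returns NaN (with a qc flag on the event) when the
    docking trace never reaches the 80% level or the marker trace does not
    cover the reference frame.
    """
    if event.marker_trace is None:
        event.qc_flags.add("no_marker_trace")
        return float("nan")
    vt = event.vesicle_trace
    if event.kind in ("fusing", "visiting"):
        ref_frame = vt.peak_frame
    else:
        target = 0.8 * plateau_level(vt)
        post = vt.post_onset()
        hits = np.nonzero(post >= target)[0]
        if not len(hits):
            event.qc_flags.add("no_80pct_plateau")
            return float("nan")
        ref_frame = vt.t0_frame + int(hits[0])
    try:
        return event.marker_trace.dff_at_frame(ref_frame)
    except IndexError:
        event.qc_flags.add("marker_trace_short")
        return float("nan")


def integrate_trace(trace: Trace, t_start_s: float = 0.0, t_end_s: float = 4.0) -> float:
    """Trapezoidal integral of dF/F over time since onset (units dF/F * s)."""
    t = trace.times_since_onset_s()
    if t[0] > t_start_s or t[-1] < t_end_s:
        raise ValueError(
            f"trace covers [{t[0]:.2f}, {t[-1]:.2f}] s; need "
            f"[{t_start_s}, {t_end_s}] s after onset"
        )
    sel = (t >= t_start_s) & (t <= t_end_s)
    return float(np.trapezoid(trace.values[sel], t[sel]))


def peak_lag(
    vesicle_trace: Trace, marker_trace: Trace, smooth_frames: int = 3
) -> float:
    """Time from the vesicle-trace peak to the marker-trace peak, seconds.

    Both traces are boxcar-smoothed over ``smooth_frames`` before taking
    the (first) argmax, suppressing single-frame shot-noise maxima. The
    default width of 3 keeps the argmax of the sharply-peaked,
    asymmetric vesicle fusion trace unbiased (wider boxcars drag it onto
    the slow decay side). Returns NaN for a flat marker trace.
    """
    if np.ptp(marker_trace.values) == 0:
        return float("nan")

    def smoothed_peak(tr: Trace) -> int:
        v = ndimage.uniform_filter1d(
            np.asarray(tr.values, dtype=float), size=smooth_frames, mode="nearest"
        )
        k0 = tr.t0_frame - tr.start_frame
        return tr.t0_frame + int(np.argmax(v[k0:]))

    dv = smoothed_peak(marker_trace) - smoothed_peak(vesicle_trace)
    return dv * vesicle_trace.frame_interval_s


def decay_slope(vesicle_trace: Trace, window_s: float = 1.0) -> float:
    """Least-squares slope (per second) of dF/F over [peak, peak + 1 s]."""
    dt = vesicle_trace.frame_interval_s
    k_peak = vesicle_trace.peak_frame - vesicle_trace.start_frame
    n = int(round(window_s / dt))
    if k_peak + n >= len(vesicle_trace.values):
        raise ValueError("trace does not cover 1 s past the peak")
    y = vesicle_trace.values[k_peak:k_peak + n + 1]
    t = np.arange(len(y)) * dt
    return float(np.polyfit(t, y, 1)[0])


def bin_fast_slow(slopes, method: str = "otsu"):
    """Split decay slopes into fast/slow at a histogram-derived threshold.

    "Fast" events lose fluorescence quickly, i.e. their slope is more
    negative, so fast = slope below the threshold. Default threshold is
    Otsu's criterion on the slope values, falling back to the median when
    Otsu is degenerate (all values equal or requested explicitly with
    ``method="median"``). Returns ``(labels, threshold)``.
    """
    slopes = np.asarray(slopes, dtype=float)
    if len(slopes) < 4:
        raise ValueError("need >= 4 events to bin")
    if np.ptp(slopes) == 0:
        logger.warning("all decay slopes equal; emitting a single 'slow' bin")
        return np.array(["slow"] * len(slopes)), float(slopes[0])
    if method == "otsu":
        try:
            thr = float(threshold_otsu(slopes))
        except ValueError:
            thr = float(np.median(slopes))
    elif method == "median":
        thr = float(np.median(slopes))
    else:
        raise ValueError(f"unknown binning method {method!r}")
    labels = np.where(slopes < thr, "fast", "slow")
    return labels, thr


def stage_relative_intensity(
    events: list[EventRecord],
    marker_movie,
    mask,
    geometry=None,
) -> pd.DataFrame:
    """Expression-corrected marker intensity per event stage.

    For each event the marker intensity in the spot circle is divided by
    the mean marker intensity over the whole cell (correcting for reporter
    expression level), read at stage-specific times: "pre" (the 5 frames
    before onset), "final" (the docking plateau, fusion peak region, or
    visitor peak). Values are reported relative to the mean pre-event
    level of visiting vesicles, so accumulation shows as an excess above 0.
    Raises when no visiting events are present to anchor the reference.
    """
    from .spots import SpotGeometry, region_pixels

    geometry = geometry or SpotGeometry()
    cell_mean = marker_movie.data[:, mask.inside].mean(axis=1)

    def ratio(event: EventRecord, frames: np.ndarray) -> float:
        circle_idx, _ = region_pixels(
            (event.candidate.y, event.candidate.x), geometry,
            marker_movie.frame_shape,
        )
        vals = marker_movie.data[np.asarray(frames)][
            :, circle_idx[:, 0], circle_idx[:, 1]
        ].mean(axis=1)
        return float((vals / cell_mean[np.asarray(frames)]).mean())

    def marker_circle_ratio_series(ev, frames):
        from .spots import region_pixels as _rp

        circle_idx, _ = _rp((ev.candidate.y, ev.candidate.x), geometry,
                            marker_movie.frame_shape)
        vals = marker_movie.data[frames][:, circle_idx[:, 0], circle_idx[:, 1]]
        return vals.mean(axis=1) / cell_mean[frames]

    rows = []
    T = marker_movie.n_frames
    for i, ev in enumerate(events):
        onset = ev.candidate.onset_frame
        pre_frames = np.arange(max(0, onset - BASELINE_FRAMES), onset)
        vt = ev.vesicle_trace
        if ev.kind == "docking":
            last = vt.start_frame + len(vt.values)
            final_frames = np.arange(last - max(1, len(vt.post_onset()) // 4), last)
        elif ev.kind == "fusing":
            # post-fusion maximum of the marker itself: the marker (e.g. a
            # PA sensor) peaks with a lag after the vesicle's fusion peak
            window = np.arange(vt.peak_frame,
                               min(vt.start_frame + len(vt.values), T))
            series = marker_circle_ratio_series(ev, window)
            m = int(np.argmax(series))
            final_frames = window[max(0, m - 2):m + 3]
        else:
            p = vt.peak_frame
            final_frames = np.arange(p, min(p + BASELINE_FRAMES, T))
        rows.append(
            dict(event_id=i, kind=ev.kind,
                 r_pre=ratio(ev, pre_frames), r_final=ratio(ev, final_frames))
        )
    table = pd.DataFrame(rows)
    visiting_pre = table.loc[table["kind"] == "visiting", "r_pre"]
    if visiting_pre.empty:
        raise ValueError("reference unavailable: no visiting events")
    ref = float(visiting_pre.mean())
    table["rel_pre"] = table["r_pre"] - ref
    table["rel_final"] = table["r_final"] - ref
    return table


def relative_fusion_rate(
    counts_per_cell,
    durations_min,
    group_labels,
    batch_labels,
    control_label: str = "control",
) -> GroupRates:
    """Per-cell fusion rates normalized to same-batch control cells.

    rate = events / duration; relative_rate = rate / mean(control-cell
    rates in the same batch). Cells with zero events are included. Each
    batch must contain at least one control cell.
    """
    df = pd.DataFrame(
        {
            "count": np.asarray(counts_per_cell, dtype=float),
            "duration_min": np.asarray(durations_min, dtype=float),
            "group_label": list(group_labels),
            "batch_label": list(batch_labels),
        }
    )
    df["rate"] = df["count"] / df["duration_min"]
    rel = np.empty(len(df))
    for batch, sub in df.groupby("batch_label"):
        ctrl = sub.loc[sub["group_label"] == control_label, "rate"]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no {control_label!r} cell")
        rel[sub.index] = sub["rate"] / ctrl.mean()
    df["relative_rate"] = rel
    return GroupRates(table=df)


def event_summary_table(records: list[EventRecord]) -> pd.DataFrame:
    """One-row-per-event summary (the table the CLI writes as events.csv)."""
    rows = []
    for i, ev in enumerate(records):
        vt = ev.vesicle_trace
        rows.append(dict(
            event_id=i, kind=ev.kind,
            y_px=ev.candidate.y, x_px=ev.candidate.x,
            onset_frame=ev.candidate.onset_frame, peak_frame=vt.peak_frame,
            rise_frames=vt.peak_frame - vt.t0_frame,
            confidence=ev.confidence,
            qc_flags=";".join(sorted(ev.qc_flags)),
        ))
    return pd.DataFrame(rows, columns=[
        "event_id", "kind", "y_px", "x_px", "onset_frame", "peak_frame",
        "rise_frames", "confidence", "qc_flags"])


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between paired per-event values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)
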