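"""Vesicle trajectory linking, MSD diffusion estimation, and mobility.

Spots are linked frame-to-frame by optimal bipartite assignment on
Euclidean distance (deterministic and order-independent, unlike pure
greedy linking), with gap closing. Diffusion coefficients come from an
unweighted line fit to the first few points of the time-averaged MSD,
D = slope / 4 for 2-D motion, with a free intercept absorbing
localization noise. A vesicle is "mobile" when its estimated D exceeds
0.0055 um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .movie_io import DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM
from .spots import Spot

MOBILITY_THRESHOLD_UM2_S = 0.0055


@dataclass
class Track:
    track_id: int
    points: list[tuple[int, float, float]]  # (frame, y_px, x_px)
    D_um2_s: float = float("nan")
    mobile: bool = False

    @property
    def n_points(self) -> int:
        return len(self.points)

    def positions_px(self) -> np.ndarray:
        return np.array([(y, x) for _, y, x in self.points])

    def frames(self) -> np.ndarray:
        return np.array([f for f, _, _ in self.points])


def link_spots(
    per_frame_spots: list[list[Spot]],
    max_disp_px: float = 3.0,
    max_gap: int = 1,
    min_track_len: int = 10,
) -> list[Track]:
    """Link per-frame spot lists into trajectories.

    Per frame, open tracks compete for new spots via minimum-total-distance
    bipartite assignment; links longer than ``max_disp_px`` (scaled
    proportionally across closed gaps) are rejected. Tracks unseen for more
    than ``max_gap`` frames are closed; tracks shorter than
    ``min_track_len`` points are dropped.
    """
    open_tracks: list[dict] = []
    closed: list[list[tuple[int, float, float]]] = []

    for frame_idx, spots in enumerate(per_frame_spots):
        # retire tracks that exceeded the allowed gap
        still_open = []
        for tr in open_tracks:
            if frame_idx - tr["last_frame"] > max_gap + 1:
                closed.append(tr["points"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        assigned_spots = set()
        if open_tracks and spots:
            cost = np.full((len(open_tracks), len(spots)), 1e9)
            for i, tr in enumerate(open_tracks):
                gap = frame_idx - tr["last_frame"]
                limit = max_disp_px * gap
                _, ty, tx = tr["points"][-1]
                for j, s in enumerate(spots):
                    d = np.hypot(s.y - ty, s.x - tx)
                    if d <= limit:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e9:
                    open_tracks[i]["points"].append((frame_idx, spots[j].y, spots[j].x))
                    open_tracks[i]["last_frame"] = frame_idx
                    assigned_spots.add(j)
        for j, s in enumerate(spots):
            if j not in assigned_spots:
                open_tracks.append(
                    {"points": [(frame_idx, s.y, s.x)], "last_frame": frame_idx}
                )
    closed.extend(tr["points"] for tr in open_tracks)

    closed.sort(key=lambda pts: (pts[0][0], pts[0][1], pts[0][2]))
    return [
        Track(track_id=i, points=pts)
        for i, pts in enumerate(p for p in closed if len(p) >= min_track_len)
    ]


def msd(
    track: Track,
    max_lag: int = 4,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> np.ndarray:
    """Time-averaged mean squared displacement, shape ``(max_lag, 2)``.

    Column 0 is the lag in seconds, column 1 the MSD in um^2, averaged over
    all point pairs at each lag (frames must be contiguous within the
    pair's lag for it to count).
    """
    if track.n_points < max_lag + 1:
        raise ValueError(
            f"track has {track.n_points} points; need >= {max_lag + 1}"
        )
    frames = track.frames()
    pos_um = track.positions_px() * pixel_size_um
    out = np.zeros((max_lag, 2))
    for lag in range(1, max_lag + 1):
        sq = []
        # pair points exactly `lag` frames apart (robust to gap-closed tracks)
        frame_to_idx = {f: i for i, f in enumerate(frames)}
        for i, f in enumerate(frames):
            j = frame_to_idx.get(f + lag)
            if j is not None:
                sq.append(np.sum((pos_um[j] - pos_um[i]) ** 2))
        out[lag - 1] = lag * frame_interval_s, (np.mean(sq) if sq else np.nan)
    return out


def diffusion_coefficient(msd_curve: np.ndarray, fit_lags: int = 4) -> float:
    """D from an unweighted line fit to the first ``fit_lags`` MSD points.

    The intercept is free (it absorbs the static localization-noise
    offset); D = slope / 4. Negative estimates are reported as-is: they are
    part of the estimator's sampling distribution and classify as
    immobile.
    """
    curve = np.asarray(msd_curve, dtype=float)[:fit_lags]
    if len(curve) < 2:
        raise ValueError("need >= 2 MSD points to fit a line")
    slope = np.polyfit(curve[:, 0], curve[:, 1], 1)[0]
    return float(slope) / 4.0


def mobility_report(
    tracks: list[Track],
    threshold_um2_s: float = MOBILITY_THRESHOLD_UM2_S,
    fit_lags: int = 4,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> dict:
    """Per-track D, mobile flags, and the per-cell mobile fraction.

    Sets ``D_um2_s`` and ``mobile`` on each track in place and returns a
    summary dict with the track table, the mobile fraction, and mean D for
    all tracks vs. the mobile-only subset.
    """
    if not tracks:
        raise ValueError("no tracks")
    rows = []
    for tr in tracks:
        curve = msd(tr, max_lag=fit_lags, pixel_size_um=pixel_size_um,
                    frame_interval_s=frame_interval_s)
        tr.D_um2_s = diffusion_coefficient(curve, fit_lags)
        tr.mobile = tr.D_um2_s > threshold_um2_s
        rows.append(dict(track_id=tr.track_id, n_points=tr.n_points,
                         D_um2_s=tr.D_um2_s, mobile=tr.mobile))
    table = pd.DataFrame(rows)
    mobile = table.loc[table["mobile"], "D_um2_s"]
    return dict(
        table=table,
        mobile_fraction=float(table["mobile"].mean()),
        mean_D_all=float(table["D_um2_s"].mean()),
        mean_D_mobile=float(mobile.mean()) if len(mobile) else float("nan"),
        threshold_um2_s=threshold_um2_s,
    )
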