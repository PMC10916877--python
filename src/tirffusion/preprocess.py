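"""Cell-footprint estimation, extracellular background, photobleach correction.

The bleach correction rescales every frame so that the background-subtracted
mean intensity inside the cell is constant over time (equal to its value in
frame 0), the normalization needed before per-event intensity traces are
comparable across a recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .movie_io import CalibratedMovie

logger = logging.getLogger(__name__)

MIN_CELL_AREA_PX = 500


@dataclass
class CellMask:
    """Cell footprint plus the extracellular background region.

    ``outside`` excludes a guard band of ``guard_px`` pixels around the cell
    so bleed-through from the cell edge never contaminates the background
    estimate. ``inside`` and ``outside`` are disjoint by construction.
    """

    inside: np.ndarray
    outside: np.ndarray
    guard_px: int

    def __post_init__(self):
        if self.guard_px < 2:
            raise ValueError("guard band must be >= 2 px")
        if not self.outside.any():
            raise ValueError("background region is empty")
        if (self.inside & self.outside).any():
            raise ValueError("inside and outside masks overlap")


def estimate_cell_mask(movie: CalibratedMovie, guard_px: int = 5) -> CellMask:
    """Segment the (single) cell footprint from the temporal-mean image.

    Otsu threshold on the temporal mean, keep the largest connected
    component (ties broken toward the lowest ``(y, x)`` centroid), fill
    holes; the background region is the complement dilated away from the
    cell by ``guard_px``.
    """
    mean_img = movie.data.mean(axis=0)
    if np.ptp(mean_img) == 0:
        raise ValueError("no cell found: image is constant")
    thr = threshold_otsu(mean_img)
    binary = mean_img > thr
    labels = label(binary, connectivity=2)
    props = regionprops(labels)
    if not props:
        raise ValueError("no cell found: nothing above threshold")
    # largest area; ties broken by lowest (y, x) centroid
    props.sort(key=lambda p: (-p.area, p.centroid[0], p.centroid[1]))
    if len(props) > 1 and props[0].area == props[1].area:
        logger.info(
            "largest-component tie: keeping component with centroid %s",
            props[0].centroid,
        )
    if props[0].area < MIN_CELL_AREA_PX:
        raise ValueError(
            f"no cell found: largest component is {props[0].area} px "
            f"(< {MIN_CELL_AREA_PX})"
        )
    inside = ndimage.binary_fill_holes(labels == props[0].label)
    outside = ~ndimage.binary_dilation(inside, iterations=guard_px)
    return CellMask(inside=inside, outside=outside, guard_px=guard_px)


def background_level(movie: CalibratedMovie, mask: CellMask, frame="all"):
    """Mean extracellular intensity for one frame, or per-frame for "all"."""
    if frame == "all":
        return movie.data[:, mask.outside].mean(axis=1)
    frame = int(frame)
    if not (0 <= frame < movie.n_frames):
        raise IndexError(f"frame {frame} out of range [0, {movie.n_frames})")
    return float(movie.data[frame][mask.outside].mean())


def correct_photobleach(
    movie: CalibratedMovie,
    mask: CellMask,
    smooth_frames: int = 0,
) -> CalibratedMovie:
    """Rescale each frame to a constant background-subtracted cell mean.

    With per-frame background ``bg_t`` and cell signal ``m_t = mean(inside)
    - bg_t``, each frame is corrected as

        corrected = (raw - bg_t) * (m_0 / m_t) + bg_0

    which makes the background-subtracted cell mean exactly ``m_0`` in every
    frame of a noiseless movie, preserves ratios between same-frame cell
    pixels, and is idempotent. ``smooth_frames`` (odd, e.g. 11) optionally
    median-smooths the ``m_t`` series before use so shot noise in the cell
    mean is not imprinted on the movie; 0 disables smoothing.
    """
    bg = background_level(movie, mask, "all")
    m = movie.data[:, mask.inside].mean(axis=1) - bg
    if smooth_frames and smooth_frames > 1:
        m = ndimage.median_filter(m, size=smooth_frames, mode="nearest")
    if np.any(m <= 0):
        bad = int(np.argmax(m <= 0))
        raise ValueError(
            f"cell signal below background at frame {bad}: cannot correct"
        )
    scale = m[0] / m
    corrected = (
        (movie.data.astype(np.float64) - bg[:, None, None]) * scale[:, None, None]
        + bg[0]
    )
    return movie.with_data(corrected)


def correction_qc_table(movie: CalibratedMovie, mask: CellMask):
    """Per-frame QC of the bleach correction: cell mean, background, scale."""
    import pandas as pd

    bg = background_level(movie, mask, "all")
    cell_mean = movie.data[:, mask.inside].mean(axis=1)
    m = cell_mean - bg
    return pd.DataFrame(
        {
            "frame": np.arange(movie.n_frames),
            "cell_mean": cell_mean,
            "bg": bg,
            "scale": m[0] / m,
        }
    )
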