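"""Calibrated movie container, TIFF round-trip, and dual-view channel splitting.

Conventions used throughout the package: coordinates are 0-based ``(row, col)
= (y, x)``; frame windows are half-open ``[start, stop)``; the time of frame
``k`` is ``k * frame_interval_s`` (frame 0 = 0 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Acquisition defaults: EMCCD TIRF at 60x with 2.5x magnifier.
DEFAULT_PIXEL_SIZE_UM = 0.109
DEFAULT_FRAME_INTERVAL_S = 0.136


@dataclass
class CalibratedMovie:
    """A T x H x W intensity stack with physical calibration.

    Parameters
    ----------
    data
        Nonnegative intensities in camera counts, shape ``(T, H, W)``.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_name
        Free-text channel label (e.g. ``"vesicle"`` or ``"marker"``).
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(
                f"movie data must be (T, H, W) with T >= 1, got {self.data.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 = 0 s)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_data(self, data: np.ndarray) -> "CalibratedMovie":
        """Copy of this movie with ``data`` replaced, calibration kept."""
        return replace(self, data=data)


@dataclass(frozen=True)
class DualViewLayout:
    """Geometry of a dual-view splitter placing two channels on one camera.

    ``registration_shift`` is the integer ``(dy, dx)`` translation applied to
    channel B to bring it into register with channel A; both channels are then
    cropped by ``crop_margin`` pixels on every side so that coordinates
    correspond pixel-for-pixel.
    """

    split_axis: str = "horizontal"
    registration_shift: tuple[int, int] = (0, 0)
    crop_margin: int = 0

    def __post_init__(self) -> None:
        if self.split_axis not in ("horizontal", "vertical"):
            raise ValueError("split_axis must be 'horizontal' or 'vertical'")
        dy, dx = self.registration_shift
        if abs(dy) > self.crop_margin or abs(dx) > self.crop_margin:
            raise ValueError(
                "registration_shift must not exceed crop_margin in any axis"
            )


def read_movie(
    path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    channel_name: str = "",
) -> CalibratedMovie:
    """Read a single- or multi-page grayscale TIFF as a calibrated movie.

    Calibration missing from the file metadata falls back to the provided
    arguments. Pages must be 2-D (single channel).
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            if len(tif.pages) == 0:
                raise ValueError(f"movie at {path} has zero frames")
            first = tif.pages[0]
            if first.samplesperpixel != 1:
                raise ValueError(
                    f"expected single-channel pages in {path}, got "
                    f"{first.samplesperpixel} samples/pixel"
                )
            data = tif.asarray()
    except (ValueError, OSError):
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"could not read TIFF movie at {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"expected single-channel pages in {path}, got shape {data.shape}"
        )
    logger.info(
        "read %s: %d frames of %dx%d (%s)",
        path, data.shape[0], data.shape[1], data.shape[2], data.dtype,
    )
    return CalibratedMovie(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_name=channel_name,
    )


def write_movie(path, movie: CalibratedMovie) -> None:
    """Write a movie as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), np.asarray(movie.data),
                     photometric="minisblack")


def split_dualview(
    frames: np.ndarray | CalibratedMovie,
    layout: DualViewLayout,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> tuple[CalibratedMovie, CalibratedMovie]:
    """Split dual-view frames into two registered, equal-shape channel movies.

    The frame is halved along ``layout.split_axis`` (horizontal = left/right).
    Channel B is translated by ``layout.registration_shift`` and both halves
    are cropped by ``layout.crop_margin`` so coordinates correspond
    pixel-for-pixel.
    """
    if isinstance(frames, CalibratedMovie):
        if pixel_size_um is None:
            pixel_size_um = frames.pixel_size_um
        if frame_interval_s is None:
            frame_interval_s = frames.frame_interval_s
        frames = frames.data
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    pixel_size_um = pixel_size_um or DEFAULT_PIXEL_SIZE_UM
    frame_interval_s = frame_interval_s or DEFAULT_FRAME_INTERVAL_S

    axis = 2 if layout.split_axis == "horizontal" else 1
    if frames.shape[axis] % 2:
        raise ValueError(
            f"frame dimension along {layout.split_axis} split must be even, "
            f"got {frames.shape[axis]}"
        )
    half = frames.shape[axis] // 2
    if layout.split_axis == "horizontal":
        a, b = frames[:, :, :half], frames[:, :, half:]
    else:
        a, b = frames[:, :half, :], frames[:, half:, :]

    dy, dx = layout.registration_shift
    if dy or dx:
        b = np.roll(b, shift=(dy, dx), axis=(1, 2))
    m = layout.crop_margin
    if m:
        a = a[:, m:-m, m:-m]
        b = b[:, m:-m, m:-m]
    kwargs = dict(pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)
    return (
        CalibratedMovie(a.copy(), channel_name="channel_a", **kwargs),
        CalibratedMovie(b.copy(), channel_name="channel_b", **kwargs),
    )


def estimate_registration(
    channel_a_frame: np.ndarray,
    channel_b_frame: np.ndarray,
    max_shift: int = 5,
) -> tuple[int, int]:
    """Integer shift ``(dy, dx)`` registering channel B onto channel A.

    Maximizes the normalized cross-correlation over integer lags within
    ``+/- max_shift``; ties are broken toward smaller ``|shift|``, then
    smaller ``dy``, then smaller ``dx``. A best correlation below 0.2 is
    logged as a warning (likely featureless or unrelated frames).
    """
    a = np.asarray(channel_a_frame, dtype=float)
    b = np.asarray(channel_b_frame, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("no features to register: constant image")

    best: tuple | None = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(b, shift=(dy, dx), axis=(0, 1))
            # trim wrapped border so wraparound never contributes
            sl_y = slice(max(dy, 0), a.shape[0] + min(dy, 0))
            sl_x = slice(max(dx, 0), a.shape[1] + min(dx, 0))
            aa = a[sl_y, sl_x]
            bb = shifted[sl_y, sl_x]
            sa, sb = aa.std(), bb.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.mean((aa - aa.mean()) * (bb - bb.mean())) / (sa * sb))
            key = (-r, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx), r)
    assert best is not None
    if best[2] < 0.2:
        logger.warning(
            "low registration correlation r=%.3f at shift %s", best[2], best[1]
        )
    return best[1]
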