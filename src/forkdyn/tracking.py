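"""Single-focus tracking, 7x7 kymograms and per-focus intensity (formula 7).

A hand-picked focus is followed frame to frame; a 7x7 crop around its
(rounded) center per frame is stitched into a kymogram strip, and the mean
intensity inside a radius-3.5 px circle around the (unrounded) center,
minus a local background, gives the single-focus trace Q_t, normalized to
a peak of 1 as nM_t.  This is the single-focus validation route for the
diffuse-pool measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movie import Movie
from .roi import moving_average

__all__ = ["FocusTrack", "Kymogram", "track_focus", "build_kymogram", "focus_trace"]

CROP = 7
MEASURE_RADIUS = 3.5
ANNULUS = (5.0, 6.0)  # default local-background annulus radii, px


@dataclass
class FocusTrack:
    """Per-frame subpixel focus centers (y, x) with validity flags."""

    centers: np.ndarray  # (T, 2)
    valid: np.ndarray  # (T,) bool
    search_radius: float

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class Kymogram:
    """Stitched strip of per-frame 7x7 crops plus per-frame background."""

    crops: np.ndarray  # (T, 7, 7)
    centers: np.ndarray  # unrounded centers used for measurement
    local_background: np.ndarray  # (T,) mean of the background ROI
    in_bounds: np.ndarray  # (T,) crop fully inside the frame
    measure_radius: float = MEASURE_RADIUS
    q_t: np.ndarray | None = None
    nm_t: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def strip(self) -> np.ndarray:
        """The (7, 7*T) kymogram image."""
        return np.concatenate(list(self.crops), axis=1)


def _circle_pixels(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _annulus_pixels(shape, center, r_in, r_out):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 > r_in**2) & (d2 <= r_out**2)


def track_focus(
    movie_or_stack,
    seed_point,
    search_radius: float = 4.0,
    *,
    channel: str | None = None,
    min_contrast: float = 0.0,
    centroid_radius: float = 3.0,
) -> FocusTrack:
    """Follow one focus: per frame, the brightest pixel within
    ``search_radius`` of the previous center refines to an
    intensity-weighted centroid.

    A frame whose peak does not exceed the local background (annulus mean)
    by ``min_contrast`` is flagged invalid and the track coasts at the last
    position.
    """
    if isinstance(movie_or_stack, Movie):
        channel = channel or next(iter(movie_or_stack.channels))
        stack = movie_or_stack.channels[channel]
    else:
        stack = np.asarray(movie_or_stack, dtype=float)
    T, H, W = stack.shape
    sy, sx = seed_point
    if not (0 <= sy < H and 0 <= sx < W):
        raise ValueError(f"seed point {seed_point} outside the image")

    centers = np.zeros((T, 2))
    valid = np.zeros(T, dtype=bool)
    prev = (float(sy), float(sx))
    for t in range(T):
        frame = stack[t]
        search = _circle_pixels((H, W), prev, search_radius)
        vals = np.where(search, frame, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        bg_px = _annulus_pixels((H, W), peak, *ANNULUS)
        local_bg = frame[bg_px].mean() if bg_px.any() else 0.0
        if frame[peak] - local_bg <= min_contrast:
            centers[t] = prev  # coast
            valid[t] = False
            continue
        yy, xx = np.mgrid[0:H, 0:W]
        # centroid, then re-centered centroid: the second pass removes most
        # of the truncation bias a window centered on the peak pixel causes
        center = peak
        cy = cx = None
        ok = True
        for _ in range(2):
            roi = _circle_pixels((H, W), center, centroid_radius)
            w = np.clip(frame - local_bg, 0, None) * roi
            tot = w.sum()
            if tot <= 0:
                ok = False
                break
            cy = float((w * yy).sum() / tot)
            cx = float((w * xx).sum() / tot)
            center = (cy, cx)
        if not ok:
            centers[t] = prev
            valid[t] = False
            continue
        centers[t] = (cy, cx)
        valid[t] = True
        prev = (cy, cx)
    return FocusTrack(centers=centers, valid=valid, search_radius=search_radius)


def build_kymogram(
    movie_or_stack,
    track: FocusTrack,
    *,
    channel: str | None = None,
    annulus: tuple[float, float] = ANNULUS,
    background_mask: np.ndarray | None = None,
) -> Kymogram:
    """Crop 7x7 windows at the rounded track centers and stitch them.

    Edge frames whose crop leaves the image are zero-padded and flagged.
    The local background per frame is the mean of ``background_mask`` if
    given, else of a ``annulus`` ring around the (unrounded) center.
    """
    if isinstance(movie_or_stack, Movie):
        channel = channel or next(iter(movie_or_stack.channels))
        stack = movie_or_stack.channels[channel]
    else:
        stack = np.asarray(movie_or_stack, dtype=float)
    T, H, W = stack.shape
    if len(track) != T:
        raise ValueError("track length does not match the movie")
    half = CROP // 2
    crops = np.zeros((T, CROP, CROP))
    in_bounds = np.zeros(T, dtype=bool)
    local_bg = np.zeros(T)
    for t in range(T):
        cy, cx = track.centers[t]
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = iy - half, iy + half + 1
        x0, x1 = ix - half, ix + half + 1
        if 0 <= y0 and y1 <= H and 0 <= x0 and x1 <= W:
            crops[t] = stack[t, y0:y1, x0:x1]
            in_bounds[t] = True
        else:
            ys0, xs0 = max(y0, 0), max(x0, 0)
            ys1, xs1 = min(y1, H), min(x1, W)
            crops[t, ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = stack[t, ys0:ys1, xs0:xs1]
        if background_mask is not None:
            if background_mask[_circle_pixels((H, W), (cy, cx), MEASURE_RADIUS)].any():
                raise ValueError(
                    f"background ROI overlaps the measurement circle at frame {t}"
                )
            local_bg[t] = stack[t][background_mask].mean()
        else:
            ring = _annulus_pixels((H, W), (cy, cx), *annulus)
            local_bg[t] = stack[t][ring].mean() if ring.any() else 0.0
    return Kymogram(
        crops=crops,
        centers=track.centers.copy(),
        local_background=local_bg,
        in_bounds=in_bounds,
    )


def focus_trace(kymogram: Kymogram, norm_window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Formula (7): Q_t = mean inside the radius-3.5 circle minus the local
    background; nM_t = Q_t / max(smoothed Q_t).

    The circle is evaluated around the unrounded center within each crop
    (a pixel belongs if its center lies within the radius); results are
    also stored on the kymogram.
    """
    T = len(kymogram.crops)
    half = CROP // 2
    q = np.zeros(T)
    for t in range(T):
        cy, cx = kymogram.centers[t]
        # center expressed in crop coordinates
        off = (cy - round(cy) + half, cx - round(cx) + half)
        circ = _circle_pixels((CROP, CROP), off, kymogram.measure_radius)
        q[t] = kymogram.crops[t][circ].mean() - kymogram.local_background[t]
    peak = moving_average(q, norm_window).max()
    nm = q / peak if peak != 0 else np.zeros_like(q)
    kymogram.q_t, kymogram.nm_t = q, nm
    return q, nm
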