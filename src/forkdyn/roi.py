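"""ROI-based diffuse-pool photometry: bound intensity and bound fraction.

The measurement scheme watches the freely diffusing pool instead of the foci
themselves: region A is the nucleus, regions B are 1-3 small nuclear regions
that never contain a focus, and region C samples the camera background
outside every cell.  With D_t the background-corrected mean of B and T_ref
its mean over a reference window where (essentially) the whole pool is
diffuse, the bound intensity is E_t = T_ref - D_t, the max-normalized bound
intensity is nE_t, and the bound fraction of the total nuclear pool is
F_t = E_t / T_ref.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects
from skimage.registration import phase_cross_correlation

from .movie import Movie

__all__ = [
    "ROISet",
    "RawTraces",
    "BoundTrace",
    "ellipse_mask",
    "disk_mask",
    "rect_mask",
    "segment_nuclei",
    "register_translation",
    "find_foci_free_regions",
    "background_region",
    "measure_raw",
    "bound_trace",
    "moving_average",
    "aggregate_cells",
    "load_rois",
    "save_rois",
]

MIN_REGION_PIXELS = 25


def ellipse_mask(shape, center, axes) -> np.ndarray:
    """Boolean ellipse; ``center`` and ``axes`` are (y, x) / (semi_y, semi_x)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def disk_mask(shape, center, radius) -> np.ndarray:
    return ellipse_mask(shape, center, (radius, radius))


def rect_mask(shape, top_left, size) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    y0, x0 = top_left
    m[y0 : y0 + size[0], x0 : x0 + size[1]] = True
    return m


@dataclass
class ROISet:
    """Nucleus (A), foci-free regions (B, 1-3) and background (C) masks."""

    nucleus: np.ndarray
    foci_free: list[np.ndarray]
    background: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= len(self.foci_free) <= 3:
            raise ValueError("need 1-3 foci-free regions")
        for i, b in enumerate(self.foci_free):
            if np.any(b & ~self.nucleus):
                raise ValueError(f"foci-free region {i} leaves the nucleus")
            if b.sum() < MIN_REGION_PIXELS:
                raise ValueError(f"foci-free region {i} smaller than {MIN_REGION_PIXELS} px")
        if np.any(self.background & self.nucleus):
            raise ValueError("background region overlaps the nucleus")
        if self.background.sum() < MIN_REGION_PIXELS or self.nucleus.sum() < MIN_REGION_PIXELS:
            raise ValueError(f"regions must cover >= {MIN_REGION_PIXELS} px")


@dataclass
class RawTraces:
    """Per-frame mean intensities of the ROIs for one channel."""

    times: np.ndarray  # minutes
    nucleus: np.ndarray  # mean of A, (T,)
    foci_free: np.ndarray  # mean of each B, (n_B, T)
    background: np.ndarray  # mean of C, (T,)

    def __post_init__(self) -> None:
        T = len(self.times)
        if not (len(self.nucleus) == self.foci_free.shape[1] == len(self.background) == T):
            raise ValueError("trace lengths differ")


@dataclass
class BoundTrace:
    """Derived bound-protein time series for one cell and channel."""

    times: np.ndarray
    diffuse: np.ndarray  # D_t, background-corrected diffuse intensity
    total_ref: float  # T_ref, the total-pool reference intensity
    bound: np.ndarray  # E_t = T_ref - D_t
    bound_norm: np.ndarray  # nE_t, peak-normalized bound intensity
    fraction: np.ndarray  # F_t = E_t / T_ref
    reference_window: tuple[float, float]
    channel: str = ""
    cell_id: str = ""


def _region_to_mask(region: dict, shape) -> np.ndarray:
    """One named region from an ROI file: ellipse, polygon or rect."""
    kind = region["type"]
    if kind == "ellipse":
        return ellipse_mask(shape, region["center"], region["axes"])
    if kind == "polygon":
        from skimage.draw import polygon as sk_polygon

        verts = np.asarray(region["vertices"], dtype=float)
        rr, cc = sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m
    if kind == "rect":
        return rect_mask(shape, region["top_left"], region["size"])
    raise ValueError(f"unknown region type {kind!r}")


def load_rois(path: str | Path, shape) -> ROISet:
    """Read an ROI JSON file into masks for frames of the given shape.

    Layout: ``{"nucleus": {...}, "foci_free": [{...}, ...],
    "background": {...}}`` where each region is
    ``{"type": "ellipse", "center": [y, x], "axes": [ay, ax]}``,
    ``{"type": "polygon", "vertices": [[y, x], ...]}`` or
    ``{"type": "rect", "top_left": [y, x], "size": [h, w]}``
    in 0-based pixel coordinates.
    """
    spec = json.loads(Path(path).read_text())
    return ROISet(
        nucleus=_region_to_mask(spec["nucleus"], shape),
        foci_free=[_region_to_mask(r, shape) for r in spec["foci_free"]],
        background=_region_to_mask(spec["background"], shape),
    )


def save_rois(regions: dict, path: str | Path) -> None:
    """Write a region-specification dict (the `load_rois` layout) to JSON."""
    Path(path).write_text(json.dumps(regions, indent=2))


def segment_nuclei(frame: np.ndarray, min_area: int = 200, sigma: float = 2.0) -> np.ndarray:
    """Label nuclei in a single frame: smooth, Otsu, fill holes, size filter.

    Returns an integer label image; all zeros (with a warning) when nothing
    of at least ``min_area`` pixels is found.
    """
    if frame.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    smoothed = gaussian(frame.astype(float), sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image: no nuclei found", stacklevel=2)
        return np.zeros(frame.shape, dtype=np.int32)
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    labels = sk_label(mask)
    if labels.max() == 0:
        warnings.warn(f"no connected component of >= {min_area} px", stacklevel=2)
    return labels.astype(np.int32)


def register_translation(
    stack: np.ndarray,
    upsample_factor: int = 20,
    min_shift: float = 0.3,
    max_shift: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and undo per-frame translation against the first frame.

    Returns ``(corrected_stack, shifts)`` where ``shifts[t]`` is the (dy, dx)
    displacement of frame ``t`` relative to frame 0 (subpixel, from
    cross-correlation); the corrected stack has each frame shifted back by
    ``-shifts[t]``.

    Estimates below ``min_shift`` pixels are treated as correlation jitter
    (foci appearing/dissolving shift the correlation peak slightly even on a
    perfectly still cell): they are reported as zero and the frame is left
    untouched rather than needlessly resampled.  Estimates above
    ``max_shift`` pixels are spurious correlation peaks (a nucleus does not
    jump across the field between frames); the previous frame's shift is
    carried over instead, with a warning.
    """
    if stack.ndim != 3:
        raise ValueError("expected a (T, Y, X) stack")
    n = stack.shape[0]
    shifts = np.zeros((n, 2))
    corrected = np.empty_like(stack, dtype=float)
    corrected[0] = stack[0]
    ref = stack[0].astype(float)
    if np.ptp(ref) == 0:
        warnings.warn("flat reference frame: assuming zero drift", stacklevel=2)
        return stack.astype(float).copy(), shifts
    for t in range(1, n):
        est, _, _ = phase_cross_correlation(
            ref, stack[t].astype(float), upsample_factor=upsample_factor
        )
        # phase_cross_correlation returns the shift that maps the moving
        # frame onto the reference, i.e. minus the displacement.
        if np.hypot(*est) - np.hypot(*shifts[t - 1]) > max_shift:
            warnings.warn(
                f"frame {t}: implausible shift {tuple(np.round(est, 1))}; "
                "reusing the previous frame's shift",
                stacklevel=2,
            )
            est = -shifts[t - 1]
        if np.hypot(*est) < min_shift:
            corrected[t] = stack[t].astype(float)
            continue
        shifts[t] = -est
        corrected[t] = ndi.shift(stack[t].astype(float), est, order=1, mode="nearest")
    return corrected, shifts


def find_foci_free_regions(
    stack: np.ndarray,
    nucleus: np.ndarray,
    n_regions: int = 3,
    radius: float = 5.0,
    focus_quantile: float = 0.90,
) -> list[np.ndarray]:
    """Pick small disks inside the nucleus that avoid foci at every frame.

    Emulates the manual selection of foci-free regions: pixels whose
    temporal-maximum intensity falls in the top ``1 - focus_quantile`` of
    nuclear pixels are treated as (ever-)focus pixels, and disk centers are
    chosen greedily to maximize distance from them and from each other.
    """
    if stack.ndim != 3:
        raise ValueError("expected a (T, Y, X) stack")
    # smooth along time before taking the max so the choice of "never
    # bright" pixels conditions on the signal, not on single-frame noise
    # (which would bias the selected pixels' noise downward near their peak)
    sm = ndi.uniform_filter1d(stack, size=min(5, stack.shape[0]), axis=0) if len(stack) > 1 else stack
    tmax = sm.max(axis=0)
    vals = tmax[nucleus]
    focus_px = np.zeros_like(nucleus)
    focus_px[nucleus] = vals > np.quantile(vals, focus_quantile)
    # keep disks well inside the nucleus: Gaussian smoothing makes the
    # segmented boundary overshoot the true edge by a few pixels, and a
    # disk straddling the real edge picks up large jitter from registration
    interior = ndi.distance_transform_edt(nucleus) > radius + 4.0
    dist = ndi.distance_transform_edt(~focus_px)
    regions: list[np.ndarray] = []
    score = np.where(interior, dist, -np.inf)
    for _ in range(n_regions):
        idx = np.unravel_index(np.argmax(score), score.shape)
        if not np.isfinite(score[idx]) or score[idx] <= radius:
            break
        m = disk_mask(nucleus.shape, idx, radius)
        regions.append(m)
        # suppress neighborhood so the next disk lands elsewhere
        score[disk_mask(nucleus.shape, idx, 3 * radius)] = -np.inf
    if not regions:
        raise ValueError("no foci-free region found; lower radius or quantile")
    return regions


def background_region(
    nucleus_labels: np.ndarray, size: tuple[int, int] = (12, 12), margin: int = 6
) -> np.ndarray:
    """A rectangle outside every nucleus, for the camera-background ROI."""
    free = ndi.binary_dilation(nucleus_labels > 0, iterations=margin)
    # slide a window over the corner-first order and take the first fit
    h, w = size
    fit = ndi.uniform_filter((~free).astype(float), size=size, mode="constant")
    candidates = np.argwhere(fit > 1.0 - 1e-9)
    if len(candidates) == 0:
        raise ValueError("no nucleus-free rectangle found for the background ROI")
    cy, cx = candidates[0]
    return rect_mask(nucleus_labels.shape, (max(cy - h // 2, 0), max(cx - w // 2, 0)), size)


def measure_raw(movie: Movie, rois: ROISet) -> dict[str, RawTraces]:
    """Per-frame mean intensity of each ROI, per channel."""
    shape = movie.frame_shape
    for m in (rois.nucleus, rois.background, *rois.foci_free):
        if m.shape != shape:
            raise ValueError(f"ROI shape {m.shape} does not match frames {shape}")
    times = movie.times
    out: dict[str, RawTraces] = {}
    for name, stack in movie.channels.items():
        nuc = stack[:, rois.nucleus].mean(axis=1)
        bg = stack[:, rois.background].mean(axis=1)
        bs = np.stack([stack[:, b].mean(axis=1) for b in rois.foci_free])
        out[name] = RawTraces(times=times, nucleus=nuc, foci_free=bs, background=bg)
    return out


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with edge shrinkage (same length as input)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def bound_trace(
    raw: RawTraces,
    reference: tuple[float, float],
    channel: str = "",
    *,
    cell_id: str = "",
    norm_window: int = 5,
    total_correction: float = 1.0,
) -> BoundTrace:
    """Apply formulas (1)-(4): D_t, E_t, nE_t and the bound fraction F_t.

    ``reference`` is a (t0, t1) time window (same unit as ``raw.times``,
    inclusive) during which the whole pool is taken as freely diffusing:
    post-dissolution for decay channels, pre-treatment for accumulation
    channels.  ``total_correction`` optionally scales T_ref to compensate a
    residual bound pool in the reference window (1.0 = none).  Negative E_t
    values are retained so noise statistics stay unbiased.
    """
    d_t = raw.foci_free.mean(axis=0) - raw.background  # formula (1), B averaged
    in_ref = (raw.times >= reference[0]) & (raw.times <= reference[1])
    if in_ref.sum() < 3:
        raise ValueError(
            f"reference window {reference} covers {in_ref.sum()} frames; need >= 3"
        )
    t_ref = float(d_t[in_ref].mean()) * total_correction
    if t_ref <= 0:
        raise ValueError("reference intensity T_ref <= 0: background exceeds signal")
    e_t = t_ref - d_t  # formula (2)
    peak = moving_average(e_t, norm_window).max()
    ne_t = e_t / peak if peak != 0 else np.zeros_like(e_t)  # formula (3)
    f_t = e_t / t_ref  # formula (4)
    return BoundTrace(
        times=raw.times,
        diffuse=d_t,
        total_ref=t_ref,
        bound=e_t,
        bound_norm=ne_t,
        fraction=f_t,
        reference_window=tuple(reference),
        channel=channel,
        cell_id=cell_id,
    )


def aggregate_cells(traces: list[BoundTrace], attr: str = "fraction"):
    """Population mean/SD per frame over cells aligned on the same timeline.

    Traces may differ in length at the edges; per-frame n is reported and
    short traces are excluded frame-wise.  Returns a dict of arrays
    (times, mean, sd, n).
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    n_frames = max(len(tr.times) for tr in traces)
    times = max(traces, key=lambda tr: len(tr.times)).times
    data = np.full((len(traces), n_frames), np.nan)
    for i, tr in enumerate(traces):
        vals = getattr(tr, attr)
        data[i, : len(vals)] = vals
    n = np.sum(~np.isnan(data), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(data, axis=0)
        sd = np.nanstd(data, axis=0)  # population SD; a single cell gives 0
    return {"times": times, "mean": mean, "sd": sd, "n": n}
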