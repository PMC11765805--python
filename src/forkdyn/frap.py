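"""FRAP normalization, two-component decomposition and exchange rates.

A photobleached replication focus recovers by two routes: fast exchange
with the freely diffusing pool and slow exchange of the replisome/ssDNA
bound pool; whatever never recovers is the immobile fraction.  The raw
focus trace is normalized in four steps: (a) subtract the camera background
from both foci; (b) set the mean of the six pre-bleach frames to one for
both; (c) divide the bleached by the unbleached focus, cancelling
acquisition photobleaching; (d) map the curve affinely so the first
post-bleach point is exactly 0 and the pre-bleach mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .movie import Movie
from .roi import disk_mask

__all__ = [
    "FRAPRecord",
    "normalize_frap",
    "fit_two_component",
    "bound_recovery",
    "exchange_rate",
    "frap_traces",
    "analyze_frap",
]

_LN2 = float(np.log(2.0))
N_PRE_NORM = 6  # pre-bleach frames entering the normalization


@dataclass
class FRAPRecord:
    """A normalized FRAP curve plus (optionally) its fitted decomposition."""

    times: np.ndarray  # seconds, 0 at the first post-bleach frame
    normalized: np.ndarray
    bleach_frame: int
    raw_bleached: np.ndarray | None = None
    raw_unbleached: np.ndarray | None = None
    a_fast: float | None = None
    k_fast: float | None = None
    a_slow: float | None = None
    k_slow: float | None = None
    two_component: bool | None = None
    bound_curve: np.ndarray | None = None
    t_half_bound: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def immobile(self) -> float | None:
        if self.a_fast is None:
            return None
        return 1.0 - self.a_fast - (self.a_slow or 0.0)

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.bleach_frame, None)
        return self.times[sl], self.normalized[sl]


def normalize_frap(
    times,
    bleached,
    unbleached,
    background,
    bleach_frame: int,
) -> FRAPRecord:
    """Normalization steps (a)-(d); ``bleach_frame`` indexes the first
    post-bleach frame.

    Raises on fewer than six pre-bleach frames, on a gap (non-finite value)
    in the unbleached trace, and on a degenerate record where no bleach is
    detectable (steps would divide by ~0).
    """
    times = np.asarray(times, dtype=float)
    fb = np.asarray(bleached, dtype=float)
    fu = np.asarray(unbleached, dtype=float)
    bg = np.asarray(background, dtype=float)
    if bleach_frame < N_PRE_NORM:
        raise ValueError(
            f"need >= {N_PRE_NORM} pre-bleach frames, got {bleach_frame}"
        )
    if not np.all(np.isfinite(fu)):
        raise ValueError("unbleached reference focus trace has gaps")
    pre = slice(bleach_frame - N_PRE_NORM, bleach_frame)

    fb = fb - bg  # (a)
    fu = fu - bg
    fb = fb / fb[pre].mean()  # (b)
    fu = fu / fu[pre].mean()
    ratio = fb / fu  # (c)
    pre_mean = ratio[pre].mean()
    post0 = ratio[bleach_frame]
    if abs(pre_mean - post0) < 1e-6 * max(abs(pre_mean), 1.0):
        raise ValueError(
            "degenerate record: no intensity drop at the bleach frame"
        )
    normalized = (ratio - post0) / (pre_mean - post0)  # (d)
    t0 = times - times[bleach_frame]
    return FRAPRecord(
        times=t0,
        normalized=normalized,
        bleach_frame=bleach_frame,
        raw_bleached=np.asarray(bleached, dtype=float),
        raw_unbleached=np.asarray(unbleached, dtype=float),
    )


def _two_exp(t, a_f, a_s, k_s, ratio):
    k_f = ratio * k_s
    return a_f * (1 - np.exp(-k_f * t)) + a_s * (1 - np.exp(-k_s * t))


def _one_exp(t, a, k):
    return a * (1 - np.exp(-k * t))


def fit_two_component(
    record: FRAPRecord,
    *,
    min_rate_ratio: float = 10.0,
    improvement: float = 0.05,
) -> FRAPRecord:
    """Fit ``A_f (1-e^{-k_f t}) + A_s (1-e^{-k_s t})`` to the recovery.

    Identifiability is enforced through ``k_f >= min_rate_ratio * k_s``.
    When the two-component fit does not reduce the single-exponential
    residual by at least ``improvement`` (fractional), the single-component
    model is kept (``a_slow = 0`` branch): this covers single-step
    recoveries such as RPA's.  The record is updated in place and returned.
    """
    t, y = record.post_bleach()
    if len(t) < 8:
        raise ValueError("too few post-bleach points to fit")
    span = t[-1] - t[0]
    plateau = float(np.mean(y[-max(len(y) // 10, 3):]))
    k0 = _LN2 / max(span / 5.0, t[1] - t[0])

    errors = []
    try:
        p1, _ = optimize.curve_fit(
            _one_exp, t, y, p0=(max(plateau, 0.1), k0),
            bounds=([0, 1e-9], [1.2, np.inf]), maxfev=20000,
        )
        ss1 = float(np.sum((_one_exp(t, *p1) - y) ** 2))
    except RuntimeError as err:
        p1, ss1 = None, np.inf
        errors.append(f"single: {err}")

    try:
        a0 = np.clip(plateau, 0.05, 1.0)
        p2, _ = optimize.curve_fit(
            _two_exp, t, y,
            p0=(0.6 * a0, 0.4 * a0, k0 / 5.0, 5.0 * min_rate_ratio),
            bounds=([0, 0, 1e-9, min_rate_ratio], [1.0, 1.0, np.inf, 1e6]),
            maxfev=40000,
        )
        ss2 = float(np.sum((_two_exp(t, *p2) - y) ** 2))
    except RuntimeError as err:
        p2, ss2 = None, np.inf
        errors.append(f"double: {err}")

    if p1 is None and p2 is None:
        raise RuntimeError("neither FRAP model converged: " + "; ".join(errors))

    use_two = p2 is not None and (p1 is None or ss2 <= (1.0 - improvement) * ss1)
    if use_two:
        a_f, a_s, k_s, ratio = p2
        record.a_fast, record.k_fast = float(a_f), float(ratio * k_s)
        record.a_slow, record.k_slow = float(a_s), float(k_s)
        record.two_component = True
    else:
        a, k = p1
        record.a_fast, record.k_fast = float(a), float(k)
        record.a_slow, record.k_slow = 0.0, np.nan
        record.two_component = False
    if record.a_fast + (record.a_slow or 0) > 1.0:
        # numerical overshoot; clip the immobile fraction at 0
        excess = record.a_fast + record.a_slow - 1.0
        record.a_fast = max(record.a_fast - excess, 0.0)
    return record


def bound_recovery(record: FRAPRecord) -> FRAPRecord:
    """Isolate the bound-pool recovery: subtract the fitted fast component
    and renormalize by ``1 - A_f``; ``t_half_bound = ln 2 / k_s``.

    For single-component records the fitted component is itself taken as
    the bound recovery (nothing to subtract).
    """
    if record.a_fast is None:
        raise ValueError("fit_two_component must run first")
    t, y = record.post_bleach()
    if record.two_component:
        if record.a_fast >= 1.0:
            raise ValueError("fast amplitude >= 1: no bound pool left")
        fast = _one_exp(t, record.a_fast, record.k_fast)
        record.bound_curve = (y - fast) / (1.0 - record.a_fast)
        record.t_half_bound = _LN2 / record.k_slow
    else:
        record.bound_curve = y.copy()
        record.t_half_bound = _LN2 / record.k_fast
    return record


def exchange_rate(record: FRAPRecord, n_bound: float, window_s: float) -> dict:
    """Complexes exchanged within ``window_s`` of bleaching, and per minute.

    The bound-normalized recovery gain over the window times the number of
    bound complexes gives the absolute exchange; scaling by 60/window gives
    a per-minute rate (the window should cover the steepest recovery part).
    """
    if n_bound <= 0:
        raise ValueError("n_bound must be positive")
    if record.bound_curve is None:
        raise ValueError("bound_recovery must run first")
    t, _ = record.post_bleach()
    if window_s > t[-1]:
        raise ValueError(f"window {window_s}s beyond data span {t[-1]}s")
    idx = int(np.argmin(np.abs(t - window_s)))
    gained = float(record.bound_curve[idx] - record.bound_curve[0])
    complexes = n_bound * gained
    return {
        "complexes": complexes,
        "per_min": complexes * 60.0 / window_s,
        "window_s": float(window_s),
    }


def frap_traces(
    movie: Movie,
    bleached_center,
    unbleached_center,
    background_mask: np.ndarray,
    *,
    channel: str | None = None,
    radius: float = 3.5,
) -> dict[str, np.ndarray]:
    """Extract the four FRAP ROI traces from a movie (means per frame)."""
    if channel is None:
        channel = next(iter(movie.channels))
    stack = movie.channels[channel]
    shape = movie.frame_shape
    mb = disk_mask(shape, bleached_center, radius)
    mu = disk_mask(shape, unbleached_center, radius)
    return {
        "times": movie.times,
        "bleached": stack[:, mb].mean(axis=1),
        "unbleached": stack[:, mu].mean(axis=1),
        "background": stack[:, background_mask].mean(axis=1),
    }


def analyze_frap(
    times, bleached, unbleached, background, bleach_frame: int, **fit_kwargs
) -> FRAPRecord:
    """Full per-record pipeline: normalize, decompose, isolate bound pool."""
    rec = normalize_frap(times, bleached, unbleached, background, bleach_frame)
    fit_two_component(rec, **fit_kwargs)
    return bound_recovery(rec)
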