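"""Half-time fitting and rate estimation on bound-fraction traces.

All transitions are modelled as single exponentials with an offset, the
minimal form carrying a half-time: a stalling decay
``y = r + (a - r) exp(-k (t - t0))`` or a saturating rise
``y = b + a (1 - exp(-k (t - t0)))``, with ``t_half = ln 2 / k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .roi import moving_average

__all__ = ["KineticFit", "fit_decay", "fit_rise", "estimate_rate", "detect_plateau"]

_LN2 = float(np.log(2.0))
RATE_MODES = ("onset_to_halfmax", "mean", "max_window")


@dataclass(frozen=True)
class KineticFit:
    """Result of a single-exponential fit."""

    model: str  # "decay" | "rise"
    amplitude: float  # starting level (decay) / total rise (rise)
    plateau: float  # residual (decay) / baseline offset (rise)
    k: float  # rate constant, 1/min
    t_half: float  # ln 2 / k, min
    window: tuple[float, float]
    r_squared: float
    flagged: bool = False  # degenerate/unstable fit (flat trace etc.)
    per_cell: bool = True


def _select(times, y, window):
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is None:
        sel = np.ones(len(times), dtype=bool)
    else:
        sel = (times >= window[0]) & (times <= window[1])
    t, v = times[sel], y[sel]
    if len(t) < 6:
        raise ValueError(f"fit window holds {len(t)} points; need >= 6")
    return t, v


def _r_squared(y, pred) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def _fit(times, y, window, model: str) -> KineticFit:
    t, v = _select(times, y, window)
    t0 = t[0]
    start, end = float(v[0]), float(v[-1])
    span = max(abs(end - start), 1e-12)
    # initial rate from the time the trace first crosses halfway
    half = start + 0.5 * (end - start)
    crossed = np.nonzero((v - half) * np.sign(end - start) >= 0)[0]
    dt_half = t[crossed[0]] - t0 if len(crossed) and crossed[0] > 0 else (t[-1] - t0) / 4
    k0 = _LN2 / max(dt_half, (t[1] - t0))

    if np.ptp(v) < 1e-12:
        return KineticFit(
            model=model, amplitude=start, plateau=start, k=np.nan, t_half=np.nan,
            window=(float(t0), float(t[-1])), r_squared=0.0, flagged=True,
        )

    if model == "decay":
        def fun(tt, a, r, k):
            return r + (a - r) * np.exp(-k * (tt - t0))
        p0 = (start, end, k0)
    else:
        def fun(tt, a, b, k):
            return b + a * (1 - np.exp(-k * (tt - t0)))
        p0 = (end - start, start, k0)

    try:
        popt, _ = optimize.curve_fit(
            fun, t, v, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"{model} fit did not converge (p0={p0}, "
            f"initial residual={np.sum((fun(t, *p0) - v) ** 2):.4g}): {err}"
        ) from err
    pred = fun(t, *popt)
    r2 = _r_squared(v, pred)
    k = float(popt[2])
    if model == "decay":
        amplitude, plateau = float(popt[0]), float(popt[1])
    else:
        amplitude, plateau = float(popt[0]), float(popt[1])
    return KineticFit(
        model=model, amplitude=amplitude, plateau=plateau, k=k, t_half=_LN2 / k,
        window=(float(t0), float(t[-1])), r_squared=r2,
        flagged=not np.isfinite(r2) or r2 < 0.2,
    )


def fit_decay(times, y, window=None) -> KineticFit:
    """Fit ``y = r + (a - r) exp(-k (t - t0))`` on the window (minutes)."""
    return _fit(times, y, window, "decay")


def fit_rise(times, y, window=None) -> KineticFit:
    """Fit ``y = b + a (1 - exp(-k (t - t0)))`` on the window (minutes)."""
    return _fit(times, y, window, "rise")


def estimate_rate(
    times,
    g_t,
    window,
    mode: str = "onset_to_halfmax",
    slide_frames: int = 5,
) -> dict:
    """Accumulation/removal rate of a complexes-per-fork trace.

    ``mode``:
      - ``"onset_to_halfmax"``: regression slope from the window start to
        the first crossing of half the net change (headline mode);
      - ``"mean"``: net change / duration over the whole window;
      - ``"max_window"``: steepest regression slope over any
        ``slide_frames``-frame sliding window.

    Negative rates indicate removal.  Returns a dict with the rate, the
    mode, and the sub-window actually used.
    """
    if mode not in RATE_MODES:
        raise ValueError(f"mode must be one of {RATE_MODES}")
    times = np.asarray(times, dtype=float)
    g = np.asarray(g_t, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    t, v = times[sel], g[sel]
    if len(t) < 3:
        raise ValueError(f"rate window holds {len(t)} frames; need >= 3")

    if mode == "mean":
        rate = (v[-1] - v[0]) / (t[-1] - t[0])
        used = (float(t[0]), float(t[-1]))
    elif mode == "onset_to_halfmax":
        half = v[0] + 0.5 * (v[-1] - v[0])
        crossed = np.nonzero((v - half) * np.sign(v[-1] - v[0] or 1.0) >= 0)[0]
        stop = crossed[0] if len(crossed) and crossed[0] >= 2 else len(v) - 1
        res = stats.linregress(t[: stop + 1], v[: stop + 1])
        rate = float(res.slope)
        used = (float(t[0]), float(t[stop]))
    else:
        if len(t) < slide_frames:
            raise ValueError("trace shorter than the sliding window")
        best, used = 0.0, (float(t[0]), float(t[slide_frames - 1]))
        for i in range(len(t) - slide_frames + 1):
            res = stats.linregress(t[i : i + slide_frames], v[i : i + slide_frames])
            if abs(res.slope) > abs(best):
                best = float(res.slope)
                used = (float(t[i]), float(t[i + slide_frames - 1]))
        rate = best
    return {"rate": float(rate), "mode": mode, "window": used}


def detect_plateau(
    times, y, tolerance: float = 0.05, min_span: float = 5.0, smooth_window: int = 5
):
    """Earliest time after which the smoothed trace stays near its final value.

    ``tolerance`` is a fraction of the smoothed trace's dynamic range; the
    trace must remain within the band for at least ``min_span`` time units.
    Returns the onset time, or ``None`` when no plateau exists.
    """
    times = np.asarray(times, dtype=float)
    sm = moving_average(np.asarray(y, dtype=float), smooth_window)
    rng = np.ptp(sm)
    if rng == 0:
        return float(times[0])
    final = sm[-1]
    within = np.abs(sm - final) <= tolerance * rng
    # earliest index from which all later points stay within the band
    ok_from = np.flip(np.logical_and.accumulate(np.flip(within)))
    candidates = np.nonzero(ok_from)[0]
    if len(candidates) == 0:
        return None
    onset = candidates[0]
    if times[-1] - times[onset] < min_span:
        return None
    return float(times[onset])
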