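"""Piecewise-exponential kinetic schedules for fork stalling and restart.

A nucleus is modelled as holding a total pool of a replisome protein of which
a time-varying fraction is bound at replication foci.  Nucleotide depletion
(hydroxyurea, HU) either removes the protein from foci (PCNA-like *decay*
channels, half-time ~2 min) or drives its accumulation on the single-stranded
DNA exposed by helicase-polymerase uncoupling (RPA-like *accumulation*
channels, half-time ~24 min).  Washing the drug out reverses both with their
own half-times.  Each phase is a single exponential parameterized by a
half-time, the minimal model consistent with reported half-times and plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelKinetics", "KineticSchedule", "evaluate_schedule", "hu_schedule"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class ChannelKinetics:
    """Bound-fraction trajectory parameters for one fluorescent channel.

    Parameters
    ----------
    kind:
        ``"decay"`` for proteins removed from foci on treatment (PCNA-like)
        or ``"accumulation"`` for proteins recruited (RPA-like).
    f0:
        Baseline bound fraction before treatment (0-1).
    f_res:
        Residual bound fraction approached during stalling (decay channels).
    f_max:
        Plateau bound fraction approached during stalling (accumulation
        channels).
    t_half_stall, t_half_restart:
        Half-times (minutes) of the stalling and restart transitions.
    f_post:
        Post-restart residual fraction approached after washout
        (accumulation channels).
    f_restart:
        Level a decay channel recovers toward after washout; defaults to
        ``f0`` (full re-accumulation).
    """

    kind: str
    f0: float
    t_half_stall: float
    t_half_restart: float
    f_res: float = 0.0
    f_max: float = 0.0
    f_post: float = 0.0
    f_restart: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("decay", "accumulation"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        for name in ("f0", "f_res", "f_max", "f_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_res > self.f0:
            raise ValueError("f_res must not exceed f0")
        if self.f_post > max(self.f_max, self.f0):
            raise ValueError("f_post must not exceed the stalling plateau")
        if self.t_half_stall <= 0 or self.t_half_restart <= 0:
            raise ValueError("half-times must be positive")


@dataclass(frozen=True)
class KineticSchedule:
    """Treatment timeline plus per-channel kinetics.

    Times are minutes.  ``t_start <= t_hu < t_w <= t_end``; setting
    ``t_w == t_end`` yields a movie without a washout/restart phase.
    """

    t_start: float
    t_hu: float
    t_w: float
    t_end: float
    channels: dict[str, ChannelKinetics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.t_start <= self.t_hu < self.t_w <= self.t_end):
            raise ValueError(
                "phase boundaries must satisfy t_start <= t_hu < t_w <= t_end; "
                f"got {self.t_start}, {self.t_hu}, {self.t_w}, {self.t_end}"
            )

    @property
    def span_min(self) -> float:
        return self.t_end - self.t_start


def _halflife_decay(dt: np.ndarray, t_half: float) -> np.ndarray:
    return np.exp2(-dt / t_half)


def evaluate_schedule(schedule: KineticSchedule, t, channel: str):
    """Closed-form bound fraction of ``channel`` at time(s) ``t`` (minutes).

    Baseline holds ``f0``; from ``t_hu`` a decay channel relaxes toward
    ``f_res`` and an accumulation channel rises toward ``f_max``, both with
    ``t_half_stall``; from ``t_w`` the trajectory relaxes from its washout
    value toward ``f_restart``/``f_post`` with ``t_half_restart``.  Continuous
    at every phase boundary by construction.
    """
    ck = schedule.channels[channel]
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < schedule.t_start) or np.any(t_arr > schedule.t_end):
        raise ValueError(
            f"time outside movie span [{schedule.t_start}, {schedule.t_end}] min"
        )

    def stall_value(tt: np.ndarray) -> np.ndarray:
        decayed = _halflife_decay(tt - schedule.t_hu, ck.t_half_stall)
        if ck.kind == "decay":
            return ck.f_res + (ck.f0 - ck.f_res) * decayed
        return ck.f_max + (ck.f0 - ck.f_max) * decayed

    f = np.full_like(t_arr, ck.f0, dtype=float)
    stalling = t_arr >= schedule.t_hu
    f[stalling] = stall_value(t_arr[stalling])

    if schedule.t_w < schedule.t_end:
        restart = t_arr >= schedule.t_w
        if np.any(restart):
            f_w = float(stall_value(np.asarray([schedule.t_w]))[0])
            target = (
                ck.f0 if ck.f_restart is None else ck.f_restart
            ) if ck.kind == "decay" else ck.f_post
            decayed = _halflife_decay(t_arr[restart] - schedule.t_w, ck.t_half_restart)
            f[restart] = target + (f_w - target) * decayed
    return f if np.ndim(t) else float(f)


def hu_schedule(
    *,
    baseline_min: float = 15.0,
    hu_min: float = 60.0,
    washout_min: float = 45.0,
    atri: bool = False,
) -> KineticSchedule:
    """Default HU stalling/restart schedule at the study's conditions.

    The decay (PCNA-like) channel starts with 27% of the pool bound and
    dissolves with t1/2 = 2.1 min; after washout it re-accumulates with
    t1/2 = 5.1 min.  The accumulation (RPA-like) channel rises with
    t1/2 = 23.9 min toward a 42% plateau — chosen so the bound fraction
    reaches ~35% at the end of a 1 h treatment, consistent with the ~40%
    plateau seen under prolonged depletion — and is removed within minutes
    of washout.  ``atri=True`` switches the accumulation channel to the
    ATR-inhibited regime (t1/2 = 5.6 min, 70% plateau, 16% of the plateau
    persisting after restart).

    Set ``washout_min=0`` for a stalling-only movie.
    """
    if atri:
        accumulation = ChannelKinetics(
            kind="accumulation", f0=0.0, f_max=0.70,
            t_half_stall=5.6, t_half_restart=2.5, f_post=0.16 * 0.70,
        )
    else:
        accumulation = ChannelKinetics(
            kind="accumulation", f0=0.0, f_max=0.42,
            t_half_stall=23.9, t_half_restart=2.5, f_post=0.0,
        )
    decay = ChannelKinetics(
        kind="decay", f0=0.27, f_res=0.0, t_half_stall=2.1, t_half_restart=5.1
    )
    t_hu = baseline_min
    t_w = baseline_min + hu_min
    return KineticSchedule(
        t_start=0.0,
        t_hu=t_hu,
        t_w=t_w,
        t_end=t_w + washout_min if washout_min > 0 else t_w,
        channels={"pcna": decay, "rpa1": accumulation},
    )
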