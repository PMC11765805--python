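"""Synthetic nucleus movies with fully known ground truth.

Renders a 2-D nucleus (an ellipse, standing for the maximum-intensity
projection the analysis consumes) holding a fixed total fluorophore budget
per channel.  At each frame the schedule's bound fraction is split across
Gaussian replication foci while the remainder is spread uniformly over the
nucleus as the freely diffusing pool, conserving total protein.  A camera
background offset, Poisson-like photon noise and Gaussian read noise are
applied on top.  FRAP movies hold the schedule at steady state, bleach one
focus at a known frame and let it recover along a known
fast-diffusing + slow-bound + immobile curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movie import Movie
from .schedule import KineticSchedule, evaluate_schedule

__all__ = [
    "SceneGeometry",
    "OpticsNoise",
    "FrapTruth",
    "GroundTruth",
    "random_geometry",
    "render_movie",
    "render_frap_movie",
]


@dataclass(frozen=True)
class SceneGeometry:
    """Static scene layout: image size, nucleus ellipse, focus positions.

    Coordinates are 0-based pixel indices, x right / y down; focus centers
    are (y, x) pairs.  ``drift`` is a (dy, dx) whole-scene translation per
    frame in pixels.
    """

    shape: tuple[int, int] = (128, 128)
    nucleus_center: tuple[float, float] = (64.0, 64.0)
    nucleus_axes: tuple[float, float] = (40.0, 48.0)  # (semi_y, semi_x)
    focus_centers: tuple[tuple[float, float], ...] = ()
    focus_sigma: float = 1.5
    focus_sigmas: tuple[float, ...] | None = None  # per-focus override
    focus_weights: tuple[float, ...] | None = None  # default: equal split
    drift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.focus_sigma <= 0:
            raise ValueError("focus_sigma must be positive")
        cy, cx = self.nucleus_center
        ay, ax = self.nucleus_axes
        for (y, x) in self.focus_centers:
            if ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 >= 1.0:
                raise ValueError(f"focus at ({y}, {x}) outside the nucleus ellipse")
        if self.focus_weights is not None:
            w = np.asarray(self.focus_weights)
            if len(w) != self.n_foci or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("focus_weights must be non-negative, one per focus")

    @property
    def n_foci(self) -> int:
        return len(self.focus_centers)

    def weights(self) -> np.ndarray:
        if self.n_foci == 0:
            return np.zeros(0)
        if self.focus_weights is None:
            return np.full(self.n_foci, 1.0 / self.n_foci)
        w = np.asarray(self.focus_weights, dtype=float)
        return w / w.sum()

    def sigmas(self) -> np.ndarray:
        if self.focus_sigmas is not None:
            return np.asarray(self.focus_sigmas, dtype=float)
        return np.full(self.n_foci, self.focus_sigma)

    def nucleus_mask(self, shift: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        cy, cx = self.nucleus_center
        ay, ax = self.nucleus_axes
        return ((yy - cy - shift[0]) / ay) ** 2 + ((xx - cx - shift[1]) / ax) ** 2 <= 1.0


@dataclass(frozen=True)
class OpticsNoise:
    """Fluorophore budget and camera model (arbitrary intensity units).

    Defaults give a focus peak signal-to-noise ratio of roughly 10 under the
    default geometry and schedule.  Setting ``photon_scale`` and
    ``read_sigma`` to zero yields a noise-free movie.
    """

    budget: float = 1.5e5
    background: float = 10.0
    photon_scale: float = 1.0
    read_sigma: float = 3.0
    bleach_rate: float = 0.0  # fraction of signal lost per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if min(self.background, self.photon_scale, self.read_sigma, self.bleach_rate) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class FrapTruth:
    """Hidden parameters of a FRAP movie.

    Recovery of the bleached focus follows
    ``A_f (1 - exp(-k_f t)) + A_s (1 - exp(-k_s t))`` with immobile
    remainder ``1 - A_f - A_s``; rates are per second.  ``bleach_depth`` is
    the multiplicative factor applied to the focus at the bleach frame.
    """

    a_fast: float
    k_fast: float
    a_slow: float
    k_slow: float
    bound_fraction: float = 0.30
    bleach_depth: float = 0.2

    def __post_init__(self) -> None:
        if self.a_fast < 0 or self.a_slow < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.a_fast + self.a_slow > 1.0 + 1e-12:
            raise ValueError("A_f + A_s must not exceed 1")
        if not 0 <= self.bleach_depth < 1:
            raise ValueError("bleach_depth must be in [0, 1)")

    @property
    def immobile(self) -> float:
        return 1.0 - self.a_fast - self.a_slow

    def recovery(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a_fast * (1 - np.exp(-self.k_fast * t)) + self.a_slow * (
            1 - np.exp(-self.k_slow * t)
        )


@dataclass
class GroundTruth:
    """Everything the simulator knows and the analysis must recover."""

    seed: int
    times: np.ndarray
    fractions: dict[str, np.ndarray]  # channel -> (T,)
    focus_amounts: dict[str, np.ndarray]  # channel -> (T, n_foci), a.u.
    schedule: KineticSchedule | None = None
    frap: FrapTruth | None = None
    bleach_frame: int | None = None
    true_recovery: np.ndarray | None = None  # normalized, post-bleach frames
    extras: dict = field(default_factory=dict)


def random_geometry(
    seed: int,
    *,
    shape: tuple[int, int] = (128, 128),
    n_foci: int = 20,
    focus_sigma: float = 1.5,
    edge_margin_sigma: float = 4.0,
    min_separation: float = 7.0,
    sigma_jitter: float = 0.0,
    drift: tuple[float, float] = (0.0, 0.0),
) -> SceneGeometry:
    """Sample a nucleus with ``n_foci`` well-separated foci.

    Foci are kept at least ``edge_margin_sigma`` PSF widths inside the
    nucleus edge (so their rendered flux is fully contained) and
    ``min_separation`` pixels apart.
    """
    rng = np.random.default_rng(seed)
    cy, cx = shape[0] / 2, shape[1] / 2
    ay, ax = 0.31 * shape[0], 0.375 * shape[1]
    margin = edge_margin_sigma * focus_sigma
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_foci:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place foci; relax separation/margin")
        y = rng.uniform(cy - ay, cy + ay)
        x = rng.uniform(cx - ax, cx + ax)
        # shrink the ellipse by the margin along both axes
        if ((y - cy) / (ay - margin)) ** 2 + ((x - cx) / (ax - margin)) ** 2 > 1.0:
            continue
        if any((y - fy) ** 2 + (x - fx) ** 2 < min_separation**2 for fy, fx in centers):
            continue
        centers.append((float(y), float(x)))
    sigmas = None
    if sigma_jitter > 0:
        sigmas = tuple(
            float(s)
            for s in np.clip(
                rng.normal(focus_sigma, sigma_jitter, size=n_foci), 0.5, None
            )
        )
    return SceneGeometry(
        shape=shape,
        nucleus_center=(cy, cx),
        nucleus_axes=(ay, ax),
        focus_centers=tuple(centers),
        focus_sigma=focus_sigma,
        focus_sigmas=sigmas,
        drift=drift,
    )


def _focus_stamps(
    geometry: SceneGeometry, shift: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Unit-sum Gaussian images, one per focus (n_foci, Y, X)."""
    ny, nx = geometry.shape
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    sigmas = geometry.sigmas()
    stamps = np.empty((geometry.n_foci, ny, nx))
    for i, (fy, fx) in enumerate(geometry.focus_centers):
        s2 = 2.0 * sigmas[i] ** 2
        gy = np.exp(-((y - fy - shift[0]) ** 2) / s2)
        gx = np.exp(-((x - fx - shift[1]) ** 2) / s2)
        stamp = gy * gx
        stamps[i] = stamp / stamp.sum()
    return stamps


def _apply_noise(clean: np.ndarray, optics: OpticsNoise, rng: np.random.Generator) -> np.ndarray:
    img = clean
    if optics.photon_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) / optics.photon_scale) * optics.photon_scale
        img = img.astype(float)
    if optics.read_sigma > 0:
        img = img + rng.normal(0.0, optics.read_sigma, size=img.shape)
    return img


def render_movie(
    schedule: KineticSchedule,
    geometry: SceneGeometry,
    optics: OpticsNoise,
    *,
    frame_interval_min: float = 0.5,
) -> tuple[Movie, GroundTruth]:
    """Render a stalling/restart time-lapse; deterministic given the seed."""
    n_frames = int(round(schedule.span_min / frame_interval_min)) + 1
    times = schedule.t_start + np.arange(n_frames) * frame_interval_min
    rng = np.random.default_rng(optics.seed)
    weights = geometry.weights()
    static = geometry.drift == (0.0, 0.0)
    if static:
        mask = geometry.nucleus_mask()
        area = mask.sum()
        stamps = _focus_stamps(geometry)

    channels: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {}
    focus_amounts: dict[str, np.ndarray] = {}
    bleach = (1.0 - optics.bleach_rate) ** np.arange(n_frames)
    for name in schedule.channels:
        f_t = evaluate_schedule(schedule, times, name)
        total_t = optics.budget * bleach
        bound_t = f_t * total_t
        diffuse_t = total_t - bound_t
        if np.any(diffuse_t < -1e-9 * optics.budget):
            bad = int(np.argmin(diffuse_t))
            raise ValueError(
                f"budget insufficient: diffuse pool negative at frame {bad}"
            )
        amounts = bound_t[:, None] * weights[None, :] if geometry.n_foci else np.zeros(
            (n_frames, 0)
        )
        stack = np.empty((n_frames, *geometry.shape))
        if static:
            base = np.full(geometry.shape, optics.background)
            for ti in range(n_frames):
                frame = base + (diffuse_t[ti] / area) * mask
                if geometry.n_foci:
                    frame = frame + np.tensordot(amounts[ti], stamps, axes=1)
                stack[ti] = frame
        else:
            for ti in range(n_frames):
                shift = (geometry.drift[0] * ti, geometry.drift[1] * ti)
                m = geometry.nucleus_mask(shift)
                frame = np.full(geometry.shape, optics.background) + (
                    diffuse_t[ti] / m.sum()
                ) * m
                if geometry.n_foci:
                    frame = frame + np.tensordot(
                        amounts[ti], _focus_stamps(geometry, shift), axes=1
                    )
                stack[ti] = frame
        channels[name] = _apply_noise(stack, optics, rng)
        fractions[name] = f_t
        focus_amounts[name] = amounts

    movie = Movie(
        channels=channels,
        frame_interval=frame_interval_min,
        time_unit="min",
        t_hu=schedule.t_hu - schedule.t_start,
        t_w=(schedule.t_w - schedule.t_start) if schedule.t_w < schedule.t_end else None,
        meta={
            "seed": optics.seed,
            "budget": optics.budget,
            "n_foci": geometry.n_foci,
            "focus_centers": [list(c) for c in geometry.focus_centers],
        },
    )
    truth = GroundTruth(
        seed=optics.seed,
        times=times,
        fractions=fractions,
        focus_amounts=focus_amounts,
        schedule=schedule,
    )
    return movie, truth


def render_frap_movie(
    frap: FrapTruth,
    geometry: SceneGeometry,
    optics: OpticsNoise,
    *,
    channel: str = "pcna",
    frame_interval_s: float = 1.0,
    n_pre: int = 6,
    post_s: float = 300.0,
    bleached_focus: int = 0,
    reference_focus: int = 1,
) -> tuple[Movie, GroundTruth]:
    """Render a FRAP movie: steady state, bleach one focus, known recovery.

    The bleached focus intensity follows
    ``pre-bleach level x (depth + (1 - depth) * R(t))`` with ``R`` the
    two-component recovery of :class:`FrapTruth`; the freely diffusing pool
    is treated as refilling within one frame, so it stays at its steady
    level.  The reference focus is untouched apart from noise.
    """
    if n_pre < 6:
        raise ValueError("need at least 6 pre-bleach frames for normalization")
    if geometry.n_foci < 2:
        raise ValueError("need a bleached and an unbleached reference focus")
    n_post = int(round(post_s / frame_interval_s)) + 1
    n_frames = n_pre + n_post
    bleach_frame = n_pre  # first acquired post-bleach frame, shows the depth
    t_rel = (np.arange(n_frames) - bleach_frame) * frame_interval_s

    rng = np.random.default_rng(optics.seed)
    mask = geometry.nucleus_mask()
    area = mask.sum()
    stamps = _focus_stamps(geometry)
    weights = geometry.weights()

    bound = frap.bound_fraction * optics.budget
    diffuse = optics.budget - bound
    amounts = np.tile(bound * weights, (n_frames, 1))
    recovery = frap.recovery(np.clip(t_rel, 0.0, None))
    factor = np.where(
        t_rel >= 0, frap.bleach_depth + (1 - frap.bleach_depth) * recovery, 1.0
    )
    amounts[:, bleached_focus] *= factor

    base = np.full(geometry.shape, optics.background) + (diffuse / area) * mask
    stack = np.empty((n_frames, *geometry.shape))
    for ti in range(n_frames):
        stack[ti] = base + np.tensordot(amounts[ti], stamps, axes=1)
    data = _apply_noise(stack, optics, rng)

    movie = Movie(
        channels={channel: data},
        frame_interval=frame_interval_s,
        time_unit="s",
        meta={
            "seed": optics.seed,
            "bleach_frame": bleach_frame,
            "bleached_focus": bleached_focus,
            "reference_focus": reference_focus,
            "focus_centers": [list(c) for c in geometry.focus_centers],
        },
    )
    fractions = np.full(n_frames, frap.bound_fraction)
    truth = GroundTruth(
        seed=optics.seed,
        times=t_rel,
        fractions={channel: fractions},
        focus_amounts={channel: amounts},
        frap=frap,
        bleach_frame=bleach_frame,
        true_recovery=recovery[bleach_frame:],
    )
    return movie, truth
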