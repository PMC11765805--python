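"""End-to-end orchestration: simulate, register, measure, fit, convert.

These are the steps the analysis scripts, the CLI and the acceptance
checks share: batch simulation at the study's conditions, the
registration -> ROI -> formulas (1)-(6) -> half-time chain for a single
cell, and population summaries across cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import KineticFit, fit_decay, fit_rise
from .movie import Movie
from .roi import (
    BoundTrace,
    ROISet,
    background_region,
    bound_trace,
    find_foci_free_regions,
    measure_raw,
    register_translation,
    segment_nuclei,
)
from .schedule import KineticSchedule, hu_schedule
from .simulate import GroundTruth, OpticsNoise, random_geometry, render_movie
from .stoichiometry import HELA, StoichiometryConstants, complexes_per_fork, ssdna_per_fork

__all__ = [
    "simulate_stalling_batch",
    "default_reference_window",
    "quantify_movie",
    "fit_traces",
    "tidy_trace_frame",
    "summarize_batch",
]

# analysis defaults, minutes
DECAY_REFERENCE_OFFSET = (15.0, 25.0)  # after t_HU, well past dissolution
DECAY_FIT_SPAN = 15.0
BASELINE_AVG_SKIP = 1.0  # skip the very first frame(s) of the movie
END_HU_AVG_SPAN = 5.0


def simulate_stalling_batch(
    n_cells: int,
    seed: int,
    *,
    schedule: KineticSchedule | None = None,
    atri: bool = False,
    washout_min: float = 0.0,
    frame_interval_min: float = 0.5,
    noise: dict | None = None,
    n_foci: int = 20,
) -> list[tuple[Movie, GroundTruth]]:
    """Render ``n_cells`` two-channel stalling movies with distinct seeds.

    Per-cell seeds are derived from ``seed`` through numpy's seed-spawning
    so cells are independent yet the whole batch is reproducible.
    """
    if schedule is None:
        schedule = hu_schedule(atri=atri, washout_min=washout_min)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_cells) % (2**31)
    out = []
    for i in range(n_cells):
        geometry = random_geometry(int(child_seeds[2 * i]), n_foci=n_foci)
        optics = OpticsNoise(seed=int(child_seeds[2 * i + 1]), **(noise or {}))
        out.append(
            render_movie(schedule, geometry, optics, frame_interval_min=frame_interval_min)
        )
    return out


def default_reference_window(kind: str, movie: Movie) -> tuple[float, float]:
    """Reference window for T_ref: post-dissolution for decay channels,
    the whole pre-treatment baseline for accumulation channels."""
    if movie.t_hu is None:
        raise ValueError("movie has no treatment time; pass a window explicitly")
    if kind == "decay":
        return (movie.t_hu + DECAY_REFERENCE_OFFSET[0], movie.t_hu + DECAY_REFERENCE_OFFSET[1])
    if kind == "accumulation":
        return (0.0, movie.t_hu - movie.frame_interval)
    raise ValueError(f"unknown channel kind {kind!r}")


def quantify_movie(
    movie: Movie,
    channel_kinds: dict[str, str],
    *,
    rois: ROISet | None = None,
    register: bool = True,
    reference_windows: dict[str, tuple[float, float]] | None = None,
    cell_id: str = "",
) -> dict:
    """Single-cell pipeline: registration -> ROIs -> formulas (1)-(4).

    When ``rois`` is omitted the nucleus is segmented from the temporal
    mean image, foci-free regions are placed automatically away from
    ever-bright pixels, and a background rectangle is taken outside the
    nucleus.  Returns a dict with the (possibly registered) movie, the
    ROIs, per-frame shifts and a ``BoundTrace`` per channel.
    """
    unknown = set(channel_kinds) - set(movie.channels)
    if unknown:
        raise ValueError(f"channels not in movie: {sorted(unknown)}")

    shifts = None
    if register:
        ref_name = next(iter(channel_kinds))
        _, shifts = register_translation(movie.channels[ref_name])
        from scipy import ndimage as ndi

        registered = {}
        for name, stack in movie.channels.items():
            reg = np.empty_like(stack, dtype=float)
            for t in range(stack.shape[0]):
                reg[t] = (
                    stack[t]
                    if not shifts[t].any()
                    else ndi.shift(stack[t].astype(float), -shifts[t], order=1, mode="nearest")
                )
            registered[name] = reg
        movie = Movie(
            channels=registered,
            frame_interval=movie.frame_interval,
            time_unit=movie.time_unit,
            t_hu=movie.t_hu,
            t_w=movie.t_w,
            pixel_size_um=movie.pixel_size_um,
            meta=dict(movie.meta),
        )

    if rois is None:
        combined = sum(
            stack / stack.mean() for name, stack in movie.channels.items()
        )
        labels = segment_nuclei(combined.mean(axis=0))
        if labels.max() == 0:
            raise ValueError("no nucleus found in the movie")
        nucleus = labels == np.argmax(np.bincount(labels[labels > 0]))
        foci_free = find_foci_free_regions(combined, nucleus)
        rois = ROISet(
            nucleus=nucleus,
            foci_free=foci_free,
            background=background_region(labels),
        )

    raw = measure_raw(movie, rois)
    traces: dict[str, BoundTrace] = {}
    for name, kind in channel_kinds.items():
        window = (
            reference_windows[name]
            if reference_windows and name in reference_windows
            else default_reference_window(kind, movie)
        )
        traces[name] = bound_trace(raw[name], window, channel=name, cell_id=cell_id)
    return {"movie": movie, "rois": rois, "shifts": shifts, "raw": raw, "traces": traces}


def fit_traces(
    traces: dict[str, BoundTrace],
    channel_kinds: dict[str, str],
    movie: Movie,
) -> dict[str, KineticFit]:
    """Per-channel half-time fit on the stalling phase.

    Decay channels are fitted from drug addition over the dissolution span;
    accumulation channels over the whole treatment phase.
    """
    t_hu = movie.t_hu
    t_end = movie.t_w if movie.t_w is not None else movie.times[-1]
    fits = {}
    for name, kind in channel_kinds.items():
        tr = traces[name]
        if kind == "decay":
            fits[name] = fit_decay(tr.times, tr.fraction, (t_hu, t_hu + DECAY_FIT_SPAN))
        else:
            fits[name] = fit_rise(tr.times, tr.fraction, (t_hu, t_end))
    return fits


def tidy_trace_frame(
    traces: dict[str, BoundTrace],
    constants: StoichiometryConstants = HELA,
    species_by_channel: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format table: one row per (cell, channel, frame), with the
    formula (1)-(6) columns (G_t/H_t where a species mapping is given)."""
    rows = []
    for name, tr in traces.items():
        df = pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "channel": name,
                "frame": np.arange(len(tr.times)),
                "time_min": tr.times,
                "D_t": tr.diffuse,
                "E_t": tr.bound,
                "nE_t": tr.bound_norm,
                "F_t": tr.fraction,
            }
        )
        species = (species_by_channel or {}).get(name)
        if species:
            g = complexes_per_fork(np.clip(tr.fraction, -0.05, 1.0), constants, species)
            df["G_t"] = g
            if species.startswith("rpa"):
                df["H_t"] = ssdna_per_fork(g, constants)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def summarize_batch(
    movies: list[tuple[Movie, GroundTruth]],
    channel_kinds: dict[str, str],
    *,
    register: bool = True,
) -> pd.DataFrame:
    """Quantify and fit every cell of a batch; one row per (cell, channel).

    Columns include the fitted half-time, the baseline-average and
    end-of-treatment-average bound fractions, and the matching ground-truth
    values for recovery checks.
    """
    records = []
    for i, (movie, truth) in enumerate(movies):
        res = quantify_movie(movie, channel_kinds, register=register, cell_id=f"cell{i:02d}")
        fits = fit_traces(res["traces"], channel_kinds, movie)
        times = movie.times
        base_sel = (times >= BASELINE_AVG_SKIP) & (times < movie.t_hu)
        t_end = movie.t_w if movie.t_w is not None else times[-1]
        end_sel = (times >= t_end - END_HU_AVG_SPAN) & (times <= t_end)
        for name, kind in channel_kinds.items():
            tr = res["traces"][name]
            fit = fits[name]
            true_f = truth.fractions[name]
            ck = truth.schedule.channels[name] if truth.schedule else None
            records.append(
                {
                    "cell_id": f"cell{i:02d}",
                    "channel": name,
                    "kind": kind,
                    "t_half_min": fit.t_half,
                    "r_squared": fit.r_squared,
                    "baseline_fraction": float(tr.fraction[base_sel].mean()),
                    "end_hu_fraction": float(tr.fraction[end_sel].mean()),
                    "true_t_half_min": ck.t_half_stall if ck else np.nan,
                    "true_baseline_fraction": float(true_f[base_sel].mean()),
                    "true_end_hu_fraction": float(true_f[end_sel].mean()),
                }
            )
    return pd.DataFrame.from_records(records)
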