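"""Multi-channel time-lapse container with TIFF + JSON sidecar I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Movie", "save_movie", "load_movie"]


@dataclass
class Movie:
    """A multi-channel time-lapse with spatial/temporal calibration.

    ``channels`` maps channel name to a float array of shape (T, Y, X).
    ``frame_interval`` is in ``time_unit`` ("min" for stalling movies,
    "s" for FRAP movies).  ``t_hu``/``t_w`` mark drug addition and washout
    in the same unit, measured from the first frame.
    """

    channels: dict[str, np.ndarray]
    frame_interval: float
    time_unit: str = "min"
    t_hu: float | None = None
    t_w: float | None = None
    pixel_size_um: float = 0.11
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(v.ndim != 3 for v in self.channels.values()):
            raise ValueError("each channel must be a (T, Y, X) stack")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ``time_unit``, first frame at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame_index(self, t: float) -> int:
        """Index of the frame closest to time ``t``."""
        return int(round(t / self.frame_interval))


def save_movie(movie: Movie, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Write one multi-page TIFF per channel plus a JSON calibration sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, stack in movie.channels.items():
        p = outdir / f"{stem}_{name}.tif"
        tifffile.imwrite(p, stack.astype(np.float32))
        paths[name] = p
    sidecar = {
        "channels": sorted(movie.channels),
        "frame_interval": movie.frame_interval,
        "time_unit": movie.time_unit,
        "t_hu": movie.t_hu,
        "t_w": movie.t_w,
        "pixel_size_um": movie.pixel_size_um,
        "n_frames": movie.n_frames,
        "meta": movie.meta,
    }
    sp = outdir / f"{stem}.json"
    sp.write_text(json.dumps(sidecar, indent=2, default=_jsonify))
    paths["sidecar"] = sp
    return paths


def load_movie(outdir: str | Path, stem: str) -> Movie:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{stem}.json").read_text())
    channels = {
        name: tifffile.imread(outdir / f"{stem}_{name}.tif").astype(float)
        for name in sidecar["channels"]
    }
    return Movie(
        channels=channels,
        frame_interval=sidecar["frame_interval"],
        time_unit=sidecar["time_unit"],
        t_hu=sidecar["t_hu"],
        t_w=sidecar["t_w"],
        pixel_size_um=sidecar["pixel_size_um"],
        meta=sidecar.get("meta", {}),
    )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
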