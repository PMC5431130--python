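"""Movie, trace and table containers plus TIFF/CSV/JSON round-trip I/O.

Movies are 16-bit multi-page TIFF hyperstacks with a JSON sidecar carrying
channel order, frame interval and stimulation frame. Traces and per-cell
metric tables are plain CSV. Time is reported in minutes post-stimulation
with frame 0 at t = 0 (imaging starts immediately after stimulation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_CHANNELS = ("EGFP", "mCherry", "bright-field")


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


@dataclass
class Movie:
    """A multi-channel time-lapse stack.

    ``pixels`` has shape (frames, channels, height, width), arbitrary
    intensity units. ``frame_interval`` is minutes between frames;
    ``stimulation_frame`` indexes the frame at which the stimulus was
    applied (default 0: imaging begins immediately after stimulation).
    """

    pixels: np.ndarray
    frame_interval: float = 3.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    stimulation_frame: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (frames, channels, height, width)")
        if self.pixels.shape[0] < 1:
            raise ValueError("movie needs at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names must match channel axis length")
        if not set(self.channel_names) & set(DEFAULT_CHANNELS):
            raise ValueError(
                "channels must include at least one of EGFP/mCherry/bright-field"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Minutes post-stimulation for each frame."""
        idx = np.arange(self.n_frames) - self.stimulation_frame
        return idx * self.frame_interval

    def channel(self, name: str) -> np.ndarray:
        """(frames, height, width) stack for one named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.pixels[:, i]


@dataclass
class RatioTrace:
    """One cell's ratio time series (Nuc/Cyt EGFP or Cell/BG mCherry)."""

    cell_id: int
    kind: str  # "nfkb_nuc_cyt" | "mcherry_cell_bg"
    times: np.ndarray
    values: np.ndarray
    smoothed: bool = False
    window_frames: int = 1
    genotype: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class TraceTable:
    """Long-format table of per-cell traces.

    Columns: cell_id, genotype, time_minutes, nuc_cyt_ratio,
    mcherry_cell_bg_ratio (either ratio column may hold NaN where the
    corresponding channel was not measured).
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "cell_id",
                "genotype",
                "time_minutes",
                "nuc_cyt_ratio",
                "mcherry_cell_bg_ratio",
            ]
        )
    )

    COLUMNS = (
        "cell_id",
        "genotype",
        "time_minutes",
        "nuc_cyt_ratio",
        "mcherry_cell_bg_ratio",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"trace table missing columns: {sorted(missing)}")

    @classmethod
    def from_traces(
        cls,
        nfkb: dict[int, RatioTrace],
        mcherry: dict[int, RatioTrace] | None = None,
        genotypes: dict[int, str] | None = None,
    ) -> "TraceTable":
        mcherry = mcherry or {}
        genotypes = genotypes or {}
        rows = []
        for cid, tr in sorted(nfkb.items()):
            mc = mcherry.get(cid)
            mc_vals = mc.values if mc is not None else np.full_like(tr.values, np.nan)
            gt = genotypes.get(cid, tr.genotype)
            for t, v, m in zip(tr.times, tr.values, mc_vals):
                rows.append((cid, gt, t, v, m))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path: str | Path) -> list[Path]:
    """Write a movie as one 16-bit multi-page TIFF plus a JSON sidecar.

    Values outside [0, 65535] are clipped with a warning. Returns the list
    of files written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = np.asarray(movie.pixels)
    if px.dtype != np.uint16:
        if px.min() < 0 or px.max() > 65535:
            warnings.warn(
                "intensities outside [0, 65535] clipped to 16-bit range",
                stacklevel=2,
            )
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, px, photometric="minisblack", metadata={"axes": "TCYX"})
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "channel_names": list(movie.channel_names),
                "frame_interval_min": movie.frame_interval,
                "stimulation_frame": movie.stimulation_frame,
            },
            indent=2,
        )
    )
    return [path, sidecar]


def read_movie(path: str | Path, metadata: dict | None = None) -> Movie:
    """Read a movie written by :func:`write_movie`.

    ``metadata`` overrides (or replaces, if the sidecar is absent) the
    sidecar fields ``channel_names``, ``frame_interval_min`` and
    ``stimulation_frame``.
    """
    path = Path(path)
    try:
        px = tifffile.imread(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if metadata:
        meta.update(metadata)
    if "channel_names" not in meta:
        raise FormatError(f"no channel mapping for {path}: sidecar or metadata required")
    if px.ndim == 3:  # single-channel stack
        px = px[:, None]
    if px.ndim != 4:
        raise FormatError(f"unexpected TIFF shape {px.shape}")
    return Movie(
        pixels=px,
        frame_interval=float(meta.get("frame_interval_min", 3.0)),
        channel_names=tuple(meta["channel_names"]),
        stimulation_frame=int(meta.get("stimulation_frame", 0)),
    )


def write_traces(table: TraceTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> TraceTable:
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise FormatError(f"cannot parse trace CSV {path}: {exc}") from exc
    return TraceTable(df)
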