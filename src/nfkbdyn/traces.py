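"""Per-cell ratio time series: Nuc/Cyt EGFP and Cell/BG mCherry.

The Nuc/Cyt ratio is the mean EGFP over the nuclear circle divided by the
mean EGFP over the cytosolic area (cell body minus circle), per frame; the
translocation curve is that ratio averaged over ten frames. The mCherry
readout is the mean over the cell body divided by the mean over the
cell-free background (all pixels outside every segmented cell dilated by
a safety margin).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter

from .io import Movie, RatioTrace
from .segmentation import CellTrack


class ExtractionError(RuntimeError):
    """Raised when a trace cannot be measured (empty cytosol/background)."""


def _circle_mask_in_bbox(
    center: tuple[float, float], radius: float, bbox: tuple[int, int, int, int]
) -> np.ndarray:
    r0, c0, r1, c1 = bbox
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _track_bbox(track: CellTrack, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    r0 = min(b[0] for b in track.bboxes.values())
    c0 = min(b[1] for b in track.bboxes.values())
    r1 = max(b[2] for b in track.bboxes.values())
    c1 = max(b[3] for b in track.bboxes.values())
    pad = 2
    return (max(r0 - pad, 0), max(c0 - pad, 0),
            min(r1 + pad, shape[0]), min(c1 + pad, shape[1]))


def extract_nfkb_raw(movie: Movie, track: CellTrack, masks: np.ndarray) -> RatioTrace:
    """Per-frame Nuc/Cyt EGFP ratio for one tracked cell.

    The nuclear circle follows the cell by the displacement of its
    centroid from the placement frame (stationary cells: fixed circle).
    """
    if track.nucleus is None:
        raise ExtractionError(f"cell {track.cell_id}: nucleus circle not set")
    masks = np.asarray(masks)
    frames = track.frames
    bbox = _track_bbox(track, masks.shape[1:])
    r0, c0, r1, c1 = bbox
    egfp = movie.channel("EGFP")[:, r0:r1, c0:c1].astype(np.float64)
    sub = masks[:, r0:r1, c0:c1]
    radius = track.nucleus.diameter / 2.0
    base_cent = np.asarray(track.centroids[frames[0]])
    values = np.empty(len(frames))
    for i, f in enumerate(frames):
        region = sub[f] == track.labels[f]
        shift = np.asarray(track.centroids[f]) - base_cent
        center = (track.nucleus.center[0] + shift[0], track.nucleus.center[1] + shift[1])
        circ = _circle_mask_in_bbox(center, radius, bbox)
        nuc = region & circ
        cyt = region & ~circ
        if not cyt.any() or not nuc.any():
            raise ExtractionError(
                f"cell {track.cell_id} frame {f}: empty "
                f"{'cytosolic' if not cyt.any() else 'nuclear'} area"
            )
        values[i] = egfp[f][nuc].mean() / egfp[f][cyt].mean()
    times = (np.asarray(frames) - movie.stimulation_frame) * movie.frame_interval
    return RatioTrace(cell_id=track.cell_id, kind="nfkb_nuc_cyt",
                      times=times, values=values)


def background_means(
    movie: Movie, masks: np.ndarray, margin: int = 5, channel: str = "mCherry"
) -> np.ndarray:
    """Per-frame mean intensity over the cell-free background.

    The background is every pixel outside the union of segmented cell
    regions dilated by ``margin`` px (dilation avoids halo contamination
    near cell edges). Raises if any frame has no background left.
    """
    ch = movie.channel(channel)
    size = 2 * margin + 1
    out = np.empty(movie.n_frames)
    for f in range(movie.n_frames):
        occupied = maximum_filter((masks[f] > 0).astype(np.uint8), size=size) > 0
        bg = ~occupied
        if not bg.any():
            raise ExtractionError(f"frame {f}: no cell-free background area")
        out[f] = ch[f][bg].mean()
    return out


def extract_mcherry(
    movie: Movie,
    track: CellTrack,
    masks: np.ndarray,
    bg_means: np.ndarray | None = None,
    margin: int = 5,
) -> RatioTrace:
    """Per-frame Cell/BG mCherry ratio for one tracked cell."""
    masks = np.asarray(masks)
    if bg_means is None:
        bg_means = background_means(movie, masks, margin=margin)
    frames = track.frames
    bbox = _track_bbox(track, masks.shape[1:])
    r0, c0, r1, c1 = bbox
    mch = movie.channel("mCherry")[:, r0:r1, c0:c1].astype(np.float64)
    sub = masks[:, r0:r1, c0:c1]
    values = np.empty(len(frames))
    for i, f in enumerate(frames):
        region = sub[f] == track.labels[f]
        if bg_means[f] <= 0:
            raise ExtractionError(f"frame {f}: non-positive background")
        values[i] = mch[f][region].mean() / bg_means[f]
    times = (np.asarray(frames) - movie.stimulation_frame) * movie.frame_interval
    return RatioTrace(cell_id=track.cell_id, kind="mcherry_cell_bg",
                      times=times, values=values)


def smooth_trace(
    raw: RatioTrace, window_frames: int = 10, mode: str = "sliding"
) -> RatioTrace:
    """Average the per-frame ratio over ``window_frames`` frames.

    ``sliding`` (default) is a centered moving average, truncated to the
    available frames at the edges, so output length equals input length.
    ``block`` averages consecutive non-overlapping blocks and assigns the
    block mean to every frame of the block. ``window_frames == 1`` is the
    identity.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if mode not in ("sliding", "block"):
        raise ValueError(f"unknown smoothing mode {mode!r}")
    v = raw.values
    n = v.size
    if window_frames == 1:
        out = v.copy()
    elif mode == "sliding":
        left = window_frames // 2
        right = window_frames - left - 1
        csum = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.clip(np.arange(n) - left, 0, n)
        hi = np.clip(np.arange(n) + right + 1, 0, n)
        out = (csum[hi] - csum[lo]) / (hi - lo)
    else:
        out = np.empty(n)
        for start in range(0, n, window_frames):
            blk = v[start: start + window_frames]
            out[start: start + window_frames] = blk.mean()
    return RatioTrace(
        cell_id=raw.cell_id,
        kind=raw.kind,
        times=raw.times,
        values=out,
        smoothed=True,
        window_frames=window_frames,
        genotype=raw.genotype,
    )


def extract_all(
    movie: Movie,
    tracks: list[CellTrack],
    masks: np.ndarray,
    margin: int = 5,
) -> tuple[dict[int, RatioTrace], dict[int, RatioTrace]]:
    """Raw Nuc/Cyt and Cell/BG traces for every included track."""
    bg = background_means(movie, masks, margin=margin)
    nfkb: dict[int, RatioTrace] = {}
    mcherry: dict[int, RatioTrace] = {}
    for t in tracks:
        if not t.included or t.nucleus is None:
            continue
        nfkb[t.cell_id] = extract_nfkb_raw(movie, t, masks)
        mcherry[t.cell_id] = extract_mcherry(movie, t, masks, bg_means=bg)
    return nfkb, mcherry
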