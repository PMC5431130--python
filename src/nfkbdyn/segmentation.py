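"""Cell-body segmentation, tracking, nucleus placement and exclusions.

Cell bodies are segmented from the EGFP channel (cells carry cytoplasmic
EGFP-p65 even at rest) combined with the dark boundary ring visible in
bright-field. The nuclear region is a circle of configured diameter placed
automatically at the EGFP-darkest position over the first baseline frames
(p65 is cytoplasmic before stimulation, so the nucleus is the dark spot);
a manual circles table can override placement. Cells are linked across
frames by nearest centroid, and any cell that touches another cell,
divides, clips the image border or disappears is excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    binary_fill_holes,
    convolve,
    gaussian_filter,
)
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

EXCLUSION_REASONS = ("none", "touching", "dividing", "border", "lost")


@dataclass(frozen=True)
class SegConfig:
    """Knobs for segmentation and tracking."""

    min_area: int = 80  # px; smaller components are discarded
    smooth_sigma: float = 1.0
    closing_radius: int = 2
    erosion_radius: int = 1  # px; trims the pre-threshold smoothing halo
    mad_sigmas: float = 6.0  # robust threshold above background
    max_displacement: float = 10.0  # px/frame tracking gate
    gap_frames: int = 2  # frames a region may vanish before the track is lost


@dataclass
class NucleusCircle:
    center: tuple[float, float]  # (row, col)
    diameter: float


@dataclass
class CellTrack:
    """One cell's region references over time plus its nuclear circle."""

    cell_id: int
    labels: dict[int, int] = field(default_factory=dict)  # frame -> region label
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    areas: dict[int, int] = field(default_factory=dict)
    nucleus: NucleusCircle | None = None
    included: bool = True
    exclusion_reason: str = "none"
    lost: bool = False  # set by the tracker when the region vanishes

    @property
    def frames(self) -> list[int]:
        return sorted(self.labels)

    @property
    def first_frame(self) -> int:
        return min(self.labels)

    @property
    def last_frame(self) -> int:
        return max(self.labels)

    def exclude(self, reason: str) -> None:
        if reason not in EXCLUSION_REASONS or reason == "none":
            raise ValueError(f"bad exclusion reason {reason!r}")
        if self.exclusion_reason == "none":
            self.exclusion_reason = reason
            self.included = False


def _robust_sigma(img: np.ndarray) -> float:
    med = float(np.median(img))
    return 1.4826 * float(np.median(np.abs(img - med)))


def _guarded_otsu(img: np.ndarray, mad_sigmas: float) -> float | None:
    """Otsu threshold, or None when it is not separated from background.

    The background (the image majority) is summarized by its median and a
    MAD-based sigma; an Otsu threshold closer than ``mad_sigmas`` robust
    sigmas to the median means there is no foreground class (blank or
    noise-only frame).
    """
    med = float(np.median(img))
    if np.ptp(img) == 0:
        return None
    thr = float(threshold_otsu(img))
    if abs(thr - med) <= mad_sigmas * max(_robust_sigma(img), 1e-6):
        return None
    # Ridler-Calvard refinement: midpoint of the class means; keeps the
    # threshold mid-edge instead of hugging the (majority) background mode
    for _ in range(8):
        lo, hi = img[img <= thr], img[img > thr]
        if lo.size == 0 or hi.size == 0:
            break
        new = 0.5 * (float(lo.mean()) + float(hi.mean()))
        if abs(new - thr) < 0.5:
            thr = new
            break
        thr = new
    return thr


def segment_frame(
    bright_field: np.ndarray, egfp: np.ndarray, config: SegConfig | None = None
) -> np.ndarray:
    """Label cell bodies in one frame from bright-field + EGFP.

    EGFP pixels above a guarded Otsu threshold mark fluorescent cell
    bodies; the bright-field contributes the dark boundary ring (below a
    guarded Otsu threshold), filled to a solid disk. The union is closed,
    hole-filled, small-object-filtered and 8-connected-component
    labelled. Constant, empty or noise-only frames yield an all-zero
    mask.
    """
    if bright_field.shape != egfp.shape:
        raise ValueError("bright-field and EGFP frames must share a shape")
    config = config or SegConfig()
    egfp_s = gaussian_filter(np.asarray(egfp, dtype=np.float32), config.smooth_sigma)
    bf_s = gaussian_filter(np.asarray(bright_field, dtype=np.float32), config.smooth_sigma)

    thr_e = _guarded_otsu(egfp_s, config.mad_sigmas)
    fg = egfp_s > thr_e if thr_e is not None and thr_e > np.median(egfp_s) else None

    thr_b = _guarded_otsu(bf_s, config.mad_sigmas)
    ring = bf_s < thr_b if thr_b is not None and thr_b < np.median(bf_s) else None

    if fg is None and ring is None:
        return np.zeros(egfp.shape, dtype=np.int32)
    mask = np.zeros(egfp.shape, dtype=bool)
    if fg is not None:
        mask |= fg
    if ring is not None:
        # the dark ring sits ON the cell boundary; only its interior is
        # cell body, so do not let the ring itself widen the mask
        mask |= binary_fill_holes(ring) & ~ring
    if config.closing_radius > 0:
        # closing as explicit dilation + erosion; the erosion treats
        # out-of-frame pixels as foreground so border-clipped cells keep
        # their edge contact (the border exclusion rule depends on it)
        s = disk(config.closing_radius)
        mask = binary_erosion(binary_dilation(mask, structure=s),
                              structure=s, border_value=1)
    mask = binary_fill_holes(mask)
    if config.erosion_radius > 0:
        # border_value=1 keeps cells clipped by the image edge from being
        # eaten back from the border (they must still register as border
        # contact for the exclusion rule)
        mask = binary_erosion(mask, structure=disk(config.erosion_radius),
                              border_value=1)
    lbl = cc_label(mask, connectivity=2).astype(np.int32)
    counts = np.bincount(lbl.ravel())
    small = np.flatnonzero(counts < config.min_area)
    if small.size:
        lbl[np.isin(lbl, small[small > 0])] = 0
        lbl = cc_label(lbl > 0, connectivity=2).astype(np.int32)
    return lbl


def segment_movie(movie, config: SegConfig | None = None) -> np.ndarray:
    """Per-frame label masks for a whole movie, shape (frames, h, w)."""
    bf = movie.channel("bright-field")
    eg = movie.channel("EGFP")
    return np.stack(
        [segment_frame(bf[f], eg[f], config) for f in range(movie.n_frames)]
    )


def track_cells(masks: np.ndarray, config: SegConfig | None = None) -> list[CellTrack]:
    """Link per-frame regions into tracks by nearest centroid.

    Regions are matched to open tracks with a Hungarian assignment gated
    at ``max_displacement`` px/frame; unmatched regions start new tracks;
    a track unmatched for more than ``gap_frames`` consecutive frames is
    closed and flagged lost.
    """
    config = config or SegConfig()
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    tracks: list[CellTrack] = []
    open_tracks: list[CellTrack] = []
    next_id = 1
    for f in range(masks.shape[0]):
        props = regionprops(masks[f])
        cents = np.array([p.centroid for p in props]).reshape(-1, 2)
        labels = [p.label for p in props]
        assigned = set()
        if open_tracks and len(props):
            prev = np.array([t.centroids[t.last_frame] for t in open_tracks])
            dist = np.linalg.norm(prev[:, None, :] - cents[None, :, :], axis=2)
            gate = config.max_displacement * np.array(
                [f - t.last_frame for t in open_tracks]
            )
            cost = dist.copy()
            cost[dist > gate[:, None]] = 1e9
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= 1e9:
                    continue
                t = open_tracks[r]
                t.labels[f] = labels[c]
                t.centroids[f] = tuple(cents[c])
                t.bboxes[f] = tuple(props[c].bbox)
                t.areas[f] = int(props[c].area)
                assigned.add(c)
        for c in range(len(props)):
            if c in assigned:
                continue
            t = CellTrack(cell_id=next_id)
            next_id += 1
            t.labels[f] = labels[c]
            t.centroids[f] = tuple(cents[c])
            t.bboxes[f] = tuple(props[c].bbox)
            t.areas[f] = int(props[c].area)
            tracks.append(t)
            open_tracks.append(t)
        still_open = []
        for t in open_tracks:
            if f - t.last_frame > config.gap_frames:
                t.lost = True
            else:
                still_open.append(t)
        open_tracks = still_open
    n_frames = masks.shape[0]
    for t in tracks:
        if t.last_frame < n_frames - 1 and (n_frames - 1 - t.last_frame) > config.gap_frames:
            t.lost = True
    return tracks


def locate_nucleus(
    movie,
    track: CellTrack,
    masks: np.ndarray,
    diameter: float,
    baseline_frames: int = 3,
    edge_margin: int = 2,
    mode: str = "dark-quantile",
) -> NucleusCircle | None:
    """Place the nuclear circle at the EGFP-darkest in-cell position.

    The default scoring image is the per-pixel 10th-percentile projection
    of EGFP over the whole track (``dark-quantile``): p65 leaves the
    nucleus between translocation pulses, so the nucleus is the region
    that gets dark at some point even in cells whose first translocation
    begins within minutes of imaging start. ``baseline-mean`` instead
    averages the first ``baseline_frames`` frames (only reliable when
    translocation starts late). The circle center minimizes the mean of
    the scoring image inside the circle, constrained so the whole circle
    stays ``edge_margin`` px inside the cell region (the margin keeps the
    dark rim outside the segmented boundary from out-competing the true
    nucleus). Returns None (and excludes the track as lost) when no
    placement fits even with the margin dropped.
    """
    if mode not in ("dark-quantile", "baseline-mean"):
        raise ValueError(f"unknown nucleus placement mode {mode!r}")
    radius = diameter / 2.0
    egfp = movie.channel("EGFP")
    f0 = track.first_frame
    pad = int(np.ceil(radius)) + edge_margin + 1
    h, w = masks.shape[-2:]
    r0 = max(min(b[0] for b in track.bboxes.values()) - pad, 0)
    c0 = max(min(b[1] for b in track.bboxes.values()) - pad, 0)
    r1 = min(max(b[2] for b in track.bboxes.values()) + pad, h)
    c1 = min(max(b[3] for b in track.bboxes.values()) + pad, w)
    region = (masks[f0] == track.labels[f0])[r0:r1, c0:c1]

    def footprint(r: float) -> np.ndarray:
        k = int(np.floor(r))
        yy, xx = np.mgrid[-k: k + 1, -k: k + 1]
        return (yy**2 + xx**2) <= r**2

    foot = footprint(radius)
    valid = binary_erosion(region, structure=footprint(radius + edge_margin))
    if not valid.any():
        valid = binary_erosion(region, structure=foot)
    if not valid.any():
        track.exclude("lost")
        return None
    stack = egfp[track.frames, r0:r1, c0:c1].astype(np.float64)
    if mode == "dark-quantile":
        score_img = np.percentile(stack, 10, axis=0)
    else:
        score_img = stack[: max(baseline_frames, 1)].mean(axis=0)
    score = convolve(score_img, foot.astype(float) / foot.sum(), mode="nearest")
    score = np.where(valid, score, np.inf)
    idx = int(np.argmin(score))
    center = (r0 + idx // region.shape[1], c0 + idx % region.shape[1])
    circ = NucleusCircle(center=(float(center[0]), float(center[1])), diameter=diameter)
    track.nucleus = circ
    return circ


def apply_manual_circles(tracks: list[CellTrack], circles: pd.DataFrame) -> None:
    """Override nucleus placement from a table (cell_id, x, y, diameter)."""
    for _, row in circles.iterrows():
        for t in tracks:
            if t.cell_id == int(row["cell_id"]):
                t.nucleus = NucleusCircle(
                    center=(float(row["y"]), float(row["x"])),
                    diameter=float(row["diameter"]),
                )


def _adjacent_label_pairs(lbl: np.ndarray) -> set[tuple[int, int]]:
    """All pairs of distinct labels that are 8-adjacent in one frame."""
    pairs: set[tuple[int, int]] = set()
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dy, dx in shifts:
        a = lbl[max(dy, 0): lbl.shape[0] + min(dy, 0),
                max(dx, 0): lbl.shape[1] + min(dx, 0)]
        b = lbl[max(-dy, 0): lbl.shape[0] + min(-dy, 0),
                max(-dx, 0): lbl.shape[1] + min(-dx, 0)]
        both = (a > 0) & (b > 0) & (a != b)
        if both.any():
            for x, y in zip(a[both].ravel(), b[both].ravel()):
                pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    return pairs


def apply_exclusions(
    tracks: list[CellTrack],
    masks: np.ndarray,
    image_shape: tuple[int, int] | None = None,
    min_split_overlap: int = 25,
) -> list[CellTrack]:
    """Flag touching, dividing, border-clipping and lost tracks.

    Touching: two tracks' regions are 8-adjacent in any frame, or two
    tracks merge into a single region (one track's region vanishes while
    its last position lies inside another track's region). Dividing: a
    track's region overlaps two or more distinct regions in the next
    frame. Border: the region touches the image edge in any frame. Flags
    are permanent for the movie; both members of a touching pair are
    excluded, as are a divider's daughters.
    """
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    n_frames, h, w = masks.shape
    image_shape = image_shape or (h, w)

    by_frame_label: dict[tuple[int, int], CellTrack] = {}
    for t in tracks:
        for f, lab in t.labels.items():
            by_frame_label[(f, lab)] = t

    # --- dividing: one region maps onto >= 2 regions in the next frame
    dividers: list[tuple[CellTrack, int]] = []
    for t in tracks:
        for f in t.frames:
            if f + 1 >= n_frames:
                continue
            region = masks[f] == t.labels[f]
            nxt = masks[f + 1][region]
            counts = np.bincount(nxt[nxt > 0])
            big = np.flatnonzero(counts >= min_split_overlap)
            if len(big) >= 2:
                dividers.append((t, f + 1))
    for t, f in dividers:
        t.exclude("dividing")
        region = masks[f - 1] == t.labels[f - 1]
        nxt = masks[f][region]
        counts = np.bincount(nxt[nxt > 0])
        for lab in np.flatnonzero(counts >= min_split_overlap):
            child = by_frame_label.get((f, int(lab)))
            if child is not None:
                child.exclude("dividing")

    # --- touching via 8-adjacency of distinct labels
    for f in range(n_frames):
        for a, b in _adjacent_label_pairs(masks[f]):
            ta, tb = by_frame_label.get((f, a)), by_frame_label.get((f, b))
            if ta is not None and tb is not None and ta is not tb:
                ta.exclude("touching")
                tb.exclude("touching")

    # --- touching via merge: a vanished track's last position lies in
    #     another track's region on the following frame
    for t in tracks:
        lf = t.last_frame
        if lf + 1 >= n_frames:
            continue
        cy, cx = (int(round(v)) for v in t.centroids[lf])
        cy = min(max(cy, 0), h - 1)
        cx = min(max(cx, 0), w - 1)
        lab = int(masks[lf + 1][cy, cx])
        if lab > 0:
            other = by_frame_label.get((lf + 1, lab))
            if other is not None and other is not t:
                t.exclude("touching")
                other.exclude("touching")

    # --- border contact
    for t in tracks:
        for f in t.frames:
            r0, c0, r1, c1 = t.bboxes[f]
            if r0 == 0 or c0 == 0 or r1 >= image_shape[0] or c1 >= image_shape[1]:
                t.exclude("border")
                break

    # --- lost (tracker gave up, or nucleus placement failed earlier)
    for t in tracks:
        if t.lost:
            t.exclude("lost")
    return tracks


def exclusion_report(tracks: list[CellTrack]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": t.cell_id,
                "included": t.included,
                "reason": t.exclusion_reason,
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
            }
            for t in tracks
        ]
    )
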