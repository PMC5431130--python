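"""Noise-thresholded peak calling and the per-cell oscillation metric panel.

The noise level is the 95th percentile of absolute deviations from the
per-cell median, pooled over unstimulated cells' raw traces. On a smoothed
translocation curve, peaks are local maxima exceeding the cell's median
baseline plus that threshold; maxima closer than a minimum separation are
merged keeping the higher (ties toward the earlier frame). Each peak gets
an initiation time — the last upward crossing of the threshold level
before the maximum, linearly interpolated between frames — and a nuclear
duration equal to peak time minus initiation time. Per-cell metrics
collect peak count, inter-peak intervals, damping rates between successive
peak heights, and the mCherry fold increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RatioTrace


@dataclass(frozen=True)
class NoiseModel:
    """Detection threshold above per-cell baseline, from unstimulated cells."""

    threshold: float
    baseline_estimator: str = "per-cell median"
    n_source: int = 0
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class Peak:
    """One called translocation event."""

    index: int  # 1 = first peak
    initiation_time: float  # minutes
    peak_time: float  # minutes
    height: float  # curve value at the maximum
    duration: float  # peak_time - initiation_time

    def __post_init__(self) -> None:
        if self.initiation_time > self.peak_time:
            raise ValueError("initiation_time must be <= peak_time")


@dataclass
class CellMetrics:
    """Full per-cell metric panel, tagged with genotype."""

    cell_id: int
    genotype: str
    peaks: list[Peak] = field(default_factory=list)
    intervals: list[float] = field(default_factory=list)  # successive peak_time gaps
    damping_rates: list[float] = field(default_factory=list)  # 1st->2nd, 2nd->3rd, ...
    mcherry_fold_increase: float = float("nan")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def estimate_noise_level(
    unstimulated_curves: list[RatioTrace], percentile: float = 95.0
) -> NoiseModel:
    """Noise threshold from fluctuations of unstimulated cells.

    Per-cell baseline is the median of the curve; the threshold is the
    given percentile of |value - baseline| pooled over all curves.
    Perfectly constant curves give threshold 0.
    """
    if not unstimulated_curves:
        raise ValueError("need at least one unstimulated curve")
    devs = []
    for tr in unstimulated_curves:
        devs.append(np.abs(tr.values - np.median(tr.values)))
    pooled = np.concatenate(devs)
    return NoiseModel(
        threshold=float(np.percentile(pooled, percentile)),
        n_source=len(unstimulated_curves),
        percentile=percentile,
    )


def _local_maxima(values: np.ndarray) -> list[int]:
    """Leftmost indices of local-maximum plateaus (endpoints count)."""
    n = values.size
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_lower = i == 0 or values[i - 1] < values[i]
        right_lower = j == n - 1 or values[j + 1] < values[i]
        if left_lower and right_lower:
            maxima.append(i)
        i = j + 1
    return maxima


def _merge_maxima(
    idx: list[int], values: np.ndarray, min_separation: int
) -> list[int]:
    """Greedy left-to-right merge keeping the higher (ties -> earlier)."""
    kept: list[int] = []
    for i in idx:
        if kept and i - kept[-1] < min_separation:
            if values[i] > values[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return kept


def detect_peaks(
    curve: RatioTrace, noise: NoiseModel, min_separation_frames: int = 5
) -> list[Peak]:
    """Call translocation peaks on a smoothed curve.

    Local maxima above baseline + threshold (baseline = per-cell median of
    the curve) are called; maxima closer than ``min_separation_frames``
    are merged keeping the higher value, ties resolved toward the earlier
    frame. A flat curve yields no peaks.
    """
    v = curve.values
    t = curve.times
    if v.size == 0:
        return []
    level = float(np.median(v)) + noise.threshold
    cand = [i for i in _local_maxima(v) if v[i] > level]
    kept = _merge_maxima(cand, v, min_separation_frames)
    peaks = []
    for rank, i in enumerate(kept, start=1):
        init_t = t[0]
        for j in range(i - 1, -1, -1):
            if v[j] < level <= v[j + 1]:
                frac = (level - v[j]) / (v[j + 1] - v[j])
                init_t = t[j] + frac * (t[j + 1] - t[j])
                break
        peaks.append(
            Peak(
                index=rank,
                initiation_time=float(init_t),
                peak_time=float(t[i]),
                height=float(v[i]),
                duration=float(t[i] - init_t),
            )
        )
    return peaks


def compute_damping(peaks: list[Peak], mode: str = "relative") -> list[float]:
    """Damping rate between successive peaks.

    ``relative`` (default): (h_k - h_{k+1}) / h_k; ``absolute``:
    h_k - h_{k+1}. Defined only where both peaks exist (fewer than two
    peaks gives an empty list); negative when a later peak is higher.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown damping mode {mode!r}")
    rates = []
    for a, b in zip(peaks, peaks[1:]):
        if a.height <= 0:
            raise ValueError("peak heights must be positive for damping")
        drop = a.height - b.height
        rates.append(drop / a.height if mode == "relative" else drop)
    return rates


def compute_fold_increase(mcherry: RatioTrace, baseline_frames: int = 10) -> float:
    """Peak Cell/BG ratio relative to the pre-response baseline mean."""
    if mcherry.values.size <= baseline_frames:
        raise ValueError("trace must be longer than baseline_frames")
    base = float(np.mean(mcherry.values[:baseline_frames]))
    if base <= 0:
        raise ExtractionBaselineError("baseline mean must be > 0")
    return float(np.max(mcherry.values) / base)


class ExtractionBaselineError(RuntimeError):
    pass


def summarize_cell(
    nfkb_curve: RatioTrace,
    mcherry_curve: RatioTrace | None,
    noise: NoiseModel,
    genotype: str = "",
    min_separation_frames: int = 5,
    damping_mode: str = "relative",
    baseline_frames: int = 10,
) -> CellMetrics:
    """Full metric panel for one cell from its two smoothed curves."""
    if mcherry_curve is not None and mcherry_curve.cell_id != nfkb_curve.cell_id:
        raise ValueError("curves belong to different cells")
    peaks = detect_peaks(nfkb_curve, noise, min_separation_frames)
    intervals = [b.peak_time - a.peak_time for a, b in zip(peaks, peaks[1:])]
    fold = float("nan")
    if mcherry_curve is not None:
        fold = compute_fold_increase(mcherry_curve, baseline_frames)
    return CellMetrics(
        cell_id=nfkb_curve.cell_id,
        genotype=genotype or nfkb_curve.genotype,
        peaks=peaks,
        intervals=intervals,
        damping_rates=compute_damping(peaks, damping_mode),
        mcherry_fold_increase=fold,
    )


def metrics_table(cells: list[CellMetrics]) -> pd.DataFrame:
    """One row per cell: timings, heights, intervals, damping, fold."""
    rows = []
    for m in cells:

        def pk(i: int, attr: str) -> float:
            return getattr(m.peaks[i], attr) if i < len(m.peaks) else np.nan

        rows.append(
            {
                "cell_id": m.cell_id,
                "genotype": m.genotype,
                "n_peaks": m.n_peaks,
                "t_init_1": pk(0, "initiation_time"),
                "t_peak_1": pk(0, "peak_time"),
                "t_peak_2": pk(1, "peak_time"),
                "t_peak_3": pk(2, "peak_time"),
                "h_1": pk(0, "height"),
                "h_2": pk(1, "height"),
                "h_3": pk(2, "height"),
                "duration_1": pk(0, "duration"),
                "interval_12": m.intervals[0] if len(m.intervals) > 0 else np.nan,
                "interval_23": m.intervals[1] if len(m.intervals) > 1 else np.nan,
                "damp_12": m.damping_rates[0] if len(m.damping_rates) > 0 else np.nan,
                "damp_23": m.damping_rates[1] if len(m.damping_rates) > 1 else np.nan,
                "fold": m.mcherry_fold_increase,
            }
        )
    return pd.DataFrame(rows)


def peaks_table(cells: list[CellMetrics]) -> pd.DataFrame:
    """One row per called peak."""
    rows = []
    for m in cells:
        for p in m.peaks:
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "genotype": m.genotype,
                    "peak_index": p.index,
                    "initiation_time": p.initiation_time,
                    "peak_time": p.peak_time,
                    "height": p.height,
                    "duration": p.duration,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "genotype",
            "peak_index",
            "initiation_time",
            "peak_time",
            "height",
            "duration",
        ],
    )
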