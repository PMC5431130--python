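"""Ground-truth dynamics and forward rendering of synthetic movies.

Per-cell NF-κB nuclear translocation is modelled as a damped train of
Gaussian pulses of the Nuc/Cyt ratio riding on a resting baseline; the
TNFα-promoter mCherry reporter as a delayed logistic rise to a peak fold
change followed by slow decay. Cells are rendered as disks with a darker
(EGFP-poor at rest) nuclear circle; the per-cell total EGFP is conserved
over time and redistributed between nucleus and cytoplasm so that the
mean-intensity Nuc/Cyt ratio of the rendered pixels equals the input trace.
The mCherry channel is uniform over the cell body at background x Cell/BG
ratio. Bright-field shows a dark ring at the cell boundary on a gray
background. Optional Poisson shot noise, Gaussian read noise and Gaussian
PSF blur complete the camera model.

The background offset is rendered only outside cell bodies (it models
medium autofluorescence); inside a cell the fluorophore signal replaces it.
This keeps the rendered ratios identical to the ground-truth ratio traces,
which is what makes exact round-trip validation of the extraction stages
possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Movie, RatioTrace
from .params import (
    GENOTYPES,
    Dist,
    GenotypePreset,
    OpticsParams,
    PulseTrainParams,
    ReporterParams,
    default_presets,
)


class LayoutError(ValueError):
    """Raised when a requested cell placement does not fit the frame."""


# ---------------------------------------------------------------------------
# per-cell trace models
# ---------------------------------------------------------------------------

def simulate_nfkb_trace(
    params: PulseTrainParams,
    n_frames: int,
    dt: float,
    seed: int | np.random.Generator = 0,
) -> tuple[RatioTrace, list[tuple[float, float]]]:
    """Sample a damped pulse train of the Nuc/Cyt ratio on a regular grid.

    The trace is ``baseline + sum_k A*damping**(k-1) *
    exp(-(t - tau_k)**2 / (2*sigma**2))`` with the first pulse time drawn
    from N(first_peak_time_mean, sd) and subsequent pulses following at
    N(interval_mean, interval_sd) spacings.

    Returns the trace sampled at t = 0, dt, ..., (n_frames-1)*dt and the
    list of true pulses as (time, height-above-baseline) pairs sorted by
    time.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t = np.arange(n_frames) * float(dt)
    values = np.full(n_frames, params.baseline_ratio, dtype=float)
    pulses: list[tuple[float, float]] = []
    tau = None
    for k in range(params.n_pulses):
        if tau is None:
            tau = rng.normal(params.first_peak_time_mean, params.first_peak_time_sd)
            tau = max(tau, 0.0)
        else:
            step = rng.normal(params.interval_mean, params.interval_sd)
            tau = tau + max(step, params.pulse_width_sd)  # keep times increasing
        height = params.first_peak_amplitude * params.damping_factor**k
        values += height * np.exp(-((t - tau) ** 2) / (2 * params.pulse_width_sd**2))
        pulses.append((float(tau), float(height)))
    trace = RatioTrace(cell_id=-1, kind="nfkb_nuc_cyt", times=t, values=values)
    return trace, pulses


def simulate_mcherry_profile(
    params: ReporterParams, n_frames: int, dt: float
) -> RatioTrace:
    """Deterministic Cell/BG mCherry profile.

    Logistic rise anchored to start at exactly 1 at t = 0 and reach
    ``fold`` exactly at ``peak_time``; exponential relaxation toward 1
    afterwards. ``fold == 1`` gives a flat non-responder trace.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = np.arange(n_frames) * float(dt)
    if params.fold == 1.0:
        return RatioTrace(cell_id=-1, kind="mcherry_cell_bg", times=t,
                          values=np.ones(n_frames))

    def _rise(x: np.ndarray) -> np.ndarray:
        k, m = params.rise_steepness, params.rise_midpoint
        sig = 1.0 / (1.0 + np.exp(-k * (x - m)))
        sig0 = 1.0 / (1.0 + np.exp(k * m))
        return sig - sig0

    peak_gain = _rise(np.array([params.peak_time]))[0]
    values = np.empty(n_frames)
    rising = t <= params.peak_time
    values[rising] = 1.0 + (params.fold - 1.0) * _rise(t[rising]) / peak_gain
    values[~rising] = 1.0 + (params.fold - 1.0) * np.exp(
        -params.decay_rate * (t[~rising] - params.peak_time)
    )
    return RatioTrace(cell_id=-1, kind="mcherry_cell_bg", times=t, values=values)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Everything the generator knows about one rendered cell."""

    cell_id: int
    genotype: str
    centers: np.ndarray  # (n_frames, 2) row/col pixel coordinates
    radius: float
    nucleus_offset: tuple[float, float]  # (drow, dcol) from cell center
    nucleus_radius: float
    baseline_ratio: float
    pulse_times: list[float]
    pulse_heights: list[float]  # above baseline
    fold: float
    seed: int
    pulse_width_sd: float = 8.0  # minutes; lets tests rebuild the exact curve
    reporter_params: dict | None = None  # full ReporterParams, same purpose
    frame_start: int = 0
    frame_end: int | None = None  # exclusive; None = whole movie

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if list(self.pulse_times) != sorted(self.pulse_times):
            raise ValueError("pulse times must be increasing")

    def center_at(self, frame: int) -> tuple[float, float]:
        i = min(frame, len(self.centers) - 1)
        return float(self.centers[i, 0]), float(self.centers[i, 1])

    def nucleus_center_at(self, frame: int) -> tuple[float, float]:
        cy, cx = self.center_at(frame)
        return cy + self.nucleus_offset[0], cx + self.nucleus_offset[1]

    def active(self, frame: int, n_frames: int) -> bool:
        end = n_frames if self.frame_end is None else self.frame_end
        return self.frame_start <= frame < end


@dataclass
class GroundTruth:
    """Cohort-level ground truth: one record per rendered cell."""

    cells: list[CellTruth]
    optics: OpticsParams
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        recs = []
        for c in self.cells:
            static = bool(np.all(c.centers == c.centers[0]))
            recs.append(
                {
                    "cell_id": c.cell_id,
                    "genotype": c.genotype,
                    "center": list(map(float, c.centers[0])) if static else None,
                    "centers": None if static else c.centers.tolist(),
                    "radius": c.radius,
                    "nucleus_offset": list(c.nucleus_offset),
                    "nucleus_radius": c.nucleus_radius,
                    "baseline_ratio": c.baseline_ratio,
                    "pulse_times": c.pulse_times,
                    "pulse_heights": c.pulse_heights,
                    "pulse_width_sd": c.pulse_width_sd,
                    "reporter_params": c.reporter_params,
                    "fold": c.fold,
                    "seed": c.seed,
                    "frame_start": c.frame_start,
                    "frame_end": c.frame_end,
                }
            )
        from dataclasses import asdict

        path.write_text(json.dumps({"optics": asdict(self.optics), "seed": self.seed,
                                    "cells": recs}, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        opt = raw["optics"]
        for key in ("image_size", "cell_radius_range"):
            opt[key] = tuple(opt[key])
        cells = []
        for r in raw["cells"]:
            centers = r["centers"] if r["centers"] is not None else [r["center"]]
            cells.append(
                CellTruth(
                    cell_id=r["cell_id"],
                    genotype=r["genotype"],
                    centers=np.asarray(centers, dtype=float),
                    radius=r["radius"],
                    nucleus_offset=tuple(r["nucleus_offset"]),
                    nucleus_radius=r["nucleus_radius"],
                    baseline_ratio=r["baseline_ratio"],
                    pulse_times=r["pulse_times"],
                    pulse_heights=r["pulse_heights"],
                    fold=r["fold"],
                    seed=r["seed"],
                    pulse_width_sd=r.get("pulse_width_sd", 8.0),
                    reporter_params=r.get("reporter_params"),
                    frame_start=r["frame_start"],
                    frame_end=r["frame_end"],
                )
            )
        return cls(cells=cells, optics=OpticsParams(**opt), seed=raw["seed"])


def reporter_asdict(params: ReporterParams) -> dict:
    from dataclasses import asdict

    return asdict(params)


def true_mcherry_values(cell: CellTruth, n_frames: int, dt: float) -> np.ndarray:
    """Reconstruct the exact ground-truth Cell/BG curve from a CellTruth."""
    if cell.reporter_params is None:
        return np.ones(n_frames)
    profile = simulate_mcherry_profile(
        ReporterParams(**cell.reporter_params), n_frames, dt
    )
    return profile.values


def true_nfkb_values(cell: CellTruth, n_frames: int, dt: float) -> np.ndarray:
    """Reconstruct the exact ground-truth Nuc/Cyt curve from a CellTruth."""
    t = np.arange(n_frames) * dt
    v = np.full(n_frames, cell.baseline_ratio, dtype=float)
    for tau, height in zip(cell.pulse_times, cell.pulse_heights):
        v += height * np.exp(-((t - tau) ** 2) / (2 * cell.pulse_width_sd**2))
    return v


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Boolean disk; membership is center distance <= radius (inclusive)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_movie(
    cells: list[tuple[CellTruth, RatioTrace, RatioTrace | None]],
    optics: OpticsParams,
    seed: int = 0,
    allow_contact: bool = False,
) -> tuple[Movie, GroundTruth]:
    """Render ground-truth cells into a 3-channel movie.

    ``cells`` holds (truth, nfkb_trace, mcherry_trace) triples; a ``None``
    mCherry trace means a flat non-responder. With noise and blur disabled
    the per-cell summed EGFP is constant over time and the pixel-level
    Nuc/Cyt and Cell/BG ratios reproduce the input traces.
    """
    h, w = optics.image_size
    n = optics.n_frames
    rng = np.random.default_rng(seed)

    for truth, _, _ in cells:
        for f in (0, n - 1):
            if not truth.active(f, n):
                continue
            cy, cx = truth.center_at(f)
            r = truth.radius
            if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
                raise LayoutError(
                    f"cell {truth.cell_id} at ({cy:.0f},{cx:.0f}) r={r} leaves "
                    f"the {h}x{w} frame"
                )
    if not allow_contact:
        for i, (a, _, _) in enumerate(cells):
            for b, _, _ in (c for c in cells[i + 1:]):
                d = np.hypot(*(np.asarray(a.center_at(0)) - b.center_at(0)))
                if d < a.radius + b.radius + 2:
                    raise LayoutError(
                        f"cells {a.cell_id} and {b.cell_id} overlap/touch; "
                        "pass allow_contact=True if intended"
                    )

    moving = any(len(t.centers) > 1 for t, _, _ in cells) or any(
        t.frame_start > 0 or t.frame_end is not None for t, _, _ in cells
    )

    def cell_geometry(truth: CellTruth, frame: int):
        cy, cx = truth.center_at(frame)
        cell = disk_mask((h, w), (cy, cx), truth.radius)
        nuc = disk_mask((h, w), truth.nucleus_center_at(frame), truth.nucleus_radius)
        nuc &= cell
        ring = disk_mask((h, w), (cy, cx), truth.radius + 0.5) & ~disk_mask(
            (h, w), (cy, cx), truth.radius - 1.5
        )
        return (
            np.flatnonzero(cell),
            np.flatnonzero(nuc & cell),
            np.flatnonzero(cell & ~nuc),
            np.flatnonzero(ring),
        )

    # static scenes: geometry computed once
    geom = None
    if not moving:
        geom = [cell_geometry(t, 0) for t, _, _ in cells]

    pixels = np.empty((n, 3, h, w), dtype=np.float32)
    bg = optics.background_offset
    for f in range(n):
        egfp = np.full((h, w), bg, dtype=np.float32)
        mch = np.full((h, w), bg, dtype=np.float32)
        bf = np.full((h, w), optics.brightfield_level, dtype=np.float32)
        for i, (truth, nfkb, mcher) in enumerate(cells):
            if not truth.active(f, n):
                continue
            cell_idx, nuc_idx, cyt_idx, ring_idx = (
                geom[i] if geom is not None else cell_geometry(truth, f)
            )
            ratio = float(nfkb.values[min(f, len(nfkb.values) - 1)])
            a_n, a_c = len(nuc_idx), len(cyt_idx)
            i_c = optics.total_egfp_per_cell / (ratio * a_n + a_c)
            egfp.flat[cyt_idx] = i_c
            egfp.flat[nuc_idx] = ratio * i_c
            m = 1.0 if mcher is None else float(mcher.values[min(f, len(mcher.values) - 1)])
            mch.flat[cell_idx] = bg * m
            bf.flat[ring_idx] = optics.brightfield_level - optics.brightfield_ring_depth
        frame_px = np.stack([egfp, mch, bf])
        if optics.psf_sigma > 0:
            for c in range(3):
                gaussian_filter(frame_px[c], optics.psf_sigma, output=frame_px[c])
        if optics.shot_noise:
            frame_px = rng.poisson(np.maximum(frame_px, 0)).astype(np.float32)
        if optics.read_noise_sd > 0:
            frame_px += rng.normal(0, optics.read_noise_sd, frame_px.shape).astype(
                np.float32
            )
        pixels[f] = np.maximum(frame_px, 0)

    movie = Movie(pixels=pixels, frame_interval=optics.frame_interval)
    truth = GroundTruth(cells=[t for t, _, _ in cells], optics=optics, seed=seed)
    return movie, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _grid_sites(optics: OpticsParams) -> np.ndarray:
    """Jitter-free lattice of cell centers that guarantees separation."""
    h, w = optics.image_size
    r_max = optics.cell_radius_range[1]
    margin = r_max + 4
    pitch = 2 * r_max + 6
    ys = np.arange(margin, h - margin + 1e-9, pitch)
    xs = np.arange(margin, w - margin + 1e-9, pitch)
    return np.array([(y, x) for y in ys for x in xs])


def draw_cell_params(
    preset: GenotypePreset, rng: np.random.Generator
) -> tuple[PulseTrainParams, ReporterParams]:
    """Draw one cell's pulse-train and reporter parameters from a preset."""
    translocates = rng.random() < preset.translocating_fraction
    n_pulses = int(round(preset.n_pulses_dist.draw(rng))) if translocates else 0
    amp = preset.amplitude.draw(rng)
    pulse = PulseTrainParams(
        baseline_ratio=preset.baseline_ratio.draw(rng),
        first_peak_amplitude=amp if n_pulses else 0.0,
        damping_factor=max(preset.damping.draw(rng), 0.05),
        n_pulses=n_pulses,
        first_peak_time_mean=preset.first_peak_time.draw(rng),
        first_peak_time_sd=0.0,  # cell-to-cell spread already drawn above
        interval_mean=preset.interval.draw(rng),
        interval_sd=preset.interval_sd_within,
        pulse_width_sd=preset.pulse_width.draw(rng),
    )
    responds = rng.random() < preset.responder_fraction
    fold = preset.fold.draw(rng) if responds else 1.0
    reporter = ReporterParams(
        fold=max(fold, 1.0),
        rise_midpoint=preset.rise_midpoint.draw(rng),
        peak_time=preset.reporter_peak_time.draw(rng),
    )
    return pulse, reporter


def generate_cohort(
    preset: GenotypePreset | str,
    n_cells: int,
    optics: OpticsParams | None = None,
    seed: int = 0,
) -> tuple[Movie, GroundTruth]:
    """Simulate and render one genotype's cohort into a single movie.

    Reproducible for a fixed seed: same seed, same movie, bit for bit.
    The returned GroundTruth carries every drawn per-cell parameter.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(preset, str):
        presets = default_presets()
        if preset not in presets:
            raise ValueError(f"unknown genotype label {preset!r}")
        preset = presets[preset]
    optics = optics or OpticsParams()

    root = np.random.SeedSequence(seed)
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    sites = _grid_sites(optics)
    if n_cells > len(sites):
        raise LayoutError(
            f"{n_cells} cells do not fit: at most {len(sites)} non-touching "
            f"sites in a {optics.image_size} frame"
        )
    order = layout_rng.permutation(len(sites))[:n_cells]

    cell_seeds = root.spawn(n_cells + 1)
    cells: list[tuple[CellTruth, RatioTrace, RatioTrace | None]] = []
    for i, site in enumerate(sites[order]):
        rng = np.random.default_rng(cell_seeds[i])
        radius = rng.uniform(*optics.cell_radius_range)
        center = np.round(site + rng.uniform(-1, 1, 2))
        pulse_params, reporter_params = draw_cell_params(preset, rng)
        nfkb, pulses = simulate_nfkb_trace(
            pulse_params, optics.n_frames, optics.frame_interval, rng
        )
        mcher = simulate_mcherry_profile(
            reporter_params, optics.n_frames, optics.frame_interval
        )
        max_off = radius - optics.nucleus_radius - 4
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(max_off, 0))
        offset = (round(rad * np.sin(ang)), round(rad * np.cos(ang)))
        truth = CellTruth(
            cell_id=i + 1,
            genotype=preset.label,
            centers=center[None, :],
            radius=radius,
            nucleus_offset=offset,
            nucleus_radius=optics.nucleus_radius,
            baseline_ratio=pulse_params.baseline_ratio,
            pulse_times=[t for t, _ in pulses],
            pulse_heights=[a for _, a in pulses],
            fold=reporter_params.fold,
            seed=int(cell_seeds[i].entropy) % (2**31),
            pulse_width_sd=pulse_params.pulse_width_sd,
            reporter_params=reporter_asdict(reporter_params),
        )
        nfkb.cell_id = mcher.cell_id = truth.cell_id
        nfkb.genotype = mcher.genotype = preset.label
        cells.append((truth, nfkb, mcher))

    render_seed = int(cell_seeds[-1].generate_state(1)[0] % (2**31))
    movie, truth = render_movie(cells, optics, seed=render_seed)
    truth.seed = seed
    return movie, truth


# ---------------------------------------------------------------------------
# exclusion-logic fixtures: touching pair and division event
# ---------------------------------------------------------------------------

def touching_pair_movie(
    optics: OpticsParams | None = None, seed: int = 0, contact_frame: int | None = None
) -> tuple[Movie, GroundTruth]:
    """Two cells that drift into contact mid-movie (for exclusion tests)."""
    optics = optics or OpticsParams(image_size=(128, 128), n_frames=30)
    n = optics.n_frames
    contact_frame = contact_frame if contact_frame is not None else n // 2
    r = optics.cell_radius_range[0]
    h, w = optics.image_size
    cy = h // 2
    gap0, gap1 = 12.0, -2.0  # surface gap before/at contact
    x_left = np.empty(n)
    x_left[:contact_frame] = np.linspace(
        w / 2 - r - gap0 / 2, w / 2 - r - gap1 / 2, contact_frame
    )
    x_left[contact_frame:] = w / 2 - r - gap1 / 2
    base = PulseTrainParams(n_pulses=2, first_peak_time_sd=0.0, interval_sd=0.0)
    cells = []
    for i, sign in enumerate((-1, 1)):
        x = w / 2 + sign * (w / 2 - x_left) if sign == 1 else x_left
        centers = np.column_stack([np.full(n, cy, dtype=float), np.round(x)])
        nfkb, pulses = simulate_nfkb_trace(base, n, optics.frame_interval, seed + i)
        truth = CellTruth(
            cell_id=i + 1,
            genotype="WT",
            centers=centers,
            radius=r,
            nucleus_offset=(0.0, 0.0),
            nucleus_radius=optics.nucleus_radius,
            baseline_ratio=base.baseline_ratio,
            pulse_times=[t for t, _ in pulses],
            pulse_heights=[a for _, a in pulses],
            fold=1.0,
            seed=seed + i,
            pulse_width_sd=base.pulse_width_sd,
        )
        cells.append((truth, nfkb, None))
    return render_movie(cells, optics, seed=seed, allow_contact=True)


def dividing_cell_movie(
    optics: OpticsParams | None = None, seed: int = 0, division_frame: int | None = None
) -> tuple[Movie, GroundTruth]:
    """One cell that splits into two separating daughters mid-movie."""
    optics = optics or OpticsParams(image_size=(128, 128), n_frames=30)
    n = optics.n_frames
    div = division_frame if division_frame is not None else n // 2
    h, w = optics.image_size
    cy, cx = h / 2, w / 2
    r_mother = optics.cell_radius_range[1]
    r_daughter = max(optics.cell_radius_range[0] * 0.8, optics.nucleus_radius + 3)
    base = PulseTrainParams(n_pulses=1, first_peak_time_sd=0.0)
    nfkb, pulses = simulate_nfkb_trace(base, n, optics.frame_interval, seed)

    def truth_for(cid, centers, radius, f0, f1):
        return CellTruth(
            cell_id=cid,
            genotype="WT",
            centers=centers,
            radius=radius,
            nucleus_offset=(0.0, 0.0),
            nucleus_radius=min(optics.nucleus_radius, radius - 2),
            baseline_ratio=base.baseline_ratio,
            pulse_times=[t for t, _ in pulses],
            pulse_heights=[a for _, a in pulses],
            fold=1.0,
            seed=seed,
            pulse_width_sd=base.pulse_width_sd,
            frame_start=f0,
            frame_end=f1,
        )

    mother = truth_for(1, np.array([[cy, cx]]), r_mother, 0, div)
    cells = [(mother, nfkb, None)]
    for cid, sign in ((2, -1), (3, 1)):
        dx = np.empty(n)
        dx[:div] = 0
        dx[div:] = sign * np.linspace(r_daughter, r_daughter + 10, n - div)
        centers = np.column_stack([np.full(n, cy), np.round(cx + dx)])
        cells.append((truth_for(cid, centers, r_daughter, div, None), nfkb, None))
    return render_movie(cells, optics, seed=seed, allow_contact=True)
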