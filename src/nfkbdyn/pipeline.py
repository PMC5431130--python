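"""End-to-end orchestration: simulate -> segment -> extract -> score -> compare.

A run is fully described by a RunConfig; for simulated inputs the whole
bundle (trace tables, per-cell metrics, group summaries, genotype
comparisons, exclusion report, manifest) is bit-reproducible for a fixed
seed. Each CSV written carries the manifest hash on a leading comment line
so every output can be traced back to the exact configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import Movie, TraceTable, read_movie, write_movie, write_traces
from .metrics import (
    CellMetrics,
    NoiseModel,
    estimate_noise_level,
    metrics_table,
    peaks_table,
    summarize_cell,
)
from .params import OpticsParams, default_presets
from .segmentation import (
    CellTrack,
    SegConfig,
    apply_exclusions,
    exclusion_report,
    locate_nucleus,
    segment_movie,
    track_cells,
)
from .simulate import generate_cohort
from .stats import comparison_table, summary_table
from .traces import extract_all, smooth_trace


class ConfigError(ValueError):
    """Raised when a run configuration is invalid, before any compute."""


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs.

    Either ``simulate`` maps genotype labels to cell counts (synthetic
    mode) or ``movies`` maps genotype labels to movie TIFF paths (real
    mode; requires ``nucleus_diameter``).
    """

    simulate: dict[str, int] | None = None
    movies: dict[str, str] | None = None
    unstimulated_n: int = 15
    optics: OpticsParams = field(default_factory=OpticsParams)
    nucleus_diameter: float | None = None  # px; defaults to optics for synthetic runs
    nucleus_baseline_frames: int = 3
    smoothing_window: int = 10
    smoothing_mode: str = "sliding"
    noise_percentile: float = 95.0
    min_separation_frames: int = 5
    damping_mode: str = "relative"
    fold_baseline_frames: int = 10
    seg: SegConfig = field(default_factory=SegConfig)
    seed: int = 0
    outdir: str = "run_output"
    write_movies: bool = False

    def validate(self) -> None:
        if (self.simulate is None) == (self.movies is None):
            raise ConfigError("exactly one of 'simulate' or 'movies' must be given")
        if self.movies is not None and self.nucleus_diameter is None:
            raise ConfigError("nucleus_diameter is required for real-movie input")
        if self.smoothing_window < 1:
            raise ConfigError("smoothing_window must be >= 1")
        if self.smoothing_mode not in ("sliding", "block"):
            raise ConfigError(f"unknown smoothing mode {self.smoothing_mode!r}")
        if self.damping_mode not in ("relative", "absolute"):
            raise ConfigError(f"unknown damping mode {self.damping_mode!r}")
        if not 0 < self.noise_percentile <= 100:
            raise ConfigError("noise_percentile must be in (0, 100]")
        if self.simulate is not None:
            presets = default_presets()
            for g in self.simulate:
                if g not in presets:
                    raise ConfigError(f"unknown genotype label {g!r}")

    @property
    def effective_nucleus_diameter(self) -> float:
        if self.nucleus_diameter is not None:
            return self.nucleus_diameter
        return 2.0 * self.optics.nucleus_radius

    def manifest_hash(self) -> str:
        # hash only analysis-relevant fields: where outputs land must not
        # change what they contain
        d = _config_dict(self)
        d.pop("outdir", None)
        d.pop("write_movies", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["optics"]["image_size"] = list(config.optics.image_size)
    d["optics"]["cell_radius_range"] = list(config.optics.cell_radius_range)
    return d


def process_movie(
    movie: Movie, config: RunConfig
) -> tuple[list[CellTrack], np.ndarray, dict, dict]:
    """Segment, track, place nuclei, apply exclusions, extract raw traces."""
    masks = segment_movie(movie, config.seg)
    tracks = track_cells(masks, config.seg)
    full = [t for t in tracks if t.first_frame == 0]
    for t in full:
        locate_nucleus(
            movie, t, masks, config.effective_nucleus_diameter,
            config.nucleus_baseline_frames,
        )
    apply_exclusions(tracks, masks, movie.pixels.shape[2:])
    nfkb_raw, mch_raw = extract_all(movie, [t for t in full if t.included], masks)
    return tracks, masks, nfkb_raw, mch_raw


def _stamp(path: Path, mhash: str) -> None:
    text = path.read_text()
    path.write_text(f"# manifest: {mhash}\n{text}")


def run_experiment(config: RunConfig) -> dict:
    """Run the full pipeline and write the output bundle.

    Returns a dict with the key dataframes and output paths. Rerunning
    with the same config and seed reproduces the simulated bundle
    bit-identically.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mhash = config.manifest_hash()
    root = np.random.SeedSequence(config.seed)

    truths: dict[str, object] = {}
    all_metrics: list[CellMetrics] = []
    excl_frames = []
    noise: NoiseModel | None = None
    unstim_raw: dict[int, object] = {}
    processed: dict[str, tuple] = {}

    # process cohorts one at a time: a full 512x512, 300-frame movie is
    # large, so movies and masks are dropped as soon as traces exist
    if config.simulate is not None:
        labels = list(config.simulate) + ["UNSTIM"]
        counts = list(config.simulate.values()) + [config.unstimulated_n]
        seeds = root.spawn(len(labels))
        sources = [
            (lab, ("sim", n, ss))
            for lab, n, ss in zip(labels, counts, seeds)
            if n >= 1
        ]
    else:
        sources = [(lab, ("file", path)) for lab, path in config.movies.items()]

    for lab, src in sources:
        if src[0] == "sim":
            _, n, ss = src
            movie, truth = generate_cohort(
                lab, n, config.optics, seed=int(ss.generate_state(1)[0] % (2**31))
            )
            truths[lab] = truth
            if config.write_movies:
                write_movie(movie, outdir / f"movie_{lab}.tif")
                truth.to_json(outdir / f"ground_truth_{lab}.json")
        else:
            movie = read_movie(src[1])
        tracks, masks, nfkb_raw, mch_raw = process_movie(movie, config)
        processed[lab] = (tracks, nfkb_raw, mch_raw)
        rep = exclusion_report(tracks)
        rep.insert(0, "genotype", lab)
        excl_frames.append(rep)
        if lab == "UNSTIM":
            unstim_raw = nfkb_raw
        del movie, masks

    if unstim_raw:
        noise = estimate_noise_level(list(unstim_raw.values()), config.noise_percentile)
    elif config.simulate is not None and config.unstimulated_n < 1:
        raise ConfigError("synthetic runs need unstimulated_n >= 1 for the noise level")
    else:
        noise = NoiseModel(threshold=0.0, n_source=0)

    # per-cell metrics plus the long trace table (raw + smoothed NF-kB,
    # raw mCherry)
    rows = []
    for lab, (tracks, nfkb_raw, mch_raw) in processed.items():
        if lab == "UNSTIM":
            continue
        for cid, raw in nfkb_raw.items():
            smooth = smooth_trace(raw, config.smoothing_window, config.smoothing_mode)
            smooth.genotype = lab
            mch = mch_raw.get(cid)
            all_metrics.append(
                summarize_cell(
                    smooth,
                    mch,
                    noise,
                    genotype=lab,
                    min_separation_frames=config.min_separation_frames,
                    damping_mode=config.damping_mode,
                    baseline_frames=config.fold_baseline_frames,
                )
            )
            mvals = mch.values if mch is not None else np.full_like(raw.values, np.nan)
            for t, v, s, mv in zip(raw.times, raw.values, smooth.values, mvals):
                rows.append(
                    {
                        "cell_id": cid,
                        "genotype": lab,
                        "time_minutes": t,
                        "nuc_cyt_ratio": v,
                        "nuc_cyt_ratio_smoothed": s,
                        "mcherry_cell_bg_ratio": mv,
                    }
                )
    traces_df = pd.DataFrame(rows)

    mdf = metrics_table(all_metrics)
    pdf = peaks_table(all_metrics)
    sdf = summary_table(mdf) if len(mdf) else pd.DataFrame()
    cdf = (
        comparison_table(mdf)
        if len(mdf) and mdf["genotype"].nunique() >= 2
        else pd.DataFrame()
    )
    excl_df = pd.concat(excl_frames, ignore_index=True) if excl_frames else pd.DataFrame()

    paths = {}
    for name, df in [
        ("traces", traces_df),
        ("cell_metrics", mdf),
        ("peaks", pdf),
        ("group_summaries", sdf),
        ("comparisons", cdf),
        ("exclusions", excl_df),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        _stamp(p, mhash)
        paths[name] = p

    manifest = {
        "manifest_hash": mhash,
        "config": _config_dict(config),
        "seed": config.seed,
        "noise_threshold": noise.threshold if noise else None,
        "versions": {
            "nfkbdyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath

    return {
        "paths": paths,
        "metrics": mdf,
        "peaks": pdf,
        "summaries": sdf,
        "comparisons": cdf,
        "exclusions": excl_df,
        "traces": traces_df,
        "noise": noise,
        "truths": truths,
        "manifest_hash": mhash,
    }
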