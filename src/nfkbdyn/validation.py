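"""Self-validation benchmarks: parameter recovery on synthetic cohorts.

Since the study's raw imaging data is not deposited, the pipeline is
validated by recovering known ground truth from its own forward model:
render cells with known pulse trains and reporter folds, run the full
segmentation -> tracking -> extraction -> peak-calling chain, and measure
how well the called metrics match the generating parameters. These
functions are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .metrics import compute_fold_increase, detect_peaks, estimate_noise_level
from .params import OpticsParams
from .pipeline import RunConfig, process_movie
from .simulate import (
    disk_mask,
    generate_cohort,
    true_mcherry_values,
    true_nfkb_values,
)
from .traces import smooth_trace


def _match_truth(track, truth):
    cy, cx = track.centroids[track.first_frame]
    return min(
        truth.cells,
        key=lambda c: (c.centers[0][0] - cy) ** 2 + (c.centers[0][1] - cx) ** 2,
    )


def roundtrip_benchmark(seed: int = 0, n_cells: int = 4, n_frames: int = 160) -> dict:
    """Noiseless forward-model round trip.

    Renders a cohort with noise and blur disabled and reports the maximum
    pointwise relative error of the extracted Nuc/Cyt and Cell/BG traces
    against the generating curves, across all cells.
    """
    optics = OpticsParams(
        image_size=(256, 256), n_frames=n_frames,
        shot_noise=False, read_noise_sd=0.0, psf_sigma=0.0,
    )
    movie, truth = generate_cohort("WT", n_cells, optics, seed=seed)
    cfg = RunConfig(simulate={"WT": n_cells}, optics=optics)
    tracks, _, nfkb_raw, mch_raw = process_movie(movie, cfg)
    nfkb_err = 0.0
    mch_err = 0.0
    for t in tracks:
        if not t.included:
            continue
        cell = _match_truth(t, truth)
        expected = true_nfkb_values(cell, optics.n_frames, optics.frame_interval)
        got = nfkb_raw[t.cell_id].values
        nfkb_err = max(nfkb_err, float(np.max(np.abs(got - expected) / expected)))
        mch_expected = true_mcherry_values(cell, optics.n_frames, optics.frame_interval)
        mch_got = mch_raw[t.cell_id].values
        mch_err = max(
            mch_err, float(np.max(np.abs(mch_got - mch_expected) / mch_expected))
        )
    return {
        "n_cells": len(truth.cells),
        "nfkb_max_rel_err": nfkb_err,
        "mcherry_max_rel_err": mch_err,
    }


def recovery_benchmark(
    seed: int = 0,
    cohorts: dict[str, int] | None = None,
    n_frames: int = 200,
    n_unstim: int = 15,
) -> dict:
    """Parameter recovery on default-noise cohorts.

    Runs the full pipeline on rendered cohorts (default 120 WT + 40 MKO +
    40 DKO cells, 200 frames) and reports: fraction of cells whose called
    peak count equals the true pulse count; mean absolute called-vs-true
    peak time difference over matched peaks; mean absolute first->second
    damping-rate error; mean relative mCherry fold error; and the
    segmentation detection fraction and mean IoU at frame 0.
    """
    cohorts = cohorts or {"WT": 120, "MKO": 40, "DKO": 40}
    optics = OpticsParams(n_frames=n_frames)
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(len(cohorts) + 1)

    # noise level from a separate unstimulated cohort (raw traces)
    un_optics = OpticsParams(n_frames=min(n_frames, 100))
    un_movie, _ = generate_cohort(
        "UNSTIM", n_unstim, un_optics,
        seed=int(seeds[-1].generate_state(1)[0] % (2**31)),
    )
    cfg = RunConfig(simulate=cohorts, optics=optics)
    _, _, un_raw, _ = process_movie(un_movie, cfg)
    noise = estimate_noise_level(list(un_raw.values()))
    del un_movie

    n_cells = 0
    n_detected = 0
    ious = []
    n_count_ok = 0
    n_scored = 0
    time_errs = []
    damp_errs = []
    fold_errs = []

    for (lab, n), ss in zip(cohorts.items(), seeds):
        movie, truth = generate_cohort(
            lab, n, optics, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        tracks, masks, nfkb_raw, mch_raw = process_movie(movie, cfg)
        n_cells += len(truth.cells)
        for cell in truth.cells:
            track = min(
                (t for t in tracks if t.first_frame == 0),
                key=lambda t: (t.centroids[0][0] - cell.centers[0][0]) ** 2
                + (t.centroids[0][1] - cell.centers[0][1]) ** 2,
                default=None,
            )
            if track is None:
                continue
            d = disk_mask(optics.image_size, tuple(cell.centers[0]), cell.radius)
            seg = masks[0] == track.labels[0]
            iou = np.sum(seg & d) / np.sum(seg | d)
            if iou < 0.3:
                continue
            n_detected += 1
            ious.append(iou)
            if not track.included or track.cell_id not in nfkb_raw:
                continue
            smooth = smooth_trace(nfkb_raw[track.cell_id])
            peaks = detect_peaks(smooth, noise)
            n_scored += 1
            if len(peaks) == len(cell.pulse_times):
                n_count_ok += 1
            if peaks and cell.pulse_times:
                called = np.array([p.peak_time for p in peaks])
                true = np.array(cell.pulse_times)
                cost = np.abs(called[:, None] - true[None, :])
                rows, cols = linear_sum_assignment(cost)
                time_errs.extend(cost[rows, cols])
            true_abs = [cell.baseline_ratio + h for h in cell.pulse_heights]
            if len(peaks) >= 2 and len(true_abs) >= 2:
                est = (peaks[0].height - peaks[1].height) / peaks[0].height
                ref = (true_abs[0] - true_abs[1]) / true_abs[0]
                damp_errs.append(abs(est - ref))
            fold = compute_fold_increase(mch_raw[track.cell_id])
            fold_errs.append(abs(fold - cell.fold) / cell.fold)
        del movie, masks

    return {
        "n_cells": n_cells,
        "noise_threshold": noise.threshold,
        "detection_fraction": n_detected / n_cells,
        "mean_iou": float(np.mean(ious)) if ious else 0.0,
        "peak_count_accuracy": n_count_ok / n_scored if n_scored else 0.0,
        "peak_time_mae_min": float(np.mean(time_errs)) if time_errs else 0.0,
        "damping_mae": float(np.mean(damp_errs)) if damp_errs else float("nan"),
        "fold_rel_err_mean": float(np.mean(fold_errs)) if fold_errs else float("nan"),
    }


def end_to_end_benchmark(
    seed: int = 0, n_per_group: int = 30, n_frames: int = 300, outdir: str | None = None
) -> dict:
    """Directional reproduction of the genotype phenotypes.

    Runs the whole pipeline on the four presets (n cells per genotype) and
    returns the group medians and the Dunn-adjusted p values for
    first-peak initiation timing, alongside the full result bundle.
    """
    from .pipeline import run_experiment

    cfg = RunConfig(
        simulate={g: n_per_group for g in ("WT", "TKO", "MKO", "DKO")},
        optics=OpticsParams(n_frames=n_frames),
        seed=seed,
        outdir=outdir or "scratch/end_to_end",
    )
    result = run_experiment(cfg)
    mdf = result["metrics"]
    cdf = result["comparisons"]
    init = cdf[cdf.metric == "t_init_1"].set_index(["group_a", "group_b"])

    def adj_p(a, b):
        for key in ((a, b), (b, a)):
            if key in init.index:
                return float(init.loc[key, "p_adjusted"])
        return float("nan")

    med = mdf.groupby("genotype")[["n_peaks", "fold"]].median()
    dko = mdf[mdf.genotype == "DKO"]
    return {
        "result": result,
        "dko_max_n_peaks": int(dko["n_peaks"].max()),
        "dko_median_fold": float(dko["fold"].median()),
        "wt_median_n_peaks": float(med.loc["WT", "n_peaks"]),
        "tko_median_n_peaks": float(med.loc["TKO", "n_peaks"]),
        "mko_median_n_peaks": float(med.loc["MKO", "n_peaks"]),
        "wt_median_fold": float(med.loc["WT", "fold"]),
        "tko_median_fold": float(med.loc["TKO", "fold"]),
        "p_init_mko_vs_wt": adj_p("MKO", "WT"),
        "p_init_mko_vs_tko": adj_p("MKO", "TKO"),
        "p_init_wt_vs_tko": adj_p("TKO", "WT"),
    }
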