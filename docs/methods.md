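# Methods

`nfkbdyn` quantifies single-cell NF-κB (EGFP-p65) nuclear translocation
dynamics and TNFα-promoter (mCherry) activation from three-channel
time-lapse movies of macrophages, and ships a forward model that renders
synthetic movies with known ground truth so that every analysis stage can
be validated by parameter recovery. This note records the models, the
defaults and why they were chosen, and what the validation does and does
not demonstrate.

## The measurement model

Each cell contributes two time series, sampled once per frame (default
every 3 minutes for 15 h, 512×512 px, 16-bit):

- **Nuc/Cyt ratio** — mean EGFP intensity inside a nuclear circle divided
  by the mean over the rest of the segmented cell body. NF-κB entering
  the nucleus raises the ratio; oscillatory shuttling produces a damped
  pulse train.
- **Cell/BG ratio** — mean mCherry over the cell body divided by the mean
  over cell-free background (cell masks dilated by 5 px before taking the
  complement, to avoid halo contamination). TNFα-promoter activation
  produces a slow rise peaking hundreds of minutes after stimulation.

Stimulation is at frame 0 (imaging starts immediately after adding LPS);
all times are minutes post-stimulation. Pixel coordinates are 0-based,
row-major; circle membership is center distance ≤ radius, inclusive.

## Synthetic movie generator

**Nuclear fraction.** The Nuc/Cyt ratio of a cell is
`baseline + Σ_k A·d^(k−1)·exp(−(t−τ_k)²/(2σ²))`: Gaussian pulses of
width σ (minutes), first amplitude `A` above baseline, per-peak damping
factor `d`, with `τ₁ ~ N(first_peak_time_mean, sd)` and subsequent pulses
spaced `N(interval_mean, interval_sd)` apart. Gaussian (symmetric) pulses
were chosen because the analysis itself assumes symmetric peaks when it
equates nuclear duration with (peak time − initiation time); no published
curve shape was available to fit.

**Reporter.** The Cell/BG ratio is a logistic rise anchored to equal 1 at
t = 0 and to reach `fold` exactly at `peak_time` (default ≈ 450 min),
then relaxes exponentially toward 1. `fold = 1` is a non-responder.

**Rendering.** Cells are disks (radius 14–18 px) with an interior nuclear
circle (radius 6 px), placed on a jittered lattice that guarantees
non-contact; cells are stationary except in the purpose-built touching
and division fixtures. Per frame, the cell's total EGFP (3×10⁵ counts) is
split between nucleus and cytoplasm so that the pixel-level mean ratio
equals the input trace exactly and total EGFP is conserved over time.
mCherry is uniform over the cell body at `background × Cell/BG`.
Bright-field is a uniform gray with a dark ring at the cell boundary.
The camera model applies an optional Gaussian PSF (σ = 1 px), Poisson
shot noise on the expected intensity and additive Gaussian read noise
(σ = 3 counts) — the standard fluorescence-camera model.

The background offset (100 counts) models medium autofluorescence and is
rendered only **outside** cell bodies. This is a deliberate forward-model
convenience: the extraction rule (like the original measurement) does not
background-subtract, so an offset added inside cells would bias every
rendered ratio toward 1 and make exact round-trip validation impossible.
Intensities are arbitrary units throughout; no counts-per-molecule
calibration exists for this system.

**Genotype presets.** Defaults were chosen once to reproduce the
qualitative phenotypes of the four macrophage lines, with no claim of
quantitative fidelity to the original (undeposited) data:

| preset | pulses (median) | first peak | amplitude | pulse σ | reporter fold |
|--------|-----------------|------------|-----------|---------|---------------|
| WT | N(3,1) clipped 1–5 (median 3) | N(30,6) min | N(1.3,0.25) | ~8 min | N(2.1,1.0) ≥ 1 |
| TKO | N(4,1.2) clipped 1–7 (median 4) | N(30,6) min | same as WT | ~8 min | N(1.2,0.3) ≥ 1 |
| MKO | N(2,0.7) clipped 1–3; 70% of cells translocate | N(120,45) min | N(0.7,0.2) | ~14 min | 1 (none) |
| DKO / unstimulated | 0 | — | 0 | — | 1 |

WT/TKO initiation (the threshold crossing, ≈ 2σ before the pulse peak)
therefore falls within ~10 minutes of stimulation; MKO initiation is
delayed and heterogeneous with broader, lower peaks; DKO is flat. The
inter-pulse interval default is 90 min (WT) / 100 min (TKO) / 110 min
(MKO).

## Analysis pipeline

**Segmentation.** Cell bodies are segmented per frame from the smoothed
EGFP image (cells carry cytoplasmic EGFP even at rest) thresholded by
Otsu with one Ridler–Calvard refinement step, unioned with the interior
of the dark bright-field ring; the mask is closed (disk r=2), hole-filled
and eroded by 1 px (the erosion trims the smoothing halo so that measured
means are not diluted by background pixels; at the image border the
erosion treats out-of-frame pixels as foreground so edge contact is
preserved for the border exclusion rule). Components smaller than 80 px
are dropped. A guard rejects thresholds within 6 robust sigmas of the
background median, so blank or noise-only frames segment to nothing.

**Tracking.** Nearest-centroid Hungarian linking, gated at 10 px/frame
(macrophages in these movies are near-stationary), with a 2-frame gap
allowance; a track that vanishes for longer is lost.

**Nuclear circle.** The original analysis placed a circle of manually
chosen diameter. Here placement is automated: the circle (diameter is
configuration; for synthetic runs it defaults to the generator's nucleus
diameter) is centered where the mean EGFP inside the circle is minimal on
the per-pixel 10th-percentile projection of EGFP over the whole track.
The dark-quantile projection is used instead of an average of the first
few frames because in wild-type-like cells the first translocation begins
within minutes of imaging start, so early frames already show a bright
nucleus; the nucleus is instead identified as the region that becomes
EGFP-dark whenever NF-κB exits between pulses. The circle is constrained
to sit 2 px inside the segmented boundary so the dark rim just outside
the cell cannot out-compete the nucleus. A manual circles CSV can
override placement per cell.

**Exclusions.** Any cell that touches another cell (label 8-adjacency in
any frame, or a track merge), divides (one region mapping onto ≥ 2
regions in the next frame, ≥ 25 px overlap each), clips the image border,
or is lost by the tracker is excluded from analysis, permanently for the
movie. Both members of a touching pair and all products of a division are
excluded. Exclusion is monotone: adding cells to a scene can only add
exclusions.

**Traces and smoothing.** The per-frame ratio curves are averaged over
ten frames. "Averaged by ten frames" is ambiguous between a sliding and a
block average; the default is a centered sliding window (truncated at the
edges, output length preserved) because it preserves per-frame curves; a
block mode is available. With an even window the center sits half a frame
left of the window, a ≤ 1.5-min systematic shift that is small against
the 3-min frame interval. A pulse peaking within half a window of t = 0
carries a larger edge-truncation bias; the default presets place the
first peak at ≈ 30 min, outside this regime.

**Noise level and peak calling.** The detection threshold is the 95th
percentile of |value − per-cell median| pooled over the *raw* traces of
unstimulated cells. Peaks are local maxima of the *smoothed* curve above
(per-cell median + threshold); maxima closer than 5 frames (15 min) are
merged keeping the higher, ties toward the earlier frame. The raw/smoothed
split is deliberate: ten-frame averaging reduces the residual noise of
the analyzed curves well below the raw-fluctuation threshold, which is
what makes thresholded local-maximum calling reliable (a threshold taken
from smoothed unstimulated curves would sit inside the fluctuation band
of the smoothed stimulated curves and generate systematic false peaks).
Each peak's initiation time is the latest upward crossing of the
threshold level at or before the maximum, linearly interpolated between
frames (a curve already above the level at t = 0 initiates at 0);
nuclear duration is peak time − initiation time, exactly.

**Per-cell metrics.** Peak count, per-peak initiation/peak time/height/
duration, successive peak-time intervals, damping rates
`(h_k − h_{k+1})/h_k` (relative decrease; an absolute-difference mode is
available; rates are undefined with fewer than two peaks and may be
negative), and the mCherry fold increase = trace maximum ÷ mean of the
first 10 frames (a constant trace gives exactly 1). Heights are read from
the smoothed curve — the translocation curve *is* the averaged one — so
smoothing attenuates absolute heights; damping ratios are much less
affected because all pulses share a width.

**Group statistics.** Kruskal–Wallis (tie-corrected mid-ranks) followed
by Dunn's pairwise z tests with Bonferroni adjustment over all pairs
(matching the Prism procedure named in the original analysis; Holm is
available). Cells lacking a metric (e.g. no second peak) are excluded
from that metric's moments but counted in the fraction-with-metric
denominator. Group summaries report mean ± sample s.d., median and range.
All identical values give H = 0, p = 1 by convention. The implementation
is hand-written (no post-hoc package is a dependency) and is checked in
the tests against `scipy.stats.kruskal` and an independently coded Dunn
oracle to ≥ 6 significant digits.

## Validation: what it shows and what it does not

Because the study's raw movies are not deposited, validation is by
parameter recovery on the forward model:

- **Round trip** (noise and blur off): extracted Nuc/Cyt and Cell/BG
  traces reproduce the generating curves to well under 2% pointwise
  (in practice to float32 precision, because the eroded mask is a subset
  of the uniform-intensity disk).
- **Oracle equivalence**: the peak caller agrees exactly with an
  exhaustive brute-force local-maximum scan on > 1000 fuzzed short
  curves.
- **Parameter recovery** (default noise, PSF on; 120 WT + 40 MKO +
  40 DKO cells, 200 frames): peak-count accuracy, matched peak-time
  error, damping-rate error and fold error are measured against ground
  truth; segmentation detection fraction and IoU likewise. The benchmark
  sizes (200 frames = 600 min; 100-cell movies) were chosen so all drawn
  pulses and the reporter peak fit the observation window.
- **End-to-end** (n = 30/group, 300 frames): DKO yields zero peaks and
  fold ≈ 1; MKO initiation is significantly delayed versus WT and TKO
  after Dunn adjustment while WT vs TKO is not significant; WT median
  peak count exceeds MKO's; WT reporter fold exceeds TKO's.

These checks validate the *pipeline* under the generator's assumptions:
stationary disk-shaped cells, uniform intracellular fluorophore
distribution, symmetric pulses, Poisson+Gaussian camera noise, and no
photobleaching, illumination drift, cell deformation or 3-D effects.
Passing them does not certify performance on real movies where those
assumptions fail; in particular, segmentation of irregular motile cells
and nucleus placement under uneven illumination would need their own
validation. Choices most likely to matter on real data: the nucleus
diameter (required configuration in real-movie mode — the original study
chose it manually), the smoothing mode, whether damping is relative or
absolute, and whether heights should be baseline-subtracted (they are
not, matching "the value of the highest point").

## Numerical conventions

Degenerate inputs are defined, not special-cased: flat curves call no
peaks; a tie in the nucleus-placement score takes the first (row-major)
position; equal-height merged maxima keep the earlier; a curve above the
detection level from the start initiates at the first frame. Rendering
clips negative intensities at 0 and 16-bit output at 65535 (with a
warning). All randomness flows from numpy `SeedSequence` spawning, so
every cohort, cell and camera realization is reproducible from one seed;
identical seeds give bit-identical movies and output tables.
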