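"""Parameter containers for the synthetic-movie generator.

The generator produces per-cell ground-truth dynamics (a damped pulse train
of the nuclear NF-κB fraction, and a delayed sigmoidal TNFα-promoter
reporter profile) and renders them into noisy multi-channel movies. The
containers here hold everything that defines one cell's dynamics and the
optics of the rendered movie; genotype presets bundle the per-cell
parameter *distributions* for the four macrophage lines (WT, TRIF-/- "TKO",
MyD88-/- "MKO", double-knockout "DKO").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

GENOTYPES = ("WT", "TKO", "MKO", "DKO")


@dataclass(frozen=True)
class PulseTrainParams:
    """Damped Gaussian pulse train of the nuclear/cytoplasmic NF-κB ratio.

    The resting Nuc/Cyt ratio is ``baseline_ratio`` (< 1 for a cytoplasmic
    factor); each translocation event adds a Gaussian pulse of width
    ``pulse_width_sd`` minutes. The first pulse height above baseline is
    ``first_peak_amplitude``; each subsequent pulse is multiplied by
    ``damping_factor``. Pulse k+1 follows pulse k after a normally
    distributed interval.
    """

    baseline_ratio: float = 0.7
    first_peak_amplitude: float = 1.3
    damping_factor: float = 0.55
    n_pulses: int = 3
    first_peak_time_mean: float = 9.0
    first_peak_time_sd: float = 3.0
    interval_mean: float = 90.0
    interval_sd: float = 6.0
    pulse_width_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")
        if self.first_peak_amplitude < 0:
            raise ValueError("first_peak_amplitude must be >= 0")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")
        if self.interval_mean <= 0:
            raise ValueError("interval_mean must be > 0")
        if self.pulse_width_sd <= 0:
            raise ValueError("pulse_width_sd must be > 0")
        if not (0 < self.damping_factor <= 1.5):
            raise ValueError("damping_factor must be in (0, 1.5]")
        if self.first_peak_time_sd < 0 or self.interval_sd < 0:
            raise ValueError("timing sds must be >= 0")


@dataclass(frozen=True)
class ReporterParams:
    """TNFα-promoter mCherry profile: logistic rise to ``fold``, then decay.

    ``fold`` is the peak Cell/BG ratio relative to the pre-stimulation
    level; ``fold == 1`` is a non-responder (flat trace). The rise is a
    logistic in time anchored so the trace starts at 1 and attains ``fold``
    exactly at ``peak_time``; afterwards it decays exponentially toward 1
    at ``decay_rate`` per minute.
    """

    fold: float = 2.1
    rise_midpoint: float = 220.0
    rise_steepness: float = 0.025
    peak_time: float = 450.0
    decay_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1 (1 = non-responder)")
        if self.peak_time <= 0:
            raise ValueError("peak_time must be > 0")
        if self.rise_steepness <= 0:
            raise ValueError("rise_steepness must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")


@dataclass(frozen=True)
class OpticsParams:
    """Rendering geometry, acquisition timing and camera noise.

    Defaults follow a 512x512 px field imaged every 3 minutes for 15 h
    (300 frames). ``background_offset`` models medium autofluorescence
    outside cell bodies; shot noise is Poisson on the expected intensity
    and ``read_noise_sd`` is additive Gaussian camera noise.
    """

    image_size: tuple[int, int] = (512, 512)
    cell_radius_range: tuple[float, float] = (14.0, 18.0)
    nucleus_radius: float = 6.0
    psf_sigma: float = 1.0
    background_offset: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 3.0
    frame_interval: float = 3.0
    n_frames: int = 300
    total_egfp_per_cell: float = 3.0e5
    brightfield_level: float = 500.0
    brightfield_ring_depth: float = 200.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.nucleus_radius >= self.cell_radius_range[0]:
            raise ValueError("nucleus_radius must be < min cell radius")
        if self.background_offset <= 0:
            raise ValueError("background_offset must be > 0")


@dataclass(frozen=True)
class Dist:
    """Normal distribution clipped to [lo, hi]; sd 0 means deterministic."""

    mean: float
    sd: float = 0.0
    lo: float = -float("inf")
    hi: float = float("inf")

    def draw(self, rng) -> float:
        x = self.mean if self.sd == 0 else rng.normal(self.mean, self.sd)
        return float(min(max(x, self.lo), self.hi))


@dataclass(frozen=True)
class GenotypePreset:
    """Per-cell parameter distributions for one macrophage genotype.

    ``responder_fraction`` is the probability a cell activates the mCherry
    reporter at all; ``translocating_fraction`` the probability it shows
    any NF-κB translocation pulses (cells failing the draw get n_pulses=0).
    """

    label: str
    baseline_ratio: Dist = field(default_factory=lambda: Dist(0.7, 0.04, 0.5, 0.95))
    amplitude: Dist = field(default_factory=lambda: Dist(1.3, 0.25, 0.3, 2.5))
    damping: Dist = field(default_factory=lambda: Dist(0.55, 0.08, 0.2, 0.9))
    n_pulses_dist: Dist = field(default_factory=lambda: Dist(3.0, 1.0, 1, 5))
    # peak of the first pulse; with an 8-min pulse sigma and the default
    # noise level the threshold crossing (initiation) lands ~23 min
    # earlier, i.e. within 10 min of stimulation
    first_peak_time: Dist = field(default_factory=lambda: Dist(30.0, 6.0, 16.0, 60.0))
    interval: Dist = field(default_factory=lambda: Dist(90.0, 10.0, 40.0, 160.0))
    interval_sd_within: float = 6.0
    pulse_width: Dist = field(default_factory=lambda: Dist(8.0, 1.0, 4.0, 20.0))
    fold: Dist = field(default_factory=lambda: Dist(2.1, 1.0, 1.0, 6.0))
    rise_midpoint: Dist = field(default_factory=lambda: Dist(220.0, 30.0, 120.0, 350.0))
    reporter_peak_time: Dist = field(default_factory=lambda: Dist(450.0, 40.0, 300.0, 580.0))
    responder_fraction: float = 1.0
    translocating_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in GENOTYPES and self.label != "UNSTIM":
            raise ValueError(
                f"unknown genotype label {self.label!r}; expected one of "
                f"{GENOTYPES + ('UNSTIM',)}"
            )
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not 0 <= self.translocating_fraction <= 1:
            raise ValueError("translocating_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def default_presets() -> dict[str, GenotypePreset]:
    """Built-in presets for the four genotypes plus an unstimulated cohort.

    WT and TKO both oscillate with comparable timing and amplitude; TKO
    shows one extra peak on median (4 vs 3), a slightly longer first
    inter-peak interval, and a much weaker reporter response (fold ~1.2 vs
    ~2.1). MKO translocation is delayed, heterogeneous, lower and broader,
    with a median of 2 peaks among the ~70% of cells that respond, and no
    reporter activation. DKO (and the unstimulated cohort used to estimate
    the noise level) shows neither translocation nor reporter activation.
    """
    wt = GenotypePreset(label="WT")
    tko = GenotypePreset(
        label="TKO",
        n_pulses_dist=Dist(4.0, 1.2, 1, 7),
        interval=Dist(100.0, 10.0, 40.0, 170.0),
        fold=Dist(1.2, 0.3, 1.0, 2.5),
    )
    mko = GenotypePreset(
        label="MKO",
        amplitude=Dist(0.7, 0.2, 0.2, 1.5),
        n_pulses_dist=Dist(2.0, 0.7, 1, 3),
        first_peak_time=Dist(120.0, 45.0, 45.0, 320.0),
        interval=Dist(110.0, 15.0, 40.0, 200.0),
        pulse_width=Dist(14.0, 2.0, 6.0, 28.0),
        fold=Dist(1.0, 0.0, 1.0, 1.0),
        responder_fraction=0.0,
        translocating_fraction=0.7,
    )
    dko = GenotypePreset(
        label="DKO",
        amplitude=Dist(0.0, 0.0, 0.0, 0.0),
        n_pulses_dist=Dist(0.0, 0.0, 0, 0),
        fold=Dist(1.0, 0.0, 1.0, 1.0),
        responder_fraction=0.0,
        translocating_fraction=0.0,
    )
    unstim = GenotypePreset(
        label="UNSTIM",
        amplitude=Dist(0.0, 0.0, 0.0, 0.0),
        n_pulses_dist=Dist(0.0, 0.0, 0, 0),
        fold=Dist(1.0, 0.0, 1.0, 1.0),
        responder_fraction=0.0,
        translocating_fraction=0.0,
    )
    return {p.label: p for p in (wt, tko, mko, dko, unstim)}
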