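"""Shared fixtures: small rendered cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from nfkbdyn.params import OpticsParams
from nfkbdyn.simulate import generate_cohort


def small_optics(**overrides) -> OpticsParams:
    base = dict(image_size=(128, 128), n_frames=40)
    base.update(overrides)
    return OpticsParams(**base)


def noiseless_optics(**overrides) -> OpticsParams:
    base = dict(shot_noise=False, read_noise_sd=0.0, psf_sigma=0.0)
    base.update(overrides)
    return small_optics(**base)


@pytest.fixture(scope="session")
def noiseless_wt_cohort():
    """4 WT cells, 40 frames, no noise/blur: exact forward model."""
    optics = noiseless_optics()
    movie, truth = generate_cohort("WT", 4, optics, seed=3)
    return movie, truth, optics


@pytest.fixture(scope="session")
def noisy_wt_cohort():
    """4 WT cells at default noise and PSF."""
    optics = small_optics()
    movie, truth = generate_cohort("WT", 4, optics, seed=3)
    return movie, truth, optics


def match_truth(track, truth):
    """Ground-truth cell whose start centroid is nearest the track's."""
    cy, cx = track.centroids[track.first_frame]
    return min(
        truth.cells,
        key=lambda c: (c.centers[0][0] - cy) ** 2 + (c.centers[0][1] - cx) ** 2,
    )
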