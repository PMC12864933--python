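"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from sleepprint.preprocess import reject_artifacts
from sleepprint.spectra import build_feature_table
from sleepprint.synthdata import (
    ArtifactSpec,
    CohortSpec,
    FingerprintPrior,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects per group, 2 nights, 40 epochs, 8 channels, no artifacts."""
    spec = CohortSpec(
        n_subjects_per_group=2, n_nights=2, epochs_per_night=40,
        n_channels=8, seed=11,
    )
    return generate_cohort(
        spec, FingerprintPrior(),
        artifacts=ArtifactSpec(epoch_probability=0.0,
                               line_noise_amplitude_uv=1.0),
    )


@pytest.fixture(scope="session")
def small_masks(small_cohort):
    return {
        (r.subject_id, r.night): reject_artifacts(r)
        for r in small_cohort.recordings
    }


@pytest.fixture(scope="session")
def small_table(small_cohort, small_masks):
    return build_feature_table(small_cohort.recordings, small_masks)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
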