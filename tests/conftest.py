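"""Shared fixtures: tiny cohorts and one cached 12-subject LOSO run."""

from __future__ import annotations

import numpy as np
import pytest

from intentsense import GeneratorConfig, PipelineConfig
from intentsense.model import IntentSensingModel
from intentsense.synthetic import (
    SubjectProfile,
    TrialSpec,
    generate_calibration,
    generate_trial,
)


@pytest.fixture(scope="session")
def default_cohort_results():
    """LOSO results on the default 12-subject synthetic cohort (seeded).

    Scaled to 5 patients / 7 controls to keep the full evaluation at
    desk scale; shared across tests because the run is the expensive
    part.
    """
    gen = GeneratorConfig(n_patients=5, n_controls=7)
    pipe = PipelineConfig(
        cohort_seed=1, split_seed=2, training_seed=3, bootstrap_seed=4, n_bootstrap=200
    )
    model = IntentSensingModel.from_synthetic(gen, seed=1, pipeline=pipe)
    return model.fit()


@pytest.fixture()
def control_profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="C01",
        group="control",
        motion_scale=1.0,
        tremor_amplitude=0.0,
        variability=1.0,
        rng_seed=1234,
    )


@pytest.fixture()
def patient_profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="P01",
        group="patient",
        motion_scale=1.0,
        tremor_amplitude=1.0,
        variability=1.0,
        rng_seed=1234,
    )


@pytest.fixture()
def control_trial(control_profile):
    spec = TrialSpec(
        subject=control_profile,
        activity="door",
        repeat_index=1,
        duration_s=21.0,
        trial_seed=42,
    )
    return generate_trial(spec, GeneratorConfig())


@pytest.fixture()
def control_calibration(control_profile):
    return generate_calibration(control_profile, config=GeneratorConfig())
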