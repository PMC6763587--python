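"""Shared fixtures: montages, small synthetic segments, and the full-scale
study run reused by the end-to-end acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from alphacog import PipelineConfig, SynthStudyConfig, run_pipeline
from alphacog.montage import equidistant_64, tentwenty_64
from alphacog.phases import Condition, Phase
from alphacog.synth import SynthPhaseSpec, plan_study, synthesize_recording

#: One root seed for every randomized fixture in the suite.
SUITE_SEED = 20260


@pytest.fixture(scope="session")
def eq_montage():
    return equidistant_64()


@pytest.fixture(scope="session")
def tt_montage():
    return tentwenty_64()


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def clean_segment(eq_montage):
    """One failure-free eyes-closed 120-s segment at protocol rate."""
    spec = SynthPhaseSpec(Phase.II, Condition.EYES_CLOSED, 120.0, 10.22)
    rec, truth = synthesize_recording(
        spec, eq_montage, subject_offset=0.1, seed=SUITE_SEED
    )
    return rec, truth


@pytest.fixture(scope="session")
def default_study_config():
    """The full study conditions: 17 subjects, two caps, 4 alpha-deficient,
    subject SD 0.26 Hz, phase means at the fatigue-shift defaults.

    Phase III carries no iAPF statistics and is omitted from this run."""
    return SynthStudyConfig(
        n_subjects=17,
        n_excluded_no_alpha=4,
        seed=SUITE_SEED,
        phases=(Phase.I, Phase.II, Phase.IV, Phase.V),
    )


@pytest.fixture(scope="session")
def default_study_report(default_study_config):
    """Full pipeline run on the default synthetic study (the expensive
    fixture: ~10 min; shared by every end-to-end assertion)."""
    return run_pipeline(PipelineConfig(synth=default_study_config))


@pytest.fixture(scope="session")
def default_study_plan(default_study_config):
    return plan_study(default_study_config)
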