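"""Shared fixtures.

The expensive end-to-end studies (synthetic dataset -> preprocessing ->
pure-spectrum training -> checkpoint selection) are session-scoped and shared
between the acceptance tests and the model-behaviour tests so the whole suite
stays within a single-CPU budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from sersmix.pipeline import RunConfig, run_study
from sersmix.preprocess import PreprocConfig
from sersmix.synthetic import GeneratorConfig


@pytest.fixture()
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


@pytest.fixture()
def quiet_config() -> GeneratorConfig:
    """Generator with baseline and noise switched off (band structure only)."""
    from sersmix.synthetic import BaselineConfig

    return GeneratorConfig(
        seed=42,
        baseline=BaselineConfig(poly_coeff_range=0.0, hump_amplitude=(0.0, 0.0)),
        noise_sd=0.0,
    )


@pytest.fixture()
def preproc_cfg() -> PreprocConfig:
    return PreprocConfig()


def _study(seed: int):
    return run_study(RunConfig(seed=seed, profile="ci"))


@pytest.fixture(scope="session")
def study_seed1():
    """Full reduced-profile study for seed 1 (dataset, training, selection)."""
    return _study(1)


@pytest.fixture(scope="session")
def study_seed2():
    return _study(2)


@pytest.fixture(scope="session")
def study_seed3():
    return _study(3)


@pytest.fixture(scope="session")
def all_studies(study_seed1, study_seed2, study_seed3):
    return {1: study_seed1, 2: study_seed2, 3: study_seed3}
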