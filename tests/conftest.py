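"""Shared fixtures: spectral library, bands, and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from wheatlai import (
    default_micasense_bands,
    default_soil_library,
    make_dataset,
)


@pytest.fixture(scope="session")
def soil_lib():
    return default_soil_library()


@pytest.fixture(scope="session")
def dry_soil(soil_lib):
    return soil_lib.dry


@pytest.fixture(scope="session")
def bands():
    return default_micasense_bands()


@pytest.fixture(scope="session")
def small_p1_dataset(dry_soil):
    """A 600-row Set#1 dataset for fast regressor tests."""
    return make_dataset("p1", dry_soil, 600, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
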