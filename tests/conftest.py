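"""Shared fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from camelscan import DemographyConfig, simulate_three_pop_wf


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    cfg = DemographyConfig(seed=42)
    return simulate_three_pop_wf(cfg, seq_length=250_000, n_scaffolds=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
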