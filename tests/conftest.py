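"""Shared fixtures: the default synthetic study, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pasa.synth import GeneratorConfig, generate_dataset, dominant_chromophore
from pasa.spectral import process_dataset

SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_records(default_cfg):
    """The default 50 + 50 study (raw traces + ground truth)."""
    return generate_dataset(50, 50, default_cfg, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def default_spectra(default_records):
    """APSD spectra of the default study, processed through the full chain."""
    return process_dataset(default_records)


@pytest.fixture(scope="session")
def ground_truth_dominance(default_cfg) -> np.ndarray:
    return dominant_chromophore(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
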