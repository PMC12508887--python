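"""Shared fixtures: one default phantom and its preprocessed form per session."""

import warnings

import numpy as np
import pytest

from ramanmqa.phantom import make_cell_phantom
from ramanmqa.preprocess import PreprocessConfig, run_preprocess


@pytest.fixture(scope="session")
def default_phantom():
    """Default bacteriocyte phantom (48x48, SNR 30, 6 spikes), seed 42."""
    return make_cell_phantom(seed=42)


@pytest.fixture(scope="session")
def preprocessed_phantom(default_phantom):
    """The default phantom after despiking, baseline correction and smoothing."""
    cube, truth = default_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, prov = run_preprocess(cube, PreprocessConfig())
    return out, truth, prov


@pytest.fixture(scope="session")
def small_phantom():
    """A 24x24 phantom for tests where speed matters more than statistics."""
    return make_cell_phantom(shape=(24, 24), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
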