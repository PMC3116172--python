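"""Shared fixtures: one default synthetic library per session."""

import numpy as np
import pytest

from cycloqsar.descriptors import build_matrix, normalize
from cycloqsar.synth import GeneratorConfig, generate_library


@pytest.fixture(scope="session")
def default_library():
    library, truth = generate_library(GeneratorConfig(seed=0))
    return library, truth


@pytest.fixture(scope="session")
def general_matrices(default_library):
    library, _ = default_library
    raw = build_matrix(library, "general")
    norm, _ = normalize(raw)
    return raw, norm


@pytest.fixture(scope="session")
def dli_matrices(default_library):
    library, _ = default_library
    raw = build_matrix(library, "drug_like_index")
    norm, _ = normalize(raw)
    return raw, norm


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
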