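"""Shared fixtures: small textured scenes and the standard synthetic fixture."""

import numpy as np
import pytest

from pollenset.synthetic import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_scene():
    """A reproducible textured grayscale scene (uint8) for fusion tests."""
    r = np.random.default_rng(7)
    return np.clip(r.normal(128, 40, size=(128, 128)), 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def easy_fixture():
    """The standard easy benchmark fixture: 2 species x 12 grains, 3 z-planes."""
    return make_fixture("easy", seed=1, with_stacks=False)


@pytest.fixture(scope="session")
def easy_fixture_with_stacks():
    """Easy fixture including defocus z-stacks (slower; built once)."""
    return make_fixture("easy", seed=1, with_stacks=True)
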