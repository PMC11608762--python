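import numpy as np
import pytest

from scmbench import alphabet, flags, voronoi


@pytest.fixture(scope="session")
def glyphs():
    return alphabet.build_glyph_set()


@pytest.fixture(scope="session")
def templates():
    return flags.build_class_templates()


@pytest.fixture(scope="session")
def intensity_null(templates):
    """99.5th-percentile chi-squared cutoffs from a reference ensemble."""
    return flags.build_intensity_null(n_images=120, seed=17, templates=templates)


@pytest.fixture(scope="session")
def voronoi_mini_ensemble():
    """40 clean realizations, 10 per class."""
    reals = []
    for i, c in enumerate([16, 32, 48, 64] * 10):
        reals.append(voronoi.generate_voronoi(c, 9_000 + i))
    return reals


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
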