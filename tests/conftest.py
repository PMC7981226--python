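import numpy as np
import pytest

from lyresong import geo, synthgen


@pytest.fixture(scope="session")
def pop_distances():
    """Names and straight-line distance matrix of the default populations."""
    pops = {f"P{i+1}": c for i, c in enumerate(synthgen.DEFAULT_POP_COORDS)}
    names, straight, _ = geo.geo_distance_matrices(pops)
    return names, straight


@pytest.fixture(scope="session")
def small_corpus(pop_distances):
    """A small default-parameter corpus: 6 populations x 5 males x 8 songs."""
    _, straight = pop_distances
    cfg = synthgen.SynthConfig(songs_per_individual=8, seed=42)
    elements, songs, dialects = synthgen.generate_corpus(cfg, geo_dist_m=straight)
    return cfg, elements, songs, dialects


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
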