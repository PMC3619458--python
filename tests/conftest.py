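import pytest

from colorchains.grid import build_wcs_array


@pytest.fixture(scope="session")
def grid():
    return build_wcs_array()


@pytest.fixture(scope="session")
def small_corpus(grid):
    """A compact synthetic reference corpus shared by fast tests."""
    from colorchains.chains import generate_synthetic_corpus

    return generate_synthetic_corpus(n_languages=6, speakers_per_language=3,
                                     noise_eps=0.05, seed=42, grid=grid)
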