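import numpy as np
import pytest

from isingspikes import IsingParameters, SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params(rng):
    """A generic well-conditioned 4-spin model."""
    n = 4
    j = rng.normal(0, 0.3, size=(n, n))
    j = np.triu(j, k=1)
    j = j + j.T
    h = rng.normal(-0.3, 0.4, size=n)
    return IsingParameters(fields=h, couplings=j)


@pytest.fixture
def tiny_raster():
    return SpikeRaster(
        np.array(
            [
                [1, -1, 1, -1],
                [1, 1, -1, -1],
                [-1, -1, -1, 1],
            ]
        ),
        sample_id="tiny",
    )


def write_raster_text(path, text):
    path.write_text(text)
    return path
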