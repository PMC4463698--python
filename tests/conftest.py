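import numpy as np
import pytest

from pycher.preprocess import SmoothedTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(values, chrom="chr1", spacing=100, start=1000, **kwargs):
    """A SmoothedTrack with evenly spaced positions (helper, not a fixture)."""
    values = np.asarray(values, dtype=float)
    positions = start + spacing * np.arange(values.size)
    return SmoothedTrack(chrom=chrom, positions=positions, values=values, **kwargs)


@pytest.fixture
def track_factory():
    return make_track
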