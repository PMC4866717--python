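import numpy as np
import pytest

from cellcheck.io import MarkerTrack
from cellcheck.simulate import SimulationConfig, _diploid_track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diploid_track(rng):
    """A clean noise-free diploid chromosome of 2000 markers."""
    return _diploid_track(SimulationConfig(n_markers=2000), rng)


def make_track(positions, baf, lrr=None, genotypes=None, alt_freq=None,
               chrom="1"):
    n = len(positions)
    baf = np.asarray(baf, dtype=float)
    if lrr is None:
        lrr = np.zeros(n)
    if genotypes is None:
        genotypes = np.where(np.isnan(baf), -1,
                             np.where(baf < 0.25, 0, np.where(baf > 0.75, 2, 1)))
    if alt_freq is None:
        alt_freq = np.full(n, 0.3)
    return MarkerTrack(chrom, np.asarray(positions), baf, np.asarray(lrr, dtype=float),
                       np.asarray(genotypes), np.asarray(alt_freq))
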