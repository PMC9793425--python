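import numpy as np
import pytest

import founderfit as ff


@pytest.fixture(scope="session")
def genome():
    return ff.GenomeMap.default()


@pytest.fixture(scope="session")
def tiny_genome():
    """A single 1-Morgan chromosome — closed forms are hand-checkable."""
    return ff.GenomeMap((100.0,))


@pytest.fixture(scope="session")
def ibd_bins():
    return ff.LengthBins.default_ibd()


@pytest.fixture(scope="session")
def study_model():
    """Single-population bottleneck shaped like the modern-cohort fit."""
    return ff.SinglePopModel(N_a=5000.0, N_b=1563.0, T_b=41.0, d=20.0, N_c=1e6)


@pytest.fixture(scope="session")
def split_model():
    """Two-population split/merge bottleneck (founder subgroup of 627)."""
    return ff.TwoPopModel(N_a=5000.0, N_b=627.0, T_b=46.0, d=22.0, N_c=1e6, f=0.52)
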