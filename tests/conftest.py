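import numpy as np
import pandas as pd
import pytest

from methreprog.core import MethylomeTrack
from methreprog.io import filter_depth
from methreprog import simulate


def make_track(rows, sample_id="s", cell_type="other"):
    """rows: (chrom, pos, context, meth, total)"""
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "context", "meth", "total"])
    return MethylomeTrack(sample_id=sample_id, cell_type=cell_type, calls=calls)


@pytest.fixture(scope="session")
def truth():
    return simulate.build_reference(seed=1)


@pytest.fixture(scope="session")
def tracks(truth):
    return simulate.simulate_methylomes(truth, model="human_retention", seed=7)


@pytest.fixture(scope="session")
def filtered(tracks):
    return {k: filter_depth(v, 3 if k == "oocyte" else 5)
            for k, v in tracks.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
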