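import numpy as np
import pandas as pd
import pytest

from ladpipe.core import GenomeLayout
from ladpipe.tags import TagLibrary


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def big_layout():
    return GenomeLayout({"chr1": 2_000_000})


def make_uniform_library(layout, n, seed, read_length=75, label="lib"):
    """Uniform random tag library over the whole layout."""
    rng = np.random.default_rng(seed)
    chroms = layout.chroms
    lens = np.array([layout[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    clen = np.array([layout[c] for c in chroms])[ci]
    start = (rng.random(n) * (clen - read_length)).astype(np.int64)
    frame = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": start,
            "end": start + read_length,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )
    return TagLibrary(frame, layout, label)


@pytest.fixture
def uniform_library(layout):
    return make_uniform_library(layout, 2_000, seed=11)


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment, shared across expensive tests."""
    from ladpipe.simulate import SimConfig, simulate_experiment

    config = SimConfig(seed=20240915)
    truth, libraries = simulate_experiment(config)
    return config, truth, libraries
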