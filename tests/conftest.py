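import numpy as np
import pandas as pd
import pytest

from ilqtl import simulate
from ilqtl.core import MarkerMap, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_map():
    """Two chromosomes, five markers each, 1 Mb / 10 cM spacing."""
    rows = []
    for c in (1, 2):
        for i in range(5):
            rows.append((f"c{c}m{i + 1}", c, 1_000_000 * (i + 1), 10.0 * i))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "cM"]))


@pytest.fixture
def toy_population(tiny_map):
    """Five hand-written BC1F4 lines on the tiny map."""
    genotypes = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            [2, 2, 0, 0, 0, 0, 0, 0, 0, 0],
            [0, 1, 1, 0, 0, 0, 0, 2, 2, 0],
            [0, 0, 0, 0, 2, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return Population(
        population_id="toy",
        recurrent_id="HHZ",
        donor_id="Teqing",
        scheme=(1, 3),
        line_ids=[f"L{i}" for i in range(5)],
        genotypes=genotypes,
        markers=tiny_map,
    )


@pytest.fixture
def small_config():
    """Small unselected single-population breeding setup."""
    return simulate.SimConfig(
        n_chromosomes=2,
        n_markers_per_chrom=10,
        n_lines=(500,),
        donors=("Teqing",),
        selection=None,
        n_selected=None,
        seed=7,
    )
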