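import numpy as np
import pandas as pd
import pytest

from tadprog.genome_io import TADMap


@pytest.fixture
def toy_chrom_sizes():
    return {"chrA": 1_000_000, "chrB": 600_000}


@pytest.fixture
def toy_map(toy_chrom_sizes):
    """Two chromosomes, four TADs on a 1 kb grid."""
    df = pd.DataFrame(
        [
            ("chrA", 10_000, 400_000),
            ("chrA", 450_000, 900_000),
            ("chrB", 0, 250_000),
            ("chrB", 300_000, 550_000),
        ],
        columns=["chrom", "start", "end"],
    )
    return TADMap("toy", "normal", df)


def make_map(rows, sample_id="m", condition="normal"):
    return TADMap(sample_id, condition,
                  pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
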