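import numpy as np
import pandas as pd
import pytest

import bulkscan as bs


@pytest.fixture(scope="session")
def cucumber_genome():
    return bs.GenomeModel.cucumber()


@pytest.fixture(scope="session")
def default_cross():
    """One default simulated cross shared by read-only tests."""
    return bs.simulate_cross(seed=11)


@pytest.fixture(scope="session")
def filtered_markers(default_cross):
    return bs.filter_informative(default_cross.markers)


def single_chrom_map(positions_bp, positions_cm, chrom="chr1"):
    """Helper: build a one-chromosome GeneticMap from explicit coordinates."""
    return bs.GeneticMap(
        pd.DataFrame(
            {
                "marker_id": [f"{chrom}_m{i}" for i in range(len(positions_bp))],
                "chrom": chrom,
                "pos_bp": np.asarray(positions_bp, dtype=np.int64),
                "pos_cm": np.asarray(positions_cm, dtype=float),
            }
        )
    )


@pytest.fixture
def tiny_map():
    return single_chrom_map([1, 1_000_000], [0.0, 100.0])
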