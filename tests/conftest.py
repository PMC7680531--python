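import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import bsaqtl as b


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes x 200 variants on a 10 Mbp / 100 cM map."""
    return b.build_variant_map(2, 200, 10_000_000, 100.0, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_map):
    return b.simulate_f2_genotypes(small_map, 300, seed=12)


def make_counts(chrom, pos, cab, dar):
    """Allele-count table from parallel lists."""
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position_bp": pos,
            "cab_allele": "A",
            "dar_allele": "G",
            "cab_count": cab,
            "dar_count": dar,
        }
    )


@pytest.fixture
def counts_factory():
    return make_counts
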