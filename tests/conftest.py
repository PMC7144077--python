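import numpy as np
import pandas as pd
import pytest

from polykaryo.coverage import SubgenomeMap
from polykaryo.io_formats import MISSING, GenotypeMatrix
from polykaryo.reference import CAMELINA_SUBGENOME_ASSIGNMENT


@pytest.fixture
def camelina_map():
    return SubgenomeMap(dict(CAMELINA_SUBGENOME_ASSIGNMENT))


@pytest.fixture
def two_pop_gm():
    """Four samples (two per population), three loci; AMOVA components for
    this matrix were worked out by hand on the pairwise squared distances."""
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "pos": [100, 200, 300],
            "ref": ["A"] * 3,
            "alt": ["T"] * 3,
            "is_indel": [False] * 3,
        }
    )
    calls = np.array(
        [
            [0, 0, 2, 2],
            [0, 1, 2, 1],
            [1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(variants, calls, ["a1", "a2", "b1", "b2"])


def make_gm(calls, sample_ids=None, is_indel=None, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samples = calls.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_loci,
            "pos": pos if pos is not None else np.arange(1, n_loci + 1) * 10,
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
            "is_indel": is_indel if is_indel is not None else [False] * n_loci,
        }
    )
    return GenotypeMatrix(variants, calls, sample_ids)
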