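import numpy as np
import pandas as pd
import pytest

from cartatac.intervals import GenomeModel, as_intervals


@pytest.fixture
def toy_genome():
    """Two autosomes of 100 kb with one central gap each, plus a sex chromosome."""
    gaps = as_intervals([("chr1", 40_000, 45_000), ("chr2", 10_000, 12_000)])
    return GenomeModel(chromosomes=(("chr1", 100_000), ("chr2", 100_000),
                                    ("chrX", 100_000)), gaps=gaps)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=90_000, max_len=800):
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, max_pos))
        rows.append((c, s, s + int(rng.integers(1, max_len))))
    return as_intervals(rows)


def random_positions(rng, n, chroms=("chr1", "chr2"), max_pos=99_999):
    return pd.DataFrame({
        "chrom": [chroms[i] for i in rng.integers(len(chroms), size=n)],
        "pos": rng.integers(0, max_pos, size=n),
    })
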