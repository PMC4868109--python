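import numpy as np
import pandas as pd
import pytest

from petqc.io import ChromSizes, PETSet, PET_COLUMNS


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 200_000, "chr2": 100_000})


def make_pets(rows, sizes, canonicalize=True):
    """Build a PETSet from (chrom1,pos1,strand1,chrom2,pos2,strand2) tuples."""
    df = pd.DataFrame(rows, columns=PET_COLUMNS)
    return PETSet.from_frame(df, sizes, canonicalize=canonicalize)


def random_pets(n, sizes, seed, intra_only=False):
    """Random canonical PETSet for property tests."""
    rng = np.random.default_rng(seed)
    names = sizes.names
    c1 = rng.choice(names, size=n)
    c2 = c1 if intra_only else rng.choice(names, size=n)
    lens = {c: sizes[c] for c in names}
    p1 = np.array([rng.integers(0, lens[c]) for c in c1])
    p2 = np.array([rng.integers(0, lens[c]) for c in c2])
    df = pd.DataFrame(
        {
            "chrom1": c1,
            "pos1": p1,
            "strand1": rng.choice(["+", "-"], size=n),
            "chrom2": c2,
            "pos2": p2,
            "strand2": rng.choice(["+", "-"], size=n),
        }
    )
    return PETSet.from_frame(df, sizes)
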