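import numpy as np
import pandas as pd
import pytest

from f2radmap.io import GenotypeMatrix


def make_matrix(calls, roles=None, bp=None, chrom="c1", depths=None, coding="ab"):
    """Build a small GenotypeMatrix from a (samples x markers) int array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if roles is None:
        roles = ["progeny"] * n
    if bp is None:
        bp = np.arange(m) * 1000 + 1
    if isinstance(chrom, str):
        chrom = [chrom] * m
    markers = pd.DataFrame(
        {
            "id": [f"M{j}" for j in range(m)],
            "chrom": chrom,
            "bp": np.asarray(bp, dtype=np.int64),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        roles=list(roles),
        markers=markers,
        calls=calls,
        depths=None if depths is None else np.asarray(depths, dtype=np.int32),
        coding=coding,
    )


@pytest.fixture
def tiny_matrix_factory():
    return make_matrix
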