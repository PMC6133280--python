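import numpy as np
import pytest

from spacc import ProbeMatrix, WeightChain


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_probes():
    """3 probes x 2 subjects on one chromosome, one missing cell."""
    values = np.array([[0.2, 0.4, 0.6],
                       [0.1, np.nan, 0.5]])
    return ProbeMatrix.from_arrays(
        values=values, chrom=["chr1"] * 3, pos=[100, 200, 350],
        probe_id=["p1", "p2", "p3"], subject_id=["s1", "s2"])


def random_instance(rng, n=3, p=6, missing=0.0):
    """Small random chain instance: (X, WeightChain)."""
    X = rng.normal(size=(n, p))
    w = rng.uniform(0.3, 1.5, size=p - 1)
    if missing:
        mask = rng.random((n, p)) < missing
        # keep at least one observed cell per column and per row
        mask[0, :] = False
        X = np.where(mask, np.nan, X)
    chain = WeightChain(weights=w, distances=np.ones(p - 1), segments=[])
    return X, chain
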