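import numpy as np
import pytest

from msatdemog.dataset import GenotypeDataset, LocusDef


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Two populations x three loci with one missing call."""
    loci = [LocusDef(f"L{i}", motif_length=1, coding=3, offset=500) for i in range(3)]
    calls = np.array(
        [
            [[0, 2], [1, 1], [0, 0]],
            [[0, 0], [1, 3], [2, 2]],
            [[2, 2], [np.nan, np.nan], [0, 2]],
            [[0, 2], [3, 3], [2, 2]],
        ],
        dtype=float,
    )
    return GenotypeDataset(
        individuals=["a1", "a2", "b1", "b2"],
        loci=loci,
        calls=calls,
        population=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
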