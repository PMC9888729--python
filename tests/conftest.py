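import numpy as np
import pytest

from treefst import AlleleCountMatrix, benchmark_tree


@pytest.fixture
def bench_tree():
    return benchmark_tree()


@pytest.fixture
def small_acm():
    """Two units, three loci, complete data."""
    return AlleleCountMatrix(
        unit_labels=["P1", "P2"],
        loci=["L1", "L2", "L3"],
        ref_count=np.array([[2, 8], [5, 5], [0, 10]]),
        n_gametes=np.full((3, 2), 10),
    )
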