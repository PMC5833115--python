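import numpy as np
import pandas as pd
import pytest

from traitnet import simulate


@pytest.fixture(scope="session")
def planted_dataset():
    """Small log-linear dataset with one 4-trait module and two exclusion pairs."""
    truth = simulate.default_truth(
        16, seed=2, n_modules=1, module_size=4, n_negative_pairs=2
    )
    x = simulate.simulate_binary_traits(400, truth, seed=5)
    frame = pd.DataFrame(
        x,
        index=[f"sp{i:04d}" for i in range(400)],
        columns=[f"trait{j:02d}" for j in range(16)],
    )
    return frame, truth


@pytest.fixture(scope="session")
def margin_class_3x3():
    """Every 3x3 binary matrix with row sums (2,1,1) and column sums (2,1,1)."""
    import itertools

    members = []
    for bits in itertools.product([0, 1], repeat=9):
        m = np.array(bits, dtype=np.int8).reshape(3, 3)
        if (m.sum(1) == [2, 1, 1]).all() and (m.sum(0) == [2, 1, 1]).all():
            members.append(m)
    assert len(members) == 5
    return members
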