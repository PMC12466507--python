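import numpy as np
import pytest

import footlever as fl


@pytest.fixture(scope="session")
def table3():
    return fl.load_table3()


@pytest.fixture(scope="session")
def table3_frame(table3):
    from footlever.datasets import records_to_frame

    return records_to_frame(table3)


@pytest.fixture(scope="session")
def small_tree():
    """Fixed 8-tip unit-depth Yule tree used across statistics tests."""
    return fl.generate_tree(8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
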