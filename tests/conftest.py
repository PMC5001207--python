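import numpy as np
import pandas as pd
import pytest

import crosslink as cl


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """3 genes x 4 samples, values chosen by hand."""
    return pd.DataFrame(
        [[1.0, 2.0, -1.0, 0.5],
         [0.0, 0.0, 3.0, 3.5],
         [-2.0, -1.5, 0.1, 0.2]],
        index=["TP53", "ESR1", "KRT5"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def small_labeled() -> cl.LabeledDataset:
    """2 well-separated classes x 3 samples over 4 genes."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(4)]
    samples = [f"s{i}" for i in range(6)]
    values = rng.normal(0, 0.1, (4, 6))
    values[0, :3] += 2.0  # g0 marks class a
    values[1, 3:] -= 2.0  # g1 marks class b
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
    return cl.LabeledDataset(matrix, labels)


@pytest.fixture(scope="session")
def planted():
    """Default-scale planted-signature dataset shared across tests."""
    dataset, truth = cl.simulate_reference(cl.SimulationConfig(seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def planted_model(planted):
    dataset, _ = planted
    config = cl.SelectionConfig(fdr_level=0.05, t1=0.1, t2=0.5)
    return cl.build_signature_model(dataset, config, seed=11)
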