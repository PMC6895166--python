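import numpy as np
import pandas as pd
import pytest

from radrecon import ExpressionDataset, SimulationConfig, generate_dataset


def make_dataset(values, doses, donors=None, dataset_id="d1", genes=None):
    """Build a small ExpressionDataset from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "dose_gy": list(doses),
            "donor_id": donors if donors is not None else [f"don{i}" for i in range(n_samples)],
            "dataset_id": dataset_id,
            "platform": "arrayA",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples), meta
    )


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(11)
    return make_dataset(rng.normal(8, 1, (6, 8)), doses=[0, 0, 1, 1, 2, 2, 4, 4])


@pytest.fixture(scope="session")
def small_study_dataset():
    """A single modest synthetic training dataset with ground truth."""
    cfg = SimulationConfig(n_genes=600)
    return generate_dataset(cfg, "train1", seed=101)
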