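import numpy as np
import pytest

from pkdb import count_tables, random_bayes_net, sample_dataset, table3_fixture
from pkdb.data_io import AttributeSpec, Dataset


@pytest.fixture(scope="session")
def table3():
    return table3_fixture()


@pytest.fixture(scope="session")
def table3_counts(table3):
    return count_tables(table3)


@pytest.fixture
def make_random_dataset():
    """Factory: dataset sampled from a random k-dependence network."""

    def _make(n_attributes=5, k=2, n_instances=200, seed=0, class_count=2,
              arity_range=(2, 3), concentration=1.0):
        net = random_bayes_net(
            n_attributes, k, arity_range, class_count, concentration, seed
        )
        return sample_dataset(net, n_instances, seed=seed + 1)

    return _make


def dataset_from_rows(rows, y, arities, class_arity):
    """Small helper to build a coded Dataset directly from integer rows."""
    specs = [
        AttributeSpec(name=f"X{i}", value_labels=[f"v{v}" for v in range(a)])
        for i, a in enumerate(arities)
    ]
    class_spec = AttributeSpec(name="Y", value_labels=[f"c{c}" for c in range(class_arity)])
    return Dataset(np.asarray(rows), np.asarray(y), specs, class_spec)
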