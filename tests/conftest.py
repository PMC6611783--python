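import numpy as np
import pytest

from enviromap.bayesnet import CategoricalDataset


def make_binary_dataset(columns: dict[str, np.ndarray], target: str) -> CategoricalDataset:
    """Build a small all-binary dataset from 0/1 column vectors."""
    names = list(columns)
    values = np.column_stack([columns[n] for n in names]).astype(np.int64)
    return CategoricalDataset(
        variable_names=names,
        cardinalities=[2] * len(names),
        level_labels=[["0", "1"]] * len(names),
        values=values,
        target_index=names.index(target),
    )


@pytest.fixture(scope="session")
def collider_dataset() -> CategoricalDataset:
    """Three binary variables, A and B independent causes of target C."""
    rng = np.random.default_rng(42)
    n = 2000
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    c = (rng.random(n) < 0.15 + 0.3 * a + 0.45 * b).astype(np.int64)
    return make_binary_dataset({"A": a, "B": b, "C": c}, target="C")


@pytest.fixture(scope="session")
def noise_dataset() -> CategoricalDataset:
    """Three mutually independent binary variables."""
    rng = np.random.default_rng(7)
    n = 2000
    return make_binary_dataset(
        {"A": rng.integers(0, 2, n), "B": rng.integers(0, 2, n),
         "C": rng.integers(0, 2, n)}, target="C"
    )


def random_dag_edges(n_vars: int, rng: np.random.Generator, p: float = 0.3):
    """Random DAG consistent with a random node order."""
    order = rng.permutation(n_vars)
    edges = set()
    for i in range(n_vars):
        for j in range(i + 1, n_vars):
            if rng.random() < p:
                edges.add((int(order[i]), int(order[j])))
    return frozenset(edges)
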