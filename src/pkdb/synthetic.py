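"""Synthetic data generation and packaged in-text fixtures.

Datasets are sampled from known k-dependence Bayesian networks (class at
the root, attributes in topological order with up to k attribute parents
each, conditional probability tables drawn from a symmetric Dirichlet), so
every learning stage can be tested against the generating ground truth
without external downloads.

Also packaged: the six-row, four-attribute worked-example table used for
the pointwise-information arithmetic, and the two 25-value thyroid-screen
case vectors used to demonstrate per-instance structure explanation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AttributeSpec, Dataset
from .structures import NetworkStructure

__all__ = [
    "GeneratingNetwork",
    "random_bayes_net",
    "sample_dataset",
    "table3_fixture",
    "case_instance_fixtures",
    "CASE_ATTRIBUTE_NAMES",
]


@dataclass
class GeneratingNetwork:
    """Exact k-dependence network used as a sampling ground truth."""

    structure: NetworkStructure
    class_prior: np.ndarray
    cpts: list[np.ndarray]  # [i] -> (m, *parent_arities, arity_i), rows sum to 1
    arities: list[int]
    n_classes: int
    seed: int


def random_bayes_net(
    n_attributes: int,
    k: int,
    arity_range: tuple[int, int] = (2, 3),
    class_count: int = 2,
    concentration: float = 1.0,
    seed: int = 0,
) -> GeneratingNetwork:
    """Sample a random k-dependence generating network.

    The attribute order is 0..n-1; the attribute at rank r receives exactly
    min(r, k) parents drawn uniformly from the higher-ranked attributes, so
    the arc count is sum_r min(r, k). Every conditional distribution (class
    prior included) is a symmetric Dirichlet draw with the given
    concentration; 1.0 (the default) is uniform over the simplex, smaller
    values give near-deterministic dependence, larger values near-uniform
    noise. Deterministic per seed.
    """
    if n_attributes < 1 or k < 0:
        raise ValueError("need n_attributes >= 1 and k >= 0")
    lo, hi = arity_range
    if lo < 2 or hi < lo:
        raise ValueError("arity range must satisfy 2 <= lo <= hi")
    if class_count < 2:
        raise ValueError("need at least 2 classes")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    arities = [int(a) for a in rng.integers(lo, hi + 1, size=n_attributes)]
    parents: list[list[int]] = []
    for r in range(n_attributes):
        n_par = min(r, k)
        chosen = sorted(rng.choice(r, size=n_par, replace=False).tolist()) if n_par else []
        parents.append([int(p) for p in chosen])
    structure = NetworkStructure(list(range(n_attributes)), parents, k, origin="eager")
    prior = rng.dirichlet([concentration] * class_count)
    cpts: list[np.ndarray] = []
    for i in range(n_attributes):
        shape = (class_count, *[arities[p] for p in parents[i]], arities[i])
        flat = rng.dirichlet([concentration] * arities[i], size=int(np.prod(shape[:-1])))
        cpts.append(flat.reshape(shape))
    return GeneratingNetwork(structure, prior, cpts, arities, class_count, seed)


def sample_dataset(net: GeneratingNetwork, n_instances: int, seed: int = 0) -> Dataset:
    """Ancestral sampling: class first, then attributes in network order."""
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    rng = np.random.default_rng(seed)
    N = n_instances
    y = rng.choice(net.n_classes, size=N, p=net.class_prior)
    X = np.zeros((N, net.structure.n_attributes), dtype=np.int64)
    for i in net.structure.attribute_order:
        idx = (y, *[X[:, p] for p in net.structure.parents[i]])
        probs = net.cpts[i][idx]  # (N, arity_i)
        u = rng.random(N)
        X[:, i] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    specs = [
        AttributeSpec(name=f"X{i}", value_labels=[f"v{v}" for v in range(a)])
        for i, a in enumerate(net.arities)
    ]
    class_spec = AttributeSpec(name="Y", value_labels=[f"c{c}" for c in range(net.n_classes)])
    return Dataset(X, y, specs, class_spec)


#: The six-row worked-example table (four attributes, no printed class).
_TABLE3_ROWS = [
    ("a", "c", "e", "b"),
    ("b", "d", "e", "b"),
    ("b", "d", "e", "c"),
    ("b", "d", "e", "c"),
    ("a", "d", "e", "c"),
    ("a", "c", "f", "d"),
]


def table3_fixture() -> Dataset:
    """The six-row training table over X_i, X_j, X_k, X_t.

    The printed table has no class column, so a constant dummy class is
    attached: class-conditioned tables stay well defined while every
    class-free (pointwise) quantity is untouched.
    """
    names = ["Xi", "Xj", "Xk", "Xt"]
    labels = [["a", "b"], ["c", "d"], ["e", "f"], ["b", "c", "d"]]
    coding = [{v: c for c, v in enumerate(lab)} for lab in labels]
    X = np.array(
        [[coding[j][row[j]] for j in range(4)] for row in _TABLE3_ROWS], dtype=np.int64
    )
    y = np.zeros(len(_TABLE3_ROWS), dtype=np.int64)
    specs = [AttributeSpec(name=n, value_labels=lab) for n, lab in zip(names, labels)]
    class_spec = AttributeSpec(name="Y", value_labels=["dummy"])
    return Dataset(X, y, specs, class_spec)


#: Attribute names for the thyroid-screen case vectors, as far as the
#: source figures reveal them; unnamed indices keep generic labels.
CASE_ATTRIBUTE_NAMES = {
    0: "Sex",
    1: "On thyroxine",
    5: "Query hypothyroid",
    6: "Query hyperthyroid",
    8: "Sick",
    9: "Tumor",
    12: "TSH measured",
    13: "T3 measured",
    15: "TT4 measured",
    16: "FTI measured",
    19: "TSH",
    20: "T3",
    21: "TT4",
    22: "T4U",
    23: "FTI",
}

# (index, value) pairs in the printed (LMI-descending) order.
_CASE1 = [
    (19, "43"), (23, "47"), (22, "1.26"), (20, "2"), (21, "59"), (12, "y"),
    (13, "y"), (6, "t"), (14, "y"), (15, "y"), (16, "y"), (5, "f"), (24, "?"),
    (17, "n"), (1, "f"), (0, "F"), (18, "28"), (4, "f"), (2, "f"), (8, "f"),
    (11, "f"), (7, "f"), (9, "t"), (3, "f"), (10, "f"),
]
_CASE2 = [
    (23, "51"), (21, "37"), (20, "0.5"), (19, "9.7"), (22, "0.72"), (13, "y"),
    (12, "y"), (1, "t"), (14, "y"), (15, "y"), (16, "y"), (5, "f"), (0, "F"),
    (24, "?"), (17, "n"), (4, "f"), (18, "46"), (6, "f"), (8, "f"), (2, "f"),
    (11, "f"), (9, "f"), (7, "f"), (3, "f"), (10, "f"),
]


def case_instance_fixtures() -> list[list[str]]:
    """The two 25-value thyroid-screen case vectors, indexed x0..x24.

    Case 1 carries a "hypothyroid" diagnosis, case 2 "negative". Each is
    returned in attribute-index order (x0 first); ``?`` marks missing.
    """
    out = []
    for case in (_CASE1, _CASE2):
        assert len(case) == 25 and sorted(i for i, _ in case) == list(range(25))
        row = [""] * 25
        for i, v in case:
            row[i] = v
        out.append(row)
    return out
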