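"""Parameter fitting, inference and ensembling over learned structures.

A fitted classifier is a network structure plus add-one (Laplace) smoothed
conditional probability tables: the class prior P(y) and, per attribute,
P(x_i | parents(i), y). Joints follow the chain-rule factorisation

    P(x, y) = P(y) * prod_i P(x_i | Pi_i, y)

accumulated in log space; posteriors are normalised joints. Ensembles
(AKDB, PKDB) average member posteriors with uniform weights.

The personalised classifier (PKDB) pairs the eager KDB with a per-instance
structure learned lazily at classification time and filtered by redundant
dependency elimination; the filter threshold delta can be chosen by
leave-one-out cross-validation on the training data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data_io import AttributeSpec, DataError, Dataset
from .infotheory import ContingencyCounts, InfoConfig, count_tables
from .structures import (
    NetworkStructure,
    RdeConfig,
    apply_rde,
    learn_kdb_structure,
    learn_local_structure,
    learn_nb_structure,
    learn_tan_structure,
)

__all__ = [
    "FittedClassifier",
    "EnsembleClassifier",
    "AodeClassifier",
    "fit_parameters",
    "joint_probability",
    "log_joint_probability",
    "posterior",
    "ensemble_posterior",
    "predict",
    "classify_akdb",
    "classify_pkdb",
    "select_delta_loocv",
    "save_model",
    "load_model",
]


@dataclass
class FittedClassifier:
    """A structure with smoothed probability tables.

    ``cpts[i]`` has shape ``(m, *parent_arities, arity_i)`` and sums to 1
    over the last axis for every (class, parent configuration).
    """

    structure: NetworkStructure
    class_prior: np.ndarray
    cpts: list[np.ndarray]
    arities: list[int]
    smoothing: str = "laplace"
    log_base: float = 2.0

    @property
    def n_classes(self) -> int:
        return self.class_prior.shape[0]


def fit_parameters(
    structure: NetworkStructure, dataset: Dataset, smoothing: str = "laplace"
) -> FittedClassifier:
    """Estimate the class prior and per-attribute CPTs on ``dataset``.

    Add-one smoothing throughout: P(x_i | pi, y) = (c + 1) / (c_pi + arity_i)
    and P(y) = (c_y + 1) / (N + m), so never-observed parent configurations
    fall back to the uniform 1/arity_i.
    """
    if smoothing != "laplace":
        raise ValueError(f"unsupported smoothing {smoothing!r}")
    n = dataset.n_attributes
    if structure.n_attributes != n:
        raise DataError("structure and dataset attribute counts differ")
    a = dataset.arities
    m = dataset.n_classes
    X, y = dataset.X, dataset.y
    prior = (np.bincount(y, minlength=m) + 1.0) / (dataset.n_instances + m)
    cpts: list[np.ndarray] = []
    for i in range(n):
        ps = structure.parents[i]
        shape = (m, *[a[p] for p in ps], a[i])
        table = np.zeros(shape)
        idx = (y, *[X[:, p] for p in ps], X[:, i])
        np.add.at(table, idx, 1.0)
        table = (table + 1.0) / (table.sum(axis=-1, keepdims=True) + a[i])
        cpts.append(table)
    return FittedClassifier(structure, prior, cpts, list(a))


def _cpt_prob(model: FittedClassifier, i: int, yy: int, instance: np.ndarray) -> float:
    """P(x_i | parents, y) with unseen (out-of-range) codes given the
    smoothed uniform mass 1/arity."""
    a = model.arities
    v = int(instance[i])
    if not 0 <= v < a[i]:
        return 1.0 / a[i]
    idx: list[int] = [yy]
    for p in model.structure.parents[i]:
        pv = int(instance[p])
        if not 0 <= pv < a[p]:
            return 1.0 / a[i]
        idx.append(pv)
    idx.append(v)
    return float(model.cpts[i][tuple(idx)])


def log_joint_probability(model: FittedClassifier, instance: Sequence[int], y: int) -> float:
    """Natural-log joint log P(x, y) under the chain-rule factorisation."""
    if not 0 <= y < model.n_classes:
        raise ValueError(f"unknown class code {y}")
    inst = np.asarray(instance, dtype=np.int64)
    total = math.log(model.class_prior[y])
    for i in range(model.structure.n_attributes):
        total += math.log(_cpt_prob(model, i, y, inst))
    return total


def joint_probability(model: FittedClassifier, instance: Sequence[int], y: int) -> float:
    """P(x, y); strictly positive under smoothing."""
    return math.exp(log_joint_probability(model, instance, y))


def posterior(model: FittedClassifier, instance: Sequence[int]) -> np.ndarray:
    """P(y | x) for every class: normalised chain-rule joints."""
    logs = np.array(
        [log_joint_probability(model, instance, yy) for yy in range(model.n_classes)]
    )
    return np.exp(logs - logsumexp(logs))


def ensemble_posterior(posteriors: Sequence[np.ndarray]) -> np.ndarray:
    """Uniformly weighted average of member posteriors."""
    if not posteriors:
        raise ValueError("no member posteriors")
    mats = [np.asarray(p, dtype=float) for p in posteriors]
    length = mats[0].shape[0]
    if any(p.shape != (length,) for p in mats):
        raise ValueError("member posterior lengths differ")
    return np.mean(mats, axis=0)


def predict(post: Sequence[float]) -> int:
    """Argmax class code; ties resolve to the smallest code."""
    vec = np.asarray(post, dtype=float)
    if vec.size == 0:
        raise ValueError("empty posterior")
    return int(np.argmax(vec))


@dataclass
class EnsembleClassifier:
    """Uniform posterior average of fitted members."""

    members: list[FittedClassifier]

    def posterior(self, instance: Sequence[int]) -> np.ndarray:
        return ensemble_posterior([posterior(mb, instance) for mb in self.members])

    def predict(self, instance: Sequence[int]) -> int:
        return predict(self.posterior(instance))


class AodeClassifier:
    """Averaged one-dependence estimators.

    One superparent model per attribute (all other attributes conditioned on
    the superparent and the class); prediction averages the member *joints*
    over superparents whose value occurs in the training data, then
    normalises.
    """

    def __init__(self, dataset: Dataset, smoothing: str = "laplace") -> None:
        n = dataset.n_attributes
        self.members: list[FittedClassifier] = []
        self.value_counts = [
            np.bincount(dataset.X[:, j], minlength=dataset.arities[j]) for j in range(n)
        ]
        for j in range(n):
            order = [j] + [i for i in range(n) if i != j]
            parents = [[j] if i != j else [] for i in range(n)]
            spode = NetworkStructure(order, parents, k=1, origin="eager")
            self.members.append(fit_parameters(spode, dataset, smoothing))

    def posterior(self, instance: Sequence[int]) -> np.ndarray:
        inst = np.asarray(instance, dtype=np.int64)
        m = self.members[0].n_classes
        logs = []
        for j, member in enumerate(self.members):
            v = int(inst[j])
            if 0 <= v < self.value_counts[j].shape[0] and self.value_counts[j][v] > 0:
                logs.append(
                    [log_joint_probability(member, inst, yy) for yy in range(m)]
                )
        if not logs:  # every superparent value unseen: fall back to all members
            logs = [
                [log_joint_probability(member, inst, yy) for yy in range(m)]
                for member in self.members
            ]
        mat = np.asarray(logs)
        mixed = logsumexp(mat, axis=0)
        return np.exp(mixed - logsumexp(mixed))

    def predict(self, instance: Sequence[int]) -> int:
        return predict(self.posterior(instance))


# ---------------------------------------------------------------------------
# Personalised classification
# ---------------------------------------------------------------------------


def classify_akdb(
    train_counts: ContingencyCounts,
    eager_model: FittedClassifier,
    dataset: Dataset,
    instance: Sequence[int],
    k: int = 2,
    cfg: InfoConfig | None = None,
) -> tuple[int, np.ndarray, NetworkStructure]:
    """Eager KDB averaged with the unfiltered per-instance structure."""
    lazy = learn_local_structure(train_counts, instance, k, cfg)
    lazy_model = fit_parameters(lazy, dataset)
    post = ensemble_posterior(
        [posterior(eager_model, instance), posterior(lazy_model, instance)]
    )
    return predict(post), post, lazy


def classify_pkdb(
    train_counts: ContingencyCounts,
    eager_model: FittedClassifier,
    dataset: Dataset,
    instance: Sequence[int],
    rde: RdeConfig,
    cfg: InfoConfig | None = None,
) -> tuple[int, np.ndarray, tuple[NetworkStructure, NetworkStructure]]:
    """Personalised prediction for one instance.

    Learns the lazy structure, filters it by redundancy elimination, fits
    its probability tables on the training data, and averages its posterior
    with the eager model's. Returns the predicted class, the ensemble
    posterior and the (lazy, filtered) structure pair for explanation.
    """
    lazy = learn_local_structure(train_counts, instance, rde.k, cfg)
    filtered = apply_rde(lazy, train_counts, instance, rde, cfg)
    filtered_model = fit_parameters(filtered, dataset)
    post = ensemble_posterior(
        [posterior(eager_model, instance), posterior(filtered_model, instance)]
    )
    return predict(post), post, (lazy, filtered)


def select_delta_loocv(
    dataset: Dataset,
    candidate_grid: Sequence[float],
    k: int = 2,
    cfg: InfoConfig | None = None,
    counts: ContingencyCounts | None = None,
) -> float:
    """Choose delta by leave-one-out zero-one loss of the personalised model.

    For each held-out instance the contingency tables are decremented (which
    equals recounting the remaining rows) and the eager model is relearned
    before classifying the instance at every candidate delta. Ties resolve
    to the smallest delta.
    """
    grid = sorted(float(d) for d in candidate_grid)
    if not grid:
        raise ValueError("empty candidate grid")
    full = counts if counts is not None else count_tables(dataset)
    errors = {d: 0 for d in grid}
    for idx in range(dataset.n_instances):
        row, truth = dataset.X[idx], int(dataset.y[idx])
        loo_counts = full.decremented(row, truth)
        loo_data = dataset.without_row(idx)
        eager = learn_kdb_structure(loo_counts, k, cfg)
        eager_model = fit_parameters(eager, loo_data)
        for d in grid:
            pred, _, _ = classify_pkdb(
                loo_counts, eager_model, loo_data, row, RdeConfig(delta=d, k=k), cfg
            )
            if pred != truth:
                errors[d] += 1
    return min(grid, key=lambda d: (errors[d], d))


def make_learner(
    name: str,
    k: int = 2,
    delta: float | None = 0.5,
    delta_grid: Sequence[float] | None = None,
    cfg: InfoConfig | None = None,
):
    """Build a training procedure for the evaluation stack.

    ``name`` is one of nb, tan, aode, kdb, akdb, pkdb. The returned callable
    maps a training dataset to a scorer ``rows -> (predictions, positive
    scores)``; positive scores are the class-1 posterior for binary data,
    else None. For pkdb, ``delta_grid`` triggers per-training-set selection
    of delta by leave-one-out cross-validation.
    """
    name = name.lower()
    if name not in {"nb", "tan", "aode", "kdb", "akdb", "pkdb"}:
        raise ValueError(f"unknown classifier {name!r}")

    def learner(train: Dataset):
        needs_triples = name == "pkdb"
        counts = count_tables(train, with_triples=needs_triples)
        if name == "aode":
            model = AodeClassifier(train)

            def scorer(rows: np.ndarray):
                posts = np.array([model.posterior(r) for r in np.atleast_2d(rows)])
                scores = posts[:, 1] if posts.shape[1] == 2 else None
                return posts.argmax(axis=1), scores

            return scorer
        if name in ("nb", "tan", "kdb"):
            if name == "nb":
                structure = learn_nb_structure(train.n_attributes)
            elif name == "tan":
                structure = learn_tan_structure(counts, cfg)
            else:
                structure = learn_kdb_structure(counts, k, cfg)
            model = fit_parameters(structure, train)

            def scorer(rows: np.ndarray):
                posts = np.array([posterior(model, r) for r in np.atleast_2d(rows)])
                scores = posts[:, 1] if posts.shape[1] == 2 else None
                return posts.argmax(axis=1), scores

            return scorer
        # lazy ensembles
        eager_model = fit_parameters(learn_kdb_structure(counts, k, cfg), train)
        chosen_delta = delta if delta is not None else 0.5
        if name == "pkdb" and delta_grid:
            chosen_delta = select_delta_loocv(train, delta_grid, k, cfg, counts=counts)

        def scorer(rows: np.ndarray):
            posts = []
            for r in np.atleast_2d(rows):
                if name == "akdb":
                    _, post, _ = classify_akdb(counts, eager_model, train, r, k, cfg)
                else:
                    _, post, _ = classify_pkdb(
                        counts, eager_model, train, r, RdeConfig(delta=chosen_delta, k=k), cfg
                    )
                posts.append(post)
            posts = np.array(posts)
            scores = posts[:, 1] if posts.shape[1] == 2 else None
            return posts.argmax(axis=1), scores

        return scorer

    return learner


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(
    path: str,
    model: FittedClassifier,
    attribute_specs: Sequence[AttributeSpec],
    class_spec: AttributeSpec,
    delta: float | None = None,
) -> None:
    """Write a fitted model plus coding specs as structured JSON text."""
    doc = {
        "format": "pkdb-model",
        "smoothing": model.smoothing,
        "log_base": model.log_base,
        "delta": delta,
        "structure": {
            "attribute_order": model.structure.attribute_order,
            "parents": model.structure.parents,
            "k": model.structure.k,
            "origin": model.structure.origin,
        },
        "class_prior": model.class_prior.tolist(),
        "cpts": [c.tolist() for c in model.cpts],
        "arities": model.arities,
        "attribute_specs": [
            {"name": s.name, "kind": s.kind, "value_labels": s.value_labels, "cuts": s.cuts}
            for s in attribute_specs
        ],
        "class_spec": {
            "name": class_spec.name,
            "kind": class_spec.kind,
            "value_labels": class_spec.value_labels,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> tuple[FittedClassifier, list[AttributeSpec], AttributeSpec, float | None]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "pkdb-model":
        raise DataError("not a pkdb model file")
    s = doc["structure"]
    structure = NetworkStructure(
        list(s["attribute_order"]),
        [list(p) for p in s["parents"]],
        int(s["k"]),
        origin=s.get("origin", "eager"),
    )
    model = FittedClassifier(
        structure,
        np.asarray(doc["class_prior"], dtype=float),
        [np.asarray(c, dtype=float) for c in doc["cpts"]],
        [int(a) for a in doc["arities"]],
        smoothing=doc.get("smoothing", "laplace"),
        log_base=float(doc.get("log_base", 2.0)),
    )
    specs = [
        AttributeSpec(d["name"], d.get("kind", "categorical"), list(d["value_labels"]), d.get("cuts"))
        for d in doc["attribute_specs"]
    ]
    cs = doc["class_spec"]
    class_spec = AttributeSpec(cs["name"], cs.get("kind", "categorical"), list(cs["value_labels"]))
    return model, specs, class_spec, doc.get("delta")
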