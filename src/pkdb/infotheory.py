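"""Co-occurrence counting and information-theoretic measures.

A single pass over the training data builds contingency tables for
singletons, pairs and triples of attribute values, with and without the
class: enough to estimate P(y), P(x_i, y), P(x_i, x_j, y), P(x_i, x_j) and
P(x_i, x_j, x_k) by maximum-likelihood frequencies. Six measures are
derived from them:

* MI   I(X_i; Y)            -- attribute/class mutual information
* CMI  I(X_i; X_j | Y)      -- pairwise dependence given the class
* LMI  I(x_i; Y)            -- the per-value summand of MI
* CLMI I(x_i; x_j | Y)      -- the per-value-pair summand of CMI
* PMI  I(x_i; x_j)          -- pointwise, class-free, may be negative
* PCMI I(x_i; x_k | x_j)    -- pointwise conditional, may be negative

Structure learning uses raw (unsmoothed) frequencies throughout; smoothing
is reserved for classification-time probability tables.

Zero conventions: summed measures (MI/CMI/LMI/CLMI) let zero-probability
terms contribute 0. The pointwise measures are undefined on a zero joint
count; they then return a flagged 0, which downstream redundancy filtering
reads as "no evidence" and skips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import Dataset

__all__ = [
    "InfoConfig",
    "ContingencyCounts",
    "count_tables",
    "mutual_information",
    "conditional_mutual_information",
    "local_mutual_information",
    "conditional_local_mutual_information",
    "pointwise_mutual_information",
    "pointwise_conditional_mutual_information",
]


@dataclass(frozen=True)
class InfoConfig:
    """Analysis-wide conventions for the information measures.

    log_base
        2 (bits, the default) or ``math.e`` (nats). The base cancels in every
        comparison the classifiers make, so it only affects reported values.
    """

    log_base: float = 2.0

    def log(self, x: float) -> float:
        return math.log(x) / math.log(self.log_base)


DEFAULT_CONFIG = InfoConfig()


def _cfg(cfg: InfoConfig | None) -> InfoConfig:
    return cfg if cfg is not None else DEFAULT_CONFIG


@dataclass
class ContingencyCounts:
    """Count tables over attribute values and the class.

    Pair tables are stored once per unordered attribute pair (i < j) and
    transposed on access; likewise triples (i < j < k). All probabilities
    downstream are counts divided by ``n_total``. Accessors tolerate
    out-of-range value codes (unseen categories) by returning zero counts.
    """

    arities: list[int]
    n_classes: int
    n_total: int
    class_counts: np.ndarray
    value_class: list[np.ndarray]  # [i] -> (arity_i, m)
    pair_class: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    triple: dict[tuple[int, int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_attributes(self) -> int:
        return len(self.arities)

    # -- accessors ---------------------------------------------------------

    def _valid(self, i: int, v: int) -> bool:
        return 0 <= v < self.arities[i]

    def value_class_count(self, i: int, v: int) -> np.ndarray:
        if not self._valid(i, v):
            return np.zeros(self.n_classes, dtype=np.int64)
        return self.value_class[i][v]

    def value_count(self, i: int, v: int) -> int:
        return int(self.value_class_count(i, v).sum())

    def pair_class_table(self, i: int, j: int) -> np.ndarray:
        """(arity_i, arity_j, m) table of counts for attributes i, j."""
        if i == j:
            raise ValueError("attribute indices must differ")
        if i < j:
            return self.pair_class[(i, j)]
        return self.pair_class[(j, i)].transpose(1, 0, 2)

    def pair_class_count(self, i: int, vi: int, j: int, vj: int) -> np.ndarray:
        if not (self._valid(i, vi) and self._valid(j, vj)):
            return np.zeros(self.n_classes, dtype=np.int64)
        return self.pair_class_table(i, j)[vi, vj]

    def pair_count(self, i: int, vi: int, j: int, vj: int) -> int:
        return int(self.pair_class_count(i, vi, j, vj).sum())

    def triple_count(self, i: int, vi: int, j: int, vj: int, k: int, vk: int) -> int:
        if len({i, j, k}) != 3:
            raise ValueError("attribute indices must be pairwise distinct")
        if not (self._valid(i, vi) and self._valid(j, vj) and self._valid(k, vk)):
            return 0
        items = sorted(zip((i, j, k), (vi, vj, vk)))
        key = tuple(a for a, _ in items)
        vals = tuple(v for _, v in items)
        return int(self.triple[key][vals])

    # -- leave-one-out support --------------------------------------------

    def decremented(self, row: Sequence[int], y: int) -> "ContingencyCounts":
        """A copy of the tables with one instance's contributions removed."""
        out = ContingencyCounts(
            arities=list(self.arities),
            n_classes=self.n_classes,
            n_total=self.n_total - 1,
            class_counts=self.class_counts.copy(),
            value_class=[t.copy() for t in self.value_class],
            pair_class={k: t.copy() for k, t in self.pair_class.items()},
            triple={k: t.copy() for k, t in self.triple.items()},
        )
        row = [int(v) for v in row]
        out.class_counts[y] -= 1
        for i, v in enumerate(row):
            out.value_class[i][v, y] -= 1
        for (i, j), t in out.pair_class.items():
            t[row[i], row[j], y] -= 1
        for (i, j, k), t in out.triple.items():
            t[row[i], row[j], row[k]] -= 1
        return out


def count_tables(dataset: Dataset, with_triples: bool = True) -> ContingencyCounts:
    """Build all contingency tables from ``dataset`` in one pass.

    Triple tables (needed only for the pointwise conditional measure) can be
    skipped to save memory on wide data.
    """
    if dataset.n_instances < 1:
        raise ValueError("dataset is empty")
    X, y = dataset.X, dataset.y
    a = dataset.arities
    m = dataset.n_classes
    n = dataset.n_attributes

    class_counts = np.bincount(y, minlength=m)
    value_class = [
        np.bincount(X[:, i] * m + y, minlength=a[i] * m).reshape(a[i], m)
        for i in range(n)
    ]
    pair_class = {}
    for i in range(n):
        for j in range(i + 1, n):
            flat = (X[:, i] * a[j] + X[:, j]) * m + y
            pair_class[(i, j)] = np.bincount(flat, minlength=a[i] * a[j] * m).reshape(
                a[i], a[j], m
            )
    triple = {}
    if with_triples:
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    flat = (X[:, i] * a[j] + X[:, j]) * a[k] + X[:, k]
                    triple[(i, j, k)] = np.bincount(
                        flat, minlength=a[i] * a[j] * a[k]
                    ).reshape(a[i], a[j], a[k])
    return ContingencyCounts(
        arities=list(a),
        n_classes=m,
        n_total=dataset.n_instances,
        class_counts=class_counts,
        value_class=value_class,
        pair_class=pair_class,
        triple=triple,
    )


# ---------------------------------------------------------------------------
# Averaged measures (sums over values; zero terms contribute 0)
# ---------------------------------------------------------------------------


def mutual_information(counts: ContingencyCounts, attr: int, cfg: InfoConfig | None = None) -> float:
    """I(X_attr; Y) = sum_{x,y} P(x,y) log P(x,y) / (P(x) P(y))."""
    cfg = _cfg(cfg)
    if not 0 <= attr < counts.n_attributes:
        raise ValueError(f"attribute index {attr} out of range")
    joint = counts.value_class[attr].astype(float)
    N = counts.n_total
    px = joint.sum(axis=1, keepdims=True)
    py = counts.class_counts.astype(float)[None, :]
    mask = joint > 0
    total = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint * N / (px * py)
    total = float((joint[mask] / N * np.log(ratio[mask])).sum())
    return total / math.log(cfg.log_base)


def conditional_mutual_information(
    counts: ContingencyCounts, attr_i: int, attr_j: int, cfg: InfoConfig | None = None
) -> float:
    """I(X_i; X_j | Y) = sum P(x_i,x_j,y) log P(x_i,x_j|y) / (P(x_i|y) P(x_j|y))."""
    cfg = _cfg(cfg)
    if attr_i == attr_j:
        raise ValueError("attribute indices must differ")
    t = counts.pair_class_table(attr_i, attr_j).astype(float)  # (ai, aj, m)
    ci = t.sum(axis=1)  # (ai, m)
    cj = t.sum(axis=0)  # (aj, m)
    cy = counts.class_counts.astype(float)
    mask = t > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t * cy[None, None, :] / (ci[:, None, :] * cj[None, :, :])
    total = float((t[mask] / counts.n_total * np.log(ratio[mask])).sum())
    return total / math.log(cfg.log_base)


def local_mutual_information(
    counts: ContingencyCounts, attr: int, value: int, cfg: InfoConfig | None = None
) -> float:
    """I(x; Y) = sum_y P(x,y) log P(x,y) / (P(x) P(y)) for one value x.

    Non-negative: equals P(x) times the KL divergence of the class posterior
    at x from the class prior. Summing over all values of the attribute
    recovers :func:`mutual_information`. Out-of-range (unseen) value codes
    yield 0.
    """
    cfg = _cfg(cfg)
    if value < 0:
        raise ValueError("negative value code")
    joint = counts.value_class_count(attr, value).astype(float)
    N = counts.n_total
    cx = joint.sum()
    cy = counts.class_counts.astype(float)
    total = 0.0
    for yy in range(counts.n_classes):
        if joint[yy] > 0:
            total += joint[yy] / N * math.log(joint[yy] * N / (cx * cy[yy]))
    return total / math.log(cfg.log_base)


def conditional_local_mutual_information(
    counts: ContingencyCounts,
    attr_i: int,
    value_i: int,
    attr_j: int,
    value_j: int,
    cfg: InfoConfig | None = None,
) -> float:
    """I(x_i; x_j | Y) = sum_y P(x_i,x_j,y) log P(x_i,x_j|y) / (P(x_i|y) P(x_j|y)).

    The per-value-pair summand of the conditional mutual information;
    symmetric in its two value arguments, but (unlike LMI) not sign
    constrained. Summing over all value pairs recovers
    :func:`conditional_mutual_information`.
    """
    cfg = _cfg(cfg)
    if attr_i == attr_j:
        raise ValueError("attribute indices must differ")
    if value_i < 0 or value_j < 0:
        raise ValueError("negative value code")
    joint = counts.pair_class_count(attr_i, value_i, attr_j, value_j).astype(float)
    ci = counts.value_class_count(attr_i, value_i).astype(float)
    cj = counts.value_class_count(attr_j, value_j).astype(float)
    cy = counts.class_counts.astype(float)
    total = 0.0
    for yy in range(counts.n_classes):
        if joint[yy] > 0:
            total += joint[yy] / counts.n_total * math.log(
                joint[yy] * cy[yy] / (ci[yy] * cj[yy])
            )
    return total / math.log(cfg.log_base)


# ---------------------------------------------------------------------------
# Pointwise measures (signed; flagged 0 on zero counts)
# ---------------------------------------------------------------------------


def pointwise_mutual_information(
    counts: ContingencyCounts,
    attr_i: int,
    value_i: int,
    attr_j: int,
    value_j: int,
    cfg: InfoConfig | None = None,
    *,
    return_flag: bool = False,
):
    """PMI I(x_i; x_j) = log P(x_i,x_j) / (P(x_i) P(x_j)); may be negative.

    Undefined when the joint count is zero; then returns 0 with
    ``defined=False`` when ``return_flag`` is set (a plain 0.0 otherwise).
    """
    cfg = _cfg(cfg)
    cij = counts.pair_count(attr_i, value_i, attr_j, value_j)
    ci = counts.value_count(attr_i, value_i)
    cj = counts.value_count(attr_j, value_j)
    if cij == 0 or ci == 0 or cj == 0:
        return (0.0, False) if return_flag else 0.0
    value = cfg.log(cij * counts.n_total / (ci * cj))
    return (value, True) if return_flag else value


def pointwise_conditional_mutual_information(
    counts: ContingencyCounts,
    attr_i: int,
    value_i: int,
    attr_k: int,
    value_k: int,
    attr_j: int,
    value_j: int,
    cfg: InfoConfig | None = None,
    *,
    return_flag: bool = False,
):
    """PCMI I(x_i; x_k | x_j) = log P(x_i,x_k|x_j) / (P(x_i|x_j) P(x_k|x_j)).

    Conditioning is on the *last* value argument ``x_j``, matching the
    reading "what x_k adds about x_i beyond x_j". A zero conditioning count
    P(x_j) = 0 is an error; a zero joint elsewhere gives a flagged 0 as for
    PMI. May be negative.
    """
    cfg = _cfg(cfg)
    cj = counts.value_count(attr_j, value_j)
    if cj == 0:
        raise ValueError("zero conditioning count: P(x_j) = 0")
    cikj = counts.triple_count(attr_i, value_i, attr_k, value_k, attr_j, value_j)
    cij = counts.pair_count(attr_i, value_i, attr_j, value_j)
    ckj = counts.pair_count(attr_k, value_k, attr_j, value_j)
    if cikj == 0 or cij == 0 or ckj == 0:
        return (0.0, False) if return_flag else 0.0
    value = cfg.log(cikj * cj / (cij * ckj))
    return (value, True) if return_flag else value
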