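"""Tabular data handling for discrete Bayesian network classifiers.

Reads delimited categorical data (CSV with header, ``?`` for missing),
integer-codes every column in first-appearance order, discretises
quantitative columns (Fayyad-Irani MDLP or equal frequency) and builds
stratified cross-validation fold plans.

Missing values are never imputed: ``?`` is an ordinary category of the
column it occurs in, so a classifier can condition on "value unknown"
exactly like on any other value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataError",
    "MISSING",
    "AttributeSpec",
    "Dataset",
    "FoldPlan",
    "read_csv_dataset",
    "read_schema",
    "write_schema",
    "mdl_discretize",
    "equal_frequency_discretize",
    "apply_cuts",
    "bin_labels",
    "stratified_folds",
]

#: The missing-value marker. Treated as a first-class category, never imputed.
MISSING = "?"


class DataError(Exception):
    """Raised for malformed input data (empty tables, ragged rows, bad codes)."""


@dataclass
class AttributeSpec:
    """Descriptor of one column after integer coding.

    ``value_labels`` fixes the label -> code mapping: code ``c`` means label
    ``value_labels[c]``. For categorical columns the order is first appearance
    in the file; for discretised quantitative columns it is bin order (with
    ``?`` appended last when the column has missing entries).
    """

    name: str
    kind: str = "categorical"  # "categorical" | "quantitative"
    value_labels: list[str] = field(default_factory=list)
    cuts: list[float] | None = None  # discretisation cut points (quantitative only)

    @property
    def arity(self) -> int:
        return len(self.value_labels)

    def code(self, label: str) -> int:
        """Integer code of ``label``; unseen labels map to ``arity`` (out of range)."""
        try:
            return self.value_labels.index(label)
        except ValueError:
            return self.arity

    def decode(self, code: int) -> str:
        return self.value_labels[code]


@dataclass
class Dataset:
    """Integer-coded instance table with a designated class column.

    ``X`` is an ``(N, n)`` integer array of attribute value codes, ``y`` the
    length-``N`` class code vector. Every code is below its column's arity.
    """

    X: np.ndarray
    y: np.ndarray
    attribute_specs: list[AttributeSpec]
    class_spec: AttributeSpec

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise DataError("instance table and class vector shapes disagree")
        if self.X.shape[0] < 1:
            raise DataError("empty table")
        if self.X.shape[1] != len(self.attribute_specs):
            raise DataError("attribute spec count does not match column count")
        for j, spec in enumerate(self.attribute_specs):
            if self.X[:, j].min() < 0 or self.X[:, j].max() >= spec.arity:
                raise DataError(f"coded value out of range for attribute {spec.name!r}")
        if self.y.min() < 0 or self.y.max() >= self.class_spec.arity:
            raise DataError("class code out of range")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return self.class_spec.arity

    @property
    def arities(self) -> list[int]:
        return [s.arity for s in self.attribute_specs]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(indices, dtype=np.int64)
        return Dataset(self.X[idx], self.y[idx], self.attribute_specs, self.class_spec)

    def without_row(self, index: int) -> "Dataset":
        keep = np.ones(self.n_instances, dtype=bool)
        keep[index] = False
        return Dataset(self.X[keep], self.y[keep], self.attribute_specs, self.class_spec)

    def encode_row(self, labels: Sequence[str]) -> np.ndarray:
        """Code a row of string labels with this dataset's specs.

        Unseen labels receive the out-of-range code ``arity``; downstream
        consumers treat such codes as zero-count categories.
        """
        if len(labels) != self.n_attributes:
            raise DataError("row length does not match attribute count")
        return np.array(
            [spec.code(str(v)) for spec, v in zip(self.attribute_specs, labels)],
            dtype=np.int64,
        )

    def decode_row(self, row: Sequence[int]) -> list[str]:
        return [spec.decode(int(v)) for spec, v in zip(self.attribute_specs, row)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            spec.name: [spec.decode(v) for v in self.X[:, j]]
            for j, spec in enumerate(self.attribute_specs)
        }
        cols[self.class_spec.name] = [self.class_spec.decode(v) for v in self.y]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a non-negative count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mdl_discretize(values: Sequence[float], class_labels: Sequence[int]) -> list[float]:
    """Recursive entropy-minimising discretisation with the MDL stopping rule.

    Candidate cut points are the midpoints between adjacent distinct observed
    values. On each interval the cut maximising class-information gain is
    tested against the minimum-description-length acceptance inequality

        gain > [log2(N-1) + log2(3^c - 2) - (c*H - c1*H1 - c2*H2)] / N

    (c = number of classes present, H = class entropy; subscripts refer to
    the two sides of the cut). Recursion stops where the inequality fails.

    Returns a sorted list of accepted cut points.
    """
    vals = np.asarray(values, dtype=float)
    cls = np.asarray(class_labels, dtype=np.int64)
    if vals.shape != cls.shape:
        raise DataError("values and class labels differ in length")
    if not np.all(np.isfinite(vals)):
        raise DataError("values must be finite")
    order = np.argsort(vals, kind="stable")
    vals, cls = vals[order], cls[order]
    n_classes = int(cls.max()) + 1 if cls.size else 0

    cuts: list[float] = []
    stack: list[tuple[int, int]] = [(0, vals.size)]
    while stack:
        lo, hi = stack.pop()
        seg_vals, seg_cls = vals[lo:hi], cls[lo:hi]
        n = hi - lo
        if n < 2:
            continue
        # candidate positions: boundaries between distinct adjacent values
        change = np.flatnonzero(seg_vals[1:] > seg_vals[:-1]) + 1
        if change.size == 0:
            continue
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), seg_cls] = 1.0
        cum = onehot.cumsum(axis=0)
        total = cum[-1]
        ent_all = _entropy(total)
        best_gain, best_pos = -np.inf, -1
        for pos in change:
            left, right = cum[pos - 1], total - cum[pos - 1]
            gain = ent_all - (pos / n) * _entropy(left) - ((n - pos) / n) * _entropy(right)
            if gain > best_gain + 1e-12:
                best_gain, best_pos = gain, int(pos)
        left = cum[best_pos - 1]
        right = total - left
        c = int((total > 0).sum())
        c1 = int((left > 0).sum())
        c2 = int((right > 0).sum())
        delta = math.log2(3**c - 2) - (c * ent_all - c1 * _entropy(left) - c2 * _entropy(right))
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain > threshold:
            cut = (seg_vals[best_pos - 1] + seg_vals[best_pos]) / 2.0
            cuts.append(float(cut))
            stack.append((lo, lo + best_pos))
            stack.append((lo + best_pos, hi))
    return sorted(cuts)


def equal_frequency_discretize(values: Sequence[float], n_bins: int = 3) -> list[float]:
    """Cut points splitting ``values`` into ``n_bins`` equally populated bins.

    Bin boundaries fall at sorted positions ``b*N // n_bins``; a boundary
    between tied values produces no cut, so ties stay in the lower bin and
    bins are as even as the row count allows. ``n_bins=1`` yields no cuts.
    """
    if n_bins < 1:
        raise DataError("n_bins must be >= 1")
    vals = np.sort(np.asarray(values, dtype=float), kind="stable")
    n = vals.size
    cuts: list[float] = []
    for b in range(1, n_bins):
        pos = b * n // n_bins
        if pos <= 0 or pos >= n:
            continue
        lo, hi = vals[pos - 1], vals[pos]
        if hi > lo:
            cut = float((lo + hi) / 2.0)
            if not cuts or cut > cuts[-1]:
                cuts.append(cut)
    return cuts


def apply_cuts(values: Sequence[float], cuts: Sequence[float]) -> np.ndarray:
    """Bin codes for ``values`` under sorted ``cuts`` (value < cut => lower bin)."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(values, dtype=float), side="left").astype(np.int64)


def bin_labels(cuts: Sequence[float]) -> list[str]:
    """Human-readable interval labels for the bins induced by ``cuts``."""
    edges = ["-inf"] + [f"{c:g}" for c in cuts] + ["inf"]
    return [f"({edges[i]}, {edges[i + 1]}]" for i in range(len(edges) - 1)]


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------


def read_schema(path: str | Path) -> dict:
    """Load a YAML schema: ``class_column``, ``quantitative`` list, optional
    ``discretizer`` (mdlp|eqfreq), ``n_bins`` and per-column ``cuts``."""
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, dict):
        raise DataError("schema file must contain a mapping")
    return schema


def write_schema(path: str | Path, schema: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema, fh, sort_keys=False)


def _encode_categorical(column: Iterable[str]) -> tuple[np.ndarray, list[str]]:
    labels: list[str] = []
    index: dict[str, int] = {}
    codes = []
    for v in column:
        if v not in index:
            index[v] = len(labels)
            labels.append(v)
        codes.append(index[v])
    return np.array(codes, dtype=np.int64), labels


def _encode_quantitative(
    column: list[str], class_codes: np.ndarray, discretizer: str, n_bins: int,
    cuts: Sequence[float] | None,
) -> tuple[np.ndarray, list[str], list[float]]:
    present = np.array([v != MISSING for v in column])
    try:
        numeric = np.array([float(v) for v, ok in zip(column, present) if ok])
    except ValueError as exc:
        raise DataError(f"non-numeric entry in quantitative column: {exc}") from exc
    if cuts is None:
        if discretizer == "mdlp":
            cuts = mdl_discretize(numeric, class_codes[present])
        elif discretizer == "eqfreq":
            cuts = equal_frequency_discretize(numeric, n_bins)
        else:
            raise DataError(f"unknown discretizer {discretizer!r}")
    cuts = [float(c) for c in cuts]
    labels = bin_labels(cuts)
    codes = np.zeros(len(column), dtype=np.int64)
    codes[present] = apply_cuts(numeric, cuts)
    if not present.all():
        labels = labels + [MISSING]
        codes[~present] = len(labels) - 1
    return codes, labels, cuts


def read_csv_dataset(
    path: str | Path,
    schema: dict | str | Path | None = None,
    class_column: str | None = None,
    discretizer: str = "mdlp",
    n_bins: int = 3,
) -> Dataset:
    """Read a header-ful CSV into an integer-coded :class:`Dataset`.

    ``schema`` (dict or YAML path) may declare ``class_column``, the list of
    ``quantitative`` columns, the ``discretizer`` and fixed per-column
    ``cuts`` (so train and test share identical bins). Without a schema every
    column is categorical and the class column defaults to the last one.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if isinstance(schema, (str, Path)):
        schema = read_schema(schema)
    schema = dict(schema or {})
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise DataError("empty table") from exc
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed CSV: {exc}") from exc
    if frame.shape[0] == 0:
        raise DataError("empty table")

    class_column = schema.get("class_column", class_column)
    if class_column is None:
        class_column = frame.columns[-1]
    if class_column not in frame.columns:
        raise DataError(f"class column {class_column!r} not in header")
    quantitative = set(schema.get("quantitative", []))
    discretizer = schema.get("discretizer", discretizer)
    n_bins = int(schema.get("n_bins", n_bins))
    fixed_cuts: dict = schema.get("cuts", {}) or {}
    unknown = quantitative - set(frame.columns)
    if unknown:
        raise DataError(f"quantitative columns not in header: {sorted(unknown)}")
    if class_column in quantitative:
        raise DataError("class column cannot be quantitative")

    y, class_labels = _encode_categorical(frame[class_column].tolist())
    class_spec = AttributeSpec(name=class_column, value_labels=class_labels)

    specs: list[AttributeSpec] = []
    columns: list[np.ndarray] = []
    for name in frame.columns:
        if name == class_column:
            continue
        raw = frame[name].tolist()
        if name in quantitative:
            codes, labels, cuts = _encode_quantitative(
                raw, y, discretizer, n_bins, fixed_cuts.get(name)
            )
            specs.append(AttributeSpec(name=name, kind="quantitative", value_labels=labels, cuts=cuts))
        else:
            codes, labels = _encode_categorical(raw)
            specs.append(AttributeSpec(name=name, value_labels=labels))
        columns.append(codes)
    if not columns:
        raise DataError("no attribute columns besides the class")
    return Dataset(np.column_stack(columns), y, specs, class_spec)


# ---------------------------------------------------------------------------
# Cross-validation fold plans
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Stratified fold assignment: ``fold_assignment[i]`` is instance i's fold."""

    fold_assignment: np.ndarray
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment != fold)


def stratified_folds(dataset: Dataset, n_folds: int, seed: int) -> FoldPlan:
    """Deterministic stratified fold plan.

    Within each class (classes processed in ascending code order) instances
    are shuffled by the seeded generator, then dealt round-robin onto folds
    with a counter carried across classes, so fold sizes differ by at most
    one both overall and within every class.
    """
    if n_folds < 2:
        raise DataError("n_folds must be >= 2")
    if n_folds > dataset.n_instances:
        raise DataError("more folds than instances")
    rng = np.random.default_rng(seed)
    assignment = np.full(dataset.n_instances, -1, dtype=np.int64)
    counter = 0
    for c in range(dataset.n_classes):
        members = np.flatnonzero(dataset.y == c)
        rng.shuffle(members)
        for idx in members:
            assignment[idx] = counter % n_folds
            counter += 1
    return FoldPlan(assignment, n_folds, seed)
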