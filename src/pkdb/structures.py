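"""Network topology learning for k-dependence Bayesian classifiers.

Four ways to pick parent sets, all over the same count tables:

* eager KDB: order attributes by mutual information with the class, give the
  attribute at rank r the min(r-1, k) strongest higher-ranked attributes by
  conditional mutual information;
* lazy per-instance KDB_P: the same topology rules but with the local
  (per-value) measures evaluated at one unlabeled instance's values;
* redundant dependency elimination (RDE): filter a lazy structure with the
  pointwise ratio criterion PCMI(x_i; cand | top) >= delta * PMI(x_i; top),
  keeping at most one extra parent per attribute (k = 2 only), yielding KDB_O;
* NB (no attribute parents) and TAN (maximum spanning tree under CMI).

All orderings and argmaxes break ties deterministically toward the smaller
original attribute index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .infotheory import (
    ContingencyCounts,
    InfoConfig,
    conditional_local_mutual_information,
    conditional_mutual_information,
    local_mutual_information,
    mutual_information,
    pointwise_conditional_mutual_information,
    pointwise_mutual_information,
)

__all__ = [
    "NetworkStructure",
    "RdeConfig",
    "learn_kdb_structure",
    "learn_local_structure",
    "apply_rde",
    "learn_nb_structure",
    "learn_tan_structure",
    "aode_arc_count",
    "count_arcs",
    "structure_diff",
    "export_structure",
    "parse_edgelist",
]


@dataclass
class NetworkStructure:
    """Attribute ordering plus per-attribute parent sets.

    ``parents[i]`` lists the attribute parents of attribute ``i`` (the class
    is implicitly a parent of every attribute and is not listed). Every
    parent of an attribute precedes it in ``attribute_order`` and
    ``len(parents[i]) <= min(rank(i), k)``.
    """

    attribute_order: list[int]
    parents: list[list[int]]
    k: int
    origin: str = "eager"  # eager | lazy | lazy_rde
    anchored_instance: np.ndarray | None = None

    @property
    def n_attributes(self) -> int:
        return len(self.parents)

    def validate(self) -> None:
        rank = {a: r for r, a in enumerate(self.attribute_order)}
        if sorted(self.attribute_order) != list(range(self.n_attributes)):
            raise ValueError("attribute_order is not a permutation")
        for i, ps in enumerate(self.parents):
            if len(ps) > min(rank[i], self.k):
                raise ValueError(f"attribute {i} has too many parents")
            for p in ps:
                if rank[p] >= rank[i]:
                    raise ValueError(f"parent {p} does not precede child {i}")


@dataclass(frozen=True)
class RdeConfig:
    """Redundancy filter settings: minimum redundancy ratio delta >= 0.

    ``delta = math.inf`` is the remove-all sentinel: no candidate ever
    qualifies and every filtered attribute keeps a single parent. The filter
    itself is defined for ``k = 2`` only.
    """

    delta: float = 0.5
    k: int = 2

    def __post_init__(self) -> None:
        if not (self.delta >= 0):
            raise ValueError("delta must be finite and >= 0, or math.inf")


def _ordered_desc(scores: Sequence[float], items: Sequence[int]) -> list[int]:
    """Items sorted by score descending, ties toward the smaller item."""
    return [it for _, it in sorted(zip(scores, items), key=lambda t: (-t[0], t[1]))]


def learn_kdb_structure(
    counts: ContingencyCounts, k: int, cfg: InfoConfig | None = None
) -> NetworkStructure:
    """Eager KDB structure over the training counts.

    Attributes are listed in descending I(X_i; Y); the attribute at rank r
    (1-based) receives exactly min(r-1, k) parents, greedily the highest
    I(X_i; X_j | Y) among higher-ranked attributes.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n = counts.n_attributes
    if n < 1:
        raise ValueError("empty counts")
    mi = [mutual_information(counts, i, cfg) for i in range(n)]
    order = _ordered_desc(mi, list(range(n)))
    parents: list[list[int]] = [[] for _ in range(n)]
    for r, child in enumerate(order):
        if r == 0 or k == 0:
            continue
        cands = order[:r]
        cmis = [conditional_mutual_information(counts, child, p, cfg) for p in cands]
        parents[child] = _ordered_desc(cmis, cands)[: min(r, k)]
    return NetworkStructure(order, parents, k, origin="eager")


def learn_local_structure(
    counts: ContingencyCounts,
    instance: Sequence[int],
    k: int,
    cfg: InfoConfig | None = None,
) -> NetworkStructure:
    """Lazy KDB_P structure anchored to one unlabeled instance.

    Identical topology rules to the eager learner, but ordering uses the
    local mutual information I(x_i; Y) of the instance's attribute values
    and parent choice uses the conditional local mutual information
    I(x_i; x_j | Y) between value pairs. Unseen value codes behave as
    zero-count categories (score 0).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n = counts.n_attributes
    inst = np.asarray(instance, dtype=np.int64)
    if inst.shape != (n,):
        raise ValueError(f"instance length {inst.shape} does not match {n} attributes")
    lmi = [local_mutual_information(counts, i, int(inst[i]), cfg) for i in range(n)]
    order = _ordered_desc(lmi, list(range(n)))
    parents: list[list[int]] = [[] for _ in range(n)]
    for r, child in enumerate(order):
        if r == 0 or k == 0:
            continue
        cands = order[:r]
        clmis = [
            conditional_local_mutual_information(
                counts, child, int(inst[child]), p, int(inst[p]), cfg
            )
            for p in cands
        ]
        parents[child] = _ordered_desc(clmis, cands)[: min(r, k)]
    return NetworkStructure(order, parents, k, origin="lazy", anchored_instance=inst)


def apply_rde(
    structure: NetworkStructure,
    counts: ContingencyCounts,
    instance: Sequence[int],
    rde: RdeConfig,
    cfg: InfoConfig | None = None,
) -> NetworkStructure:
    """Filter a lazy structure's second parents by the redundancy ratio.

    For each attribute at rank >= k+2, rank all higher-ranked attribute
    values by conditional local mutual information (list L'); the strongest,
    L'[1], is always retained as sole guaranteed parent. Scanning the
    remaining candidates in L' order, the first whose pointwise conditional
    mutual information given L'[1] satisfies

        PCMI(x_i; cand | L'[1]) >= delta * PMI(x_i; L'[1])

    becomes the only second parent; if none qualifies the attribute keeps a
    single parent. When the reference PMI is non-positive (or carries no
    evidence) the ratio degenerates and a candidate qualifies iff its PCMI
    is strictly positive. Candidates whose pointwise score is undefined
    (zero joint count) are skipped. ``delta = inf`` disables qualification
    entirely. Idempotent; never increases the arc count.
    """
    if structure.origin not in ("lazy", "lazy_rde"):
        raise ValueError("RDE applies to lazy (per-instance) structures only")
    if rde.k != 2 or structure.k != 2:
        raise ValueError("redundancy elimination is defined for k = 2 only")
    n = structure.n_attributes
    inst = np.asarray(instance, dtype=np.int64)
    if inst.shape != (n,):
        raise ValueError("instance length does not match structure")
    if structure.anchored_instance is not None and not np.array_equal(
        structure.anchored_instance, inst
    ):
        raise ValueError("structure is anchored to a different instance")

    order = list(structure.attribute_order)
    parents = [list(p) for p in structure.parents]
    for r in range(rde.k + 1, n):  # 1-based rank k+2 .. n
        child = order[r]
        cands = order[:r]
        clmis = [
            conditional_local_mutual_information(
                counts, child, int(inst[child]), p, int(inst[p]), cfg
            )
            for p in cands
        ]
        lprime = _ordered_desc(clmis, cands)
        top = lprime[0]
        ref, ref_defined = pointwise_mutual_information(
            counts, child, int(inst[child]), top, int(inst[top]), cfg, return_flag=True
        )
        chosen: list[int] = [top]
        if not math.isinf(rde.delta):
            for cand in lprime[1:]:
                gain, defined = pointwise_conditional_mutual_information(
                    counts,
                    child,
                    int(inst[child]),
                    cand,
                    int(inst[cand]),
                    top,
                    int(inst[top]),
                    cfg,
                    return_flag=True,
                )
                if not defined:
                    continue  # no evidence for this value pair
                if ref_defined and ref > 0:
                    ok = gain >= rde.delta * ref
                else:
                    ok = gain > 0
                if ok:
                    chosen = [top, cand]
                    break
        parents[child] = chosen
    return NetworkStructure(
        order, parents, structure.k, origin="lazy_rde", anchored_instance=inst
    )


def learn_nb_structure(n: int) -> NetworkStructure:
    """Naive Bayes topology: no attribute parents at all."""
    if n < 1:
        raise ValueError("need at least one attribute")
    return NetworkStructure(list(range(n)), [[] for _ in range(n)], k=0, origin="eager")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def learn_tan_structure(
    counts: ContingencyCounts, cfg: InfoConfig | None = None
) -> NetworkStructure:
    """Tree-augmented naive Bayes: maximum spanning tree under CMI weights.

    Kruskal with edges sorted by (weight desc, i asc, j asc); the tree is
    rooted at attribute 0 and arcs point away from the root, giving exactly
    n-1 attribute arcs for n attributes.
    """
    n = counts.n_attributes
    if n < 1:
        raise ValueError("empty counts")
    if n == 1:
        return NetworkStructure([0], [[]], k=1, origin="eager")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = conditional_mutual_information(counts, i, j, cfg)
            edges.append((w, i, j))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = _UnionFind(n)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    taken = 0
    for w, i, j in edges:
        if uf.union(i, j):
            adj[i].append(j)
            adj[j].append(i)
            taken += 1
            if taken == n - 1:
                break
    # orient away from root 0, BFS with ascending-index neighbor order
    parents: list[list[int]] = [[] for _ in range(n)]
    order = [0]
    seen = {0}
    queue = [0]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adj[node]):
            if nb not in seen:
                seen.add(nb)
                parents[nb] = [node]
                order.append(nb)
                queue.append(nb)
    return NetworkStructure(order, parents, k=1, origin="eager")


def aode_arc_count(n: int) -> int:
    """Ordered parent->child attribute pairs across all superparent models.

    Each of the n one-dependence estimators conditions the other n-1
    attributes on its superparent, so the ensemble represents n(n-1)
    conditional dependencies.
    """
    if n < 1:
        raise ValueError("need at least one attribute")
    return n * (n - 1)


def count_arcs(structure: NetworkStructure) -> int:
    """Number of attribute->attribute arcs (implicit class arcs excluded)."""
    return sum(len(p) for p in structure.parents)


def structure_diff(before: NetworkStructure, after: NetworkStructure) -> dict:
    """Arc-level difference between two structures over the same attributes.

    Returns ``{"removed": [(p, c), ...], "added": [(p, c), ...]}`` in
    deterministic (child, parent) order. Used to annotate which dependencies
    a redundancy filter dropped or substituted.
    """
    def arcs(s: NetworkStructure) -> set[tuple[int, int]]:
        return {(p, c) for c, ps in enumerate(s.parents) for p in ps}

    a, b = arcs(before), arcs(after)
    key = lambda arc: (arc[1], arc[0])
    return {"removed": sorted(a - b, key=key), "added": sorted(b - a, key=key)}


def _arc_annotations(
    structure: NetworkStructure,
    counts: ContingencyCounts | None,
    cfg: InfoConfig | None,
    baseline: NetworkStructure | None,
) -> dict[tuple[int, int], str]:
    notes: dict[tuple[int, int], str] = {}
    inst = structure.anchored_instance
    if counts is not None and inst is not None:
        for child, ps in enumerate(structure.parents):
            for p in ps:
                score = conditional_local_mutual_information(
                    counts, child, int(inst[child]), p, int(inst[p]), cfg
                )
                notes[(p, child)] = f"clmi={score:.6g}"
    if baseline is not None:
        diff = structure_diff(baseline, structure)
        for p, c in diff["added"]:
            notes[(p, c)] = (notes.get((p, c), "") + " substituted").strip()
    return notes


def export_structure(
    structure: NetworkStructure,
    format: str = "edgelist",
    attribute_names: Sequence[str] | None = None,
    class_name: str = "Y",
    counts: ContingencyCounts | None = None,
    cfg: InfoConfig | None = None,
    baseline: NetworkStructure | None = None,
) -> str:
    """Render a structure as a tab-separated edge list or a DOT document.

    Class arcs are always included. Lazy structures with ``counts`` supplied
    annotate each attribute arc with its conditional local mutual
    information; passing the pre-filter structure as ``baseline`` marks
    substituted arcs and appends the arcs the filter removed.
    """
    n = structure.n_attributes
    names = list(attribute_names) if attribute_names else [f"X{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("attribute name count mismatch")
    notes = _arc_annotations(structure, counts, cfg, baseline)
    removed = structure_diff(baseline, structure)["removed"] if baseline else []

    if format == "edgelist":
        lines = [f"# order: {' '.join(str(i) for i in structure.attribute_order)}"]
        lines.append(f"# k: {structure.k}")
        lines.append(f"# origin: {structure.origin}")
        for child in structure.attribute_order:
            lines.append(f"{class_name}\t{names[child]}")
        for child in structure.attribute_order:
            for p in structure.parents[child]:
                note = notes.get((p, child), "")
                lines.append(f"{names[p]}\t{names[child]}" + (f"\t{note}" if note else ""))
        for p, c in removed:
            lines.append(f"# removed: {names[p]}\t{names[c]}")
        return "\n".join(lines) + "\n"
    if format == "dot":
        lines = [f'digraph "{structure.origin}" {{']
        lines.append(f'  "{class_name}" [shape=doublecircle];')
        for child in structure.attribute_order:
            lines.append(f'  "{class_name}" -> "{names[child]}" [style=dashed];')
        for child in structure.attribute_order:
            for p in structure.parents[child]:
                note = notes.get((p, child), "")
                attr = f' [label="{note}"]' if note else ""
                lines.append(f'  "{names[p]}" -> "{names[child]}"{attr};')
        for p, c in removed:
            lines.append(
                f'  "{names[p]}" -> "{names[c]}" [style=dotted, color=red, label="removed"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def parse_edgelist(
    text: str,
    attribute_names: Sequence[str] | None = None,
    class_name: str = "Y",
) -> NetworkStructure:
    """Parse an edge list produced by :func:`export_structure` (round-trip)."""
    order: list[int] | None = None
    k = 0
    origin = "eager"
    arcs: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# order:"):
            order = [int(t) for t in line.split(":", 1)[1].split()]
            continue
        if line.startswith("# k:"):
            k = int(line.split(":", 1)[1])
            continue
        if line.startswith("# origin:"):
            origin = line.split(":", 1)[1].strip()
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        arcs.append((parts[0], parts[1]))
    if order is None:
        raise ValueError("edge list lacks an order header")
    n = len(order)
    names = list(attribute_names) if attribute_names else [f"X{i}" for i in range(n)]
    index = {nm: i for i, nm in enumerate(names)}
    parents: list[list[int]] = [[] for _ in range(n)]
    for parent, child in arcs:
        if parent == class_name:
            continue
        parents[index[child]].append(index[parent])
    return NetworkStructure(order, parents, k=k, origin=origin)
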