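"""Neighbor-joining phylogenetics and subfamily assignment.

A multiple alignment of AOX and PTOX proteins, clustered by neighbor
joining on uncorrected p-distances, places the two families in clearly
separate clades; the same machinery, applied to the conserved 444 bp
amplicon fragment, resolves the AOX1 vs. AOX2 subfamilies but nothing
finer.  This module implements the Saitou-Nei neighbor-joining algorithm
from scratch, Newick serialization with deterministic ordering,
bipartition-based monophyly tests, and nearest-reference subfamily
assignment with a fragment guard: fragment-length queries are never given
member-level labels, because the conserved fragment carries no
member-level signal.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .seqio import GAP, SequenceRecord

#: Ungapped query length at or below which only subfamily-level calls are
#: made: 148 residues, one third of the 444 nt conserved amplicon.
FRAGMENT_THRESHOLD_AA = 148
FRAGMENT_THRESHOLD_NT = 444

_SUBFAMILY_RE = re.compile(r"(AOX[12])", re.IGNORECASE)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if v.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {v.shape} does not match {n} labels"
            )
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


class TreeNode:
    """A node of a phylogenetic tree; ``length`` is the branch to its parent."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None) -> None:
        self.label = label
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree, stored rooted at the final neighbor-joining join.

    The root is a trifurcation for trees of three or more leaves and
    carries no branch of its own.
    """

    root: TreeNode

    def leaf_labels(self) -> set[str]:
        return {leaf.label for leaf in self.root.leaves()}

    def total_branch_length(self) -> float:
        total = 0.0
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            total += node.length
            stack.extend(node.children)
        return total

    def bipartitions(self) -> Iterator[frozenset[str]]:
        """Leaf sets under each internal edge (edge above an internal node)."""
        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset({node.label})
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                yield_list.append(below)
            return below

        yield_list: list[frozenset[str]] = []
        walk(self.root)
        yield from yield_list


def p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Uncorrected p-distance with pairwise gap deletion.

    The proportion of differing residues over columns where neither
    sequence is gapped.  Unequal lengths or zero comparable columns are
    errors.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"p_distance: {a.id!r} ({len(a.residues)}) and {b.id!r} "
            f"({len(b.residues)}) have unequal aligned lengths"
        )
    comparable = 0
    diffs = 0
    for x, y in zip(a.residues, b.residues):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError(
            f"p_distance: {a.id!r} and {b.id!r} share no comparable columns"
        )
    return diffs / comparable


def poisson_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Poisson-corrected distance, ``-ln(1 - p)``; infinite at p = 1."""
    p = p_distance(a, b)
    if p >= 1.0:
        return math.inf
    return -math.log(1.0 - p)


def distance_matrix(
    records: Sequence[SequenceRecord],
    metric=p_distance,
) -> DistanceMatrix:
    """All pairwise distances between aligned records, input order preserved."""
    if len(records) < 2:
        raise ValueError("distance_matrix: need at least 2 records")
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = metric(records[i], records[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(r.id for r in records), values=values)


def _clamped(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(
            f"nj: negative branch length {length:.6g} at {context} clamped to 0",
            stacklevel=3,
        )
        return 0.0
    return length


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``;
    among minimal-Q pairs the lexicographically smallest index pair is
    joined, which makes the algorithm deterministic.  Branch lengths use
    the standard formulas; negatives are clamped to zero with a warning.
    On additive matrices the generating tree is recovered exactly.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("nj: need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    if n == 2:
        d = float(dm.values[0, 1])
        for node in nodes:
            node.length = d / 2.0
        return PhyloTree(root=TreeNode(children=nodes))
    D = dm.values.astype(float).copy()
    while D.shape[0] > 3:
        m = D.shape[0]
        S = D.sum(axis=1)
        # evaluate Q on the upper triangle only: row-major order makes
        # np.argmin's first-occurrence rule the lexicographic tie-break
        rows, cols = np.triu_indices(m, k=1)
        q = (m - 2) * D[rows, cols] - S[rows] - S[cols]
        best = int(np.argmin(q))
        i, j = int(rows[best]), int(cols[best])
        d_ij = D[i, j]
        li = 0.5 * d_ij + (S[i] - S[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        nodes[i].length = _clamped(li, f"join of {i},{j}")
        nodes[j].length = _clamped(lj, f"join of {i},{j}")
        joined = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], new_row[keep][:, None]]),
            np.hstack([new_row[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [joined]
    # final star over the three remaining nodes
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        (d_ab + d_ac - d_bc) / 2.0,
        (d_ab + d_bc - d_ac) / 2.0,
        (d_ac + d_bc - d_ab) / 2.0,
    )
    for node, length in zip(nodes, lengths):
        node.length = _clamped(length, "final star")
    return PhyloTree(root=TreeNode(children=nodes))


_NEWICK_UNSAFE = set(" \t\n()[]':;,")


def _newick_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode) -> tuple[str, str]:
    """(smallest contained leaf label, newick string) for deterministic order."""
    if node.is_leaf:
        return node.label, f"{_newick_label(node.label)}:{node.length:.6f}"
    parts = sorted(_newick_node(c) for c in node.children)
    inner = ",".join(text for _, text in parts)
    return parts[0][0], f"({inner}):{node.length:.6f}"


def to_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with branch lengths at 6-decimal fixed precision.

    Children are ordered lexicographically by their smallest contained leaf
    label, so serialization is deterministic: the same tree always yields
    byte-identical output.
    """
    root = tree.root
    if root.is_leaf:
        return f"{_newick_label(root.label)};"
    parts = sorted(_newick_node(c) for c in root.children)
    return "(" + ",".join(text for _, text in parts) + ");"


def path_lengths(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (sums of branch lengths)."""
    adjacency: dict[int, list[tuple[TreeNode, float]]] = {}
    node_by_id: dict[int, TreeNode] = {}

    def register(node: TreeNode) -> None:
        node_by_id[id(node)] = node
        adjacency.setdefault(id(node), [])
        for child in node.children:
            adjacency[id(node)].append((child, child.length))
            adjacency.setdefault(id(child), []).append((node, child.length))
            register(child)

    register(tree.root)
    leaves = sorted(tree.root.leaves(), key=lambda lf: lf.label)
    labels = [lf.label for lf in leaves]
    n = len(leaves)
    values = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        # Dijkstra is unnecessary: a tree has unique paths, BFS accumulates them
        dist = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for neighbor, w in adjacency[id(node)]:
                if id(neighbor) not in dist:
                    dist[id(neighbor)] = dist[id(node)] + w
                    stack.append(neighbor)
        for j, other in enumerate(leaves):
            values[i, j] = dist[id(other)]
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(labels=tuple(labels), values=values)


def is_separated(tree: PhyloTree, group: set[str]) -> bool:
    """True iff some internal edge splits exactly ``group`` from the rest.

    Unrooted monophyly: the group and its complement each form a clade on
    one side of a single internal edge.
    """
    leaves = tree.leaf_labels()
    unknown = set(group) - leaves
    if unknown:
        raise ValueError(f"is_separated: unknown leaf labels {sorted(unknown)}")
    if not group or set(group) == leaves:
        raise ValueError("is_separated: group must be a proper non-empty subset")
    target = frozenset(group)
    complement = frozenset(leaves - target)
    for below in tree.bipartitions():
        if below == target or below == complement:
            return True
    return False


@dataclass(frozen=True)
class SubfamilyAssignment:
    """Nearest-reference call for one query sequence.

    ``level`` is ``member`` (full-length query, unique nearest reference),
    ``subfamily`` (fragment guard applied, or nearest references tied
    within one subfamily), or ``unresolved`` (tie across subfamilies).
    ``margin`` is the distance separating the best subfamily from the
    second best (``inf`` when only one subfamily is represented).
    """

    query_id: str
    label: str
    level: str
    nearest_id: str
    distance: float
    margin: float


def subfamily_of(member_label: str) -> str:
    """AOX1/AOX2 subfamily of a member-level label such as ``AOX1a``."""
    match = _SUBFAMILY_RE.search(member_label)
    if not match:
        raise ValueError(
            f"cannot derive AOX subfamily from label {member_label!r}"
        )
    return match.group(1).upper()


def assign_subfamily(
    query: SequenceRecord,
    references: Sequence[SequenceRecord],
    labels: Mapping[str, str] | None = None,
    fragment_threshold: int = FRAGMENT_THRESHOLD_AA,
) -> SubfamilyAssignment:
    """Assign a query to an AOX subfamily (or member) by nearest reference.

    The query must be aligned into the reference column space.  The nearest
    reference by p-distance determines the call, with two guards:

    * fragment guard — when the query's ungapped length is at most
      ``fragment_threshold`` (default 148 residues, the 444 nt amplicon in
      amino acids), the returned label is truncated to subfamily level
      (AOX1 or AOX2) no matter how close the nearest member is;
    * tie guard — a query exactly equidistant from two subfamilies is
      ``unresolved``.
    """
    if not references:
        raise ValueError("assign_subfamily: no reference sequences")
    if labels is None:
        labels = {r.id: r.description or r.id for r in references}
    missing = [r.id for r in references if r.id not in labels]
    if missing:
        raise ValueError(f"assign_subfamily: no labels for references {missing}")
    dists = [(p_distance(query, ref), ref) for ref in references]
    best_by_subfamily: dict[str, float] = {}
    for d, ref in dists:
        sub = subfamily_of(labels[ref.id])
        if d < best_by_subfamily.get(sub, math.inf):
            best_by_subfamily[sub] = d
    ranked = sorted(best_by_subfamily.items(), key=lambda kv: (kv[1], kv[0]))
    best_sub, best_d = ranked[0]
    margin = (ranked[1][1] - best_d) if len(ranked) > 1 else math.inf
    nearest = min(dists, key=lambda dr: (dr[0], dr[1].id))
    if len(ranked) > 1 and margin == 0.0:
        return SubfamilyAssignment(
            query_id=query.id, label="unresolved", level="unresolved",
            nearest_id=nearest[1].id, distance=best_d, margin=0.0,
        )
    is_fragment = query.ungapped_length <= fragment_threshold
    if is_fragment:
        return SubfamilyAssignment(
            query_id=query.id, label=best_sub, level="subfamily",
            nearest_id=nearest[1].id, distance=best_d, margin=margin,
        )
    tied = sorted(
        {labels[ref.id] for d, ref in dists
         if d == best_d and subfamily_of(labels[ref.id]) == best_sub}
    )
    if len(tied) == 1:
        return SubfamilyAssignment(
            query_id=query.id, label=tied[0], level="member",
            nearest_id=nearest[1].id, distance=best_d, margin=margin,
        )
    return SubfamilyAssignment(
        query_id=query.id, label=best_sub, level="subfamily",
        nearest_id=nearest[1].id, distance=best_d, margin=margin,
    )


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a distance matrix in square (relaxed) PHYLIP format."""
    lines = [f"{len(dm)}"]
    for label, row in zip(dm.labels, dm.values):
        lines.append(label + "  " + "  ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square (relaxed) PHYLIP distance matrix."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in lines[1:n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=tuple(labels), values=np.array(rows))
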