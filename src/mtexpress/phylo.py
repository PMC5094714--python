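"""Haplogroup assignment and neighbor-joining phylogenetics.

Haplogroups are clades of mtDNA sequences identified by sets of defining
variants accumulated along the path from the phylogeny root.  Assignment
scores each candidate clade by the fraction of its cumulative (root-to-clade)
defining variants observed in a sample's variant list; recurrent variants —
the same (position, allele) arising on independent branches — are supported
throughout.  The tree-building side offers uncorrected p-distances with
pairwise deletion of uncalled sites and a standard neighbor-joining
agglomeration, which recovers the generating topology on additive matrices.
"""

from __future__ import annotations

import io as _io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo

__all__ = [
    "HaplogroupDefinition",
    "HaplogroupCall",
    "assign_haplogroup",
    "p_distance_matrix",
    "neighbor_joining",
    "check_monophyly",
]


@dataclass(frozen=True)
class HaplogroupDefinition:
    """A rooted clade tree with per-branch defining variants.

    Parameters
    ----------
    parent
        Mapping clade label -> parent label; the root maps to ``None``.
    defining
        Mapping clade label -> tuple of ``(position, derived_allele)``
        variants private to the branch leading into that clade.  The root
        must carry an empty set.
    reference_length
        Length of the coordinate frame (1-based positions must not
        exceed it).
    """

    parent: Mapping[str, str | None]
    defining: Mapping[str, tuple[tuple[int, str], ...]]
    reference_length: int = 16569

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots!r}")
        if self.defining.get(roots[0]):
            raise ValueError("root clade must have an empty defining set")
        for clade, variants in self.defining.items():
            if clade not in self.parent:
                raise ValueError(f"clade {clade!r} missing from parent map")
            for pos, allele in variants:
                if not 1 <= pos <= self.reference_length:
                    raise ValueError(
                        f"defining position {pos} of clade {clade!r} outside "
                        f"reference length {self.reference_length}"
                    )
                if allele not in "ACGT":
                    raise ValueError(f"invalid derived allele {allele!r}")
        # reject cycles / dangling parents
        for clade in self.parent:
            self.path(clade)

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    @property
    def clades(self) -> tuple[str, ...]:
        return tuple(self.parent)

    def path(self, clade: str) -> tuple[str, ...]:
        """Root-to-clade label path (inclusive of both ends)."""
        chain: list[str] = []
        node: str | None = clade
        seen: set[str] = set()
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle in haplogroup tree at {node!r}")
            seen.add(node)
            chain.append(node)
            if node not in self.parent:
                raise ValueError(f"clade {node!r} has no parent entry")
            node = self.parent[node]
        return tuple(reversed(chain))

    def depth(self, clade: str) -> int:
        return len(self.path(clade)) - 1

    def cumulative(self, clade: str) -> tuple[tuple[int, str], ...]:
        """All defining variants on the root-to-clade path, in path order."""
        out: list[tuple[int, str]] = []
        for node in self.path(clade):
            out.extend(self.defining.get(node, ()))
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        """Tabular (clade, parent, position, derived_allele) representation."""
        rows = []
        for clade in self.parent:
            variants = self.defining.get(clade, ())
            if not variants and self.parent[clade] is not None:
                rows.append((clade, self.parent[clade], pd.NA, pd.NA))
            for pos, allele in variants:
                rows.append((clade, self.parent[clade], pos, allele))
            if self.parent[clade] is None:
                rows.append((clade, "", pd.NA, pd.NA))
        return pd.DataFrame(
            rows, columns=["clade", "parent", "position", "derived_allele"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, reference_length: int = 16569
    ) -> "HaplogroupDefinition":
        parent: dict[str, str | None] = {}
        defining: dict[str, list[tuple[int, str]]] = {}
        for row in frame.itertuples(index=False):
            par = None if (pd.isna(row.parent) or row.parent == "") else str(row.parent)
            parent[str(row.clade)] = par
            defining.setdefault(str(row.clade), [])
            if not pd.isna(row.position):
                defining[str(row.clade)].append(
                    (int(row.position), str(row.derived_allele))
                )
        return cls(
            parent=parent,
            defining={c: tuple(v) for c, v in defining.items()},
            reference_length=reference_length,
        )


@dataclass(frozen=True)
class HaplogroupCall:
    """Result of assigning one sample to a haplogroup."""

    clade: str
    score: float
    unassigned: bool = False


def assign_haplogroup(
    variants: Iterable[tuple[int, str]],
    defs: HaplogroupDefinition,
    uncalled_positions: Iterable[int] = (),
) -> HaplogroupCall:
    """Assign the best-supported haplogroup for a sample's variant list.

    Each clade is scored as (observed cumulative defining variants) /
    (cumulative defining variants on its root path); private variants not in
    any defining set carry no penalty.  The deepest fully supported clade
    wins; among partially supported clades tied at the maximal score the
    shallowest is returned, to avoid overcalling depth.  A sample whose
    consensus is uncalled (N) at every defining position of the tree is
    flagged ``unassigned``.
    """
    variant_set = set(variants)
    uncalled = set(uncalled_positions)
    all_defining = {
        pos for clade in defs.clades for pos, _ in defs.cumulative(clade)
    }
    if all_defining and all_defining <= uncalled:
        return HaplogroupCall(defs.root, float("nan"), unassigned=True)

    scored: list[tuple[float, int, str]] = []  # (score, depth, clade)
    any_match = False
    for clade in defs.clades:
        cum = defs.cumulative(clade)
        if not cum:
            continue
        matched = sum(1 for v in cum if v in variant_set)
        if matched:
            any_match = True
            scored.append((matched / len(cum), defs.depth(clade), clade))

    if not any_match:
        # Nothing ties the sample to any branch: the root is the vacuous
        # assignment, with full score only when there is nothing to explain.
        return HaplogroupCall(defs.root, 1.0 if not variant_set else 0.0)

    best = max(s for s, _, _ in scored)
    candidates = [(d, c) for s, d, c in scored if s == best]
    if best == 1.0:
        pick_depth = max(d for d, _ in candidates)
    else:
        pick_depth = min(d for d, _ in candidates)
    clade = min(c for d, c in candidates if d == pick_depth)
    return HaplogroupCall(clade, best)


def p_distance_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise uncorrected p-distances with pairwise deletion of N sites.

    distance(a, b) = mismatches / compared sites, where any position that is
    ``N`` in either sequence is excluded from the comparison.  Raises if a
    pair has no comparable sites.
    """
    names = list(sequences)
    lengths = {len(sequences[n]) for n in names}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    arrs = {
        n: np.frombuffer(sequences[n].encode("ascii"), dtype=np.uint8)
        for n in names
    }
    n_code = ord("N")
    mat = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        a, b = arrs[names[i]], arrs[names[j]]
        comparable = (a != n_code) & (b != n_code)
        n_comp = int(comparable.sum())
        if n_comp == 0:
            raise ValueError(
                f"no comparable sites between {names[i]!r} and {names[j]!r}"
            )
        d = float((a[comparable] != b[comparable]).sum()) / n_comp
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{child.newick()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner})"


def neighbor_joining(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Standard Saitou–Nei agglomeration: at each step the pair minimizing
    Q(i,j) = (n-2)·d(i,j) − r(i) − r(j) is joined, with the usual
    branch-length formulas.  Ties in Q are broken toward the lexicographically
    smallest label pair, making the merge order deterministic.  Negative
    branch lengths are clamped to zero with the residual moved to the sibling
    branch.  On additive matrices the generating topology (and its path
    distances) are recovered.
    """
    labels = list(distances.index)
    if list(distances.columns) != labels:
        raise ValueError("distance matrix index and columns must match")
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = distances.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")

    nodes: list[_Node] = [_Node(name=str(lab)) for lab in labels]
    names: list[str] = [str(lab) for lab in labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: smallest (label_i, label_j) pair
        tied = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            ((int(a), int(b)) for a, b in tied if a < b),
            key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))),
        )
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dn[keep]
        d_new[:-1, -1] = dn[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [f"({names[i]},{names[j]})"]

    # terminal 3-taxon star: closed-form branch lengths
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    branches = []
    for node, length in zip(nodes, (la, lb, lc)):
        branches.append((node, max(length, 0.0)))
    root = _Node(children=branches)
    return root.newick() + ";"


def _bipartitions(newick: str) -> tuple[set[frozenset[str]], frozenset[str]]:
    tree = Phylo.read(_io.StringIO(newick), "newick")
    taxa = frozenset(t.name for t in tree.get_terminals())
    parts: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals() + tree.get_terminals():
        side = frozenset(t.name for t in clade.get_terminals())
        parts.add(side)
        parts.add(taxa - side)
    return parts, taxa


def check_monophyly(newick: str, taxa_subset: Iterable[str]) -> bool:
    """True iff some edge bipartition of the unrooted tree isolates the subset."""
    subset = frozenset(taxa_subset)
    parts, taxa = _bipartitions(newick)
    missing = subset - taxa
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if subset == taxa:
        return True
    return subset in parts


def tree_path_distances(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf patristic distances of a newick tree (branch-length sums)."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    terminals = tree.get_terminals()
    names = [t.name for t in terminals]
    mat = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        dist = tree.distance(terminals[i], terminals[j])
        mat[i, j] = mat[j, i] = dist
    return pd.DataFrame(mat, index=names, columns=names)
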