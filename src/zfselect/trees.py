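"""Phylogenetic trees: Newick I/O and neighbor-joining.

The in-memory tree is a minimal rooted representation (the likelihood model is
time-reversible, so the placement of the root does not affect any computed
quantity).  Parsing delegates to ``Bio.Phylo``; neighbor-joining delegates to
Biopython's ``DistanceTreeConstructor`` with taxa pre-sorted lexicographically
so that tie-breaks are deterministic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

__all__ = ["Clade", "Tree", "parse_newick", "write_newick", "neighbor_joining"]


@dataclass
class Clade:
    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Clade

    def leaves(self) -> list[Clade]:
        return [c for c in self.postorder() if c.is_leaf]

    def leaf_names(self) -> list[str]:
        return [c.name for c in self.leaves()]

    def postorder(self) -> list[Clade]:
        out: list[Clade] = []

        def walk(node: Clade) -> None:
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def total_branch_length(self) -> float:
        return sum(c.length for c in self.postorder() if c is not self.root)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side leaf sets by name)."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: Clade) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return out

    def copy(self) -> "Tree":
        def dup(node: Clade) -> Clade:
            return Clade(node.name, node.length, [dup(c) for c in node.children])

        return Tree(dup(self.root))


def _check_newick(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"newick parse error: unbalanced ')' at offset {i}")
    if depth != 0:
        raise ValueError("newick parse error: unbalanced '(' at end of input")
    if ";" not in text:
        raise ValueError(
            f"newick parse error: missing ';' terminator at offset {len(text)}"
        )


def _from_biopython(clade) -> Clade:
    node = Clade(
        name=clade.name,
        length=float(clade.branch_length) if clade.branch_length else 0.0,
        children=[_from_biopython(c) for c in clade.clades],
    )
    if node.length < 0:
        warnings.warn(f"negative branch length clipped to 0 on {node.name!r}")
        node.length = 0.0
    return node


def parse_newick(text: str) -> Tree:
    """Parse a Newick string; missing branch lengths become 0."""
    _check_newick(text)
    bio = Phylo.read(io.StringIO(text), "newick")
    return Tree(_from_biopython(bio.root))


def write_newick(tree: Tree) -> str:
    def render(node: Clade, top: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(render(c, False) for c in node.children) + ")"
            if node.name:
                body += node.name
        return body if top else f"{body}:{node.length:g}"

    return render(tree.root, True) + ";"


def neighbor_joining(labels, matrix) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    ``matrix`` is a square array-like indexed consistently with ``labels``.
    Taxa are sorted lexicographically before agglomeration (deterministic
    tie-breaks); negative branch lengths are clipped to 0 with a warning.
    """
    labels = list(labels)
    d = np.asarray(matrix, dtype=float)
    if len(labels) < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if d.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    names = [labels[i] for i in order]
    d = d[np.ix_(order, order)]
    lower = [[float(d[i, j]) for j in range(i + 1)] for i in range(len(names))]
    dm = DistanceMatrix(names, lower)
    bio = DistanceTreeConstructor().nj(dm)
    root = _from_biopython(bio.root)

    # drop biopython's autogenerated internal labels
    def strip(node: Clade) -> None:
        if node.children and node.name and node.name.startswith("Inner"):
            node.name = None
        for c in node.children:
            strip(c)

    strip(root)
    return Tree(root)
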