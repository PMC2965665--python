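"""Neighbor-joining trees and tree-based sequence QC flags.

Implements the Saitou–Nei agglomeration on a complete distance matrix,
with deterministic (lexicographic) tie-breaking so trees are reproducible,
and the two tree-level screens used to weed out suspect barcodes: leaves
on conspicuously long terminal branches, and leaves whose closest relative
in the tree belongs to a different higher taxon than their own label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_seq import SpecimenRecord, ValidationError, records_by_sequence
from .distance_k2p import DistanceMatrix


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree serialized with an arbitrary trifurcating root."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def terminal_branch_lengths(self) -> dict:
        out: dict = {}

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                if child.is_leaf:
                    out[child.name] = length
                else:
                    walk(child)

        walk(self.root)
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """All leaf-to-leaf path lengths (sum of branch lengths)."""
        names = self.leaves()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            merged: dict = {}
            for child, length in node.children:
                sub = walk(child)
                sub = {k: v + length for k, v in sub.items()}
                for a, da in merged.items():
                    for b, db in sub.items():
                        D[a, b] = D[b, a] = da + db
                merged.update(sub)
            return merged

        walk(self.root)
        return pd.DataFrame(D, index=names, columns=names)


def nj(m: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j; exact Q
    ties break on the lexicographically smallest taxon-id pair (internal
    nodes are keyed by the smallest leaf id beneath them).  Negative
    branch lengths are clamped to zero with the deficit moved onto the
    sibling edge, preserving path lengths.
    """
    n = len(m.taxa)
    if n < 2:
        raise ValidationError("NJ needs at least 2 taxa")
    if not m.is_complete():
        raise ValidationError(
            f"distance matrix has missing entries: {m.excluded}")
    if not np.allclose(m.d, m.d.T, atol=1e-12, equal_nan=True):
        raise ValidationError("distance matrix is not symmetric")
    if n == 2:
        half = float(m.d[0, 1]) / 2.0
        root = TreeNode(children=[(TreeNode(name=m.taxa[0]), half),
                                  (TreeNode(name=m.taxa[1]), half)])
        return PhyloTree(root)

    D = m.d.astype(float).copy()
    nodes = [TreeNode(name=t) for t in m.taxa]
    keys = list(m.taxa)

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q is symmetric only up to rounding of the subtraction order, so
        # normalize candidate pairs instead of filtering one triangle
        cand = {(min(a, b), max(a, b)) for a, b in np.argwhere(Q == qmin)}
        i, j = min(cand,
                   key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        Dk = D[np.ix_(keep, keep)]
        row = dnew[keep]
        D = np.zeros((k - 1, k - 1))
        D[:-1, :-1] = Dk
        D[-1, :-1] = row
        D[:-1, -1] = row
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # trifurcating root from the last three nodes
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode(children=[(nodes[0], max(a, 0.0)),
                              (nodes[1], max(b, 0.0)),
                              (nodes[2], max(c, 0.0))])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Newick serialization

def _quote_label(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree) -> str:
    """Newick with branch lengths at 6 decimal places."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote_label(node.name)
        inner = ",".join(f"{fmt(child)}:{length:.6f}"
                         for child, length in node.children)
        return f"({inner})"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Tree-based QC flags

@dataclass(frozen=True)
class LeafFlags:
    leaf: str
    terminal_branch_length: float
    long_branch: bool
    taxonomic_outlier: bool
    nearest_leaf: str
    nearest_higher_taxon: str


def flag_tree_outliers(tree: PhyloTree,
                       records: Sequence[SpecimenRecord],
                       c_long: float = 3.0) -> dict:
    """Flag leaves on long terminal branches and taxonomic misplacements.

    ``long_branch``: terminal branch > c_long x median terminal branch.
    ``taxonomic_outlier``: the leaf's nearest leaf by path length carries a
    different higher-taxon label *and* the leaf is long-branched — both
    lines of evidence are required, because a long branch alone may simply
    reflect sparse taxon sampling.
    """
    rec_map = records_by_sequence(records)
    leaves = tree.leaves()
    for leaf in leaves:
        if leaf not in rec_map:
            raise ValidationError(f"no specimen record for leaf {leaf!r}")
        if not rec_map[leaf].higher_taxon:
            raise ValidationError(f"leaf {leaf!r} lacks a higher_taxon label")
    terminal = tree.terminal_branch_lengths()
    median = float(np.median(list(terminal.values())))
    paths = tree.leaf_distances()
    flags: dict = {}
    for leaf in leaves:
        others = [l for l in leaves if l != leaf]
        nearest = min(others, key=lambda o: (paths.loc[leaf, o], o))
        long_branch = terminal[leaf] > c_long * median
        different = (rec_map[nearest].higher_taxon
                     != rec_map[leaf].higher_taxon)
        flags[leaf] = LeafFlags(
            leaf=leaf,
            terminal_branch_length=float(terminal[leaf]),
            long_branch=long_branch,
            taxonomic_outlier=long_branch and different,
            nearest_leaf=nearest,
            nearest_higher_taxon=rec_map[nearest].higher_taxon,
        )
    return flags


def write_flag_report(flags: dict, path) -> None:
    rows = [{
        "leaf": f.leaf,
        "terminal_branch": f.terminal_branch_length,
        "long_branch": f.long_branch,
        "taxonomic_outlier": f.taxonomic_outlier,
        "nearest_leaf": f.nearest_leaf,
    } for f in flags.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
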