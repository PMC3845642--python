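"""Neighbor-joining trees, bootstrap supports, and clade queries.

The NJ agglomeration uses the rate-corrected Q criterion with deterministic
lexicographic tie-breaking, and clamps negative branch lengths to zero,
moving the deficit to the sister branch of the same join so path lengths
are preserved. Bootstrap supports come from codon-column (or site)
resampling; each internal edge is annotated with the percentage of
replicate trees containing its bipartition. Tree storage and Newick I/O
are backed by dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "neighbor_joining",
    "bootstrap_support",
    "is_monophyletic",
    "parse_newick",
    "write_newick",
]


@dataclass
class PhyloTree:
    """A phylogenetic tree (wrapper around a dendropy Tree).

    Tip labels are gene identifiers or species codes; internal edges may
    carry a ``support`` percentage in [0, 100] (stored on the head node).
    """

    tree: dendropy.Tree

    # -- basic queries ------------------------------------------------------

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    def find_tip(self, label: str) -> dendropy.Node:
        node = self.tree.find_node_with_taxon_label(label)
        if node is None:
            raise KeyError(f"tip {label!r} not in tree")
        return node

    def rooted_on(self, outgroup: str) -> "PhyloTree":
        """Return a copy rooted on the edge leading to ``outgroup``."""
        out = self.clone()
        node = out.tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise KeyError(f"outgroup {outgroup!r} not in tree")
        length = node.edge.length
        out.tree.is_rooted = True
        out.tree.reroot_at_edge(
            node.edge,
            length1=(length / 2 if length else None),
            length2=(length / 2 if length else None),
            update_bipartitions=False)
        return out

    def clade_tips(self, labels: Sequence[str]) -> set[str]:
        """Tip labels of the smallest clade containing ``labels`` (rooted tree)."""
        taxa = [self.find_tip(lbl).taxon for lbl in labels]
        mrca = self.tree.mrca(taxa=taxa)
        return {leaf.taxon.label for leaf in mrca.leaf_iter()}

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as frozensets of the smaller side's tips."""
        all_tips = frozenset(self.tip_labels())
        out = set()
        for node in self.tree.preorder_internal_node_iter():
            if node is self.tree.seed_node:
                continue
            side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            if 1 < len(side) < len(all_tips) - 1:
                other = all_tips - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def as_newick(self) -> str:
        return write_newick(self)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; numeric internal labels become supports."""
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = None
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with supports (when present) as internal node labels."""
    clone = tree.clone()
    for node in clone.tree.preorder_internal_node_iter():
        support = getattr(node, "support", None)
        if support is not None:
            node.label = f"{support:g}"
    return clone.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True).strip()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(matrix: pd.DataFrame,
                     flags: Optional[pd.DataFrame] = None) -> PhyloTree:
    """Standard NJ on a symmetric distance matrix.

    Ties in the Q criterion break lexicographically on the pair of cluster
    labels (a cluster is labelled by its smallest tip). Negative branch
    lengths are clamped to zero with the deficit moved to the sister branch
    of the same join. Flagged (saturated) matrices are refused.
    """
    if flags is not None and flags.to_numpy().any():
        raise ValueError("distance matrix contains saturated entries; "
                         "NJ refuses flagged matrices")
    labels = [str(x) for x in matrix.index]
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(matrix.to_numpy()).any():
        raise ValueError("distance matrix contains NaN entries")
    if not np.allclose(matrix.to_numpy(), matrix.to_numpy().T):
        raise ValueError("distance matrix is not symmetric")

    taxa = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    minlab: dict[str, str] = {}
    for lbl in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lbl))
        nodes[lbl] = node
        minlab[lbl] = lbl

    D: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            D[frozenset((a, b))] = float(matrix.loc[a, b])

    def d(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    active = list(labels)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = tuple(sorted((minlab[a], minlab[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        va = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        vb = d(a, b) - va
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        new = dendropy.Node()
        nodes[a].edge.length = va
        nodes[b].edge.length = vb
        new.add_child(nodes[a])
        new.add_child(nodes[b])
        key = f"@{counter}"
        counter += 1
        nodes[key] = new
        minlab[key] = min(minlab[a], minlab[b])
        for c in active:
            if c in (a, b):
                continue
            D[frozenset((key, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [key]

    # final three-way join (three-point formulas)
    a, b, c = active
    root = dendropy.Node()
    va = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    vb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    vc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for child, v in ((a, va), (b, vb), (c, vc)):
        nodes[child].edge.length = max(v, 0.0)
        root.add_child(nodes[child])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(tree_builder: Callable[[np.ndarray], PhyloTree],
                      tree: PhyloTree, n_columns: int,
                      replicates: int, seed: int) -> tuple[PhyloTree, int]:
    """Annotate ``tree`` with bootstrap supports.

    ``tree_builder`` maps an array of resampled column indices to a
    replicate tree (it closes over the alignment and distance model).
    Replicates whose matrix is degenerate (saturated or otherwise
    unbuildable) are dropped and counted. Supports are percentages of
    usable replicates containing each internal bipartition.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    used = 0
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_columns, size=n_columns)
        try:
            rep = tree_builder(cols)
        except (ValueError, ZeroDivisionError):
            dropped += 1
            continue
        used += 1
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    if used == 0:
        raise ValueError("all bootstrap replicates degenerate")

    out = tree.clone()
    all_tips = frozenset(t for t in tree.tip_labels())
    for node in out.tree.preorder_internal_node_iter():
        if node is out.tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if not (1 < len(side) < len(all_tips) - 1):
            continue
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(canon, 0) / used
    return out, dropped


def is_monophyletic(tree: PhyloTree, tips: set[str] | Sequence[str],
                    outgroup: Optional[str] = None) -> bool:
    """True iff the smallest clade containing ``tips`` contains no others.

    Unrooted trees must supply an ``outgroup`` tip used for rooting.
    """
    tips = set(tips)
    known = set(tree.tip_labels())
    unknown = tips - known
    if unknown:
        raise KeyError(f"unknown tips {sorted(unknown)!r}")
    if len(tips) <= 1 or tips == known - ({outgroup} if outgroup else set()):
        return True
    work = tree
    if outgroup is not None:
        work = tree.rooted_on(outgroup)
    elif not tree.rooted:
        raise ValueError("unrooted tree: an outgroup is required")
    return work.clade_tips(sorted(tips)) == tips
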