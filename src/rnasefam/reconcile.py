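"""Duplication/loss mapping on the species phylogeny.

Two complementary procedures: LCA reconciliation of a rooted gene tree
against the species tree (duplications where a node maps to the same
species-tree node as one of its children; losses by the standard
gap-filling rule along species-tree paths), and Dollo minimum-loss
counting from a presence/absence pattern under a single-origin assumption
(each loss is placed on the highest branch whose entire descendant set
lacks the gene).

The bundled species tree covers the 20 study mammals with approximate
divergence times (My) as branch lengths and named internal nodes
(Eutheria, Theria, Caniformia, Hystricognathi, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import dendropy

from . import seq_io
from .phylo import PhyloTree, parse_newick

__all__ = [
    "SpeciesTree",
    "ReconciliationResult",
    "load_species_tree",
    "lca_reconcile",
    "dollo_min_losses",
]


def _branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "+".join(tips)


@dataclass
class SpeciesTree:
    """A rooted species phylogeny over species codes."""

    phylo: PhyloTree

    def __post_init__(self) -> None:
        self.phylo.tree.is_rooted = True
        self._parent: dict[dendropy.Node, Optional[dendropy.Node]] = {}
        self._depth: dict[dendropy.Node, int] = {}
        self._tipmap: dict[str, dendropy.Node] = {}
        for node in self.phylo.tree.preorder_node_iter():
            parent = node.parent_node
            self._parent[node] = parent
            self._depth[node] = 0 if parent is None else self._depth[parent] + 1
            if node.is_leaf():
                self._tipmap[node.taxon.label] = node

    @property
    def species(self) -> list[str]:
        return sorted(self._tipmap)

    def tip(self, code: str) -> dendropy.Node:
        try:
            return self._tipmap[code]
        except KeyError:
            raise KeyError(f"species {code!r} not in species tree") from None

    def node_by_label(self, label: str) -> dendropy.Node:
        if label in self._tipmap:
            return self._tipmap[label]
        for node in self.phylo.tree.preorder_internal_node_iter():
            if node.label == label:
                return node
        raise KeyError(f"no species-tree node labelled {label!r}")

    def depth(self, node: dendropy.Node) -> int:
        return self._depth[node]

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self._depth[a] > self._depth[b]:
            a = self._parent[a]
        while self._depth[b] > self._depth[a]:
            b = self._parent[b]
        while a is not b:
            a = self._parent[a]
            b = self._parent[b]
        return a

    def clade_species(self, node: dendropy.Node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}


def load_species_tree(path=None) -> SpeciesTree:
    """Load the bundled 20-mammal dated species tree (or a user Newick)."""
    p = path or seq_io.data_path("species_tree_20mammals.nwk")
    with open(p) as fh:
        tree = parse_newick(fh.read())
    return SpeciesTree(phylo=tree)


@dataclass
class ReconciliationResult:
    """Duplication and loss events assigned to species-tree branches."""

    duplications: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)

    @property
    def total_dups(self) -> int:
        return sum(self.duplications.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


def lca_reconcile(gene_tree: PhyloTree, species_tree: SpeciesTree,
                  species_of: dict[str, str]) -> ReconciliationResult:
    """LCA-map a rooted gene tree onto the species tree.

    A gene-tree node is a duplication iff its species mapping equals that
    of one of its children; losses are counted by the gap-filling rule and
    placed on the species branch of each off-path sibling subtree.
    """
    if not gene_tree.rooted:
        raise ValueError("gene tree must be rooted (supply an outgroup first)")
    result = ReconciliationResult()
    mapping: dict[dendropy.Node, dendropy.Node] = {}

    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in species_of:
                raise KeyError(f"gene tip {label!r} has no species mapping")
            mapping[node] = species_tree.tip(species_of[label])
            continue
        children = node.child_nodes()
        m = mapping[children[0]]
        for c in children[1:]:
            m = species_tree.lca(m, mapping[c])
        mapping[node] = m
        is_dup = any(mapping[c] is m for c in children)
        if is_dup:
            lbl = _branch_label(m)
            result.duplications[lbl] = result.duplications.get(lbl, 0) + 1
        for c in children:
            _count_path_losses(mapping[c], m, is_dup, species_tree, result)
    return result


def _count_path_losses(lower: dendropy.Node, upper: dendropy.Node,
                       at_duplication: bool, stree: SpeciesTree,
                       result: ReconciliationResult) -> None:
    """Losses for a gene lineage passing from species node ``upper`` down to
    ``lower``: one per off-path child at every strictly intermediate node,
    plus one at ``upper`` itself when the parent gene node is a duplication."""
    path = []
    node = lower
    while node is not upper:
        path.append(node)
        node = stree._parent[node]
        if node is None:
            raise ValueError("mapping path escaped the species tree root")
    # path[k] is on-path child of path[k+1] (or of upper for the last entry)
    for k in range(1, len(path)):
        _loss_at(path[k], path[k - 1], result)
    if at_duplication and path:
        _loss_at(upper, path[-1], result)


def _loss_at(species_node: dendropy.Node, on_path_child: dendropy.Node,
             result: ReconciliationResult) -> None:
    for child in species_node.child_nodes():
        if child is not on_path_child:
            lbl = _branch_label(child)
            result.losses[lbl] = result.losses.get(lbl, 0) + 1


def dollo_min_losses(presence: dict[str, bool], species_tree: SpeciesTree,
                     origin: Optional[str] = None) -> tuple[int, list[str]]:
    """Minimum independent losses under single-origin (Dollo) parsimony.

    ``presence`` maps species codes to functional presence. ``origin`` is a
    species-tree node label ancestral to all present species (default: their
    MRCA). Species in the origin clade missing from ``presence`` are treated
    as absent with a warning. Each loss sits on the highest branch whose
    whole descendant species set lacks the gene. Returns (count, branches).
    """
    present = {sp for sp, ok in presence.items() if ok}
    if not present:
        raise ValueError("no species has the gene: origin undefined")
    nodes = [species_tree.tip(sp) for sp in sorted(present)]
    mrca = nodes[0]
    for n in nodes[1:]:
        mrca = species_tree.lca(mrca, n)
    if origin is None:
        origin_node = mrca
    else:
        origin_node = species_tree.node_by_label(origin)
        clade = species_tree.clade_species(origin_node)
        outside = present - clade
        if outside:
            raise ValueError(f"present species outside origin clade: "
                             f"{sorted(outside)}")
    clade = species_tree.clade_species(origin_node)
    unscored = clade - set(presence)
    if unscored:
        warnings.warn(f"species without presence data treated as absent: "
                      f"{sorted(unscored)}", stacklevel=2)

    has: dict[dendropy.Node, bool] = {}
    for node in origin_node.postorder_iter():
        if node.is_leaf():
            has[node] = node.taxon.label in present
        else:
            has[node] = any(has[c] for c in node.child_nodes())
    branches = []
    for node in origin_node.preorder_iter():
        if node is origin_node:
            continue
        parent = node.parent_node
        if has[parent] and not has[node]:
            branches.append(_branch_label(node))
    return len(branches), sorted(branches)
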