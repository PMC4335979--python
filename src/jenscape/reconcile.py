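"""Duplication-loss parsimony reconciliation of a rooted gene tree against
a rooted species tree.

The LCA (lowest-common-ancestor) mapping sends each gene-tree node to the
species-tree LCA of the species of its descendant genes; it is the unique
reconciliation minimizing duplications, and with losses charged for the
species branches skipped by child mappings it also minimizes the total
duplication + loss count.  A gene node is a duplication iff its image
equals the image of one of its children; losses on a gene edge (v, c)
number ``path_edges(M(v), M(c)) - 1`` when v is a speciation and
``path_edges`` when v is a duplication, each placed on the species branch
skipped by the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .io_formats import TreeNode

SPECIATION = "speciation"
DUPLICATION = "duplication"


def leaf_map_from_names(gene_tree: TreeNode, sep: str = "__") -> Dict[str, str]:
    """Derive the gene-leaf -> species map from ``species__copy`` naming."""
    mapping = {}
    for name in gene_tree.leaf_names():
        if sep not in name:
            raise ValueError(f"gene leaf {name!r} lacks the {sep!r} species separator")
        mapping[name] = name.split(sep)[0]
    return mapping


class _SpeciesIndex:
    """Parent/ancestor bookkeeping for a rooted species tree."""

    def __init__(self, species_tree: TreeNode):
        self.root = species_tree
        self.depth: Dict[int, int] = {}
        self.by_name: Dict[str, TreeNode] = {}
        counter = 0
        for node in species_tree.preorder():
            parent = node.parent
            self.depth[id(node)] = 0 if parent is None else self.depth[id(parent)] + 1
            if node.name is None:
                counter += 1
                node.name = f"n{counter}"
            if node.name in self.by_name:
                raise ValueError(f"duplicate species-tree node name {node.name!r}")
            self.by_name[node.name] = node

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self.depth[id(a)], self.depth[id(b)]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def path_down(self, top: TreeNode, bottom: TreeNode) -> List[TreeNode]:
        """Nodes from ``top`` down to ``bottom`` inclusive; top must be an
        ancestor-or-equal of bottom."""
        path = [bottom]
        node = bottom
        while node is not top:
            node = node.parent
            if node is None:
                raise ValueError("path_down: top is not an ancestor of bottom")
            path.append(node)
        return list(reversed(path))

    def other_child(self, parent: TreeNode, child: TreeNode) -> TreeNode:
        a, b = parent.children
        return b if a is child else a


@dataclass
class ReconciliationResult:
    gene_tree: TreeNode
    species_tree: TreeNode
    mapping: Dict[int, TreeNode]          # id(gene node) -> species node
    events: Dict[int, str]                # id(internal gene node) -> event
    losses: List[Tuple[Tuple[TreeNode, TreeNode], TreeNode]]
    n_duplications: int
    n_losses: int
    _index: _SpeciesIndex = field(repr=False, default=None)

    def species_of(self, gene_node: TreeNode) -> TreeNode:
        return self.mapping[id(gene_node)]

    def event_of(self, gene_node: TreeNode) -> str:
        return self.events[id(gene_node)]


def _check_binary(tree: TreeNode, label: str) -> None:
    for node in tree.preorder():
        if node.children and len(node.children) != 2:
            raise ValueError(
                f"{label} tree has a non-binary node "
                f"({len(node.children)} children); resolve polytomies first"
            )


def lca_reconcile(gene_tree: TreeNode, species_tree: TreeNode,
                  leaf_map: Optional[Dict[str, str]] = None) -> ReconciliationResult:
    """Minimum duplication-loss reconciliation via the LCA mapping.

    ``leaf_map`` sends every gene leaf name to a species leaf name; by
    default it is derived from ``species__copy`` leaf naming.
    """
    _check_binary(gene_tree, "gene")
    _check_binary(species_tree, "species")
    if leaf_map is None:
        leaf_map = leaf_map_from_names(gene_tree)
    index = _SpeciesIndex(species_tree)

    species_leaves = {leaf.name: leaf for leaf in species_tree.leaves()}
    mapping: Dict[int, TreeNode] = {}
    events: Dict[int, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf():
            if node.name not in leaf_map:
                raise ValueError(f"gene leaf {node.name!r} missing from leaf map")
            species_name = leaf_map[node.name]
            if species_name not in species_leaves:
                raise ValueError(
                    f"gene leaf {node.name!r} maps to unknown species {species_name!r}"
                )
            mapping[id(node)] = species_leaves[species_name]
        else:
            c1, c2 = node.children
            m = index.lca(mapping[id(c1)], mapping[id(c2)])
            mapping[id(node)] = m
            if m is mapping[id(c1)] or m is mapping[id(c2)]:
                events[id(node)] = DUPLICATION
            else:
                events[id(node)] = SPECIATION

    losses: List[Tuple[Tuple[TreeNode, TreeNode], TreeNode]] = []
    for node in gene_tree.preorder():
        if node.is_leaf():
            continue
        mv = mapping[id(node)]
        dup = events[id(node)] == DUPLICATION
        for child in node.children:
            mc = mapping[id(child)]
            path = index.path_down(mv, mc)  # mv .. mc inclusive
            # skipped species nodes where the lineage failed to keep its
            # sister copy: interior nodes always; mv itself only after a
            # duplication (the copy was already present at mv)
            start = 0 if dup else 1
            for k in range(start, len(path) - 1):
                skipped = index.other_child(path[k], path[k + 1])
                losses.append(((node, child), skipped))

    n_dup = sum(1 for e in events.values() if e == DUPLICATION)
    return ReconciliationResult(gene_tree, species_tree, mapping, events,
                                losses, n_dup, len(losses), index)


def clade_event_summary(result: ReconciliationResult,
                        species_clade) -> Tuple[int, int, int]:
    """(duplications, losses, total) placed on branches within the clade,
    including the clade's stem branch."""
    if isinstance(species_clade, str):
        node = result._index.by_name.get(species_clade)
        if node is None:
            raise ValueError(f"unknown species clade {species_clade!r}")
    else:
        node = species_clade
    clade_ids = {id(n) for n in node.preorder()}
    dups = sum(
        1 for gid, ev in result.events.items()
        if ev == DUPLICATION and id(result.mapping[gid]) in clade_ids
    )
    loss = sum(1 for _, branch in result.losses if id(branch) in clade_ids)
    return dups, loss, dups + loss


def scenario_report(result: ReconciliationResult,
                    species_tree: Optional[TreeNode] = None) -> pd.DataFrame:
    """Per species-branch bookkeeping: events placed and gene-copy flow.

    Each species branch is identified by its lower node's name (the root's
    stem is a virtual branch).  Copy counts are derived from the lineage
    segments implied by the reconciliation, so the identity
    ``copies_out == copies_in + duplications - losses`` is an emergent
    consistency check, not an assignment.
    """
    species_tree = species_tree or result.species_tree
    index = result._index
    entering: Dict[int, int] = {}
    leaving: Dict[int, int] = {}
    dups: Dict[int, int] = {}
    loss_count: Dict[int, int] = {}
    for node in species_tree.preorder():
        entering[id(node)] = leaving[id(node)] = 0
        dups[id(node)] = loss_count[id(node)] = 0

    for gid, ev in result.events.items():
        if ev == DUPLICATION:
            dups[id(result.mapping[gid])] += 1
    for _, branch in result.losses:
        loss_count[id(branch)] += 1
        entering[id(branch)] += 1  # the side lineage that entered and died

    gene_root = result.gene_tree
    m_root = result.species_of(gene_root)
    entering[id(m_root)] += 1  # founding lineage enters the stem
    is_dup = {gid: ev == DUPLICATION for gid, ev in result.events.items()}

    def crosses_bottom(child: TreeNode) -> bool:
        # a lineage reaches the species node at the bottom of its last
        # branch unless it is consumed there by a duplication
        return child.is_leaf() or not is_dup[id(child)]

    if crosses_bottom(gene_root):
        leaving[id(m_root)] += 1

    for node in result.gene_tree.preorder():
        if node.is_leaf():
            continue
        mv = result.species_of(node)
        dup = is_dup[id(node)]
        for child in node.children:
            mc = result.species_of(child)
            path = index.path_down(mv, mc)
            if dup:
                # born inside the branch of mv; crosses its bottom unless
                # it ends there consumed by another duplication
                if len(path) > 1 or crosses_bottom(child):
                    leaving[id(mv)] += 1
                traversed = path[1:]
            else:
                traversed = path[1:]
            for k, s in enumerate(traversed):
                entering[id(s)] += 1
                last = k == len(traversed) - 1
                if not last or crosses_bottom(child):
                    leaving[id(s)] += 1

    rows = []
    for node in species_tree.preorder():
        rows.append({
            "branch": node.name,
            "duplications": dups[id(node)],
            "losses": loss_count[id(node)],
            "copies_in": entering[id(node)],
            "copies_out": leaving[id(node)],
        })
    return pd.DataFrame(rows)


def validate_ortholog_constraints(result: ReconciliationResult,
                                  pairs: List[Tuple[str, str]]) -> List[Tuple[str, str]]:
    """Check user-asserted ortholog pairs (e.g. from synteny evidence).

    A pair is violated when the LCA of the two gene leaves is labeled a
    duplication.  Returns the violated pairs; callers may warn on them.
    """
    leaves = {leaf.name: leaf for leaf in result.gene_tree.leaves()}
    violated = []
    for a, b in pairs:
        if a not in leaves or b not in leaves:
            raise ValueError(f"constraint pair ({a!r}, {b!r}) not in gene tree")
        na = leaves[a]
        ancestors_a = set()
        node = na
        while node is not None:
            ancestors_a.add(id(node))
            node = node.parent
        node = leaves[b]
        while id(node) not in ancestors_a:
            node = node.parent
        if not node.is_leaf() and result.event_of(node) == DUPLICATION:
            violated.append((a, b))
    return violated
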