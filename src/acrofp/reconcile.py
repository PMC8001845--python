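"""Duplication-loss parsimony reconciliation against a species tree.

Implements LCA mapping of a rooted binary gene tree onto a rooted species
tree, per-branch event ledgers with ancestral copy numbers, per-color-class
histories on pruned gene trees, random polytomy resolution, and a parsimony
rooting fallback for gene trees without a surviving outgroup.

Conventions: a duplication is attributed to the species branch *ending* at
the node it maps to; each loss is attributed to the branch ending at the
species node where the copy went missing.  When the gene-tree root maps below
the species root, the family is treated as a single ancestral copy at the
species root with one loss charged to every branch leaving the stem path, so
that copy-number bookkeeping stays exact on every branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .trees import Node, to_newick

__all__ = [
    "Reconciliation",
    "EventLedger",
    "lca_map",
    "build_ledger",
    "ancestral_copy_number",
    "per_class_history",
    "resolve_polytomies",
    "parsimony_root",
    "split_leaf_tag",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


def split_leaf_tag(label: str) -> tuple[str, str]:
    """Split a gene-tree leaf tag ``species|gene_id`` into its parts."""
    if "|" not in label:
        return label, label
    species, gene = label.split("|", 1)
    return species, gene


@dataclass
class Reconciliation:
    gene_root: Node
    species_root: Node
    mapping: dict[Node, Node]
    events: dict[Node, str]                 # internal gene node -> event
    losses: list[tuple[Node, Node]]         # (gene edge child, species node lost at)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    @property
    def total_events(self) -> int:
        return self.n_duplications + self.n_losses

    def to_rows(self) -> list[tuple[str, str, str]]:
        rows = []
        for gnode, snode in self.mapping.items():
            event = ("leaf" if gnode.is_leaf
                     else self.events.get(gnode, SPECIATION))
            rows.append((gnode.label or to_newick(gnode, lengths=False),
                         snode.label or "?", event))
        return rows


def _index_species(species_root: Node) -> tuple[dict[str, Node], dict[Node, int]]:
    by_label: dict[str, Node] = {}
    depth: dict[Node, int] = {}
    for node in species_root.preorder():
        if node.label is not None:
            by_label[node.label] = node
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1
    return by_label, depth


def _lca(a: Node, b: Node, depth: dict[Node, int]) -> Node:
    while a is not b:
        if depth[a] >= depth[b]:
            a = a.parent
        else:
            b = b.parent
    return a


def lca_map(gene_root: Node, species_root: Node,
            species_of: Optional[Callable[[str], str]] = None) -> Reconciliation:
    """LCA duplication-loss parsimony reconciliation.

    ``species_of`` extracts the species name from a gene leaf label; the
    default takes the part before ``|``.  Raises ``KeyError`` naming the leaf
    if its species is absent from the species tree, ``ValueError`` if the gene
    tree is not binary.
    """
    if species_of is None:
        species_of = lambda label: split_leaf_tag(label)[0]
    species_by_label, depth = _index_species(species_root)
    leaf_species = {leaf.label for leaf in species_root.leaves()}

    mapping: dict[Node, Node] = {}
    events: dict[Node, str] = {}
    for gnode in gene_root.postorder():
        if gnode.is_leaf:
            sp = species_of(gnode.label)
            if sp not in species_by_label:
                raise KeyError(
                    f"gene leaf {gnode.label!r} names unknown species {sp!r}")
            mapping[gnode] = species_by_label[sp]
            continue
        if len(gnode.children) != 2:
            raise ValueError("gene tree must be binary; resolve polytomies first")
        a, b = (mapping[c] for c in gnode.children)
        m = _lca(a, b, depth)
        mapping[gnode] = m
        dup = any(mapping[c] is m for c in gnode.children)
        events[gnode] = DUPLICATION if dup else SPECIATION

    losses: list[tuple[Node, Node]] = []
    for gnode in gene_root.preorder():
        if gnode.is_leaf:
            continue
        mu = mapping[gnode]
        is_dup = events[gnode] == DUPLICATION
        for child in gnode.children:
            node = mapping[child]
            while node is not mu:
                parent = node.parent
                at_top = parent is mu
                if (not at_top) or is_dup:
                    for sib in parent.children:
                        if sib is not node:
                            losses.append((child, sib))
                node = parent
    return Reconciliation(gene_root, species_root, mapping, events, losses)


# ---------------------------------------------------------------------------
# ledgers
# ---------------------------------------------------------------------------

@dataclass
class EventLedger:
    """Per-species-branch duplication/loss counts and per-node copy numbers.

    Branches are keyed by the label of the species node they end at; the
    species root's own key may carry duplications mapped to the root itself.
    """

    root_label: str
    dups: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    copies: dict[str, int] = field(default_factory=dict)
    classes: dict[str, "EventLedger"] = field(default_factory=dict)

    def dup_count(self, branch: str) -> int:
        return self.dups.get(branch, 0)

    def loss_count(self, branch: str) -> int:
        return self.losses.get(branch, 0)

    def copies_at(self, node_label: str) -> int:
        if node_label not in self.copies:
            raise KeyError(f"unknown species node {node_label!r}")
        return self.copies[node_label]

    def validate(self, species_root: Node) -> None:
        """Check copy-number conservation on every branch (and sub-ledgers)."""
        for node in species_root.preorder():
            if node.parent is None:
                continue
            expected = (self.copies[node.parent.label]
                        + self.dup_count(node.label)
                        - self.loss_count(node.label))
            if self.copies[node.label] != expected:
                raise ValueError(
                    f"ledger inconsistent on branch to {node.label!r}: "
                    f"{self.copies[node.label]} != {expected}")
        for sub in self.classes.values():
            sub.validate(species_root)

    def check_class_sums(self, species_root: Node) -> None:
        if not self.classes:
            return
        for node in species_root.preorder():
            label = node.label
            total = sum(sub.copies.get(label, 0) for sub in self.classes.values())
            if total != self.copies.get(label, 0):
                raise ValueError(
                    f"class copy numbers do not sum to total at {label!r}")

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        branches = sorted(set(self.dups) | set(self.losses) | set(self.copies))
        return [(b, self.dup_count(b), self.loss_count(b),
                 self.copies.get(b, 0)) for b in branches]


def _empty_ledger(species_root: Node) -> EventLedger:
    ledger = EventLedger(root_label=species_root.label)
    for node in species_root.preorder():
        ledger.copies[node.label] = 0
    return ledger


def build_ledger(rec: Optional[Reconciliation], species_root: Node) -> EventLedger:
    """Aggregate a reconciliation into per-branch counts and copy numbers."""
    ledger = _empty_ledger(species_root)
    if rec is None:
        return ledger
    ledger.dups = {}
    ledger.losses = {}
    for gnode, event in rec.events.items():
        if event == DUPLICATION:
            label = rec.mapping[gnode].label
            ledger.dups[label] = ledger.dups.get(label, 0) + 1
    for _edge_child, snode in rec.losses:
        ledger.losses[snode.label] = ledger.losses.get(snode.label, 0) + 1
    # stem completion: single ancestral copy assumed at the species root
    stem_top = rec.mapping[rec.gene_root]
    node = stem_top
    while node.parent is not None:
        for sib in node.parent.children:
            if sib is not node:
                ledger.losses[sib.label] = ledger.losses.get(sib.label, 0) + 1
        node = node.parent
    root_label = species_root.label
    ledger.copies[root_label] = 1 + ledger.dup_count(root_label)
    for snode in species_root.preorder():
        if snode.parent is None:
            continue
        ledger.copies[snode.label] = (ledger.copies[snode.parent.label]
                                      + ledger.dup_count(snode.label)
                                      - ledger.loss_count(snode.label))
    return ledger


def ancestral_copy_number(ledger: EventLedger, node_label: str) -> int:
    """Copy number at a named species-tree node."""
    return ledger.copies_at(node_label)


def per_class_history(gene_root: Node, colors: dict[str, str],
                      species_root: Node,
                      classes: Sequence[str] = ("GFP/CFP", "RFP", "ChrP"),
                      species_of: Optional[Callable[[str], str]] = None,
                      ) -> dict[str, EventLedger]:
    """Reconcile the gene tree restricted to each color class independently.

    ``colors`` maps every gene-tree leaf label to its class.  A class with no
    leaves yields an all-zero ledger.
    """
    missing = [l for l in gene_root.leaf_labels() if l not in colors]
    if missing:
        raise ValueError(f"uncolored gene-tree leaves: {missing[:5]}")
    ledgers: dict[str, EventLedger] = {}
    for cls in classes:
        keep = {l for l, c in colors.items() if c == cls}
        pruned = _prune_to(gene_root, keep)
        if pruned is None:
            ledgers[cls] = _empty_ledger(species_root)
            continue
        rec = lca_map(pruned, species_root, species_of=species_of)
        ledgers[cls] = build_ledger(rec, species_root)
    return ledgers


def _prune_to(gene_root: Node, keep: set[str]) -> Optional[Node]:
    root = gene_root.copy()
    while True:
        doomed = [n for n in root.preorder()
                  if n.is_leaf and n.label not in keep]
        if not doomed:
            break
        for node in doomed:
            if node.parent is None:
                return None
            node.detach()
    root = root.suppress_unary()
    if root.is_leaf and root.label not in keep:
        return None
    return root


# ---------------------------------------------------------------------------
# polytomy resolution and rooting
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: Node, seed: int = 0) -> Node:
    """Randomly resolve every polytomy into a binary subtree.

    Resolution draws uniformly over labeled binary topologies by sequential
    leaf insertion at a uniformly chosen edge; reproducible for a fixed seed.
    Binary input is returned structurally unchanged (as a copy).
    """
    rng = np.random.default_rng(seed)
    root = tree.copy()
    for node in list(root.preorder()):
        while len(node.children) > 2:
            children = [c.detach() for c in list(node.children)]
            # build a uniform random binary tree over the children
            top = children[0]
            for child in children[1:]:
                edges: list[Node] = [n for n in top.preorder()]
                pick = edges[int(rng.integers(len(edges)))]
                joint = Node(length=0.0)
                if pick is top:
                    top = joint
                else:
                    parent = pick.parent
                    idx = parent.children.index(pick)
                    parent.children[idx] = joint
                    joint.parent = parent
                    pick.parent = None
                joint.add_child(pick)
                joint.add_child(child)
            # re-attach the two top-level groups to the original node
            for group in list(top.children):
                node.add_child(group.detach())
    return root


def parsimony_root(unrooted: Node, species_root: Node,
                   species_of: Optional[Callable[[str], str]] = None) -> Node:
    """Root an unrooted gene tree minimizing total duplications + losses.

    Ties are broken by the lexicographically smallest bipartition induced by
    the rooting edge.
    """
    from .phylo_classify import _reroot_on_edge  # shared rerooting machinery

    candidates: list[tuple[int, tuple, Node]] = []
    all_leaves = sorted(unrooted.leaf_labels())
    for node in unrooted.preorder():
        if node.parent is None:
            continue
        rooted = _reroot_on_edge(unrooted, node, (node.length or 0.0) / 2.0)
        rec = lca_map(rooted, species_root, species_of=species_of)
        side = tuple(sorted(node.leaf_labels()))
        other = tuple(sorted(set(all_leaves) - set(side)))
        key = min(side, other)
        candidates.append((rec.total_events, key, rooted))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]
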