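"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or naive dynamic
programming, independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np

from acrofp.trees import Node

NEG = float("-inf")


# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps (Gotoh), biopython gap convention:
# a gap of length k costs open + (k - 1) * extend.
# ---------------------------------------------------------------------------

def smith_waterman(a: str, b: str, score_fn, gap_open: float = -11.0,
                   gap_extend: float = -1.0) -> float:
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                       Iy[i - 1][j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


# ---------------------------------------------------------------------------
# duplication-loss reconciliation cost by exhaustive mapping enumeration
# ---------------------------------------------------------------------------

def _species_nodes(root: Node) -> list[Node]:
    return list(root.preorder())


def _ancestors_or_self(node: Node) -> list[Node]:
    return [node] + list(node.ancestors())


def _path_len(low: Node, high: Node) -> int:
    d = 0
    node = low
    while node is not high:
        node = node.parent
        d += 1
    return d


def brute_force_dl_cost(gene_root: Node, species_root: Node,
                        species_of) -> int:
    """Minimum duplications + losses over all valid mappings."""
    species_by_label = {n.label: n for n in species_root.preorder()
                        if n.label is not None}
    gnodes = list(gene_root.postorder())
    internal = [g for g in gnodes if not g.is_leaf]
    leaf_map = {}
    for g in gnodes:
        if g.is_leaf:
            leaf_map[g] = species_by_label[species_of(g.label)]

    def _is_dup(mu: Node, kids: list[Node]) -> bool:
        if any(k is mu for k in kids):
            return True
        # speciation requires the children to separate into different child
        # subtrees of the mapped species node
        tops = []
        for k in kids:
            node = k
            while node.parent is not mu:
                node = node.parent
            tops.append(id(node))
        return len(set(tops)) < len(tops)

    def cost_of(mapping: dict) -> Optional[int]:
        dups = 0
        losses = 0
        for g in internal:
            mu = mapping[g]
            kids = [mapping[c] for c in g.children]
            for k in kids:
                if not mu.is_ancestor_of(k, include_self=True):
                    return None
            is_dup = _is_dup(mu, kids)
            if is_dup:
                dups += 1
            for k in kids:
                d = _path_len(k, mu)
                losses += d if is_dup else max(d - 1, 0)
        return dups + losses

    best = None
    domains = []
    for g in internal:
        # any ancestor-or-self of the LCA of its leaf species is a candidate
        leaves_below = [leaf_map[l] for l in g.leaves()]
        lca = leaves_below[0]
        for other in leaves_below[1:]:
            while not lca.is_ancestor_of(other, include_self=True):
                lca = lca.parent
        domains.append(_ancestors_or_self(lca))
    for combo in itertools.product(*domains):
        mapping = dict(leaf_map)
        mapping.update(dict(zip(internal, combo)))
        ok = True
        for g in internal:
            for c in g.children:
                if not mapping[g].is_ancestor_of(mapping[c], include_self=True):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        c = cost_of(mapping)
        if c is not None and (best is None or c < best):
            best = c
    return best


# ---------------------------------------------------------------------------
# tree enumeration and least-squares topology fit
# ---------------------------------------------------------------------------

def all_rooted_topologies(labels: Sequence[str]) -> list[Node]:
    """All rooted binary labeled topologies over the labels."""
    labels = list(labels)
    if len(labels) == 1:
        return [Node(label=labels[0])]
    out: list[Node] = []
    first, rest = labels[0], labels[1:]
    for sub in all_rooted_topologies(rest):
        for k, node in enumerate(list(sub.preorder())):
            clone = sub.copy()
            target = list(clone.preorder())[k]
            joint = Node()
            if target.parent is None:
                joint.add_child(target)
                joint.add_child(Node(label=first))
                out.append(joint)
            else:
                parent = target.parent
                idx = parent.children.index(target)
                parent.children[idx] = joint
                joint.parent = parent
                target.parent = None
                joint.add_child(target)
                joint.add_child(Node(label=first))
                out.append(clone)
    return out


def unrooted_splits(tree: Node) -> frozenset:
    """Canonical set of non-trivial splits of a tree viewed as unrooted."""
    leaves = frozenset(tree.leaf_labels())
    anchor = min(leaves)
    splits = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        if len(side) <= 1 or len(leaves - side) <= 1:
            continue
        splits.add(side if anchor not in side else leaves - side)
    return frozenset(splits)


def quartet_least_squares(d: np.ndarray, labels: Sequence[str]) -> frozenset:
    """Best of the three 4-taxon topologies by least-squares branch fit."""
    assert len(labels) == 4
    idx = {l: i for i, l in enumerate(labels)}
    best = None
    for split in [(labels[0], labels[1]), (labels[0], labels[2]),
                  (labels[0], labels[3])]:
        a, b = split
        c, e = [l for l in labels if l not in split]
        i, j, k, l = idx[a], idx[b], idx[c], idx[e]
        # five-parameter least squares for topology ((a,b),(c,e))
        A = []
        y = []
        pairs = [(i, j, (1, 1, 0, 0, 0)), (i, k, (1, 0, 1, 0, 1)),
                 (i, l, (1, 0, 0, 1, 1)), (j, k, (0, 1, 1, 0, 1)),
                 (j, l, (0, 1, 0, 1, 1)), (k, l, (0, 0, 1, 1, 0))]
        for p, q, row in pairs:
            A.append(row)
            y.append(d[p, q])
        coeff, res, *_ = np.linalg.lstsq(np.array(A, dtype=float),
                                         np.array(y), rcond=None)
        fit = np.array(A) @ coeff
        sse = float(((fit - np.array(y)) ** 2).sum())
        key = frozenset({frozenset({a, b}), frozenset({c, e})})
        if best is None or sse < best[0] - 1e-12:
            best = (sse, key)
    return best[1]


# ---------------------------------------------------------------------------
# exhaustive multiple alignment (unit costs) for the center-star bound
# ---------------------------------------------------------------------------

def optimal_sp_cost_3(seqs: Sequence[str]) -> int:
    """Optimal sum-of-pairs cost of aligning three sequences.

    Costs: match 0, mismatch 1, gap-vs-residue 1, gap-vs-gap 0.
    """
    assert len(seqs) == 3
    a, b, c = seqs

    def sub(x: Optional[str], y: Optional[str]) -> int:
        if x is None and y is None:
            return 0
        if x is None or y is None:
            return 1
        return 0 if x == y else 1

    la, lb, lc = len(a), len(b), len(c)
    big = 10 ** 9
    dp = np.full((la + 1, lb + 1, lc + 1), big, dtype=int)
    dp[0, 0, 0] = 0
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                cur = dp[i, j, k]
                if cur >= big:
                    continue
                for di, dj, dk in itertools.product((0, 1), repeat=3):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > la or nj > lb or nk > lc:
                        continue
                    x = a[i] if di else None
                    y = b[j] if dj else None
                    z = c[k] if dk else None
                    step = sub(x, y) + sub(x, z) + sub(y, z)
                    if cur + step < dp[ni, nj, nk]:
                        dp[ni, nj, nk] = cur + step
    return int(dp[la, lb, lc])


def sp_cost(rows: Sequence[str]) -> int:
    """Sum-of-pairs cost of a given alignment under the unit-cost scheme."""
    cost = 0
    ncol = len(rows[0])
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for col in range(ncol):
                x, y = rows[i][col], rows[j][col]
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    cost += 1
                elif x != y:
                    cost += 1
    return cost
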