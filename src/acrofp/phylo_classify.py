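"""Alignment, neighbor-joining trees with bootstrap, and color classification.

The classification workflow aligns complete FP candidates together with reference
proteins of known emission color, builds a bootstrapped tree, and classifies
candidates by membership in well-supported RFP / ChrP clades, everything else
defaulting to the GFP/CFP group.  Tree inference here is distance-based
(neighbor-joining on p-distances); likelihood optimization is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .trees import Node

logger = logging.getLogger(__name__)

__all__ = [
    "MSA",
    "GeneTree",
    "align",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "root_tree",
    "midpoint_root",
    "assign_colors",
    "bipartitions",
]

DEFAULT_SUPPORT_MIN = 90.0
DEFAULT_BOOTSTRAP_REPLICATES = 1000

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# multiple alignment (center star)
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    rows: list[tuple[str, str]]
    chromophore_columns: tuple[int, ...] = ()

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def columns_of(self, row_id: str, positions: Sequence[int]) -> tuple[int, ...]:
        """1-based alignment columns of 1-based ungapped positions in a row."""
        gapped = self.row(row_id)
        pos_to_col = {}
        pos = 0
        for col, ch in enumerate(gapped, start=1):
            if ch != "-":
                pos += 1
                pos_to_col[pos] = col
        return tuple(pos_to_col[p] for p in positions)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")


def _pairwise_aligner(match: Optional[float], mismatch: Optional[float],
                      gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if match is None:
        aligner.substitution_matrix = _BLOSUM62
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _alignment_path(alignment) -> list[tuple[Optional[int], Optional[int]]]:
    """Expand a biopython pairwise alignment into per-column index pairs."""
    path: list[tuple[Optional[int], Optional[int]]] = []
    t_prev = q_prev = 0
    blocks_t, blocks_q = alignment.aligned
    for (t_lo, t_hi), (q_lo, q_hi) in zip(blocks_t, blocks_q):
        while t_prev < t_lo:
            path.append((t_prev, None))
            t_prev += 1
        while q_prev < q_lo:
            path.append((None, q_prev))
            q_prev += 1
        for k in range(t_hi - t_lo):
            path.append((t_lo + k, q_lo + k))
        t_prev, q_prev = t_hi, q_hi
    t_len = len(alignment.target)
    q_len = len(alignment.query)
    while t_prev < t_len:
        path.append((t_prev, None))
        t_prev += 1
    while q_prev < q_len:
        path.append((None, q_prev))
        q_prev += 1
    return path


def align(sequences: Sequence[tuple[str, str]],
          match: Optional[float] = None, mismatch: Optional[float] = None,
          gap: float = -12.0) -> MSA:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing the summed pairwise alignment score
    against all others; remaining sequences are merged onto it under the
    "once a gap, always a gap" rule.  With default arguments scoring is
    BLOSUM62; pass ``match``/``mismatch`` for simple scoring schemes.
    """
    ids = [sid for sid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    if len(sequences) < 2:
        raise ValueError("alignment needs at least two sequences")
    aligner = _pairwise_aligner(match, mismatch, gap)
    n = len(sequences)
    score_sum = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(sequences[i][1], sequences[j][1])
            score_sum[i] += s
            score_sum[j] += s
    center_idx = int(np.argmax(score_sum))
    center_id, center_seq = sequences[center_idx]
    others = [sequences[k] for k in range(n) if k != center_idx]

    Lc = len(center_seq)
    # per-sequence: insertions before each center position, and residue (or
    # gap) aligned to each center position
    ins: list[list[list[str]]] = []
    matched: list[list[Optional[str]]] = []
    for _, seq in others:
        path = _alignment_path(aligner.align(center_seq, seq)[0])
        my_ins: list[list[str]] = [[] for _ in range(Lc + 1)]
        my_match: list[Optional[str]] = [None] * Lc
        cpos = 0
        for t, q in path:
            if t is None:
                my_ins[cpos].append(seq[q])
            else:
                my_match[t] = seq[q] if q is not None else None
                cpos = t + 1
        ins.append(my_ins)
        matched.append(my_match)

    block = [max((len(my_ins[k]) for my_ins in ins), default=0)
             for k in range(Lc + 1)]
    out_rows = ["" for _ in range(len(others))]
    center_row = ""
    for k in range(Lc + 1):
        width = block[k]
        if width:
            center_row += "-" * width
            for r, my_ins in enumerate(ins):
                chunk = "".join(my_ins[k])
                out_rows[r] += chunk + "-" * (width - len(chunk))
        if k < Lc:
            center_row += center_seq[k]
            for r, my_match in enumerate(matched):
                out_rows[r] += my_match[k] or "-"

    rows = [(center_id, center_row)]
    rows += [(others[r][0], out_rows[r]) for r in range(len(others))]
    order = {sid: i for i, sid in enumerate(ids)}
    rows.sort(key=lambda item: order[item[0]])
    msa = MSA(rows)
    for rid, row in msa.rows:
        original = dict(sequences)[rid]
        if row.replace("-", "") != original:
            raise AssertionError(f"alignment corrupted row {rid}")
    return msa


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def distance_matrix(msa: MSA, correction: Optional[str] = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances with pairwise deletion of gap columns.

    ``correction="poisson"`` applies the 20-state multiple-hit correction
    ``d = -(19/20) ln(1 - 20 p / 19)`` (saturated pairs are capped), which the
    tree-building pipeline uses to keep distances near-additive at higher
    divergence; the default returns raw p-distances.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    ids = [rid for rid, _ in msa.rows]
    arr = np.array([list(seq) for _, seq in msa.rows])
    valid = arr != "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]} and {ids[j]}")
            p = int((arr[i][both] != arr[j][both]).sum()) / total
            if correction == "poisson":
                p = min(p, 0.94)
                p = -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0)
            d[i, j] = d[j, i] = p
    return d, ids


def _cluster_key(label_sets: list[frozenset], i: int) -> str:
    return min(label_sets[i])


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> Node:
    """Neighbor joining (Saitou-Nei, Studier-Keppler Q criterion).

    Returns an unrooted tree represented as a :class:`Node` whose root is the
    final trifurcation (bifurcation for n=2... n>=3 required).  Ties in Q are
    broken by the lexicographically smallest joined pair of cluster labels;
    negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining requires n >= 3")
    nodes: list[Node] = [Node(label=l) for l in labels]
    keys: list[str] = [str(l) for l in labels]
    D = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - totals[ai] - totals[aj]
                pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = Node()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.add_child(ni)
        parent.add_child(nj_)
        # distances from the new node to every other active cluster
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the final three clusters at an unrooted hub
    i, j, k = active
    hub = Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        length = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        nodes[a].length = max(length, 0.0)
        hub.add_child(nodes[a])
    return hub


def bipartitions(tree: Node) -> dict[frozenset, Node]:
    """Non-trivial bipartitions of an (un)rooted tree, canonically encoded.

    Each internal edge is encoded as the frozenset of the leaf-label side that
    does *not* contain the lexicographically smallest leaf.
    """
    all_leaves = frozenset(tree.leaf_labels())
    if not all_leaves:
        return {}
    anchor = min(all_leaves)
    out: dict[frozenset, Node] = {}
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            continue
        key = side if anchor not in side else all_leaves - side
        out[key] = node
    return out


def bootstrap_support(msa: MSA, n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
                      seed: int = 0,
                      correction: Optional[str] = None) -> dict[frozenset, float]:
    """Column-resampling bootstrap support (percent) per bipartition.

    Supports are attached to bipartitions, not node identities, so they
    survive re-rooting.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncol = msa.ncol
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = [(rid, "".join(seq[c] for c in cols)) for rid, seq in msa.rows]
        d, ids = distance_matrix(MSA(rows), correction=correction)
        tree = nj_tree(d, ids)
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / n_replicates for split, c in counts.items()}


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: Node) -> dict[int, list[tuple[Node, float]]]:
    adj: dict[int, list[tuple[Node, float]]] = {}
    index: dict[int, Node] = {}
    for node in tree.preorder():
        index[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            w = child.length or 0.0
            adj[id(node)].append((child, w))
            adj.setdefault(id(child), []).append((node, w))
    return adj


def _reroot_on_edge(tree: Node, below: Node, dist_below: float) -> Node:
    """Root the (possibly unrooted) tree on the edge above ``below``,
    ``dist_below`` along the edge starting from ``below``."""
    adj = _adjacency(tree)
    edge_len = below.length or 0.0
    parent = below.parent
    root = Node()

    def build(node: Node, come_from: Optional[Node]) -> Node:
        clone = Node(label=node.label)
        for nbr, w in adj[id(node)]:
            if come_from is not None and nbr is come_from:
                continue
            sub = build(nbr, node)
            sub.length = w
            clone.add_child(sub)
        return clone

    left = build(below, parent)
    right = build(parent, below)
    # a previously rooted input leaves its old root as a degree-2 node
    left = left.suppress_unary() if left.children else left
    right = right.suppress_unary() if right.children else right
    left.length = dist_below
    right.length = max(edge_len - dist_below, 0.0)
    root.add_child(left)
    root.add_child(right)
    return root


def root_tree(tree: Node, outgroup: Sequence[str]) -> Node:
    """Root on the edge separating the outgroup leaves from the rest.

    Falls back to midpoint rooting (with a warning) when the outgroup is empty
    or does not form one side of any edge of the unrooted tree.
    """
    outgroup_set = frozenset(outgroup)
    leaves = frozenset(tree.leaf_labels())
    if not outgroup_set or not outgroup_set <= leaves:
        if outgroup_set:
            logger.warning("outgroup %s not fully present; midpoint rooting",
                           sorted(outgroup_set - leaves))
        return midpoint_root(tree)
    if outgroup_set == leaves:
        logger.warning("outgroup covers all leaves; midpoint rooting")
        return midpoint_root(tree)
    if len(tree.children) == 2:
        for child in tree.children:
            if frozenset(child.leaf_labels()) == outgroup_set:
                return tree  # already rooted on this outgroup: idempotent

    for node in tree.preorder():
        if node.parent is None:
            continue
        side = frozenset(node.leaf_labels())
        if side == outgroup_set or leaves - side == outgroup_set:
            return _reroot_on_edge(tree, node, (node.length or 0.0) / 2.0)
    logger.warning("outgroup %s is not a cluster in the unrooted tree; "
                   "midpoint rooting", sorted(outgroup_set))
    return midpoint_root(tree)


def midpoint_root(tree: Node) -> Node:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    leaves = tree.leaves()
    if len(leaves) == 1:
        return tree
    # distances from each node to its farthest descendant leaf, then combine
    adj = _adjacency(tree)

    def far_leaf(start: Node) -> tuple[float, list[tuple[Node, float]]]:
        # BFS returning distance and path to the farthest leaf
        best = (0.0, [])
        stack = [(start, None, 0.0, [])]
        while stack:
            node, came, dist, path = stack.pop()
            if node.is_leaf and node is not start and dist > best[0]:
                best = (dist, path)
            for nbr, w in adj[id(node)]:
                if nbr is came:
                    continue
                stack.append((nbr, node, dist + w, path + [(nbr, w)]))
        return best

    d1, path1 = far_leaf(leaves[0])
    end1 = path1[-1][0] if path1 else leaves[0]
    d2, path2 = far_leaf(end1)
    target = d2 / 2.0
    walked = 0.0
    prev = end1
    for node, w in path2:
        if walked + w >= target and w > 0:
            # root lies on edge between prev and node
            along = target - walked
            if node.parent is prev:
                return _reroot_on_edge(tree, node, (node.length or 0.0) - along)
            return _reroot_on_edge(tree, prev, along)
        walked += w
        prev = node
    return _reroot_on_edge(tree, path2[-1][0], 0.0)


# ---------------------------------------------------------------------------
# color classification
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """Rooted gene tree plus bipartition-keyed bootstrap supports."""

    root: Node
    supports: dict[frozenset, float] = field(default_factory=dict)

    def clade_support(self, node: Node) -> float:
        all_leaves = frozenset(self.root.leaf_labels())
        side = frozenset(node.leaf_labels())
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            return 100.0
        anchor = min(all_leaves)
        key = side if anchor not in side else all_leaves - side
        if key in self.supports:
            return self.supports[key]
        return 100.0 if not self.supports else 0.0

    def mrca(self, labels: Sequence[str]) -> Node:
        want = set(labels)
        for node in self.root.postorder():
            if want <= set(node.leaf_labels()):
                return node
        raise KeyError(f"labels {sorted(want)} not all present")


def assign_colors(gene_tree: GeneTree, reference_colors: dict[str, str],
                  support_min: float = DEFAULT_SUPPORT_MIN
                  ) -> dict[str, tuple[str, str]]:
    """Assign every non-reference leaf a color class.

    The RFP clade is the smallest rooted clade containing every RFP-labelled
    reference; its members are classified RFP when the clade support reaches
    ``support_min``.  Likewise ChrP.  Everything else defaults to GFP/CFP.
    Returns ``{gene id: (class, provenance)}`` with provenance ``clade`` or
    ``default``.
    """
    leaves = gene_tree.root.leaf_labels()
    rfp_refs = [l for l in leaves if reference_colors.get(l) == "RFP"]
    chrp_refs = [l for l in leaves if reference_colors.get(l) == "ChrP"]
    if not rfp_refs or not chrp_refs:
        raise ValueError("tree must contain RFP and ChrP references")

    clades: list[tuple[str, set[str]]] = []
    for cls, refs in (("RFP", rfp_refs), ("ChrP", chrp_refs)):
        node = gene_tree.mrca(refs)
        if gene_tree.clade_support(node) >= support_min:
            clades.append((cls, set(node.leaf_labels())))
    if len(clades) == 2 and clades[0][1] & clades[1][1]:
        logger.warning("RFP and ChrP clades overlap; smaller clade wins")
        clades.sort(key=lambda item: len(item[1]))
        clades[1] = (clades[1][0], clades[1][1] - clades[0][1])

    assignment: dict[str, tuple[str, str]] = {}
    for leaf in leaves:
        if leaf in reference_colors:
            continue
        assigned = None
        for cls, members in clades:
            if leaf in members:
                assigned = (cls, "clade")
                break
        assignment[leaf] = assigned or ("GFP/CFP", "default")
    return assignment
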