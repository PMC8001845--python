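"""Gene clusters on scaffolds, orthology links, tandem vs dispersed
duplication calls, and gene-order comparison between clusters.

Cluster gaps are measured in intervening gene count (gene-order units), and
cross-cluster comparison is a gene-order alignment rather than a
nucleotide-level dot plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .reconcile import DUPLICATION, Reconciliation, split_leaf_tag

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "GeneCluster",
    "OrthologLink",
    "read_gff_genes",
    "detect_clusters",
    "orthology_links",
    "pair_relation",
    "classify_duplication",
    "compare_cluster_order",
    "DEFAULT_MAX_INTERVENING",
]

DEFAULT_MAX_INTERVENING = 10


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    family: str = "unknown"   # FP | decoy | unknown


def read_gff_genes(path: str, species: str) -> list[GeneFeature]:
    """Read ``gene`` features from a GFF3 file."""
    import gffutils.iterators

    out: list[GeneFeature] = []
    for feat in gffutils.iterators.DataIterator(path):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        family = feat.attributes.get("family", ["unknown"])[0]
        out.append(GeneFeature(gene_id, species, feat.seqid,
                               feat.start, feat.end, feat.strand, family))
    return out


@dataclass
class GeneCluster:
    species: str
    scaffold: str
    members: list[tuple[str, str, int]]          # (gene_id, strand, rank)
    class_counts: dict[str, int] = field(default_factory=dict)
    flanking: tuple[Optional[str], Optional[str]] = (None, None)

    @property
    def gene_ids(self) -> list[str]:
        return [gid for gid, _, _ in self.members]

    def rank_of(self, gene_id: str) -> int:
        for gid, _, rank in self.members:
            if gid == gene_id:
                return rank
        raise KeyError(gene_id)

    def strand_of(self, gene_id: str) -> str:
        for gid, strand, _ in self.members:
            if gid == gene_id:
                return strand
        raise KeyError(gene_id)

    def majority_strand(self) -> str:
        plus = sum(1 for _, s, _ in self.members if s == "+")
        return "+" if plus * 2 >= len(self.members) else "-"


def detect_clusters(features: Sequence[GeneFeature], fp_ids: Iterable[str],
                    max_intervening: int = DEFAULT_MAX_INTERVENING,
                    colors: Optional[dict[str, str]] = None
                    ) -> list[GeneCluster]:
    """Find runs of FP genes on one scaffold with at most ``max_intervening``
    non-FP genes between consecutive members (transitive closure).

    Singleton FP genes form no cluster.  ``colors`` optionally supplies a
    class label per FP gene for the cluster's composition counts.
    """
    fp_set = set(fp_ids)
    clusters: list[GeneCluster] = []
    by_scaffold: dict[tuple[str, str], list[GeneFeature]] = {}
    for feat in features:
        by_scaffold.setdefault((feat.species, feat.scaffold), []).append(feat)
    for (species, scaffold), genes in sorted(by_scaffold.items()):
        genes = sorted(genes, key=lambda f: (f.start, f.end))
        for left, right in zip(genes, genes[1:]):
            if right.start <= left.end:
                logger.warning("overlapping genes %s / %s on %s",
                               left.gene_id, right.gene_id, scaffold)
        fp_positions = [i for i, f in enumerate(genes) if f.gene_id in fp_set]
        if len(fp_positions) < 2:
            continue
        runs: list[list[int]] = [[fp_positions[0]]]
        for pos in fp_positions[1:]:
            if pos - runs[-1][-1] - 1 <= max_intervening:
                runs[-1].append(pos)
            else:
                runs.append([pos])
        for run in runs:
            if len(run) < 2:
                continue
            members = [(genes[p].gene_id, genes[p].strand, r + 1)
                       for r, p in enumerate(run)]
            counts: dict[str, int] = {}
            for gid, _, _ in members:
                cls = (colors or {}).get(gid, "unassigned")
                counts[cls] = counts.get(cls, 0) + 1
            before = next((genes[i].gene_id for i in range(run[0] - 1, -1, -1)
                           if genes[i].gene_id not in fp_set), None)
            after = next((genes[i].gene_id for i in range(run[-1] + 1, len(genes))
                          if genes[i].gene_id not in fp_set), None)
            clusters.append(GeneCluster(species, scaffold, members, counts,
                                        (before, after)))
    return clusters


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologLink:
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    relation: str            # ortholog | paralog
    lca_species: str


def _gene_lca(rec: Reconciliation, leaf_a, leaf_b):
    ancestors_a = [leaf_a] + list(leaf_a.ancestors())
    seen = {id(n) for n in ancestors_a}
    node = leaf_b
    while id(node) not in seen:
        node = node.parent
    return node


def pair_relation(rec: Reconciliation, leaf_a, leaf_b) -> tuple[str, str]:
    """(relation, species label of the pair's LCA image)."""
    lca = _gene_lca(rec, leaf_a, leaf_b)
    event = rec.events.get(lca, "leaf")
    relation = "paralog" if event == DUPLICATION else "ortholog"
    return relation, rec.mapping[lca].label or "?"


def orthology_links(rec: Reconciliation) -> list[OrthologLink]:
    """Relation of every cross-species gene pair, from the reconciliation.

    A pair is orthologous iff its gene-tree LCA is a speciation node.
    """
    leaves = rec.gene_root.leaves()
    links: list[OrthologLink] = []
    for i, la in enumerate(leaves):
        sp_a, gid_a = split_leaf_tag(la.label)
        for lb in leaves[i + 1:]:
            sp_b, gid_b = split_leaf_tag(lb.label)
            if sp_a == sp_b:
                continue
            relation, lca_sp = pair_relation(rec, la, lb)
            links.append(OrthologLink(gid_a, gid_b, sp_a, sp_b,
                                      relation, lca_sp))
    return links


# ---------------------------------------------------------------------------
# duplication mode and cluster comparison
# ---------------------------------------------------------------------------

def classify_duplication(pair: tuple[str, str], clusters: Sequence[GeneCluster],
                         placed_genes: Optional[Iterable[str]] = None) -> str:
    """Classify a paralog pair as ``tandem`` (both in one cluster) or
    ``dispersed``.

    If ``placed_genes`` is given, genes absent from it raise ``KeyError``.
    """
    if placed_genes is not None:
        placed = set(placed_genes)
        for gid in pair:
            if gid not in placed:
                raise KeyError(f"gene {gid!r} has no genomic placement")
    for cluster in clusters:
        ids = set(cluster.gene_ids)
        if pair[0] in ids and pair[1] in ids:
            return "tandem"
    return "dispersed"


def compare_cluster_order(cluster_a: GeneCluster, cluster_b: GeneCluster,
                          links: Sequence[OrthologLink]
                          ) -> tuple[str, list[tuple]]:
    """Gene-order comparison of two clusters through their ortholog links.

    Verdict is ``collinear`` (ranks monotone increasing, strands concordant),
    ``inverted`` (ranks monotone decreasing, strands anti-concordant),
    ``rearranged`` otherwise, or ``insufficient links`` with fewer than two
    usable ortholog links.  Strand concordance is a majority vote over the
    linked pairs, so a single-gene strand flip does not flag a whole-cluster
    inversion.  The returned table is the gene-order surrogate for a
    nucleotide dot plot.
    """
    ids_a = set(cluster_a.gene_ids)
    ids_b = set(cluster_b.gene_ids)
    pairs: list[tuple[str, str]] = []
    for link in links:
        if link.relation != "ortholog":
            continue
        if link.gene_a in ids_a and link.gene_b in ids_b:
            pairs.append((link.gene_a, link.gene_b))
        elif link.gene_b in ids_a and link.gene_a in ids_b:
            pairs.append((link.gene_b, link.gene_a))
    if len(pairs) < 2:
        return "insufficient links", []
    table = []
    for ga, gb in pairs:
        ra, rb = cluster_a.rank_of(ga), cluster_b.rank_of(gb)
        sa, sb = cluster_a.strand_of(ga), cluster_b.strand_of(gb)
        table.append((ga, gb, ra, rb, sa, sb, sa == sb))
    table.sort(key=lambda row: (row[2], row[3]))
    ranks_b = [row[3] for row in table]
    increasing = all(x < y for x, y in zip(ranks_b, ranks_b[1:]))
    decreasing = all(x > y for x, y in zip(ranks_b, ranks_b[1:]))
    same_votes = sum(row[6] for row in table)
    majority_same = 2 * same_votes >= len(table)
    if increasing and majority_same:
        verdict = "collinear"
    elif decreasing and not majority_same:
        verdict = "inverted"
    else:
        verdict = "rearranged"
    return verdict, table
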