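"""In-memory pipeline orchestration: scan -> classify -> reconcile -> synteny.

The CLI wraps these stage functions with file I/O; tests and the recovery
benchmarks call them directly on simulator output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import family_scan as fs
from . import phylo_classify as pc
from . import reconcile as rc
from . import synteny_clusters as sc
from .synteny_clusters import GeneFeature
from .trees import Node

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "ClassifyResult", "scan_stage",
           "classify_stage", "reconcile_stage", "synteny_stage",
           "candidate_tree"]

ACROPORID_GENERA = ("Acropora", "Montipora", "Astreopora", "Astrepora")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and knobs for one pipeline run.

    Defaults follow the published values where printed (E-value cutoff 1e-5,
    1000 bootstrap replicates, 90% clade support) and declared surrogates
    elsewhere (coverage/gap completeness rule, cluster gap in gene-order
    units).
    """

    seed: int = 0
    e_threshold: float = fs.DEFAULT_E_THRESHOLD
    coverage_min: float = 0.8
    max_gap_run: int = 30
    support_min: float = pc.DEFAULT_SUPPORT_MIN
    n_replicates: int = pc.DEFAULT_BOOTSTRAP_REPLICATES
    max_intervening: int = sc.DEFAULT_MAX_INTERVENING

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "seed", "e_threshold", "coverage_min", "max_gap_run",
            "support_min", "n_replicates", "max_intervening")}


@dataclass
class ScanResult:
    complete: list[fs.FPCandidate]
    removed: list[fs.FPCandidate]

    @property
    def all_candidates(self) -> list[fs.FPCandidate]:
        return self.complete + self.removed


def scan_stage(proteomes: dict[str, list[tuple[str, str]]],
               features: dict[str, Sequence[GeneFeature]],
               config: RunConfig = RunConfig(),
               panel: Optional[fs.QueryPanel] = None,
               reference: Optional[list[tuple[str, str]]] = None,
               chromophore_columns: Optional[tuple[int, ...]] = None,
               ) -> ScanResult:
    """Run similarity search, domain scan, splitting, completeness filtering
    and chromophore extraction over per-species proteomes."""
    if panel is None:
        panel = fs.load_query_panel()
    if reference is None:
        reference, chromophore_columns = fs.load_reference_alignment()
    profile = fs.build_profile(reference)
    complete_all: list[fs.FPCandidate] = []
    removed_all: list[fs.FPCandidate] = []
    for species in sorted(proteomes):
        feature_of = {f.gene_id: f for f in features.get(species, [])}
        hits = fs.search_candidates(proteomes[species], panel,
                                    e_threshold=config.e_threshold)
        seqs = dict(proteomes[species])
        candidates: list[fs.FPCandidate] = []
        for pid, e, best_q in hits:
            feat = feature_of.get(pid)
            if feat is None:
                logger.warning("hit %s has no gene feature; skipping", pid)
                continue
            cand = fs.FPCandidate(
                gene_id=pid, species=species, scaffold=feat.scaffold,
                start=feat.start, end=feat.end, strand=feat.strand,
                sequence=seqs[pid], best_hit=best_q, evalue=e)
            domain_hits = tuple(fs.scan_domains(cand.sequence, profile))
            cand = fs.replace(cand, domain_hits=domain_hits)
            candidates.extend(fs.split_multidomain(cand)
                              if len(domain_hits) > 1 else [cand])
        complete, removed = fs.filter_complete(
            candidates, reference, coverage_min=config.coverage_min,
            max_gap_run=config.max_gap_run)
        complete = [fs.extract_chromophore(c, reference, chromophore_columns)[0]
                    for c in complete]
        complete_all.extend(complete)
        removed_all.extend(removed)
    return ScanResult(complete_all, removed_all)


@dataclass
class ClassifyResult:
    msa: pc.MSA
    gene_tree: pc.GeneTree
    colors: dict[str, tuple[str, str]]     # leaf -> (class, provenance)

    def color_of(self) -> dict[str, str]:
        return {leaf: cls for leaf, (cls, _) in self.colors.items()}


def _leaf_tag(candidate: fs.FPCandidate) -> str:
    return f"{candidate.species}|{candidate.gene_id}"


def reference_color_classes(panel: fs.QueryPanel) -> dict[str, str]:
    out = {}
    for entry in panel.entries:
        if entry.color == "Red":
            out[entry.accession] = "RFP"
        elif entry.color == "Non-fluorescent":
            out[entry.accession] = "ChrP"
        elif entry.color in ("Green", "Cyan"):
            out[entry.accession] = "GFP/CFP"
    return out


def classify_stage(complete: Sequence[fs.FPCandidate],
                   config: RunConfig = RunConfig(),
                   panel: Optional[fs.QueryPanel] = None) -> ClassifyResult:
    """Align complete candidates with the color-annotated references, build
    a bootstrapped NJ tree, root on the non-acroporid references (midpoint
    fallback), and classify by supported clade membership."""
    if panel is None:
        panel = fs.load_query_panel()
    ref_colors = reference_color_classes(panel)
    sequences = [(e.accession, e.sequence) for e in panel.entries
                 if e.accession in ref_colors]
    sequences += [(_leaf_tag(c), c.sequence) for c in complete]
    msa = pc.align(sequences)
    d, ids = pc.distance_matrix(msa, correction="poisson")
    unrooted = pc.nj_tree(d, ids)
    supports = pc.bootstrap_support(msa, n_replicates=config.n_replicates,
                                    seed=config.seed, correction="poisson")
    outgroup = [e.accession for e in panel.entries
                if e.accession in ref_colors
                and not e.species.startswith(ACROPORID_GENERA)]
    rooted = pc.root_tree(unrooted, outgroup)
    gene_tree = pc.GeneTree(rooted, supports)
    assignment = pc.assign_colors(gene_tree, ref_colors,
                                  support_min=config.support_min)
    return ClassifyResult(msa, gene_tree, assignment)


def candidate_tree(gene_tree: pc.GeneTree, species_tree: Node,
                   reference_ids: set[str]) -> Optional[Node]:
    """Prune reference leaves and re-root the candidate-only tree by
    duplication-loss parsimony."""
    keep = {l for l in gene_tree.root.leaf_labels() if l not in reference_ids}
    pruned = rc._prune_to(gene_tree.root, keep)
    if pruned is None or pruned.is_leaf:
        return pruned
    return rc.parsimony_root(pruned, species_tree)


def reconcile_stage(candidate_root: Node, species_tree: Node,
                    colors: Optional[dict[str, str]] = None
                    ) -> tuple[rc.Reconciliation, rc.EventLedger]:
    """LCA reconciliation plus total and per-class ledgers."""
    rec = rc.lca_map(candidate_root, species_tree)
    ledger = rc.build_ledger(rec, species_tree)
    if colors:
        ledger.classes = rc.per_class_history(candidate_root, colors,
                                              species_tree)
    return rec, ledger


@dataclass
class SyntenyResult:
    clusters: list[sc.GeneCluster]
    links: list[sc.OrthologLink]
    comparisons: list[tuple[str, str, str, int]]


def synteny_stage(features: dict[str, Sequence[GeneFeature]],
                  fp_ids: Sequence[str], rec: Optional[rc.Reconciliation],
                  config: RunConfig = RunConfig(),
                  colors: Optional[dict[str, str]] = None) -> SyntenyResult:
    all_features = [f for flist in features.values() for f in flist]
    clusters = sc.detect_clusters(all_features, fp_ids,
                                  max_intervening=config.max_intervening,
                                  colors=colors)
    links = sc.orthology_links(rec) if rec is not None else []
    comparisons = []
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1:]:
            if ca.species == cb.species:
                continue
            verdict, table = sc.compare_cluster_order(ca, cb, links)
            comparisons.append((f"{ca.species}:{ca.scaffold}",
                                f"{cb.species}:{cb.scaffold}",
                                verdict, len(table)))
    return SyntenyResult(clusters, links, comparisons)
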