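"""Summary tables and packaged fixtures.

Ships the transcription of the published per-species FP counts, the
acroporid backbone species tree with clade annotations, and the stem-branch
event ledger, plus the table builders that mirror them for pipeline output.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

from .reconcile import EventLedger
from .trees import Node, parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "CountsTable",
    "load_table2",
    "load_species_tree",
    "load_species_metadata",
    "load_stem_ledger",
    "make_counts_table",
    "summarize_ancestral",
    "ACROPORA_CLADES",
]

ACROPORA_CLADES = ("I", "II", "III", "IV")

CLASS_ORDER = ("GFP/CFP", "RFP", "ChrP")


def _fixture_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "fixtures", name)


@dataclass
class CountsTable:
    """Per-species class counts; the machine form of the published table."""

    rows: list[tuple[str, str, int, int, int, int]]
    # (species, clade, gfp_cfp, rfp, chrp, fp_total)

    def validate(self) -> None:
        for species, _, g, r, c, total in self.rows:
            if g + r + c != total:
                raise ValueError(
                    f"row {species!r}: {g}+{r}+{c} != total {total}")

    def grand_total(self) -> int:
        return sum(total for *_, total in self.rows)

    def acropora_rows(self) -> list[tuple[str, str, int, int, int, int]]:
        return [row for row in self.rows if row[1] in ACROPORA_CLADES]

    def clade_means(self) -> dict[str, float]:
        sums: dict[str, list[int]] = {}
        for _, clade, *_rest, total in self.rows:
            if clade in ACROPORA_CLADES:
                sums.setdefault(clade, []).append(total)
        return {clade: sum(v) / len(v) for clade, v in sums.items()}

    def write(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("species\tclade\tgfp_cfp\trfp\tchrp\tfp_total\n")
            for row in self.rows:
                handle.write("\t".join(str(x) for x in row) + "\n")


def load_table2(path: Optional[str] = None) -> CountsTable:
    """Load the packaged per-species FP counts fixture."""
    path = path or _fixture_path("table2_counts.tsv")
    rows = []
    with open(path) as handle:
        handle.readline()
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            sp, clade, g, r, c, total = line.rstrip("\n").split("\t")
            rows.append((sp, clade, int(g), int(r), int(c), int(total)))
    table = CountsTable(rows)
    table.validate()
    return table


def load_species_tree(path: Optional[str] = None) -> Node:
    """Load the packaged acroporid backbone species tree."""
    path = path or _fixture_path("species_tree.nwk")
    with open(path) as handle:
        text = "".join(line for line in handle if not line.startswith("#"))
    return parse_newick(text)


def load_species_metadata(path: Optional[str] = None) -> dict[str, str]:
    """Species -> clade annotation (I-IV, Montipora, Astreopora)."""
    table = load_table2(path)
    return {species: clade for species, clade, *_ in table.rows}


def load_stem_ledger(species_tree: Optional[Node] = None,
                     path: Optional[str] = None) -> EventLedger:
    """Load the stem-branch event ledger fixture and propagate copy numbers.

    The fixture records the root complement and the duplications on the
    branch to the Acropora ancestor (total and per class); all other branches
    carry zero events, so copy numbers elsewhere are plain propagation.
    """
    path = path or _fixture_path("stem_ledger.tsv")
    if species_tree is None:
        species_tree = load_species_tree()
    root_copies: dict[str, int] = {}
    branch_events: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as handle:
        handle.readline()
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            record, cls, node, a, b = line.rstrip("\n").split("\t")
            if record == "root_copies":
                root_copies[cls] = int(a)
            elif record == "branch":
                branch_events.setdefault(cls, {})[node] = (int(a), int(b))

    def build(cls: str) -> EventLedger:
        ledger = EventLedger(root_label=species_tree.label)
        for node, (d, l) in branch_events.get(cls, {}).items():
            if d:
                ledger.dups[node] = d
            if l:
                ledger.losses[node] = l
        ledger.copies[species_tree.label] = root_copies.get(cls, 0)
        for node in species_tree.preorder():
            if node.parent is None:
                continue
            ledger.copies[node.label] = (ledger.copies[node.parent.label]
                                         + ledger.dup_count(node.label)
                                         - ledger.loss_count(node.label))
        return ledger

    total = build("total")
    for cls in CLASS_ORDER:
        total.classes[cls] = build(cls)
    total.validate(species_tree)
    total.check_class_sums(species_tree)
    return total


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def make_counts_table(candidates: Sequence, colors: dict[str, str],
                      species_metadata: dict[str, str]) -> CountsTable:
    """Count complete candidates per species and color class.

    ``candidates`` need ``gene_id`` and ``species`` attributes; ``colors``
    maps gene id to class.  A species absent from the metadata gets clade
    ``unknown`` with a warning.
    """
    per_species: dict[str, dict[str, int]] = {}
    for cand in candidates:
        cls = colors.get(cand.gene_id, "unassigned")
        bucket = per_species.setdefault(cand.species, {})
        bucket[cls] = bucket.get(cls, 0) + 1
    rows = []
    for species in sorted(per_species):
        clade = species_metadata.get(species)
        if clade is None:
            logger.warning("species %s missing clade metadata", species)
            clade = "unknown"
        counts = per_species[species]
        g = counts.get("GFP/CFP", 0)
        r = counts.get("RFP", 0)
        c = counts.get("ChrP", 0)
        rows.append((species, clade, g, r, c, g + r + c))
    table = CountsTable(rows)
    table.validate()
    return table


def summarize_ancestral(ledger: EventLedger, species_tree: Node,
                        nodes: Optional[Sequence[str]] = None
                        ) -> list[tuple[str, int, int, int, int]]:
    """Per-node, per-class ancestral complements.

    Returns rows ``(node, gfp_cfp, rfp, chrp, total)``.  Raises ``ValueError``
    naming the first offending node if the class sub-ledgers do not sum to
    the total ledger.
    """
    if nodes is None:
        nodes = [n.label for n in species_tree.preorder() if not n.is_leaf]
    rows = []
    for label in nodes:
        total = ledger.copies_at(label)
        if ledger.classes:
            per = [ledger.classes.get(cls, EventLedger(label)).copies.get(label, 0)
                   for cls in CLASS_ORDER]
            if sum(per) != total:
                raise ValueError(
                    f"class complements {per} do not sum to {total} at {label!r}")
        else:
            per = [0, 0, 0]
        rows.append((label, *per, total))
    return rows
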