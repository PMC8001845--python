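"""Identification of FP candidate genes in a proteome.

Pipeline stage 1: local-alignment search against the packaged 40-entry query
panel, position-specific domain scan, splitting of multi-domain gene models,
completeness filtering, and chromophore extraction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "QueryPanel",
    "PanelEntry",
    "DomainHit",
    "FPCandidate",
    "Profile",
    "load_query_panel",
    "load_reference_alignment",
    "search_candidates",
    "build_profile",
    "scan_domains",
    "split_multidomain",
    "filter_complete",
    "extract_chromophore",
    "write_candidate_table",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_E_THRESHOLD = 1e-5

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}
_B62 = np.zeros((20, 20))
for _i, _a in enumerate(_AA_ORDER):
    for _j, _b in enumerate(_AA_ORDER):
        _B62[_i, _j] = _BLOSUM62[_a][_b]


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _global_aligner() -> Align.PairwiseAligner:
    """Semi-global aligner (free end gaps) used to map candidates onto the
    reference; terminal truncation then shows up as uncovered columns."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0
    return aligner


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - np.log(KA_K)) / np.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value: E = m * n * 2^(-bit score)."""
    return float(m) * float(n) * 2.0 ** (-bit_score(raw_score))


# ---------------------------------------------------------------------------
# query panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    accession: str
    description: str
    species: str
    color: str  # Green | Cyan | Red | Non-fluorescent | unreported
    sequence: str


@dataclass(frozen=True)
class QueryPanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self):
        accs = [e.accession for e in self.entries]
        if len(set(accs)) != len(accs):
            raise ValueError("query panel accessions must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def by_color(self, color: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.color == color]


def _fixture_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "fixtures", name)


def load_query_panel(path: Optional[str] = None) -> QueryPanel:
    """Load the packaged 40-entry query panel (or a panel TSV at ``path``)."""
    path = path or _fixture_path("query_panel.tsv")
    entries = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            entries.append(PanelEntry(
                accession=parts[idx["accession"]],
                description=parts[idx["description"]],
                species=parts[idx["species"]],
                color=parts[idx["color"]],
                sequence=parts[idx["sequence"]]))
    return QueryPanel(tuple(entries))


def load_reference_alignment(path: Optional[str] = None
                             ) -> tuple[list[tuple[str, str]], tuple[int, ...]]:
    """Load the packaged reference FP alignment.

    Returns (rows, chromophore_columns); rows are (id, aligned sequence) and
    chromophore columns are 1-based alignment column indices.
    """
    path = path or _fixture_path("reference_alignment.fasta")
    rows: list[tuple[str, str]] = []
    chromophore: tuple[int, ...] = ()
    with open(path) as handle:
        name, chunks = None, []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(";chromophore_columns="):
                chromophore = tuple(
                    int(x) for x in line.split("=", 1)[1].split(","))
            elif line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if name is not None:
            rows.append((name, "".join(chunks)))
    if not chromophore:
        raise ValueError("reference alignment lacks chromophore annotation")
    return rows, chromophore


# ---------------------------------------------------------------------------
# similarity search
# ---------------------------------------------------------------------------

def search_candidates(proteome: Iterable[tuple[str, str]], panel: QueryPanel,
                      e_threshold: float = DEFAULT_E_THRESHOLD
                      ) -> list[tuple[str, float, str]]:
    """Smith-Waterman search of every protein against the query panel.

    Returns ``(protein id, best E-value, best query accession)`` for proteins
    whose best E-value is at or below ``e_threshold``.  Records containing
    non-amino-acid characters are rejected with a logged warning.
    """
    aligner = _local_aligner()
    hits: list[tuple[str, float, str]] = []
    for pid, seq in proteome:
        if not seq or not set(seq) <= VALID_AA:
            logger.warning("rejecting %s: non-amino-acid characters", pid)
            continue
        best_e, best_q = np.inf, None
        for entry in panel.entries:
            score = aligner.score(entry.sequence, seq)
            e = evalue(score, len(entry.sequence), len(seq))
            if e < best_e:
                best_e, best_q = e, entry.accession
        if best_q is not None and best_e <= e_threshold:
            hits.append((pid, best_e, best_q))
    return hits


# ---------------------------------------------------------------------------
# profile scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Profile:
    """Position-specific score model over the 20 amino acids.

    ``scores[c, a]`` is the mean BLOSUM62 score of amino acid ``a`` against
    the residues observed in retained column ``c`` of the source alignment.
    """

    scores: np.ndarray
    consensus: str
    profile_id: str = "FPdom"

    def __len__(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def window_score(self, fragment: str) -> float:
        idx = np.fromiter((_AA_INDEX[a] for a in fragment), dtype=int)
        return float(self.scores[np.arange(len(idx)), idx].sum())


@dataclass(frozen=True)
class DomainHit:
    start: int   # 1-based inclusive
    end: int
    score: float
    profile_id: str = "FPdom"
    partial: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("DomainHit start must be <= end")


def build_profile(alignment: Sequence[tuple[str, str]],
                  profile_id: str = "FPdom") -> Profile:
    """Build a position-specific score model from an aligned reference set.

    Columns that are gaps in every row are dropped.  Column scores are mean
    BLOSUM62 scores against the observed residues, so a single-row alignment
    reduces to that sequence's substitution-matrix rows.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0][1])
    if any(len(row) != ncol for _, row in alignment):
        raise ValueError("alignment rows differ in length")
    cols: list[np.ndarray] = []
    consensus: list[str] = []
    for c in range(ncol):
        residues = [row[c] for _, row in alignment if row[c] not in "-."]
        if not residues:
            continue
        col = np.mean([_B62[_AA_INDEX[r]] for r in residues], axis=0)
        cols.append(col)
        consensus.append(_AA_ORDER[int(np.argmax(col))])
    return Profile(np.array(cols), "".join(consensus), profile_id)


def scan_domains(protein: str, profile: Profile,
                 threshold: Optional[float] = None) -> list[DomainHit]:
    """All non-overlapping profile hits in a protein, greedily resolved by
    descending score (ties by leftmost start).

    ``threshold`` defaults to 30% of the profile's maximal score; a protein
    shorter than the profile can yield at most one hit, flagged partial, with
    the threshold scaled to the covered fraction.
    """
    L = len(profile)
    if threshold is None:
        threshold = 0.3 * profile.max_score()
    n = len(protein)
    if n == 0:
        return []
    idx = np.fromiter((_AA_INDEX.get(a, -1) for a in protein), dtype=int)
    if (idx < 0).any():
        raise ValueError("protein contains non-amino-acid characters")
    if n < L:
        # best ungapped placement of the whole protein inside the profile
        best = -np.inf
        for off in range(L - n + 1):
            s = float(profile.scores[np.arange(off, off + n), idx].sum())
            best = max(best, s)
        if best >= threshold * (n / L):
            return [DomainHit(1, n, best, profile.profile_id, partial=True)]
        return []
    window_scores = []
    rows = np.arange(L)
    for start in range(n - L + 1):
        s = float(profile.scores[rows, idx[start:start + L]].sum())
        if s >= threshold:
            window_scores.append((s, start))
    window_scores.sort(key=lambda t: (-t[0], t[1]))
    taken: list[DomainHit] = []
    for s, start in window_scores:
        if all(start + L <= h.start - 1 or start >= h.end for h in taken):
            taken.append(DomainHit(start + 1, start + L, s, profile.profile_id))
    taken.sort(key=lambda h: h.start)
    return taken


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FPCandidate:
    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    best_hit: Optional[str] = None
    evalue: Optional[float] = None
    domain_hits: tuple[DomainHit, ...] = ()
    chromophore: Optional[str] = None
    chromophore_flag: str = "unknown"   # canonical | divergent | other | undefined
    complete: Optional[bool] = None
    color_class: str = "unassigned"

    @property
    def was_split(self) -> bool:
        tail = self.gene_id.rsplit("_", 1)[-1]
        return len(tail) == 1 and tail.isalpha() and tail.isupper()


_SUFFIXES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def split_multidomain(candidate: FPCandidate) -> list[FPCandidate]:
    """Split a gene model with several domain hits into one candidate per hit.

    The protein is cut at the midpoints between adjacent hits and the pieces
    get ``_A``, ``_B``, ... suffixes in coordinate order.  A single-domain
    candidate is returned unchanged.
    """
    hits = sorted(candidate.domain_hits, key=lambda h: h.start)
    if len(hits) <= 1:
        return [candidate]
    if len(hits) > 3:
        logger.warning("%s has %d domains; extending suffixes past _C",
                       candidate.gene_id, len(hits))
    seq = candidate.sequence
    cut_points = [0]
    for left, right in zip(hits, hits[1:]):
        cut_points.append((left.end + right.start - 1) // 2)
    cut_points.append(len(seq))
    pieces: list[FPCandidate] = []
    for i, hit in enumerate(hits):
        lo, hi = cut_points[i], cut_points[i + 1]
        piece_seq = seq[lo:hi]
        shifted = DomainHit(hit.start - lo, hit.end - lo, hit.score,
                            hit.profile_id, hit.partial)
        if candidate.strand == "-":
            g_end = candidate.end - 3 * lo
            g_start = candidate.end - 3 * hi + 1
        else:
            g_start = candidate.start + 3 * lo
            g_end = candidate.start + 3 * hi - 1
        pieces.append(replace(
            candidate,
            gene_id=f"{candidate.gene_id}_{_SUFFIXES[i]}",
            sequence=piece_seq,
            start=g_start, end=g_end,
            domain_hits=(shifted,)))
    return pieces


# ---------------------------------------------------------------------------
# completeness and chromophore
# ---------------------------------------------------------------------------

def _reference_consensus(reference: Sequence[tuple[str, str]]) -> str:
    return build_profile(reference).consensus


def _map_to_reference(candidate_seq: str, consensus: str) -> dict[int, int]:
    """Map 1-based reference positions to 1-based candidate positions."""
    aligner = _global_aligner()
    alignment = aligner.align(consensus, candidate_seq)[0]
    mapping: dict[int, int] = {}
    for (t_lo, t_hi), (q_lo, q_hi) in zip(*alignment.aligned):
        for k in range(t_hi - t_lo):
            mapping[t_lo + k + 1] = q_lo + k + 1
    return mapping


def filter_complete(candidates: Sequence[FPCandidate],
                    reference: Sequence[tuple[str, str]],
                    coverage_min: float = 0.8,
                    max_gap_run: int = 30
                    ) -> tuple[list[FPCandidate], list[FPCandidate]]:
    """Partition candidates into complete and removed sets.

    A candidate is complete iff its alignment to the reference consensus
    covers at least ``coverage_min`` of the reference columns and contains no
    internal run of more than ``max_gap_run`` uncovered columns.
    """
    consensus = _reference_consensus(reference)
    nref = len(consensus)
    complete_set: list[FPCandidate] = []
    removed: list[FPCandidate] = []
    for cand in candidates:
        mapping = _map_to_reference(cand.sequence, consensus)
        covered = sorted(mapping)
        ok = False
        if covered:
            coverage = len(covered) / nref
            longest_internal = 0
            run = 0
            for pos in range(covered[0], covered[-1] + 1):
                if pos in mapping:
                    longest_internal = max(longest_internal, run)
                    run = 0
                else:
                    run += 1
            longest_internal = max(longest_internal, run)
            ok = coverage >= coverage_min and longest_internal <= max_gap_run
        out = replace(cand, complete=ok)
        (complete_set if ok else removed).append(out)
    return complete_set, removed


def extract_chromophore(candidate: FPCandidate,
                        reference: Sequence[tuple[str, str]],
                        chromophore_columns: tuple[int, ...],
                        ) -> tuple[FPCandidate, str, str]:
    """Read the residues at the reference chromophore columns.

    Returns (updated candidate, tripeptide, flag) where flag is ``canonical``
    (X-Y-G), ``divergent`` (X-F-G), ``other``, or ``undefined`` when any
    chromophore column is gapped in the candidate.
    """
    rows = reference
    consensus = _reference_consensus(rows)
    # translate alignment columns to consensus (ungapped) positions using the
    # first reference row's gap pattern — the packaged alignment is gapless,
    # in which case columns equal positions.
    ref_row = rows[0][1]
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch not in "-.":
            pos += 1
            col_to_pos[col] = pos
    mapping = _map_to_reference(candidate.sequence, consensus)
    residues = []
    for col in chromophore_columns:
        ref_pos = col_to_pos.get(col)
        cand_pos = mapping.get(ref_pos) if ref_pos else None
        residues.append(candidate.sequence[cand_pos - 1] if cand_pos else "-")
    tri = "".join(residues)
    if "-" in tri:
        flag = "undefined"
    elif tri[1] == "Y" and tri[2] == "G":
        flag = "canonical"
    elif tri[1] == "F" and tri[2] == "G":
        flag = "divergent"
    else:
        flag = "other"
    updated = replace(candidate, chromophore=None if flag == "undefined" else tri,
                      chromophore_flag=flag)
    return updated, tri, flag


def write_candidate_table(candidates: Sequence[FPCandidate], path: str) -> None:
    cols = ["gene_id", "species", "scaffold", "start", "end", "strand",
            "evalue", "n_domains", "chromophore", "chromophore_flag",
            "complete", "color_class"]
    with open(path, "w") as handle:
        handle.write("\t".join(cols) + "\n")
        for c in candidates:
            handle.write("\t".join([
                c.gene_id, c.species, c.scaffold, str(c.start), str(c.end),
                c.strand, "." if c.evalue is None else f"{c.evalue:.3g}",
                str(len(c.domain_hits)), c.chromophore or ".",
                c.chromophore_flag,
                "." if c.complete is None else str(int(c.complete)),
                c.color_class]) + "\n")
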