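"""Regenerate the sequence-bearing packaged fixtures.

The published query panel lists accessions and reported colors but not the
sequences themselves; the packaged panel therefore carries deterministic
synthetic stand-in sequences derived from the simulator's seed proteins, one
family branch per color class, so that scanning and classification behave
like the real panel would.  Run from the repository root:

    python scripts/build_fixtures.py
"""

from __future__ import annotations

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from acrofp.synthetic_data import (AMINO_ACIDS, CHROMOPHORE_POSITIONS,
                                   SEED_PROTEINS)

FIXDIR = os.path.join(os.path.dirname(__file__), "..", "src", "acrofp",
                      "fixtures")

# (accession, description, species, reported color)
PANEL = [
    ("AAU06846.1", "green fluorescent protein", "Acropora millepora", "Green"),
    ("FAA00739.1", "TPA: fluorescent protein 2", "Acropora digitifera", "unreported"),
    ("ABB17973.1", "green fluorescent GFP-like protein", "Acropora millepora", "Green"),
    ("ACH89428.1", "green fluorescent protein FP512", "Acropora millepora", "Green"),
    ("FAA00741.1", "TPA: fluorescent protein 4", "Acropora digitifera", "unreported"),
    ("FAA00743.1", "TPA: fluorescent protein 6, partial", "Acropora digitifera", "unreported"),
    ("FAA00742.1", "TPA: fluorescent protein 5, partial", "Acropora digitifera", "unreported"),
    ("AAU06851.1", "cyan fluorescent protein 2", "Acropora robusta", "Cyan"),
    ("FAA00738.1", "TPA: fluorescent protein 1", "Acropora digitifera", "unreported"),
    ("ACH53606.1", "green fluorescent-like protein, partial", "Acropora millepora", "Green"),
    ("ACH89426.1", "cyan fluorescent protein FP484", "Acropora millepora", "Cyan"),
    ("AAU06849.1", "cyan fluorescent protein", "Acropora millepora", "Cyan"),
    ("ACH89427.1", "green fluorescent protein FP497", "Acropora millepora", "Green"),
    ("FAA00740.1", "TPA: fluorescent protein 3", "Acropora digitifera", "unreported"),
    ("AAS18271.1", "green fluorescent protein 2", "Astrangia lajollaensis", "Green"),
    ("AAT77753.1", "colorless GFP-like protein", "Acropora millepora", "Red"),
    ("ACH53607.1", "red fluorescent-like protein, partial", "Acropora millepora", "Red"),
    ("ACH89429.1", "red fluorescent protein FP597", "Acropora millepora", "Red"),
    ("AAU06852.1", "red fluorescent protein", "Acropora millepora", "Red"),
    ("FAA00746.1", "TPA: fluorescent protein 10", "Acropora digitifera", "unreported"),
    ("ACD13194.1", "green fluorescent GFP-like protein", "Platygyra lamellina", "Cyan"),
    ("ABB17955.1", "cyan fluorescent GFP-like protein", "Mycedium elephantotus", "Green"),
    ("AAM10625.3", "green fluorescent protein", "Dendronephthya sp. SSAL-2002", "Green"),
    ("ABB17949.1", "GFP-like chromoprotein", "Goniopora djiboutiensis", "Non-fluorescent"),
    ("FAA00744.1", "TPA: fluorescent protein 7, partial", "Acropora digitifera", "unreported"),
    ("FAA00745.1", "TPA: fluorescent protein 9, partial", "Acropora digitifera", "unreported"),
    ("BAM10197.1", "fluorescent protein 8", "Acropora digitifera", "unreported"),
    ("AAU06854.1", "chromoprotein", "Acropora millepora", "Non-fluorescent"),
    ("AAG16224.1", "red fluorescent protein", "Discosoma sp. SSAL-2000", "Red"),
    ("AAF03370.1", "fluorescent protein FP483", "Discosoma striata", "unreported"),
    ("XP_001634522.1", "predicted protein", "Nematostella vectensis", "unreported"),
    ("XP_001633713.1", "predicted protein", "Nematostella vectensis", "unreported"),
    ("AAN05449.1", "red fluorescent protein FP611", "Entacmaea quadricolor", "Red"),
    ("AAL27541.1", "GFP-like chromoprotein", "Condylactis passiflora", "Green"),
    ("AAK71342.1", "cgigFP-g", "Condylactis gigantea", "Non-fluorescent"),
    ("AAQ01187.1", "green fluorescent protein 2", "Pontella meadi", "Green"),
    ("AAQ01186.1", "green fluorescent protein 1", "Pontella meadi", "Green"),
    ("BAE78442.1", "green fluorescent protein", "Chiridius poppei", "Green"),
    ("AAR85351.1", "green fluorescent protein 2", "Anthomedusae sp. SL-2003", "Green"),
    ("AAR85350.1", "green fluorescent protein 1", "Anthomedusae sp. SL-2003", "Green"),
]

REFERENCE_ROWS = [
    "AAU06846.1", "ACH89428.1", "AAU06849.1", "ACH89426.1", "AAS18271.1",
    "ACH89429.1", "AAN05449.1", "AAU06854.1", "ABB17949.1",
]

_CLASS_OF_COLOR = {"Red": "RFP", "Non-fluorescent": "ChrP"}


def _derive(seed_seq: str, divergence: float, rng: np.random.Generator,
            chromophore: str) -> str:
    c0 = CHROMOPHORE_POSITIONS[0] - 1
    seq = list(seed_seq)
    n_sub = int(divergence * len(seq))
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for s in sites:
        if c0 <= s < c0 + 3:
            continue
        alternatives = [a for a in AMINO_ACIDS if a != seq[s]]
        seq[s] = alternatives[rng.integers(len(alternatives))]
    seq[c0:c0 + 3] = list(chromophore)
    return "".join(seq)


def _blend(class_seed: str, family_seed: str, fraction: float,
           rng: np.random.Generator, chromophore: str) -> str:
    """A sequence part-way between the class seed and the family ancestor:
    a stand-in for an early-diverging (basal) member of the class."""
    c0 = CHROMOPHORE_POSITIONS[0] - 1
    seq = list(class_seed)
    for i, (a, b) in enumerate(zip(class_seed, family_seed)):
        if a != b and rng.random() < fraction and not c0 <= i < c0 + 3:
            seq[i] = b
    seq[c0:c0 + 3] = list(chromophore)
    return "".join(seq)


def main() -> None:
    rng = np.random.default_rng(40)
    sequences: dict[str, str] = {}
    lines = ["accession\tdescription\tspecies\tcolor\tsequence"]
    # stagger divergences so each class has near-basal and derived members;
    # the first RFP / ChrP entry is blended toward the family ancestor so
    # the class references bracket the whole class clade in the tree
    ladder: dict[str, int] = {}
    for accession, description, species, color in PANEL:
        cls = _CLASS_OF_COLOR.get(color, "GFP/CFP")
        chromophore = "DYG" if cls == "RFP" else "QYG"
        rank = ladder.get(cls, 0)
        ladder[cls] = rank + 1
        if cls in ("RFP", "ChrP") and rank == 0:
            seq = _blend(SEED_PROTEINS[cls], SEED_PROTEINS["GFP/CFP"],
                         0.35, rng, chromophore)
        else:
            steps = [0.03, 0.06, 0.10, 0.14, 0.18]
            divergence = steps[rank % len(steps)]
            seq = _derive(SEED_PROTEINS[cls], divergence=divergence, rng=rng,
                          chromophore=chromophore)
        sequences[accession] = seq
        lines.append("\t".join([accession, description, species, color, seq]))
    with open(os.path.join(FIXDIR, "query_panel.tsv"), "w") as handle:
        handle.write("\n".join(lines) + "\n")

    cols = ",".join(str(c) for c in CHROMOPHORE_POSITIONS)
    ref_lines = [f";chromophore_columns={cols}"]
    for accession in REFERENCE_ROWS:
        ref_lines.append(f">{accession}")
        ref_lines.append(sequences[accession])
    with open(os.path.join(FIXDIR, "reference_alignment.fasta"), "w") as handle:
        handle.write("\n".join(ref_lines) + "\n")
    print(f"wrote fixtures to {os.path.abspath(FIXDIR)}")


if __name__ == "__main__":
    main()
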