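from __future__ import annotations

import pytest

from acrofp import synthetic_data as sd
from acrofp.synteny_clusters import GeneFeature


def parse_sim_fasta(text: str) -> list[tuple[str, str]]:
    records, name, chunks = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif line:
            chunks.append(line)
    if name:
        records.append((name, "".join(chunks)))
    return records


def parse_sim_gff(text: str, species: str) -> list[GeneFeature]:
    feats = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=") for kv in f[8].split(";"))
        feats.append(GeneFeature(attrs["ID"], species, f[0], int(f[3]),
                                 int(f[4]), f[6], attrs["family"]))
    return feats


def sim_inputs(fastas: dict[str, str], gffs: dict[str, str]):
    proteomes = {sp: parse_sim_fasta(t) for sp, t in fastas.items()}
    features = {sp: parse_sim_gff(gffs[sp], sp) for sp in gffs}
    return proteomes, features


def true_fp_counts(features) -> dict[str, int]:
    return {sp: sum(1 for f in flist if f.family == "FP")
            for sp, flist in features.items()}


@pytest.fixture(scope="session")
def query_panel():
    from acrofp.family_scan import load_query_panel
    return load_query_panel()


@pytest.fixture(scope="session")
def reference_alignment():
    from acrofp.family_scan import load_reference_alignment
    return load_reference_alignment()


@pytest.fixture(scope="session")
def recovery_sim():
    """One simulated low-divergence dataset shared across tests."""
    config = sd.preset("recovery", seed=2)
    fastas, gffs, log = sd.simulate_family(config)
    return config, fastas, gffs, log
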