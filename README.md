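# acrofp

Gene-family expansion analysis for coral (acroporid) fluorescent proteins:

- **`synthetic_data`** — birth–death simulator for an FP-like gene family on a
  species tree, with tandem vs dispersed duplicate placement, Poisson
  amino-acid substitution with a protected chromophore tripeptide (X-Y-G),
  chromophore class switches, decoy background genes, and a lossless
  ground-truth event log.
- **`family_scan`** — candidate identification in a proteome: Smith–Waterman
  search against a packaged 40-entry query panel (Karlin–Altschul E-values,
  default cutoff 1e-5), position-specific domain scan, splitting of
  multi-domain gene models (`_A`/`_B`/`_C` suffixes), completeness filtering,
  chromophore extraction.
- **`phylo_classify`** — center-star multiple alignment, p-distance matrices
  (optional Poisson correction), neighbor-joining trees, column-resampling
  bootstrap (default 1000 replicates), outgroup/midpoint rooting, and color
  classification from supported RFP / ChrP clades (support ≥ 90%; GFP/CFP is
  the default class).
- **`reconcile`** — LCA duplication–loss parsimony reconciliation of gene
  trees against the species tree, per-branch event ledgers with ancestral
  copy numbers, per-color-class histories, random polytomy resolution, and a
  parsimony rooting fallback.
- **`synteny_clusters`** — FP gene clusters on scaffolds (gap measured in
  intervening gene count), ortholog/paralog links from the reconciliation,
  tandem vs dispersed duplication calls, and gene-order comparison between
  clusters (collinear / inverted / rearranged).
- **`report`** + **`cli`** — counts tables, ancestral complement summaries,
  packaged fixtures (per-species count table, acroporid backbone species
  tree, stem-branch event ledger, query panel), and a stage-oriented CLI.

## CLI

```bash
# simulate a dataset and run every stage
acrofp all --preset recovery --seed 1 --out runs/demo

# or stage by stage
acrofp simulate --preset acroporid --seed 1 --out runs/acro
acrofp scan     --run runs/acro
acrofp classify --run runs/acro --n-replicates 100
acrofp reconcile --run runs/acro
acrofp synteny  --run runs/acro
acrofp report   --run runs/acro
```

Outputs are TSV / Newick / aligned FASTA; every table carries a config hash
and the seed, and identical configurations reproduce identical bytes.
Exit codes: 0 success, 2 bad input, 3 stage failure.

## Fixture regeneration

`scripts/build_fixtures.py` regenerates the sequence-bearing fixtures
(query panel sequences and the reference alignment) deterministically; the
panel's accessions, descriptions and reported colors are transcriptions,
while the sequences are synthetic stand-ins derived from the simulator's
seed proteins.
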