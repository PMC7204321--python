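# netpharm

A network-pharmacology inference toolkit for multi-herb remedies: compound
ADME/drug-likeness screening, herb-compound-target network assembly,
drug/disease target intersection, iterative centrality-based core-target
screening of PPI networks, and hypergeometric gene-set enrichment.

The package ships a worked case study as packaged fixtures: a 77-entry
herb-compound descriptor table over eight herbs, a 161-protein drug-target
table, and a 38-gene disease-target list. Every pipeline stage is also
exercisable on synthetic inputs from seeded generators, so nothing requires
database access.

## Features

- **ADME screen** (`netpharm.adme_screen`) — six inclusive descriptor
  thresholds (MW ≤ 500, AlogP ≤ 5, Hdon ≤ 5, Hacc ≤ 10, OB ≥ 30 %,
  DL ≥ 0.18) plus the Tanimoto drug-likeness coefficient
  `A·B / (|A|² + |B|² − A·B)` against a descriptor reference set.
- **Target assembly** (`netpharm.target_assembly`) — gene-symbol
  deduplication, score-filtered disease lists, drug/disease intersection,
  and bipartite herb-compound / compound-target networks.
- **Topology screen** (`netpharm.topology_screen`) — degree, Wasserman-Faust
  closeness, and normalized betweenness; multi-round inclusive threshold
  screening in fixed-centralities (default) or recompute mode; quantile-based
  threshold suggestion.
- **Enrichment** (`netpharm.enrichment`) — exact one-sided hypergeometric
  over-representation with Benjamini-Hochberg adjustment and an optional
  conservative `k−1` (EASE-style) variant.
- **Synthetic data** (`netpharm.synthetic_data`) — seeded, bit-reproducible
  generators for compound tables, overlapping target lists, planted-core PPI
  networks, and planted-enrichment annotation collections.
- **IO** (`netpharm.tables_io`) — TSV/CSV tables, STRING-style scored edge
  lists (unit or 0-999 scale), GMT gene sets, gene lists, and
  Cytoscape-compatible SIF/GraphML export.

## CLI

```sh
netpharm screen --compounds compounds.tsv --out kept.tsv --summary summary.json
netpharm intersect --drug-targets drug.tsv --disease-targets disease.tsv \
    --score-min 57.56 --out genes.txt
netpharm network --compounds kept.tsv --out herb_compound
netpharm ppi-screen --edges ppi.tsv --score-min 0.7 \
    --round "dc=20,cc=0.685,bc=0.011" --round "dc=26,cc=0.771,bc=0.029" \
    --out rounds.json
netpharm enrich --genes genes.txt --gmt sets.gmt --background bg.txt --out table.tsv
netpharm simulate --scenario all --seed 42 --out simdir/
netpharm run --config cfg.yaml --out outdir/
```

A minimal pipeline configuration using the packaged fixtures:

```yaml
fixtures: paper
```

which screens the packaged compound table (77 entries kept, 72 unique
molecules), deduplicates targets (161 gene symbols), and intersects with the
disease list (38 shared genes); the PPI and enrichment stages are skipped
unless you configure `ppi.edges` / `enrich.gmt` (for example from
`netpharm simulate` output — see `tests/test_pipeline_cli.py` for a full
synthetic configuration).

## Layout

```
src/netpharm/          package modules
src/netpharm/data/     packaged fixture tables (UTF-8 TSV)
tests/                 pytest suite (unit, property, acceptance)
scripts/acceptance.py  acceptance report generator
```
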