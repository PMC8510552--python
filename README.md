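# assemblage

Community-assembly and species-association analysis for OTU count tables:

- **Synthetic data** (`assemblage.synth`): birth–death trees, Brownian niche
  traits, a stations × depth-layers sampling design, and OTU tables assembled
  under tunable mixtures of environmental selection, dispersal limitation,
  homogenizing dispersal, and drift — with ground truth attached.
- **I/O and preprocessing** (`assemblage.io`): TSV / BIOM (JSON) OTU tables,
  sample metadata, rarefaction without replacement, prevalence filtering,
  haversine geographic distances.
- **Phylogenetic signal** (`assemblage.signal`): abundance-weighted niche
  values and Mantel correlograms with permutation tests and progressive Holm
  correction.
- **Assembly null models** (`assemblage.nullmodels`): weighted βMNTD, βNTI
  against a tip-shuffled null, Raup–Crick on Bray–Curtis, and the
  classification of community pairs into selection / dispersal limitation /
  homogenizing dispersal / drift.
- **Neutral community model** (`assemblage.ncm`): Sloan-model fit of
  occurrence frequency vs mean relative abundance (least-squares Nm, R²,
  Wilson confidence band, OTU bootstrap CI) and the per-OTU
  above/within/below partition.
- **Community statistics** (`assemblage.stats`): Bray–Curtis, Mantel /
  partial Mantel / MRM with permutation inference, dissimilarity–environment
  regressions, Levins' niche breadth, rank-sum comparisons, and CCA-based
  variation partitioning with PCA (Kaiser–Guttman) environmental axes and
  dbMEM spatial axes.
- **Co-occurrence networks** (`assemblage.network`): SparCC correlations with
  bootstrap p-values and BH-FDR, thresholded graph construction, topology
  summaries, Louvain modules, within-module degree (z) / participation
  coefficient (c) node roles, balanced subsampling, and per-sample
  subnetworks.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
identities, null-model calibration, ground-truth process recovery,
neutral-model parameter recovery, SparCC and node-role oracles).

## CLI

Each stage is a subcommand taking a `key=value` config file plus `--seed`
and `--outdir`; parameters and library versions are logged to
`<outdir>/run.log`.

```bash
assemblage simulate --seed 1 --outdir out/sim
assemblage rarefy   --table out/sim/synthetic_otu_table.tsv --depth 1000 --outdir out/rar
assemblage signal   --table ... --metadata ... --tree ... --variable temperature
assemblage assembly --table ... --metadata ... --tree ... --n-null 1000
assemblage ncm      --table ... --n-bootstrap 1000
assemblage niche    --table ...
assemblage stats    --table ... --metadata ... --variables temperature,salinity
assemblage network  --table ... --prevalence 0.6 --r-min 0.7 --p-max 0.01
```

Example end-to-end run on synthetic data:

```bash
assemblage simulate --seed 7 --outdir out/sim
assemblage assembly \
    --table out/sim/synthetic_otu_table.tsv \
    --metadata out/sim/synthetic_metadata.tsv \
    --tree out/sim/synthetic_tree.nwk \
    --n-null 200 --seed 7 --outdir out/assembly
```

## Notes on conventions

- Prevalence filtering is strict (`> min_fraction`).
- βNTI nulls shuffle OTU identities across all tips; standardization is per
  sample pair; |βNTI| > 2 and |RC| > 0.95 are the default process
  thresholds (configurable).
- The neutral-model detection limit defaults to 1 / mean reads per sample.
- Network topology metrics are computed on the unsigned, unweighted simple
  graph; diameter and average path length use the largest connected
  component; edge signs feed only the positive/negative edge percentages.
- Node-role categories partition nodes by the z = 2.5 and c = 0.6
  thresholds.
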