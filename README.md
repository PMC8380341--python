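# cerna

Integrated competing-endogenous-RNA (ceRNA) network inference from
feature-by-sample count matrices and transcript sequences, with a synthetic
data generator for end-to-end validation against planted ground truth.

The pipeline has five stages:

1. **synthdata** — negative-binomial count matrices around log-normal
   baselines for four RNA classes (mRNA, lncRNA, circRNA, miRNA), with
   planted fold changes and planted sponge–miRNA–mRNA triads whose sequences
   carry real 8mer seed sites; emits the truth set for recovery testing.
2. **diffexpr** — per-feature two-sided Fisher's exact test on group-pooled
   counts versus pooled mapped-library totals; log2 fold change on group
   means of normalized abundance (CPM; SRPBM for circRNAs); direction calls
   at |log2FC| > 1 with per-class alpha (0.05 default, 0.01 for miRNA);
   BH-adjusted q reported. Includes a 2^−ΔΔCt helper and a circRNA
   genomic-origin summary.
3. **targetpred** — dual, independent miRNA-target scorers intersected:
   canonical seed-site scanning (6mer / 7mer-A1 / 7mer-m8 / 8mer; circular
   targets scanned across the back-splice junction) with a 0–100
   context-style score, and local duplex alignment (Watson–Crick + G:U,
   affine gaps, extra seed-mismatch penalty) with an additive hybridization
   energy. A pair passes when context ≥ 50 **and** energy < −10.
4. **cernet** — direction-consistent network assembly (miRNA opposite its
   partners), sponge–miRNA–mRNA triads (up-down-up / down-up-down),
   lncRNA+circRNA quad integration on shared miRNA and mRNA, distinct-miRNA
   hub ranking, and SIF/GraphML/TSV export (Cytoscape-ready).
5. **enrich** — hypergeometric over-representation of the DE gene set
   against a user-supplied GMT collection, BH-adjusted, with an optional
   EASE-style (k−1) mode.

## CLI

```sh
cerna simulate --out-dir data --seed 1 --n-triads 10
cerna diffexpr --counts mRNA=data/mRNA_counts.tsv ... \
    --sample-map data/sample_map.tsv --totals data/mapped_totals.tsv --out de.tsv
cerna targets --mirna-fasta data/miRNA.fasta --target-fasta mRNA=data/mRNA.fasta ... --out pairs.tsv
cerna network --de de.tsv --pairs pairs.tsv --out-dir net/
cerna enrich --de de.tsv --gmt terms.gmt --out enrichment.tsv
cerna run-all --config config.yaml --seed 1 --out-dir out/
```

`run-all` consumes a YAML `PipelineConfig` (see `cerna.pipeline`); with no
`data_dir` it simulates a dataset first. All outputs are TSVs with
`#`-prefixed provenance headers plus SIF/GraphML network exports, and are
byte-identical across reruns at a fixed seed.

## File formats

- FASTA with `class=` / `topology=` header fields (`topology=circular`
  marks back-splice-junction sequences stored linearized, junction at
  position 1; `T` is read as `U`).
- Count TSV: first column `feature_id`, remaining columns sample ids.
- Sample map TSV: `sample_id`, `group` ∈ {case, control}.
- Mapped totals TSV: `sample_id`, `mapped_total`.
- GMT: `term<TAB>description<TAB>member...`; a `BP|name`-style description
  sets the GO category.
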