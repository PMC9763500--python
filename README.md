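# epioverlap

Tools for asking a sharp question about epigenome-wide association
studies (EWAS): **do the genes tagged by trait-associated DNA-methylation
sites coincide with the genes tagged by GWAS of the same trait, beyond
what genomic position alone would produce?** If EWAS signal is dominated
by confounding and reverse causation, its hit genes need not be the
causal genes GWAS tags — and the degree of overlap, measured carefully,
carries information about that architecture.

The package is aimed at statistical geneticists and epigenetics
researchers working with summary statistics. It provides:

- **Mapping** — fixed-width (500 kb) genome binning with probe-based
  block filtering and region co-occurrence tallies; nearest-gene
  assignment of significant sites (all containing genes, else the
  nearest by edge distance, ties to all).
- **Overlap statistics** — for EWAS gene list E, GWAS gene list G and
  universe U, the gene-overlap odds ratio

  OR = (a·d)/(b·c),  a = |E∩G|, b = |E∖G|, c = |G∖E|, d = |U| − |E∪G|

  with a two-sided Fisher exact p; per-geneset enrichment ORs of the
  same form; Spearman correlation ρ between two studies' enrichment
  profiles; Benjamini–Hochberg FDR; rank AUC with DeLong 95% CI.
- **Resampling nulls** — expected overlap from (a) random genomic
  positions and (b) spacing-preserving shifted positions
  (BP_new = BP + max gene size × iteration, wrapping last chromosome →
  first), each with a z-test `p_diff` for the observed statistic.
- **Power simulation** — how well each overlap statistic distinguishes
  an EWAS sampling partly causal genes from one sampling none, as a
  function of detection power, list size and causal proportion
  (scenario-vs-null AUC).
- **Architecture inference** — given known GWAS/EWAS genes, a grid of
  candidate architectures (total-gene multipliers 1–20×, pool overlap
  0–1) is re-simulated and scored against the observed enrichment
  correlation; scenarios incompatible at FDR < 0.05 are flagged.
- **Synthetic data** — genomes, gene models, genesets and full
  GWAS/EWAS summary-statistics tables with known causal/associated
  architecture and per-study detection power, so every stage runs with
  ground truth and no downloads.

Inputs are plain text: UCSC `chrom.sizes`, a BED-like gene table, GMT
genesets, and tab-separated summary statistics (`site_id, chromosome,
position, p_value[, effect]`; common aliases accepted). The package is
a library: `examples/` contains one short runnable script per
capability, in order.

## Worked example

```sh
cd examples
python 01_simulate_bundle.py     # writes example_bundle/
python 03_gene_geneset_overlap.py
python 04_null_distributions.py
```

prints (seeded, so reproducible):

```
GWAS: 54 sites -> 54 genes
EWAS: 54 sites -> 54 genes
gene overlap: a=27, OR=8.11, Fisher p=1.06e-09
geneset overlap: a=60, OR=inf
enrichment-score correlation: rho=0.309

observed gene-overlap OR: 8.11
random positions   expected OR = 1.05  p_diff = 6.33e-64
shifted positions  expected OR = 1.00  p_diff = 1.90e-32
```

The bundle was generated with causal and associated pools of 60 genes
sharing 30, and both studies at 90% power: 27 of the ~54 genes each
study detects coincide, an odds ratio of 8.1 against a 300-gene
universe. Both resampling nulls put the expected OR at ≈1, so the
observed overlap is far beyond positional chance (`p_diff`), and the
two null schemes agree with each other. The +inf geneset-overlap OR is
the saturation convention: with a 60-set panel, both studies identify
every geneset, so the identified-set lists coincide; the enrichment
correlation remains informative there. `05_power_simulation.py` and
`06_architecture_inference.py` run the two simulation frameworks the
same way.

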