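# Methods

`epioverlap` quantifies how much of the signal found by epigenome-wide
association studies (EWAS) coincides with the signal found by genome-wide
association studies (GWAS) of the same trait, and simulates what such
coincidence — or its absence — implies about trait architecture. This note
records the models, the parameter choices, the numerical conventions and
the limits of what the synthetic-data experiments can show.

## The model of a trait

A trait is described by two gene pools:

- **causal genes** — genes whose products influence the trait. GWAS hits
  are assumed to tag these.
- **associated genes** — genes whose activity correlates with the trait
  through any mechanism: causation, confounding, or reverse causation
  (the trait altering methylation). EWAS hits are assumed to tag these.

The single architecture parameter of interest is the overlap between the
pools: the fraction of associated genes that are also causal. If EWAS
mostly detects reverse-causation and confounding signal, the overlap is
small and GWAS/EWAS hit lists should coincide no more than chance allows.

## Observed-overlap statistics

Sites significant at the study threshold (GWAS p < 5×10⁻⁸, EWAS
p < 1×10⁻⁷, both configurable) are mapped to genes, and three statistics
compare the two gene lists over a declared gene universe U:

1. **Gene-overlap odds ratio.** With a = |E∩G|, b = |E∖G|, c = |G∖E|,
   d = |U| − |E∪G|, the cross-product ratio OR = (a·d)/(b·c), with a
   two-sided Fisher exact p-value. The odds of a gene being identified
   by both studies are compared with the odds of being identified by the
   EWAS only.
2. **Geneset-enrichment profiles and their correlation.** For every
   geneset S the same 2×2 machinery gives an enrichment OR for each
   study's hit list. Enrichment scores are heavily non-normal — many
   zeros (no hit in the set), occasional infinities — so profiles are
   compared by Spearman rank correlation; since log is monotone, ranks
   of the raw scores equal ranks of the log scores, and zeros/infinities
   participate through their ranks.
3. **Direct geneset overlap.** A geneset counts as "identified" by a
   study when at least one hit gene is a member; the identified-set
   lists enter the same 2×2 odds ratio over the geneset universe.

Conventions: no continuity correction and no pseudo-count by default
(zero scores are meaningful and preserved; a Haldane–Anscombe-style
adjustment would distort the rank structure the correlation relies on).
When b·c = 0 the OR is +∞ for a non-empty intersection — one list
contains the other with empty complement cells, which also resolves the
0/0 corner where both lists cover the whole universe (this arises at
desk scale when a small geneset panel is saturated by both studies) —
and 0 when the intersection is empty. The gene universe is all genes in
the loaded annotation by default, with a protein-coding-only mode; the
universe size is an explicit, configurable input precisely because the
2×2 cell d depends on it.

### Region analysis

Each chromosome is tiled into 500 kb blocks; blocks without a
methylation probe are removed (arrays measure a small minority of CpG
sites, so unprobed blocks are uninformative). Retained blocks are
classified as containing significant GWAS sites, EWAS sites, both or
neither, at a lenient threshold of min(1×10⁻⁵, the maximum p-value
reported in the EWAS). A rank AUC asks whether the largest |GWAS
effect| in a block predicts the presence of an EWAS hit there.

### Site-to-gene mapping

A site maps to every gene whose body contains it; otherwise to the
gene(s) at minimal distance on the same chromosome, where distance is
base pairs from the site to the nearer gene edge (coordinates are
0-based half-open throughout; BED-style input passes through unchanged
and 1-based input is converted on read). Equidistant ties map to all
tied genes — deterministic, with no arbitrary left/right preference and
consistent with the many-to-many treatment of sites inside overlapping
genes. Strand is ignored. Sites on chromosomes without genes are
counted and reported, never silently dropped.

## Expected overlap: two resampling nulls

- **Random positions**: per repetition, as many uniform positions on
  the concatenated genome (length-weighted across chromosomes) as the
  EWAS had significant sites; positions are mapped to genes and every
  statistic recomputed against the fixed GWAS results. Default 1000
  repetitions.
- **Shifted positions**: repetition I advances every observed site by
  `max gene size × I` along the concatenated genome, wrapping from the
  last chromosome to the first. This preserves the multiset of
  inter-site gaps, hence approximately the local correlation structure
  of the probe panel. The shift unit is the global maximum gene length
  in the loaded annotation — the only reading that gives one fixed
  offset per iteration; shifts exceeding the genome length reduce
  modulo its total length with a logged note.

The reported `p_diff` is a two-sided z-test of the observed statistic
against the null's mean and standard deviation. A calibration check in
the test suite (and the acceptance script) verifies that when the
"observed" data are themselves drawn from the random-position process,
the p-values are uniform. The calibration uses the enrichment-score
correlation, whose resampling distribution is close to normal at the
problem sizes used; the gene-overlap OR null is visibly right-skewed at
small counts, where the normal z-approximation — not the resampling
machinery — would be the thing failing a uniformity test.

## Power simulation

Each scenario fixes the number of GWAS genes, the number of associated
genes an EWAS could detect at full power ("Assoc genes"), the EWAS
power, and the proportion of the EWAS list that is causal. A draw
samples the GWAS list from the causal pool and the EWAS list with
exactly `round(prop × n)` causal-pool genes, the remainder from the
associated pool excluding the causal pool (keeping the composition
exact; study power is operationalised purely as the number of genes
detected). The three statistics are computed per draw, and the rank AUC
(with a DeLong 95% CI — the standard distribution-free choice) measures
how well each statistic separates a scenario from its matched
zero-causal-proportion twin across 2×reps draws.

Defaults: causal and associated pools of 1000 genes each over a 20,000
gene universe (disjoint pools); proportion grid {0, 0.05, 1}; detected
associated genes {50, 100, 500}; power {0.2, 0.5, 1}; 1000 iterations.
All are configuration, not constants. The random streams deliberately
exclude the annotation identifier so that annotation methods are
compared on identical gene draws. The test suite exercises smaller
worlds (2000-gene universe, 600-gene pools, 80 genesets, tens of
iterations per scenario) so the full suite runs in about two minutes.

## Architecture inference

Given the known GWAS genes (KGG) and known EWAS genes (KEG) of a trait,
each candidate architecture sets pool sizes `N_KTG × multiplier`
(N_KTG = N_KGG + N_KEG; multiplier ∈ {1, 2, 3, 5, 10, 20}, so total
simulated trait genes run from 2× to 40× the known genes) and an
overlap proportion ∈ {0, 0.01, 0.1, 0.5, 1}. The knowns are embedded —
KGG in the causal pool, KEG in the associated pool — and the remainder
filled from the universe. The overlap endpoints are: at 0, the pools
share only the forced KGG∩KEG; at 1, the only associated genes outside
the causal pool are KEG∖KGG. Intermediate proportions interpolate
linearly over the feasible extra overlap (the endpoints are the
constraint; linear interpolation is the minimal completion). Pools are
constructed once per scenario; each of the (default 1000) repetitions
re-draws N_KGG genes from the causal pool and N_KEG from the associated
pool and correlates their enrichment profiles. A two-sided z-test
compares the empirically observed correlation with the simulated
distribution; Benjamini–Hochberg FDR is applied across the pooled
scenario list (per-trait FDR is available), and scenarios with
FDR < 0.05 are flagged as unlikely. Infeasible grid points (e.g. a
universe too small for a 20× pool) raise named errors rather than being
silently dropped.

Inference here is deliberately modest: simulated correlation
distributions vary only weakly across scenarios, so the grid rarely
rejects more than the extremes — the parameter-recovery test asserts
exactly the property that matters, that the true grid point survives.

## Cross-study comparison

Enrichment profiles for many studies on a shared geneset domain are
compared by all pairwise Spearman correlations. Each pair is tested
one-sided against the grand mean of all pairwise correlations using the
empirical SD of those correlations (the variance choice is recorded in
the output; a pooled empirical SD is the simplest defensible option),
with BH-FDR across pairs, and summarised by pair kind (GWAS–GWAS,
GWAS–EWAS, EWAS–EWAS).

## The synthetic-data generator

The generator emulates exactly the structure the analyses consume:
equal-length chromosomes; non-overlapping genes placed by a symmetric
multinomial split of the free space (uniform without overlap — real
genomes have overlapping and nested genes, which the mapping code
handles but the generator does not produce); genesets sampled uniformly
with a configurable fraction of "broad" (>100-member) sets; and
summary-statistics tables in which each signal gene receives
`n_sites_per_gene` sites inside its body, one of which gets a
sub-threshold p-value with probability equal to the study's power.
Sub-threshold p-values are drawn log-uniformly on [10⁻³⁰, threshold) so
that magnitudes span the range sorting and formatting code must handle;
background sites are uniform over the genome at a configurable density
(default 10 per Mb) with Uniform(0,1] p-values. Confounded and
reverse-causal associated genes are not distinguished — both pools
behave identically in every analysis here.

What passing tests therefore do **not** show: behaviour under linkage
disequilibrium or co-methylation correlation between sites (no
correlation structure is generated; the shifted null's *purpose* is to
be robust to it, and only the spacing-preservation property is
testable here), under polygenic effect-size distributions, or with the
size and nesting structure of real ontology annotations. Ground-truth
recovery results (e.g. that at power 1 the mapping recovers the signal
genes exactly) validate the plumbing, not the biology.

## Numerical and degenerate-input choices

- One run seed; every stochastic stage derives an independent child
  stream from (seed, stage name, scenario parameters, iteration), so any
  scenario is reproducible in isolation and results are independent of
  execution order.
- Z-tests against a degenerate null (sd = 0) raise rather than return 0
  or 1. Spearman correlation requires ≥3 genesets and non-constant
  profiles. AUC requires both classes; a single observation per class
  yields a defined AUC but a degenerate CI, with a warning.
- Two-sided Fisher p-values use the conventional minimum-likelihood
  tail definition (as implemented in scipy); the sample cross-product
  OR is reported rather than the conditional MLE, honouring the verbal
  odds definition and the convention that an empty intersection prints
  OR = 0.
- Ties in nearest-gene distance and in ranks use deterministic
  all-tied / average-rank rules; no randomness is hidden in
  tie-breaking.

## Problem sizes

Default simulation sizes (1000 repetitions, 1000-gene pools, the full
6×5 architecture grid) reflect the intended analysis scale. The bundled
tests and the acceptance script run the same code paths on reduced
worlds — hundreds to a few thousand genes, 60–80 genesets, 30–200
repetitions, 20 replicate runs for recovery and trend checks — chosen
as the smallest sizes at which the statistical assertions (binomial and
KS bands, sign tests) retain power.
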