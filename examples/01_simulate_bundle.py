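"""Generate a complete synthetic GWAS/EWAS input bundle.

Builds a small genome with non-overlapping genes, random genesets, a
trait architecture (60 causal genes, 60 associated genes, half shared)
and full summary-statistics tables for a GWAS and an EWAS at 90%
detection power, then writes everything as plain-text files.
"""

from epioverlap import simulate

layout, genes = simulate.generate_genome(
    n_chromosomes=3, chrom_length=5_000_000, n_genes=300,
    gene_length_range=(1_000, 10_000), seed=11,
)
annotation = simulate.generate_genesets(genes, n_sets=60, size_range=(10, 120),
                                        broad_fraction=0.2, seed=11)
arch = simulate.generate_architecture(genes, n_causal=60, n_associated=60,
                                      overlap_proportion=0.5, seed=11)
gwas_df, gwas_truth = simulate.generate_study(
    arch, simulate.StudyDesign("gwas", power=0.9), layout, genes, seed=21
)
ewas_df, ewas_truth = simulate.generate_study(
    arch, simulate.StudyDesign("ewas", power=0.9), layout, genes, seed=22
)
paths = simulate.write_bundle(
    "example_bundle", layout, genes, annotation, gwas_df, ewas_df,
    truth={"gwas_detected": gwas_truth.detected_genes,
           "ewas_detected": ewas_truth.detected_genes},
)

print(f"genome: {len(layout.chromosomes)} chromosomes, "
      f"{layout.total_length/1e6:.0f} Mb, {len(genes)} genes")
print(f"architecture: {len(arch.causal_genes)} causal, "
      f"{len(arch.associated_genes)} associated, "
      f"{len(arch.causal_genes & arch.associated_genes)} shared")
print(f"GWAS table: {len(gwas_df)} sites, "
      f"{len(gwas_truth.detected_genes)} genes detectable at 5e-8")
print(f"EWAS table: {len(ewas_df)} sites, "
      f"{len(ewas_truth.detected_genes)} genes detectable at 1e-7")
print("files:", ", ".join(p.name for p in paths.values()))
# The shared half of the two pools is the ground-truth overlap every
# downstream stage should be able to rediscover.
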