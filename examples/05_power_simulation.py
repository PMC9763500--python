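"""Power to detect GWAS/EWAS overlap as causal proportion varies.

Simulates study gene draws from causal and associated pools and asks
how well each overlap metric separates a scenario with causal EWAS
genes from the matched scenario with none (rank AUC).
"""

from epioverlap import power, simulate

layout, genes = simulate.generate_genome(4, 10_000_000, 2000, (1_000, 8_000),
                                         seed=7)
ids = [g.gene_id for g in genes]
causal, assoc = power.default_pools(ids, n_causal=600, n_assoc=600, seed=7)
annotation = simulate.generate_genesets(genes, 80, (10, 150), 0.25, seed=7)

grid = [power.PowerScenario(n_gwas_genes=100, n_assoc_detected=100,
                            ewas_power=pw, prop_causal_ewas=pr)
        for pw in (0.2, 1.0) for pr in (0.0, 0.05, 1.0)]
results = power.run_power_grid(grid, causal, assoc, annotation,
                               seed=1, reps=100)

print("power  prop_causal   AUC(gene OR)  AUC(geneset OR)  AUC(rho)")
for r in results:
    s = r.scenario
    print(f"{s.ewas_power:5.1f}  {s.prop_causal_ewas:11.2f}   "
          f"{r.auc['or_g'].auc:12.3f}  {r.auc['or_p'].auc:15.3f}  "
          f"{r.auc['rho_p'].auc:8.3f}")
# AUC 0.5 = indistinguishable from the no-causal-gene scenario, 1.0 =
# perfectly distinguishable. Discrimination improves with the causal
# proportion and with detection power, and the gene-overlap OR is the
# most powerful of the three metrics.
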