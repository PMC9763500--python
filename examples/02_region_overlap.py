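"""Region-level co-occurrence of GWAS and EWAS signals.

Tiles the genome into 500 kb blocks, drops blocks without a methylation
probe, and counts blocks containing significant GWAS sites, EWAS sites,
both or neither. Run 01_simulate_bundle.py first.
"""

from epioverlap import io, mapping

layout, genes = io.read_genome("example_bundle/chrom.sizes",
                               "example_bundle/genes.tsv")
ewas_all = io.read_summary_stats("example_bundle/ewas.tsv", "ewas",
                                 threshold=1.0)  # full probe panel
gwas_all = io.read_summary_stats("example_bundle/gwas.tsv", "gwas", threshold=1.0)

regions = mapping.bin_genome(layout, width=500_000)
retained = mapping.filter_regions(regions, ewas_all.sites)
region_p = mapping.resolve_region_threshold(
    max(s.p_value for s in ewas_all.sites)
)
tally = mapping.tally_regions(retained, gwas_all, ewas_all, region_p)

print(f"{len(regions)} blocks of 500 kb; {len(retained)} contain a probe")
print(f"region p-value threshold: {region_p:g}")
for category, count in tally.counts.items():
    print(f"  {category:10s} {count}")
# "both" counts blocks where the two study types co-localise; with a
# half-shared architecture a large fraction of signal blocks overlap.
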