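import math

import numpy as np
import pytest

from epioverlap import mapping
from epioverlap.types import (
    GeneRecord,
    GenomeLayout,
    SiteRecord,
    StudyHits,
    ValidationError,
)


def _site(chrom, pos, p=1e-9, sid=None, effect=None):
    return SiteRecord(sid or f"s{chrom}_{pos}", chrom, pos, p, effect)


class TestBinGenome:
    @pytest.mark.parametrize("length,width,n,last", [
        (1_000_000, 500_000, 2, 500_000),
        (1_200_000, 500_000, 3, 200_000),
    ])
    def test_forced_arithmetic(self, length, width, n, last):
        layout = GenomeLayout((("chr1", length),))
        regions = mapping.bin_genome(layout, width)
        assert len(regions) == n
        assert regions[-1].end - regions[-1].start == last

    def test_tiling_matches_per_chromosome_brute_force(self, rng):
        """Region count and coverage equal an independent tiling."""
        lengths = rng.integers(100_000, 3_000_000, size=22)
        layout = GenomeLayout(tuple((f"chr{i+1}", int(l)) for i, l in enumerate(lengths)))
        width = 500_000
        regions = mapping.bin_genome(layout, width)
        assert len(regions) == sum(math.ceil(l / width) for l in lengths)
        for name, length in layout.chromosomes:
            sub = [r for r in regions if r.chromosome == name]
            assert sub[0].start == 0 and sub[-1].end == length
            covered = sum(r.end - r.start for r in sub)
            assert covered == length  # disjoint exact tiling
            for r1, r2 in zip(sub, sub[1:]):
                assert r1.end == r2.start


class TestFilterRegions:
    def setup_method(self):
        self.layout = GenomeLayout((("chr1", 1_000_000), ("chr2", 700_000)))
        self.regions = mapping.bin_genome(self.layout, 100_000)

    def test_no_probes_empty(self):
        assert mapping.filter_regions(self.regions, []) == []

    def test_one_probe_per_region_keeps_all(self):
        probes = [_site(r.chromosome, r.start, 0.5) for r in self.regions]
        kept = mapping.filter_regions(self.regions, probes)
        assert len(kept) == len(self.regions)
        assert all(r.contains_probe for r in kept)

    def test_random_probes_match_membership_scan(self, rng):
        probes = [
            _site(c, int(p), 0.5, sid=f"p{i}")
            for i, (c, p) in enumerate(
                zip(rng.choice(["chr1", "chr2"], 50),
                    rng.integers(0, 700_000, 50))
            )
        ]
        kept = mapping.filter_regions(self.regions, probes)
        expect = [
            r for r in self.regions
            if any(s.chromosome == r.chromosome and r.start <= s.position < r.end
                   for s in probes)
        ]
        assert [(r.chromosome, r.start) for r in kept] == \
               [(r.chromosome, r.start) for r in expect]


class TestTallyRegions:
    def setup_method(self):
        self.layout = GenomeLayout((("chr1", 1_000_000),))
        self.regions = mapping.bin_genome(self.layout, 100_000)

    def _hits(self, study_type, sites):
        return StudyHits("t", study_type, sites, threshold=1.0)

    def test_no_subthreshold_sites_all_neither(self):
        gwas = self._hits("gwas", [_site("chr1", 5, 0.5)])
        ewas = self._hits("ewas", [_site("chr1", 6, 0.5)])
        tally = mapping.tally_regions(self.regions, gwas, ewas, region_p=1e-5)
        assert tally.counts["neither"] == len(self.regions)
        assert tally.total == len(self.regions)

    def test_shared_region_counts_as_both(self):
        gwas = self._hits("gwas", [_site("chr1", 5)])
        ewas = self._hits("ewas", [_site("chr1", 99_999)])
        tally = mapping.tally_regions(self.regions, gwas, ewas, region_p=1e-5)
        assert tally.counts["both"] == 1
        assert tally.counts["neither"] == len(self.regions) - 1

    def test_unknown_chromosome_rejected(self):
        gwas = self._hits("gwas", [_site("chrX", 5)])
        ewas = self._hits("ewas", [])
        with pytest.raises(ValidationError, match="chrX"):
            mapping.tally_regions(self.regions, gwas, ewas, region_p=1e-5)

    def test_random_hits_match_brute_force_scan(self, rng):
        gsites = [_site("chr1", int(p), 1e-6, sid=f"g{i}")
                  for i, p in enumerate(rng.integers(0, 1_000_000, 30))]
        esites = [_site("chr1", int(p), 1e-6, sid=f"e{i}")
                  for i, p in enumerate(rng.integers(0, 1_000_000, 30))]
        tally = mapping.tally_regions(
            self.regions, self._hits("gwas", gsites), self._hits("ewas", esites),
            region_p=1e-5,
        )
        counts = {"neither": 0, "gwas_only": 0, "ewas_only": 0, "both": 0}
        for r in self.regions:
            g = any(r.start <= s.position < r.end for s in gsites)
            e = any(r.start <= s.position < r.end for s in esites)
            counts["both" if g and e else "gwas_only" if g
                   else "ewas_only" if e else "neither"] += 1
        assert tally.counts == counts
        assert tally.total == len(self.regions)

    def test_region_threshold_fallback_rule(self):
        assert mapping.resolve_region_threshold(0.9) == 1e-5
        assert mapping.resolve_region_threshold(1e-8) == 1e-8


class TestRegionEffectAuc:
    def setup_method(self):
        self.layout = GenomeLayout((("chr1", 500_000),))
        self.regions = mapping.bin_genome(self.layout, 100_000)

    def test_perfect_separation(self):
        gwas_sites = [_site("chr1", r.start, 1e-6, sid=f"g{i}", effect=float(5 - i))
                      for i, r in enumerate(self.regions)]
        ewas = StudyHits("t", "ewas", [_site("chr1", 0, 1e-8)], 1e-7)
        res = mapping.region_effect_auc(self.regions, gwas_sites, ewas)
        assert res.auc == 1.0

    def test_single_class_labels_rejected(self):
        gwas_sites = [_site("chr1", r.start, 1e-6, sid=f"g{i}", effect=1.0)
                      for i, r in enumerate(self.regions)]
        ewas = StudyHits("t", "ewas", [], 1e-7)
        with pytest.raises(ValidationError, match="identical"):
            mapping.region_effect_auc(self.regions, gwas_sites, ewas)

    def test_independent_labels_near_half(self, rng):
        """Labels unrelated to scores: AUC concentrates around 0.5."""
        layout = GenomeLayout((("chr1", 10_000_000),))
        regions = mapping.bin_genome(layout, 10_000)
        gwas_sites = [_site("chr1", r.start, 1e-6, sid=f"g{i}",
                            effect=float(rng.normal()))
                      for i, r in enumerate(regions)]
        ewas_positions = rng.choice([r.start for r in regions], size=500, replace=False)
        ewas = StudyHits("t", "ewas",
                         [_site("chr1", int(p), 1e-8, sid=f"e{i}")
                          for i, p in enumerate(ewas_positions)], 1e-7)
        res = mapping.region_effect_auc(regions, gwas_sites, ewas)
        assert abs(res.auc - 0.5) < 0.06


class TestMapSitesToGenes:
    GENES = [
        GeneRecord("gA", "chr1", 1_000, 10_000),
        GeneRecord("gB", "chr1", 8_000, 12_000),
        GeneRecord("gC", "chr1", 20_000, 21_000),
        GeneRecord("gD", "chr2", 5_000, 6_000),
    ]

    def test_site_inside_single_gene(self):
        m = mapping.map_sites_to_genes([_site("chr1", 5_000)], self.GENES)
        assert m.genes == {"gA"}

    def test_site_inside_overlapping_genes_maps_to_all(self):
        m = mapping.map_sites_to_genes([_site("chr1", 9_000)], self.GENES)
        assert m.genes == {"gA", "gB"}

    def test_equidistant_site_maps_to_both_neighbours(self):
        genes = [GeneRecord("gL", "chr1", 0, 1_000),
                 GeneRecord("gR", "chr1", 3_001, 4_000)]
        # last base of gL is 999: d(gL) = 2_000 - 999 = 1_001 = d(gR)
        m = mapping.map_sites_to_genes([_site("chr1", 2_000)], genes)
        assert m.genes == {"gL", "gR"}
        # one base to the left breaks the tie
        m = mapping.map_sites_to_genes([_site("chr1", 1_999)], genes)
        assert m.genes == {"gL"}

    def test_no_cross_chromosome_mapping(self):
        m = mapping.map_sites_to_genes([_site("chr2", 0)], self.GENES)
        assert m.genes == {"gD"}

    def test_chromosome_without_genes_unmapped(self):
        m = mapping.map_sites_to_genes([_site("chrX", 0)], self.GENES)
        assert m.genes == set() and m.unmapped == ["schrX_0"]

    def test_random_sites_match_all_pairs_oracle(self, rng):
        """100 random sites vs 50 random genes: assignment equals the
        brute-force all-pairs distance minimisation."""
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 990_000))
            genes.append(GeneRecord(f"g{i}", "chr1", start,
                                    start + int(rng.integers(100, 10_000))))
        sites = [_site("chr1", int(p), sid=f"s{i}")
                 for i, p in enumerate(rng.integers(0, 1_000_000, 100))]
        m = mapping.map_sites_to_genes(sites, genes)
        for s in sites:
            dists = {}
            for g in genes:
                if g.start <= s.position < g.end:
                    dists[g.gene_id] = 0
                elif s.position < g.start:
                    dists[g.gene_id] = g.start - s.position
                else:
                    dists[g.gene_id] = s.position - (g.end - 1)
            dmin = min(dists.values())
            expect = {gid for gid, d in dists.items() if d == dmin}
            assert set(m.trace[s.site_id]) == expect

    def test_mapping_monotone_under_threshold_tightening(self, rng):
        genes = self.GENES
        sites = [
            SiteRecord(f"s{i}", "chr1", int(rng.integers(0, 25_000)),
                       float(10 ** -rng.uniform(1, 12)))
            for i in range(60)
        ]
        loose = mapping.map_sites_to_genes([s for s in sites if s.p_value < 1e-4], genes)
        tight = mapping.map_sites_to_genes([s for s in sites if s.p_value < 1e-8], genes)
        assert tight.genes <= loose.genes
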