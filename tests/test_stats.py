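import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import comb

from epioverlap import stats
from epioverlap.stats import ContingencyTable, NullDistribution
from epioverlap.types import GenesetAnnotation, ValidationError


def _fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins,
    summing probabilities of tables no more likely than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherOr:
    def test_zero_cell_gives_zero_or(self):
        r = stats.fisher_or(ContingencyTable(0, 10, 10, 80))
        assert r.odds_ratio == 0.0

    def test_forced_arithmetic(self):
        r = stats.fisher_or(ContingencyTable(5, 5, 5, 85))
        assert r.odds_ratio == pytest.approx(17.0)

    def test_infinite_or_when_complement_empty(self):
        r = stats.fisher_or(ContingencyTable(5, 0, 3, 10))
        assert math.isinf(r.odds_ratio)

    def test_empty_first_list_rejected(self):
        with pytest.raises(ValidationError):
            stats.fisher_or(ContingencyTable(0, 0, 5, 5))

    def test_p_matches_hypergeometric_enumeration(self):
        r = stats.fisher_or(ContingencyTable(3, 2, 2, 3))
        assert r.fisher_p == pytest.approx(_fisher_p_enumeration(3, 2, 2, 3))

    def test_p_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0:
                continue
            r = stats.fisher_or(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert r.fisher_p == pytest.approx(
                _fisher_p_enumeration(int(a), int(b), int(c), int(d)), rel=1e-8
            )

    def test_p_invariant_to_list_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 15, size=4))
            p1 = stats.fisher_or(ContingencyTable(a, b, c, d)).fisher_p
            p2 = stats.fisher_or(ContingencyTable(a, c, b, d)).fisher_p
            assert p1 == pytest.approx(p2)


class TestGeneOverlap:
    UNIVERSE = {f"g{i}" for i in range(500)}

    def test_identical_lists_infinite_or(self):
        e = {"g1", "g2", "g3"}
        r = stats.gene_overlap(e, set(e), self.UNIVERSE)
        assert math.isinf(r.odds_ratio)

    def test_disjoint_lists_zero_or(self):
        r = stats.gene_overlap({"g1", "g2"}, {"g3", "g4"}, self.UNIVERSE)
        assert r.odds_ratio == 0.0

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="nope"):
            stats.gene_overlap({"nope"}, {"g1"}, self.UNIVERSE)

    def test_table_matches_set_arithmetic_on_random_lists(self, rng):
        genes = sorted(self.UNIVERSE)
        for _ in range(100):
            e = set(rng.choice(genes, rng.integers(1, 60), replace=False))
            g = set(rng.choice(genes, rng.integers(1, 60), replace=False))
            t = stats.gene_overlap(e, g, self.UNIVERSE).table
            assert (t.a, t.b, t.c, t.d) == (
                len(e & g), len(e - g), len(g - e), 500 - len(e | g)
            )
            assert t.n == 500


class TestEnrichmentProfile:
    def _annotation(self):
        genes = {f"g{i}" for i in range(200)}
        sets = {
            "S0": {f"g{i}" for i in range(30)},
            "S1": {f"g{i}" for i in range(25, 60)},
            "S2": {f"g{i}" for i in range(100, 120)},
        }
        return GenesetAnnotation(sets, universe=genes)

    def test_hits_equal_set_gives_infinity(self):
        ann = self._annotation()
        p = stats.enrichment_profile(set(ann.sets["S0"]), ann)
        assert math.isinf(p.as_dict()["S0"])

    def test_disjoint_hits_give_zero(self):
        ann = self._annotation()
        p = stats.enrichment_profile({"g150", "g151"}, ann)
        assert p.as_dict()["S0"] == 0.0

    def test_empty_hits_rejected(self):
        with pytest.raises(ValidationError):
            stats.enrichment_profile(set(), self._annotation())

    def test_scores_match_brute_force_tables(self, rng):
        genes = [f"g{i}" for i in range(200)]
        sets = {
            f"S{j}": set(rng.choice(genes, rng.integers(5, 50), replace=False))
            for j in range(20)
        }
        ann = GenesetAnnotation(sets, universe=set(genes))
        hits = set(rng.choice(genes, 30, replace=False))
        profile = stats.enrichment_profile(hits, ann).as_dict()
        for gs_id, members in sets.items():
            a = len(hits & members)
            b = len(hits - members)
            c = len(members - hits)
            d = 200 - len(hits | members)
            expect = stats.cross_product_or(a, b, c, d)
            assert profile[gs_id] == pytest.approx(expect)


class TestGenesetOverlap:
    def test_shared_single_set(self):
        genes = {f"g{i}" for i in range(50)}
        ann = GenesetAnnotation(
            {"S0": {"g0", "g1"}, "S1": {"g10"}, "S2": {"g20"}}, universe=genes
        )
        pa = stats.enrichment_profile({"g0"}, ann)
        pb = stats.enrichment_profile({"g1"}, ann)
        r = stats.geneset_overlap(pa, pb)
        assert r.table.a == 1  # S0 identified by both

    def test_no_shared_sets_zero_or(self):
        genes = {f"g{i}" for i in range(50)}
        ann = GenesetAnnotation(
            {"S0": {"g0"}, "S1": {"g10"}, "S2": {"g20", "g21"}}, universe=genes
        )
        pa = stats.enrichment_profile({"g0"}, ann)
        pb = stats.enrichment_profile({"g10"}, ann)
        assert stats.geneset_overlap(pa, pb).odds_ratio == 0.0

    def test_random_case_matches_membership_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        sets = {
            f"S{j}": set(rng.choice(genes, rng.integers(3, 30), replace=False))
            for j in range(25)
        }
        ann = GenesetAnnotation(sets, universe=set(genes))
        ha = set(rng.choice(genes, 15, replace=False))
        hb = set(rng.choice(genes, 15, replace=False))
        r = stats.geneset_overlap(
            stats.enrichment_profile(ha, ann), stats.enrichment_profile(hb, ann)
        )
        ia = {g for g, m in sets.items() if m & ha}
        ib = {g for g, m in sets.items() if m & hb}
        assert (r.table.a, r.table.b, r.table.c) == (
            len(ia & ib), len(ia - ib), len(ib - ia)
        )


class TestEnrichmentCorrelation:
    def _profiles(self, s1, s2):
        ids = [f"S{i}" for i in range(len(s1))]
        return (
            stats.EnrichmentProfile("a", ids, np.asarray(s1, float)),
            stats.EnrichmentProfile("b", ids, np.asarray(s2, float)),
        )

    def test_identical_profiles_rho_one(self):
        p1, p2 = self._profiles([0, 1, 2, 3, np.inf], [0, 1, 2, 3, np.inf])
        assert stats.enrichment_correlation(p1, p2) == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        p1, p2 = self._profiles([1, 2, 3, 4], [4, 3, 2, 1])
        assert stats.enrichment_correlation(p1, p2) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        s1 = rng.exponential(size=50)
        s2 = rng.exponential(size=50)
        s1[rng.choice(50, 10, replace=False)] = 0.0  # realistic zero scores
        p1, p2 = self._profiles(s1, s2)
        rho = stats.enrichment_correlation(p1, p2)
        r1, r2 = sps.rankdata(s1), sps.rankdata(s2)
        assert rho == pytest.approx(np.corrcoef(r1, r2)[0, 1])

    def test_log_transform_leaves_rho_unchanged(self, rng):
        s = rng.exponential(size=30) + 0.01
        t = rng.exponential(size=30) + 0.01
        p1, p2 = self._profiles(s, t)
        q1, q2 = self._profiles(np.log(s), np.log(t))
        assert stats.enrichment_correlation(p1, p2) == \
            stats.enrichment_correlation(q1, q2)

    def test_too_few_sets_and_zero_variance_rejected(self):
        p1, p2 = self._profiles([1, 2], [2, 1])
        with pytest.raises(ValidationError, match="3 genesets"):
            stats.enrichment_correlation(p1, p2)
        p1, p2 = self._profiles([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError, match="variance"):
            stats.enrichment_correlation(p1, p2)


class TestZTest:
    def test_observed_at_mean_gives_p_one(self):
        null = NullDistribution("x", np.array([1.0, 2.0, 3.0]))
        assert stats.z_test_vs_null(2.0, null) == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        null = NullDistribution("x", np.array([-1.0, 0.0, 1.0]))
        obs = null.mean + 1.959964 * null.sd
        assert stats.z_test_vs_null(obs, null) == pytest.approx(0.05, abs=1e-5)

    def test_matches_normal_cdf_oracle(self, rng):
        draws = rng.normal(5, 2, size=200)
        null = NullDistribution("x", draws)
        for obs in rng.normal(5, 3, size=20):
            z = (obs - draws.mean()) / draws.std(ddof=1)
            assert stats.z_test_vs_null(obs, null) == pytest.approx(
                2 * sps.norm.sf(abs(z))
            )

    def test_degenerate_null_rejected(self):
        null = NullDistribution("x", np.ones(10))
        with pytest.raises(ValidationError, match="degenerate"):
            stats.z_test_vs_null(1.5, null)


class TestBhFdr:
    def test_single_p(self):
        assert stats.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_derived_step_up(self):
        # raw: 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> cum-min from top = 0.04
        assert stats.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert stats.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            stats.bh_fdr([0.5, 1.5])

    @given(st.lists(st.sampled_from([0.001, 0.01, 0.04, 0.2, 0.5, 0.8, 1.0]),
                    min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        """Step-up q-values: q_(i) = min over j >= i of p_(j)*m/j."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        raw = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(q_sorted, 1.0)
        assert stats.bh_fdr(p) == pytest.approx(expect)


class TestRankAuc:
    def test_perfect_separation(self):
        r = stats.rank_auc([4, 3, 2, 1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_half(self):
        r = stats.rank_auc([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            stats.rank_auc([1, 2, 3], [1, 1, 1])

    def test_matches_pairwise_comparison_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            scores = rng.choice([0.0, 1.0, 2.5, 3.0, np.inf], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expect = wins / (len(pos) * len(neg))
            assert stats.rank_auc(scores, labels, ci=False).auc == pytest.approx(expect)

    def test_negation_antisymmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = stats.rank_auc(scores, labels, ci=False).auc
        b = stats.rank_auc(-scores, labels, ci=False).auc
        assert a == pytest.approx(1.0 - b)

    def test_delong_ci_covers_auc_and_shrinks(self, rng):
        small = stats.rank_auc(rng.normal(1, 1, 40).tolist() + rng.normal(0, 1, 40).tolist(),
                               [1] * 40 + [0] * 40)
        big = stats.rank_auc(rng.normal(1, 1, 400).tolist() + rng.normal(0, 1, 400).tolist(),
                             [1] * 400 + [0] * 400)
        assert small.ci_low <= small.auc <= small.ci_high
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)
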