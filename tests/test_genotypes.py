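"""Calling rules and hygiene filters: boundaries, sampling behaviour,
idempotence."""

import numpy as np
import pytest

from paleoproject import genotypes as gt
from paleoproject import simgen
from paleoproject.errors import InsufficientDataError
from paleoproject.genotypes import (MISSING, GenotypeMatrix, Observation,
                                    PileupSite, Site, SiteTable)

SITE = Site("rs1", "1", 1000, "C", "A")


def _obs(base, q=40, d5=10, d3=10, strand="+"):
    return Observation(base, q, d5, d3, strand)


def _pileup(bases, **kw):
    return PileupSite(SITE, [_obs(b, **kw) for b in bases])


class TestCallPseudohaploid:
    def test_single_alt_read_calls_alt(self):
        assert gt.call_pseudohaploid(_pileup("A"), rng=0) == 2

    def test_low_quality_reads_give_missing(self):
        assert gt.call_pseudohaploid(_pileup("AAAA", q=20), rng=0) == MISSING

    def test_read_end_exclusion(self):
        p = PileupSite(SITE, [_obs("A", d5=1), _obs("A", d3=0)])
        assert gt.call_pseudohaploid(p, rng=0) == MISSING

    def test_off_panel_bases_dropped(self):
        p = PileupSite(SITE, [_obs("G"), _obs("T")])
        assert gt.call_pseudohaploid(p, rng=0) == MISSING

    def test_frequency_weighted_sampling(self):
        # 3 ref + 1 alt survivors: alt drawn in 1/4 of calls
        p = _pileup("CCCA")
        rng = np.random.default_rng(77)
        n = 10_000
        calls = np.array([gt.call_pseudohaploid(p, rng) for _ in range(n)])
        frac_alt = (calls == 2).mean()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac_alt - 0.25) < 3 * se

    def test_never_heterozygous(self, rng):
        for _ in range(200):
            bases = rng.choice(list("ACGT"), size=rng.integers(0, 6))
            call = gt.call_pseudohaploid(_pileup("".join(bases)), rng)
            assert call in (0, 2, MISSING)

    def test_order_invariant_given_one_draw_per_site(self):
        a = gt.call_pseudohaploid(_pileup("CCA"), rng=5)
        b = gt.call_pseudohaploid(_pileup("ACC"), rng=5)
        assert a == b


class TestCallDiploid:
    def test_depth_below_three_is_missing(self):
        call = gt.call_diploid_site(_pileup("AA"))
        assert call.genotype == MISSING and call.reason == "low_depth"

    def test_homozygous_alt(self):
        assert gt.call_diploid_site(_pileup("AAAAA")).genotype == 2

    def test_homozygous_ref(self):
        assert gt.call_diploid_site(_pileup("CCCC")).genotype == 0

    def test_heterozygote_needs_each_allele_twice(self):
        assert gt.call_diploid_site(_pileup("CCAA")).genotype == 1
        call = gt.call_diploid_site(_pileup("CCCA"))
        assert call.genotype == MISSING and call.reason == "inconclusive"

    def test_recovers_truth_on_clean_fixed_depth_pileups(self):
        # error-free, damage-free reads at fixed depth 8: accuracy of the
        # called (non-missing) genotypes is >= 99%
        rng = np.random.default_rng(404)
        n_sites, depth = 2000, 8
        truth = rng.integers(0, 3, size=n_sites)
        correct = called = 0
        for g in truth:
            reads = "".join("A" if rng.random() < g / 2 else "C"
                            for _ in range(depth))
            call = gt.call_diploid_site(_pileup(reads))
            if call.genotype != MISSING:
                called += 1
                correct += call.genotype == g
        assert called > n_sites * 0.8
        assert correct / called >= 0.99


class TestFilters:
    def test_transition_pair_removed_transversion_kept(self):
        sites = SiteTable(["a", "b"], ["1", "1"], np.array([1, 2]),
                          ["C", "A"], ["T", "C"])
        kept = gt.filter_transversions(sites)
        assert kept.site_id == ["b"]

    def test_full_enumeration_removes_exactly_the_transition_classes(self):
        # all 12 ordered ref/alt pairs: the A/G and C/T classes (4 ordered
        # pairs) are removed, the 4 transversion classes (8 ordered) survive
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        sites = SiteTable([f"s{i}" for i in range(12)], ["1"] * 12,
                          np.arange(1, 13), [p[0] for p in pairs],
                          [p[1] for p in pairs])
        kept = gt.filter_transversions(sites)
        assert len(kept) == 8
        removed = {frozenset(p) for p in pairs} - {
            frozenset((r, a)) for r, a in zip(kept.ref, kept.alt)}
        assert removed == {frozenset("AG"), frozenset("CT")}

    def test_transversion_filter_idempotent(self):
        sites = SiteTable(["a", "b", "c"], ["1"] * 3, np.array([1, 2, 3]),
                          ["C", "A", "G"], ["T", "C", "T"])
        once = gt.filter_transversions(sites)
        twice = gt.filter_transversions(once)
        assert once.site_id == twice.site_id

    def test_triallelic_site_removed(self):
        sites = SiteTable(["a", "b"], ["1", "1"], np.array([1, 2]),
                          ["A", "A"], ["C", "C"])
        piles = [PileupSite(sites.row(0),
                            [_obs("A"), _obs("C"), _obs("G")]),
                 PileupSite(sites.row(1), [_obs("A"), _obs("C")])]
        kept = gt.drop_triallelic(sites, piles)
        assert kept.site_id == ["b"]

    def test_triallelic_five_site_panel(self):
        sites = SiteTable([f"s{i}" for i in range(5)], ["1"] * 5,
                          np.arange(1, 6), ["A"] * 5, ["C"] * 5)
        piles = [PileupSite(sites.row(i), [_obs("A"), _obs("C")])
                 for i in range(5)]
        piles[2] = PileupSite(sites.row(2),
                              [_obs("A"), _obs("C"), _obs("T")])
        assert len(gt.drop_triallelic(sites, piles)) == 4

    def test_triallelic_ignores_filtered_observations(self):
        sites = SiteTable(["a"], ["1"], np.array([1]), ["A"], ["C"])
        piles = [PileupSite(sites.row(0),
                            [_obs("A"), _obs("C"), _obs("G", q=10)])]
        assert len(gt.drop_triallelic(sites, piles)) == 1


class TestSampleInclusion:
    @staticmethod
    def _matrix(n_called_per_ind, j=20):
        n = len(n_called_per_ind)
        counts = np.full((n, j), MISSING, dtype=np.int8)
        for i, k in enumerate(n_called_per_ind):
            counts[i, :k] = 2
        return GenotypeMatrix(counts, [f"i{i}" for i in range(n)],
                              [f"s{x}" for x in range(j)], "pseudo_haploid")

    def test_boundary_at_threshold(self):
        gm = self._matrix([5, 4, 6], j=20)
        kept = gt.apply_sample_inclusion(gm, min_snps=5)
        assert kept.individual_ids == ["i0", "i2"]

    def test_boundary_15000(self):
        gm = self._matrix([14_999, 15_000], j=15_000)
        kept = gt.apply_sample_inclusion(gm, min_snps=15_000)
        assert kept.individual_ids == ["i1"]

    def test_survivors_equal_direct_count(self, rng):
        n, j = 30, 50
        counts = rng.integers(0, 3, size=(n, j)).astype(np.int8)
        miss = rng.random((n, j)) < rng.random((n, 1))
        counts[miss] = MISSING
        gm = GenotypeMatrix(counts, [f"i{i}" for i in range(n)],
                            [f"s{x}" for x in range(j)], "diploid")
        kept = gt.apply_sample_inclusion(gm, min_snps=25)
        expected = [f"i{i}" for i in range(n)
                    if (counts[i] != MISSING).sum() >= 25]
        assert kept.individual_ids == expected

    def test_all_dropped_raises(self):
        gm = self._matrix([1, 2], j=20)
        with pytest.raises(InsufficientDataError):
            gt.apply_sample_inclusion(gm, min_snps=10)

    def test_idempotent(self):
        gm = self._matrix([5, 15, 20], j=20)
        once = gt.apply_sample_inclusion(gm, min_snps=10)
        twice = gt.apply_sample_inclusion(once, min_snps=10)
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestMtVariantFilter:
    def test_low_depth_rejected(self):
        assert not gt.mt_variant_filter(2, [(10, 10)])

    def test_end_only_support_rejected(self):
        assert not gt.mt_variant_filter(5, [(2, 30), (3, 40), (1, 50)])

    def test_interior_support_accepted(self):
        assert gt.mt_variant_filter(5, [(2, 30), (12, 20)])


def test_pseudohaploid_calls_recover_allele_frequency():
    # end-to-end: simulate clean pileups from known genotypes, call, compare
    F = simgen.gen_frequencies(1, 400, 0.0, seed=1)
    gm = simgen.gen_genotypes([simgen.AdmixtureVector(np.array([1.0]))],
                              F, "diploid", seed=2)
    sites = SiteTable([f"s{i}" for i in range(400)], ["1"] * 400,
                      np.arange(1, 401), ["C"] * 400, ["A"] * 400)
    piles = simgen.gen_pileup(gm, sites, mean_depth=10.0, seed=3)["ind1"]
    calls = gt.call_pseudohaploid_panel(piles, seed=4)
    called = calls != MISSING
    # dosage of pseudo-haploid calls is an unbiased frequency estimate
    assert abs(calls[called].mean() / 2 - gm.counts[0].mean() / 2) < 0.08
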