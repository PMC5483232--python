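"""Generator correctness: distributional moments, degenerate limits,
seed determinism."""

import numpy as np
import pytest

from paleoproject import simgen
from paleoproject.errors import ParameterError
from paleoproject.genotypes import MISSING
from paleoproject.simgen import AdmixtureVector, DamageParams


class TestGenFrequencies:
    def test_zero_divergence_gives_identical_rows(self):
        table = simgen.gen_frequencies(K=2, J=10, divergence=0.0, seed=1)
        np.testing.assert_array_equal(table.frequencies[0],
                                      table.frequencies[1])

    def test_pairwise_squared_difference_matches_balding_nichols(self):
        # Var(f|p) = c p(1-p), two independent components:
        # E[(f1-f2)^2] = 2c E[p(1-p)] with p ~ U(0.05, 0.95)
        c, J = 0.2, 10_000
        table = simgen.gen_frequencies(K=3, J=J, divergence=c, seed=7)
        d2 = (table.frequencies[0] - table.frequencies[1]) ** 2
        a, b = 0.05, 0.95
        ep = (a + b) / 2
        ep2 = ep**2 + (b - a) ** 2 / 12
        expected = 2 * c * (ep - ep2)
        mc_se = d2.std(ddof=1) / np.sqrt(J)
        assert abs(d2.mean() - expected) < 3 * mc_se

    @pytest.mark.parametrize("divergence", [-0.1, 1.0, 1.5, float("nan")])
    def test_out_of_range_divergence_rejected(self, divergence):
        with pytest.raises(ParameterError):
            simgen.gen_frequencies(2, 5, divergence, seed=0)

    def test_frequencies_within_unit_interval(self):
        table = simgen.gen_frequencies(4, 2000, 0.4, seed=3)
        assert table.frequencies.min() >= 0
        assert table.frequencies.max() <= 1


class TestGenGenotypes:
    def test_deterministic_limit_all_alt(self):
        F = simgen.FrequencyTable(np.array([[1.0] * 5, [0.0] * 5]),
                                  ["a", "b"], [f"s{i}" for i in range(5)])
        gm = simgen.gen_genotypes([AdmixtureVector(np.array([1.0, 0.0]))],
                                  F, "diploid", seed=0)
        assert (gm.counts == 2).all()

    def test_admixed_binomial_expectation(self):
        J = 10_000
        F = simgen.FrequencyTable(np.vstack([np.ones(J), np.zeros(J)]),
                                  ["a", "b"], [f"s{i}" for i in range(J)])
        gm = simgen.gen_genotypes([AdmixtureVector(np.array([0.5, 0.5]))],
                                  F, "diploid", seed=5)
        dosage = gm.counts[0] / 2.0
        se = np.sqrt(0.5 * 0.5 / 2 / J)  # Var(g/2) = p(1-p)/2 per site
        assert abs(dosage.mean() - 0.5) < 3 * se

    def test_pseudo_haploid_has_no_heterozygotes(self):
        F = simgen.gen_frequencies(2, 2000, 0.2, seed=9)
        gm = simgen.gen_genotypes([AdmixtureVector(np.array([0.3, 0.7]))],
                                  F, "pseudo_haploid", seed=11)
        assert set(np.unique(gm.counts)) <= {0, 2}

    def test_pseudo_haploid_marginal_mean_matches_diploid(self):
        F = simgen.gen_frequencies(2, 20_000, 0.2, seed=13)
        q = [AdmixtureVector(np.array([0.4, 0.6]))]
        dip = simgen.gen_genotypes(q, F, "diploid", seed=21)
        ph = simgen.gen_genotypes(q, F, "pseudo_haploid", seed=22)
        # both dosages estimate the same mean allele frequency
        se = np.sqrt(2 * 0.25 / 20_000)  # generous bound on either SE
        assert abs(dip.counts.mean() / 2 - ph.counts.mean() / 2) < 3 * se

    def test_dimension_mismatch_rejected(self):
        F = simgen.gen_frequencies(3, 10, 0.2, seed=1)
        with pytest.raises(ParameterError):
            simgen.gen_genotypes([AdmixtureVector(np.array([0.5, 0.5]))],
                                 F, "diploid", seed=0)


def _one_ind_panel(J, ref="C", alt="A", genotype=0):
    from paleoproject.genotypes import GenotypeMatrix, SiteTable
    sites = SiteTable([f"s{i}" for i in range(J)], ["1"] * J,
                      np.arange(1, J + 1), [ref] * J, [alt] * J)
    gm = GenotypeMatrix(np.full((1, J), genotype, dtype=np.int8),
                        ["ind1"], [f"s{i}" for i in range(J)], "diploid")
    return gm, sites


class TestGenPileup:
    def test_clean_pileup_matches_truth(self):
        gm, sites = _one_ind_panel(200, genotype=0)
        piles = simgen.gen_pileup(gm, sites, mean_depth=5.0, error_rate=0.0,
                                  seed=3)["ind1"]
        for p in piles:
            assert all(o.base == "C" for o in p.observations)

    def test_terminal_ct_damage_rate(self):
        # truth all-C sites, decay=1 so every position damages at delta5
        gm, sites = _one_ind_panel(3000, genotype=0)
        damage = DamageParams(delta5=0.2, delta3=0.0, decay=1.0)
        piles = simgen.gen_pileup(gm, sites, mean_depth=5.0, error_rate=0.0,
                                  damage=damage, seed=17)["ind1"]
        obs = [o for p in piles for o in p.observations]
        assert len(obs) >= 10_000
        rate = np.mean([o.base == "T" for o in obs])
        se = np.sqrt(0.2 * 0.8 / len(obs))
        assert abs(rate - 0.2) < 3 * se

    def test_invalid_decay_rejected(self):
        with pytest.raises(ParameterError):
            DamageParams(0.1, 0.1, decay=0.0)
        with pytest.raises(ParameterError):
            DamageParams(0.1, 0.1, decay=1.5)

    def test_missing_genotype_yields_empty_pileup(self):
        from paleoproject.genotypes import GenotypeMatrix, SiteTable
        sites = SiteTable(["s0"], ["1"], np.array([1]), ["C"], ["A"])
        gm = GenotypeMatrix(np.array([[MISSING]], dtype=np.int8),
                            ["i"], ["s0"], "diploid")
        piles = simgen.gen_pileup(gm, sites, mean_depth=10.0, seed=0)["i"]
        assert piles[0].observations == []


class TestGenSexReadCounts:
    def test_female_ry_level(self):
        n = 100_000
        n_x, n_y = simgen.gen_sex_read_counts("XX", n, seed=2)
        se = np.sqrt(0.0046 * (1 - 0.0046) / n)
        assert abs(n_y / n - 0.0046) < 3 * se
        assert n_x + n_y == n

    def test_zero_ry_gives_zero_y_reads(self):
        _, n_y = simgen.gen_sex_read_counts("XY", 10, ry_xy=0.0, seed=0)
        assert n_y == 0


def _haplotypes(length, n_diff, seed):
    """Consensus and a contaminant differing at n_diff transversion sites."""
    rng = np.random.default_rng(seed)
    cons = rng.choice(list("ACGT"), size=length)
    cont = cons.copy()
    pos = rng.choice(length, size=n_diff, replace=False)
    transversion = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for i in pos:
        cont[i] = transversion[cons[i]]
    return "".join(cons), "".join(cont), sorted(int(i) + 1 for i in pos)


class TestGenMtPileup:
    def test_no_contamination_no_damage_is_clean(self):
        cons, cont, pos = _haplotypes(500, 20, seed=31)
        pile = simgen.gen_mt_pileup(cons, cont, c=0.0, depth=10, seed=5)
        for p in pos:
            assert all(o.base == cons[p - 1] for o in pile.column(p))

    def test_full_contamination_consensus_is_contaminant(self):
        cons, cont, _ = _haplotypes(300, 10, seed=33)
        pile = simgen.gen_mt_pileup(cons, cont, c=1.0, depth=30, seed=7)
        called = pile.consensus()
        covered = [i for i, b in enumerate(called) if b != "N"]
        assert all(called[i] == cont[i] for i in covered)

    def test_contaminant_read_fraction(self):
        cons, cont, _ = _haplotypes(1000, 20, seed=35)
        pile = simgen.gen_mt_pileup(cons, cont, c=0.02, depth=60, seed=9)
        frac = np.mean([r.true_source == "contaminant" for r in pile.reads])
        se = np.sqrt(0.02 * 0.98 / len(pile.reads))
        assert abs(frac - 0.02) < 3 * se

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            simgen.gen_mt_pileup("ACGT", "ACG", c=0.1, depth=5, seed=0)


@pytest.mark.parametrize("factory", [
    lambda s: simgen.gen_frequencies(2, 50, 0.5, seed=s).frequencies,
    lambda s: simgen.gen_genotypes(
        [AdmixtureVector(np.array([0.5, 0.5]))],
        simgen.gen_frequencies(2, 50, 0.2, seed=99), "diploid", seed=s).counts,
    lambda s: simgen.gen_sex_read_counts("XY", 1000, seed=s),
    lambda s: [(r.bases, r.true_source) for r in simgen.gen_mt_pileup(
        "ACGT" * 50, "TGCA" * 50, c=0.3, depth=5, seed=s).reads],
], ids=["frequencies", "genotypes", "sex_counts", "mt_pileup"])
def test_seed_determinism(factory):
    a, b = factory(42), factory(42)
    if isinstance(a, np.ndarray):
        np.testing.assert_array_equal(a, b)
    else:
        assert a == b


def test_pileup_seed_determinism():
    gm, sites = _one_ind_panel(30, genotype=1)
    kw = dict(mean_depth=4.0, error_rate=0.01,
              damage=DamageParams(0.2, 0.2, 0.5))
    a = simgen.gen_pileup(gm, sites, seed=8, **kw)["ind1"]
    b = simgen.gen_pileup(gm, sites, seed=8, **kw)["ind1"]
    assert [p.observations for p in a] == [p.observations for p in b]
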