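"""Forward simulator: placement rules, Mendelian transmission, selection
regimes and population-genetic expectations."""

import numpy as np
import pytest
from scipy.stats import binom, ks_2samp

from magicsweep import pedigree as pg
from magicsweep import simulator as sim
from magicsweep.io_formats import N_FOUNDERS, ValidationError


class TestConfig:
    def test_defaults_are_consistent(self):
        cfg = sim.SimConfig()
        assert cfg.n_crosses * cfg.progeny_per_cross == cfg.n_individuals
        assert cfg.n_selected == 2 * cfg.n_crosses

    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 100},       # breaks crosses x progeny
        {"n_selected": 30},           # breaks 2 x crosses
        {"n_advantageous_alleles": 0},
        {"n_advantageous_alleles": 20},
        {"regime": "disruptive"},
        {"allele_effect": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sim.SimConfig(**kwargs)


class TestPlaceTraitLoci:
    LOCI = (303, 195, 233, 184, 268)

    def test_five_loci_one_per_chromosome(self):
        pos = sim.place_trait_loci(5, self.LOCI)
        assert sorted(c for c, _ in pos) == [0, 1, 2, 3, 4]
        for c, l in pos:
            assert l == self.LOCI[c] // 2

    def test_single_locus_on_first_chromosome(self):
        assert sim.place_trait_loci(1, self.LOCI) == ((0, self.LOCI[0] // 2),)

    def test_ten_loci_split_chromosomes_into_thirds(self):
        pos = sim.place_trait_loci(10, self.LOCI)
        per_chrom = {}
        for c, l in pos:
            per_chrom.setdefault(c, []).append(l)
        for c, ls in per_chrom.items():
            assert len(ls) == 2
            L = self.LOCI[c]
            assert ls == [round(L / 3), round(2 * L / 3)]

    @pytest.mark.parametrize("n", [7, 12, 23, 30])
    def test_spacing_oracle_gap_ratio(self, n):
        # equal spacing: within a chromosome, max/min inter-locus gap
        # (including the chromosome ends) stays below 1.5
        pos = sim.place_trait_loci(n, self.LOCI)
        per_chrom = {}
        for c, l in pos:
            per_chrom.setdefault(c, []).append(l)
        for c, ls in per_chrom.items():
            if len(ls) < 1:
                continue
            edges = [0] + sorted(ls) + [self.LOCI[c] - 1]
            gaps = np.diff(edges)
            assert gaps.max() / gaps.min() <= 1.5

    def test_too_many_loci_rejected(self):
        with pytest.raises(ValidationError):
            sim.place_trait_loci(sum(self.LOCI) + 1, self.LOCI)


class TestInitFounders:
    def test_fixed_seed_reproducible(self):
        cfg = sim.SimConfig(rng_seed=0)
        a = sim.init_founders(cfg, np.random.default_rng(5))
        b = sim.init_founders(cfg, np.random.default_rng(5))
        for ga, gb in zip(a.genotypes, b.genotypes):
            np.testing.assert_array_equal(ga, gb)

    def test_allele_frequencies_within_binomial_interval(self):
        # each allele ~ Binomial(400, 1/19): observed frequency inside the
        # 99% interval at >= 99% of loci (up to binomial fluctuation)
        cfg = sim.SimConfig()
        pop = sim.init_founders(cfg, np.random.default_rng(1))
        lo, hi = binom.ppf([0.005, 0.995], 400, 1 / N_FOUNDERS)
        inside = total = 0
        for g in pop.genotypes:
            counts = (g == 0).sum(axis=(0, 1))  # allele 0 at each locus
            inside += ((counts >= lo) & (counts <= hi)).sum()
            total += g.shape[2]
        assert inside / total >= 0.975

    def test_mean_he_matches_sample_expectation(self):
        # E[He of a 400-gene sample] = (1 - 1/400) x 18/19
        cfg = sim.SimConfig()
        pop = sim.init_founders(cfg, np.random.default_rng(2))
        he = []
        for c in sim._allele_counts(pop):
            p = c / 400
            he.append(1 - (p ** 2).sum(axis=0))
        he = np.concatenate(he)
        expected = (1 - 1 / 400) * 18 / 19
        assert abs(he.mean() - expected) <= 3 * he.std() / np.sqrt(len(he))


class TestAssignPhenotypes:
    def test_null_architecture_standard_normal(self):
        cfg = sim.SimConfig()
        pop = sim.init_founders(cfg, np.random.default_rng(3))
        arch = sim.TraitArchitecture((), 1, 0.0)
        sim.assign_phenotypes(pop, arch, np.random.default_rng(3))
        assert abs(pop.phenotypes.mean()) <= 4 / np.sqrt(pop.size)

    def test_homozygous_dose_arithmetic(self):
        cfg = sim.SimConfig(loci_per_chromosome=(5, 5, 5, 5, 5))
        pop = sim.init_founders(cfg, np.random.default_rng(4))
        arch = sim.TraitArchitecture(((0, 2), (1, 2), (2, 2)), 1, 0.2)
        for c, l in arch.positions:
            pop.genotypes[c][0, :, l] = 0  # homozygous advantageous
            pop.genotypes[c][1:, :, l] = 5  # everyone else non-carrier
        dose = sim.advantage_dose(pop, arch)
        assert dose[0] == 6 and (dose[1:] == 0).all()
        # mu = 2 copies x 3 loci x 0.2
        assert 0.2 * dose[0] == pytest.approx(1.2)

    def test_population_mean_matches_expectation(self):
        cfg = sim.SimConfig(n_trait_loci=5, n_advantageous_alleles=4,
                            allele_effect=0.3)
        pop = sim.init_founders(cfg, np.random.default_rng(5))
        arch = sim.TraitArchitecture(
            sim.place_trait_loci(5, cfg.loci_per_chromosome), 4, 0.3)
        sim.assign_phenotypes(pop, arch, np.random.default_rng(5))
        expected = 0.3 * 2 * 5 * 4 / N_FOUNDERS
        # SE ~ 1/sqrt(n) from noise plus dose variance; use a loose bound
        assert abs(pop.phenotypes.mean() - expected) <= 0.3


class TestSelectParents:
    def test_directional_takes_largest(self):
        idx = sim.select_parents(np.array([1., 2., 3., 4., 5.]),
                                 "directional", 2, np.random.default_rng(0))
        assert sorted(idx) == [3, 4]

    def test_stabilising_takes_closest_to_mean(self):
        idx = sim.select_parents(np.array([1., 2., 3., 4., 5.]),
                                 "stabilising", 1, np.random.default_rng(0))
        assert list(idx) == [2]

    def test_random_with_full_population_is_identity(self):
        idx = sim.select_parents(np.arange(6, dtype=float), "random", 6,
                                 np.random.default_rng(0))
        assert sorted(idx) == list(range(6))

    def test_too_small_population_rejected(self):
        with pytest.raises(ValidationError):
            sim.select_parents(np.array([1.0]), "random", 2,
                               np.random.default_rng(0))


class TestBreeding:
    def make_parent_pop(self, rng):
        cfg = sim.SimConfig(n_individuals=40, n_selected=8, n_crosses=4,
                            progeny_per_cross=10,
                            loci_per_chromosome=(30, 20))
        pop = sim.init_founders(cfg, rng)
        return cfg, pop

    def test_zero_recombination_transmits_whole_haplotype(self):
        rng = np.random.default_rng(6)
        cfg, pop = self.make_parent_pop(rng)
        cfg2 = sim.SimConfig(**{**cfg.__dict__, "recombination_rate": 0.0})
        off, _ = sim.breed_generation(pop, np.arange(8), cfg2, 1, rng)
        ped_sires = np.arange(8)
        for g_off, g_par in zip(off.genotypes, pop.genotypes):
            for i in range(off.size):
                for h in range(2):
                    hap = g_off[i, h]
                    matches = [(hap == g_par[p, ph]).all()
                               for p in range(pop.size) for ph in range(2)]
                    assert any(matches)

    def test_mendelian_property_every_allele_from_a_parent(self):
        rng = np.random.default_rng(7)
        cfg, pop = self.make_parent_pop(rng)
        off, ped = sim.breed_generation(pop, np.arange(8), cfg, 1, rng)
        id_pos = {iid: i for i, iid in enumerate(pop.ids)}
        for i in range(off.size):
            s = id_pos[ped["sire_id"].iloc[i]]
            d = id_pos[ped["dam_id"].iloc[i]]
            for c in range(len(cfg.loci_per_chromosome)):
                pat, mat = off.genotypes[c][i]
                sg, dg = pop.genotypes[c][s], pop.genotypes[c][d]
                assert ((pat == sg[0]) | (pat == sg[1])).all()
                assert ((mat == dg[0]) | (mat == dg[1])).all()

    def test_crossover_count_matches_poisson_moment(self):
        # mean crossovers over 10,000 gametes = 2 within 3 SE
        rng = np.random.default_rng(8)
        n = 10_000
        L = 100
        parent = np.zeros((n, 2, L), dtype=np.int8)
        parent[:, 1, :] = 1  # haplotypes distinguishable everywhere
        gametes = sim._make_gametes(parent, 2.0, rng)
        switches = (np.diff(gametes, axis=1) != 0).sum(axis=1)
        se = np.sqrt(2.0 / n)
        assert abs(switches.mean() - 2.0) <= 3 * se

    def test_odd_selection_rejected(self):
        rng = np.random.default_rng(9)
        cfg, pop = self.make_parent_pop(rng)
        with pytest.raises(ValidationError):
            sim.breed_generation(pop, np.arange(7), cfg, 1, rng)


class TestRunExperiment:
    SMALL = dict(n_individuals=60, n_selected=12, n_crosses=6,
                 progeny_per_cross=10, n_generations=5,
                 loci_per_chromosome=(40, 30, 30, 25, 35))

    def test_determinism_bit_identical(self):
        cfg = sim.SimConfig(**self.SMALL, n_trait_loci=2, allele_effect=0.5,
                            rng_seed=10)
        a = sim.run_experiment(cfg, compute_inbreeding=False)
        b = sim.run_experiment(cfg, compute_inbreeding=False)
        assert a.h2 == b.h2
        for ca, cb in zip(a.allele_counts[-1], b.allele_counts[-1]):
            np.testing.assert_array_equal(ca, cb)
        assert a.phenotypes.equals(b.phenotypes)

    def test_allele_count_conservation_every_generation(self):
        cfg = sim.SimConfig(**self.SMALL, rng_seed=11)
        res = sim.run_experiment(cfg, compute_inbreeding=False)
        for gen_counts in res.allele_counts:
            for c in gen_counts:
                assert (c.sum(axis=0) == 2 * cfg.n_individuals).all()

    def test_neutral_control_h2_centred_on_zero(self):
        h2s = [sim.run_experiment(
            sim.SimConfig(**self.SMALL, allele_effect=0.0, rng_seed=s),
            compute_inbreeding=False, record_counts=False).h2
            for s in range(50)]
        h2s = np.array(h2s)
        assert abs(h2s.mean()) <= 2 * h2s.std(ddof=1) / np.sqrt(len(h2s))

    def test_directional_selection_raises_mean_phenotype(self):
        gains = []
        for s in range(12):
            cfg = sim.SimConfig(**self.SMALL, n_trait_loci=3,
                                allele_effect=0.4, rng_seed=s)
            res = sim.run_experiment(cfg, compute_inbreeding=False,
                                     record_counts=False)
            gains.append(res.selection["R"].iloc[-1])
        assert np.mean(gains) > 0

    def test_random_regime_he_matches_gene_drop_null(self):
        # marginal distribution of final He across loci should match the
        # gene-drop null run on the simulation's own pedigree
        cfg = sim.SimConfig(regime="random", rng_seed=7)
        res = sim.run_experiment(cfg, compute_inbreeding=False,
                                 record_counts=False)
        he_sim = np.concatenate(res.final_he)
        null = pg.gene_drop_null(res.pedigree, 1000, np.random.default_rng(7))
        assert ks_2samp(he_sim, null.values).pvalue > 0.01

    def test_strong_single_locus_sweep_localised(self):
        # where heritability is realised, the minimum-He locus falls on the
        # trait locus's chromosome in >= 80% of replicates
        hits = total = 0
        for s in range(15):
            cfg = sim.SimConfig(n_trait_loci=1, allele_effect=1.0, rng_seed=s)
            res = sim.run_experiment(cfg, compute_inbreeding=False,
                                     record_counts=False)
            if res.h2 > 0.05:
                total += 1
                c_trait = res.architecture.positions[0][0]
                mins = [hv.min() for hv in res.final_he]
                hits += int(np.argmin(mins) == c_trait)
        assert total > 0
        assert hits / total >= 0.8

    def test_pedigree_consistent_with_crosses(self):
        cfg = sim.SimConfig(**self.SMALL, rng_seed=12)
        res = sim.run_experiment(cfg, compute_inbreeding=False,
                                 record_counts=False)
        ped = res.pedigree.data
        for gen in range(1, cfg.n_generations + 1):
            rows = ped[ped["generation"] == gen]
            assert len(rows) == cfg.n_individuals
            # 20-cross structure: progeny_per_cross offspring per parent pair
            pairs = rows.groupby(["sire_id", "dam_id"]).size()
            assert (pairs == cfg.progeny_per_cross).all()
            assert len(pairs) == cfg.n_crosses
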