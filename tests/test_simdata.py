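"""Simulator: inheritance rules, determinism, variance architecture."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from hympred.simdata import (
    GeneticMap,
    Population,
    SimConfig,
    TraitArchitecture,
    advance_generation,
    assign_phenotypes,
    build_map,
    meiosis_female,
    sample_broods,
    simulate,
    simulate_founders,
)


def make_map(n_snps: int, lengths=(100.0,)) -> GeneticMap:
    per = n_snps // len(lengths)
    chrom = np.repeat(np.arange(len(lengths)), per)
    pos_cm = np.concatenate(
        [np.linspace(0, length, per, endpoint=False) for length in lengths]
    )
    pos_bp = (pos_cm * 1000).astype(np.int64) + 1 + chrom * 10**9
    return GeneticMap(chrom=chrom, pos_bp=pos_bp, pos_cm=pos_cm,
                      chrom_lengths_cm=tuple(lengths))


class TestConfigValidation:
    def test_rejects_inconsistent_architecture(self):
        with pytest.raises(ValueError):
            TraitArchitecture("t", h2_target=0.6, host_variance_fraction=0.5)

    def test_rejects_zero_total_map_length(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=1, chrom_lengths_cm=(0.0,))

    def test_rejects_oversized_broods(self):
        with pytest.raises(ValueError):
            SimConfig(max_brood_size=100)


class TestFoundersAndMap:
    def test_variant_bookkeeping(self, rng):
        cfg = small_config(n_snps=1000)
        gmap = build_map(cfg, rng)
        assert gmap.n_snps == 1000
        for c in range(cfg.n_chromosomes):
            sl = gmap.chrom_slice(c)
            pos = gmap.pos_bp[sl]
            assert pos.size > 0
            assert np.all(np.diff(pos) > 0)

    def test_founder_haplotypes_are_biallelic_draws(self, rng):
        cfg = small_config(n_founder_haplotypes=2, n_snps=200)
        gmap = build_map(cfg, rng)
        haps = simulate_founders(cfg, gmap, rng)
        assert haps.shape == (2, 200)
        assert set(np.unique(haps)) <= {0, 1}

    def test_deterministic_under_fixed_seed(self):
        cfg = small_config(seed=77)
        a = simulate(cfg)
        b = simulate(cfg)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        pd.testing.assert_frame_equal(a.samples.frame, b.samples.frame)


class TestMeiosis:
    def test_zero_length_chromosome_transmits_intact_haplotype(self, rng):
        gmap = make_map(50, lengths=(0.0,))
        mother = rng.integers(0, 2, size=(2, 50)).astype(np.int8)
        for _ in range(5):
            gamete = meiosis_female(mother, gmap, rng)
            assert np.array_equal(gamete, mother[0]) or np.array_equal(
                gamete, mother[1]
            )

    def test_homozygous_mother_gives_identical_gamete(self, rng):
        gmap = make_map(80, lengths=(150.0,))
        hap = rng.integers(0, 2, size=80).astype(np.int8)
        mother = np.stack([hap, hap])
        gamete = meiosis_female(mother, gmap, rng)
        assert np.array_equal(gamete, hap)

    def test_crossover_rate_matches_map_length(self, rng):
        # Mother heterozygous everywhere: each haplotype switch along the
        # gamete marks a crossover.  On a dense 100 cM map the expected
        # number of switches per meiosis is 1.
        n = 2000
        gmap = make_map(n, lengths=(100.0,))
        mother = np.stack([np.zeros(n), np.ones(n)]).astype(np.int8)
        n_meioses = 2000
        switches = 0
        for _ in range(n_meioses):
            gamete = meiosis_female(mother, gmap, rng)
            switches += int(np.sum(np.abs(np.diff(gamete))))
        mean = switches / n_meioses
        # Poisson(1) mean over 2000 draws: SE ~ 0.022, allow 4 SE.
        assert abs(mean - 1.0) < 0.09


class TestInheritance:
    def test_daughters_carry_father_genome_exactly(self, rng):
        cfg = small_config(n_snps=120)
        gmap = build_map(cfg, rng)
        founders = simulate_founders(cfg, gmap, rng)
        pop = Population(females=founders[:4].reshape(2, 2, -1),
                         males=founders[4:5])
        nxt = advance_generation(pop, gmap, cfg, rng, n_females=6, n_males=2)
        for i in range(6):
            assert np.array_equal(nxt.females[i, 1], pop.males[0])

    def test_extinct_population_raises(self, rng):
        cfg = small_config(n_snps=50)
        gmap = build_map(cfg, rng)
        empty = Population(
            females=np.empty((0, 2, 50), dtype=np.int8),
            males=np.empty((0, 50), dtype=np.int8),
        )
        with pytest.raises(RuntimeError, match="extinct"):
            advance_generation(empty, gmap, cfg, rng)

    def test_brood_mates_share_host_and_parents(self, rng):
        cfg = small_config(n_snps=100)
        gmap = build_map(cfg, rng)
        founders = simulate_founders(cfg, gmap, rng)
        pop = Population(females=founders[:20].reshape(10, 2, -1),
                         males=founders[20:30])
        genomes, hosts = sample_broods(pop, gmap, cfg, rng, n_females=12,
                                       n_hosts=3, generation_label="GX")
        assert len(set(hosts)) == 3
        hosts = np.asarray(hosts)
        for h in np.unique(hosts):
            members = np.flatnonzero(hosts == h)
            assert members.size == 4
            # Full sisters: identical paternal haplotype.
            for m in members[1:]:
                assert np.array_equal(genomes[m, 1], genomes[members[0], 1])

    def test_loci_stay_biallelic(self, small_sim):
        assert set(np.unique(small_sim.genotypes.codes)) <= {0, 1, 2}


class TestPhenotypes:
    def test_null_architecture_is_pure_residual(self, rng):
        codes = rng.integers(0, 3, size=(400, 50)).astype(np.int8)
        hosts = [f"h{i % 40}" for i in range(400)]
        trait = TraitArchitecture("t", h2_target=0.0, host_variance_fraction=0.0,
                                  phenotype_sd=3.0)
        y, truth = assign_phenotypes(codes, hosts, trait, rng)
        assert truth["variance_parts"]["additive"] == 0.0
        assert truth["variance_parts"]["host"] == 0.0
        assert np.isclose(np.var(y), 9.0)

    def test_realized_scaling_hits_targets_exactly(self, rng):
        codes = rng.integers(0, 3, size=(500, 200)).astype(np.int8)
        hosts = [f"h{i % 50}" for i in range(500)]
        trait = TraitArchitecture("t", h2_target=0.25, host_variance_fraction=0.30,
                                  phenotype_sd=2.0)
        y, truth = assign_phenotypes(codes, hosts, trait, rng)
        parts = truth["variance_parts"]
        assert np.isclose(parts["additive"], 0.25 * 4.0)
        assert np.isclose(parts["host"], 0.30 * 4.0)
        assert np.isclose(parts["residual"], 0.45 * 4.0)

    def test_host_mates_more_similar_than_strangers(self, rng):
        codes = rng.integers(0, 3, size=(600, 50)).astype(np.int8)
        hosts = [f"h{i % 100}" for i in range(600)]
        trait = TraitArchitecture("t", h2_target=0.0, host_variance_fraction=0.5)
        y, _ = assign_phenotypes(codes, hosts, trait, rng)
        frame = pd.DataFrame({"host": hosts, "y": y})
        within_var = frame.groupby("host")["y"].var(ddof=1).mean()
        total_var = frame["y"].var(ddof=1)
        # Intraclass correlation ~ 0.5: within-host variance ~ half the total.
        assert within_var < 0.75 * total_var

    def test_recorded_only_mode_breaks_first_generation_host_sharing(self):
        cfg_all = small_config(seed=21, traits=(
            TraitArchitecture("t", h2_target=0.0, host_variance_fraction=0.6),))
        cfg_rec = small_config(seed=21, shared_host_effects="recorded", traits=(
            TraitArchitecture("t", h2_target=0.0, host_variance_fraction=0.6),))

        def g1_within_host_variance(sim):
            frame = sim.samples.frame.assign(true_host=sim.truth["hosts_all"])
            g1 = frame[frame["generation"] == "G1"]
            return (g1.groupby("true_host")["t"].var(ddof=1).mean(),
                    g1["t"].var(ddof=1))

        within_all, total_all = g1_within_host_variance(simulate(cfg_all))
        within_rec, total_rec = g1_within_host_variance(simulate(cfg_rec))
        # Shared mode: brood-mates resemble each other (within << total);
        # recorded-only mode: G1 host variance is individual-level noise.
        assert within_all < 0.7 * total_all
        assert within_rec > 0.8 * total_rec

    def test_host_ids_hidden_for_first_generation_only(self, small_sim):
        frame = small_sim.samples.frame
        assert frame.loc[frame["generation"] == "G1", "host"].isna().all()
        assert frame.loc[frame["generation"] == "G2", "host"].notna().all()
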