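"""Simulator: Wright-Fisher expectations, determinism, emitters."""
import numpy as np
import pandas as pd
import pytest

from driftld.config import ConfigError, SimConfig
from driftld.simcore import (
    emit_individuals,
    emit_poolseq,
    simulate_expansion,
    true_heterozygosity,
)

from conftest import tiny_config


class TestConfig:
    def test_layout_must_tile_genome(self):
        with pytest.raises(ConfigError, match="layout"):
            tiny_config(genome_length=10_000)

    def test_founders_bounded_by_core(self):
        with pytest.raises(ConfigError, match="founder"):
            tiny_config(founder_size=40, core_size=30)

    @pytest.mark.parametrize("field,value", [
        ("dominance", 1.5), ("seq_error", -0.1),
        ("selfing_rate_per_deme", 1.2),
    ])
    def test_probabilities_validated(self, field, value):
        with pytest.raises(ConfigError):
            tiny_config(**{field: value})

    def test_selfing_list_length_checked(self):
        with pytest.raises(ConfigError, match="selfing"):
            tiny_config(selfing_rate_per_deme=[0.1, 0.2]).selfing_rates()

    def test_gene_intervals_tile_with_intergenic(self):
        cfg = tiny_config()
        blocks = sorted(cfg.gene_intervals() + cfg.intergenic_intervals())
        assert blocks[0][0] == 0
        assert blocks[-1][1] == cfg.genome_length
        for (_, e1), (s2, _) in zip(blocks[:-1], blocks[1:]):
            assert e1 == s2


class TestSimulate:
    def test_no_mutation_no_polymorphism(self):
        pop = simulate_expansion(tiny_config(per_bp_mutation=0.0,
                                             burn_in_generations=30))
        assert len(pop.site_table) == 0

    def test_deterministic_given_seed(self):
        cfg = tiny_config(seed=7)
        a = simulate_expansion(cfg)
        b = simulate_expansion(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.haplotypes, b.haplotypes))
        pd.testing.assert_frame_equal(a.site_table, b.site_table)

    def test_neutral_equilibrium_diversity(self):
        # single neutral deme at mutation-drift equilibrium: mean pairwise
        # diversity per bp should match 4*N*mu within 3 Monte-Carlo SE
        N, mu = 25, 2e-5
        pis = []
        for seed in range(20):
            cfg = tiny_config(
                n_demes=1, core_size=N, per_bp_mutation=mu,
                burn_in_generations=8 * N, seed=seed)
            pop = simulate_expansion(cfg)
            f = pop.deme_frequencies(0)
            n = 2 * N
            pi = (2 * f * (1 - f) * n / (n - 1)).sum() / cfg.genome_length
            pis.append(pi)
        expected = 4 * N * mu
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) < 3 * se

    def test_deleterious_only_in_genes(self, tiny_pop):
        dele = tiny_pop.site_table.query(
            "functional_class == 'deleterious'")
        assert (dele["genic"]).all()

    def test_segregating_somewhere(self, tiny_pop):
        total = sum(H.sum(axis=0, dtype=int) for H in tiny_pop.haplotypes)
        size = sum(H.shape[0] for H in tiny_pop.haplotypes)
        assert ((total > 0) & (total < size)).all()

    def test_deme_meta_distances_linear(self, tiny_pop):
        d = tiny_pop.deme_meta["distance_km"].to_numpy()
        assert np.allclose(np.diff(d), tiny_pop.config.deme_step_km)


class TestEmitPoolseq:
    def test_fixed_haplotype_single_cell(self):
        # one haplotype effectively fixed: every pair table has one cell
        cfg = tiny_config(n_demes=1, core_size=2, founder_size=2,
                          seq_error=0.0, per_bp_mutation=5e-5,
                          burn_in_generations=4,
                          selfing_rate_per_deme=1.0, pool_depth=60)
        pop = simulate_expansion(cfg)
        # force total homozygosity: collapse each individual to one haplotype
        for H in pop.haplotypes:
            H[1::2] = H[0::2]
            H[2:] = H[:2]
        ac, pc = emit_poolseq(pop, 0, cfg)
        if len(pc):
            cells = pc[["n11", "n12", "n21", "n22"]].to_numpy()
            assert ((cells > 0).sum(axis=1) == 1).all()

    def test_high_depth_recovers_frequencies(self):
        # pool covers the whole deme, no sequencing error, depth >= 1e4:
        # pooled frequencies match true deme frequencies within 0.02
        cfg = tiny_config(n_demes=1, core_size=20, seq_error=0.0,
                          pool_depth=10_000, burn_in_generations=150)
        pop = simulate_expansion(cfg)
        ac, _ = emit_poolseq(pop, 0, cfg)
        truth = pop.deme_frequencies(0)
        obs = (ac["alt_count"] / ac["depth"]).to_numpy()
        covered = ac["depth"].to_numpy() > 0
        assert np.abs(obs[covered] - truth[covered]).max() < 0.02

    def test_pair_distance_geometry(self):
        # insert_mean + 2*insert_sd + 2*read_length < 400 => pairs <= 500 bp
        cfg = tiny_config(insert_mean=100, insert_sd=20, read_length=80,
                          pool_depth=200)
        pop = simulate_expansion(cfg)
        _, pc = emit_poolseq(pop, 1, cfg)
        if len(pc):
            assert (pc["pos2"] - pc["pos1"]).max() <= 500

    def test_empty_deme_rejected(self, tiny_pop):
        with pytest.raises(ValueError):
            emit_poolseq(tiny_pop, 99, tiny_pop.config)


class TestEmitIndividuals:
    def test_exact_calls_without_error(self):
        cfg = tiny_config(seq_error=0.0, individual_depth_mean=60)
        pop = simulate_expansion(cfg)
        gt = emit_individuals(pop, 0, 2, cfg)
        covered = gt[gt["DP"] > 0]
        # reconstruct truth per individual
        for ind, grp in covered.groupby("individual"):
            idx = int(ind.split("ind")[1])
            H = pop.haplotypes[0]
            dosage = H[2 * idx].astype(int) + H[2 * idx + 1]
            called = grp["genotype"].map({"0/0": 0, "0/1": 1, "1/1": 2})
            pos_idx = np.searchsorted(pop.positions, grp["pos"].to_numpy() - 1)
            assert (called.to_numpy() == dosage[pos_idx]).all()

    def test_zero_individuals_empty_table(self, tiny_pop):
        gt = emit_individuals(tiny_pop, 0, 0, tiny_pop.config)
        assert gt.empty

    def test_too_many_individuals_rejected(self, tiny_pop):
        with pytest.raises(ValueError):
            emit_individuals(tiny_pop, 0, 10_000, tiny_pop.config)

    def test_selfing_erodes_heterozygosity(self):
        # a fully selfing deme loses heterozygosity roughly as (1/2)^g;
        # after g >= 6 selfed generations the paired outcrossing run keeps
        # far more heterozygosity than the selfed run
        het_out, het_self = [], []
        for seed in range(5):
            for selfing, bucket in ((0.0, het_out), (1.0, het_self)):
                cfg = tiny_config(
                    n_demes=1, core_size=30, burn_in_generations=60,
                    selfing_rate_per_deme=selfing, seed=seed)
                pop = simulate_expansion(cfg)
                bucket.append(np.mean([
                    true_heterozygosity(pop, 0, i) for i in range(10)]))
        assert np.mean(het_self) < 0.5 * np.mean(het_out)
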