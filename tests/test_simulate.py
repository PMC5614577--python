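import json
import math

import numpy as np
import pytest

from colonykin import (ColonyPedigree, SimConfig, estimate_error_rate,
                       observe_with_dropout, read_genotype_table,
                       simulate_colony, simulate_population)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"k_drones": 0}, {"dropout_rate": 1.0}, {"csd_alleles": 1},
        {"n_workers": -1}])
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_marker_panel_names_used_for_default_loci(self):
        assert SimConfig(n_loci=2).locus_names == ("LIST2020B", "R1-36")


class TestPopulation:
    def test_same_seed_gives_identical_tables(self):
        cfg = SimConfig(seed=4)
        t1, t2 = simulate_population(cfg), simulate_population(cfg)
        assert t1.frequencies == t2.frequencies

    def test_monomorphic_when_single_allele(self):
        pop = simulate_population(SimConfig(alleles_per_locus=1, seed=1))
        assert all(list(f.values()) == [1.0] for f in pop.frequencies.values())

    def test_high_concentration_approaches_uniform(self):
        pop = simulate_population(SimConfig(alleles_per_locus=4,
                                            dirichlet_alpha=1e4, seed=2))
        for freqs in pop.frequencies.values():
            assert max(freqs.values()) - min(freqs.values()) < 0.05


class TestColony:
    def test_seed_determinism_of_colony_and_truth(self):
        cfg = SimConfig(seed=9, k_drones=2, dropout_rate=0.05)
        pop = simulate_population(cfg)
        inds1, truth1 = simulate_colony(pop, cfg)
        inds2, truth2 = simulate_colony(pop, cfg)
        assert [i.genotype.calls for i in inds1] == \
            [i.genotype.calls for i in inds2]
        assert truth1.to_json() == truth2.to_json()

    def test_error_free_offspring_satisfy_mendelian_invariants(self):
        cfg = SimConfig(seed=6, k_drones=3, dropout_rate=0.0)
        pop = simulate_population(cfg)
        inds, truth = simulate_colony(pop, cfg)
        for ind in inds:
            rec = truth.offspring[ind.id]
            for locus, pair in ind.genotype.calls.items():
                queen = set(truth.queen_genotype[locus])
                if rec.ploidy == 1:
                    assert pair[0] == pair[1] and pair[0] in queen
                else:
                    d = truth.drone_haplotypes[rec.patriline][locus]
                    x, y = pair
                    assert (x in queen and y == d) or (y in queen and x == d)

    def test_single_drone_colony_shares_paternal_allele_everywhere(self):
        cfg = SimConfig(seed=7, k_drones=1, dropout_rate=0.0, n_haploid_eggs=0)
        pop = simulate_population(cfg)
        inds, truth = simulate_colony(pop, cfg)
        drone = truth.drone_haplotypes[0]
        for ind in inds:
            for locus, pair in ind.genotype.calls.items():
                assert drone[locus] in pair

    def test_matched_mating_yields_half_diploid_males(self):
        cfg = SimConfig(seed=8, n_loci=1, k_drones=1, n_workers=2000,
                        n_haploid_eggs=0, force_matched_mating=True,
                        dropout_rate=0.0)
        pop = simulate_population(cfg)
        inds, truth = simulate_colony(pop, cfg)
        males = sum(truth.offspring[i.id].sex == "diploid_male" for i in inds)
        se = math.sqrt(2000 * 0.25)
        assert abs(males - 1000) <= 3 * se

    def test_unmatched_mating_cannot_produce_diploid_males(self):
        cfg = SimConfig(seed=10, n_loci=1, n_workers=200, csd_alleles=3,
                        force_matched_mating=False)
        pop = simulate_population(cfg)
        _, truth = simulate_colony(pop, cfg)
        for rec in truth.offspring.values():
            if rec.ploidy == 2 and rec.sex == "diploid_male":
                # possible only when a drone matched the queen by chance
                assert truth.drone_csd[rec.patriline] in truth.queen_csd


class TestDropout:
    def test_duplicate_genotyping_mismatch_rate_matches_theory(self):
        """Per-allele repeat mismatch rate is f_het * e * (1 - e/2):
        a heterozygote mismatches one allele when exactly one run drops
        (2e(1-e)) and both alleles when the runs drop different alleles
        (e^2/2); homozygous loci cannot reveal dropout."""
        e = 0.05
        cfg = SimConfig(seed=12, n_workers=600, n_haploid_eggs=0,
                        dropout_rate=0.0, alleles_per_locus=4)
        pop = simulate_population(cfg)
        inds, truth = simulate_colony(pop, cfg)
        rng = np.random.default_rng(13)
        pairs = []
        n_het = n_called = 0
        for ind in inds:
            true_calls = truth.offspring[ind.id].genotype
            n_called += len(true_calls)
            n_het += sum(1 for p in true_calls.values() if p[0] != p[1])
            pairs.append((observe_with_dropout(true_calls, e, rng),
                          observe_with_dropout(true_calls, e, rng)))
        est = estimate_error_rate(pairs)
        mean_m = 2 * e - e * e  # mismatched alleles per het locus
        expected = n_het * mean_m / (2 * n_called)
        var_m = (2 * e * (1 - e) + 2 * e * e) - mean_m ** 2
        se = math.sqrt(n_het * var_m) / (2 * n_called)
        assert abs(est.rate - expected) <= 3 * se
        # single-run dropouts dominate; double-dropout to different alleles
        # (rate e^2/2 per het locus) surfaces as rare "other" mismatches
        assert est.breakdown["dropout"] > est.breakdown.get("other", 0)

    def test_dropout_only_affects_heterozygous_loci(self):
        rng = np.random.default_rng(3)
        true_calls = {"L1": (100, 100), "L2": (100, 104)}
        for _ in range(50):
            obs = observe_with_dropout(true_calls, 0.9, rng)
            assert obs.alleles("L1") == (100, 100)
            a, b = obs.alleles("L2")
            assert {a, b} <= {100, 104}


class TestEndToEndRecovery:
    def test_noisy_colonies_recovered_with_one_relaxed_locus(self):
        """Headline robustness: 3% dropout, one tolerated dropout locus."""
        ok = 0
        n_rep = 60
        seed_rng = np.random.default_rng(2023)
        for _ in range(n_rep):
            sub = int(seed_rng.integers(2**31))
            alleles = int(seed_rng.integers(3, 7))
            cfg = SimConfig(seed=sub, k_drones=1, dropout_rate=0.03,
                            alleles_per_locus=alleles)
            pop = simulate_population(cfg)
            inds, truth = simulate_colony(pop, cfg)
            res = ColonyPedigree(inds, max_drones=3, max_mismatch_loci=1).fit()
            if (res.consistent and res.n_drones == 1
                    and res.solutions[0].queen == truth.queen_genotype
                    and dict(res.solutions[0].drones[0])
                    == truth.drone_haplotypes[0]):
                ok += 1
        assert ok / n_rep >= 0.80


class TestFixtureNest:
    def test_fixture_files_deterministic_and_readable(self, fixture_nest_paths,
                                                      tmp_path):
        from colonykin import make_fixture_nest

        inds = read_genotype_table(fixture_nest_paths["genotypes"])
        assert {i.location for i in inds} == {
            "Tetbury nest", "Tetbury2", "Somerset", "Bath"}
        truth = json.loads(open(fixture_nest_paths["truth"]).read())
        assert len(truth["drone_haplotypes"]) == 1
        again = make_fixture_nest(tmp_path / "again", seed=20160916)
        assert open(again["genotypes"]).read() == \
            open(fixture_nest_paths["genotypes"]).read()
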