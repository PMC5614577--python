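import pytest

from bruteforce import brute_force_infer, canonical_solutions
from util import build, dip, random_instances

from colonykin import (ColonyPedigree, Individual, MultilocusGenotype,
                       PedigreeSolution, SimConfig, count_patrilines,
                       exclusion_test, infer_parents, simulate_colony,
                       simulate_population)


class TestInferParents:
    def test_eggs_pin_queen_and_single_drone_is_unique(self):
        # diploids (a,c),(b,c) plus eggs {a},{b} identify queen (a,b) x drone c
        inds, calls = build([{"L": (1, 3)}, {"L": (2, 3)}],
                            [{"L": 1}, {"L": 2}])
        sols = infer_parents(inds, ploidy=calls, haploid_mode="constrain")
        assert len(sols) == 1
        sol = sols[0]
        assert sol.queen == {"L": (1, 2)}
        assert [d["L"] for d in sol.drones] == [3]
        assert sol.n_drones == 1 and not sol.ambiguous_loci
        assert sol.offspring_assignments == {
            "d0": 0, "d1": 0, "h0": "maternal", "h1": "maternal"}

    def test_uniform_heterozygotes_leave_four_configurations(self):
        inds, calls = build([{"L": (1, 2)}] * 3, [])
        sols = infer_parents(inds, ploidy=calls, haploid_mode="constrain")
        configs = {(s.queen["L"], tuple(d["L"] for d in s.drones))
                   for s in sols}
        assert configs == {((1, 1), (2,)), ((1, 2), (1,)),
                           ((1, 2), (2,)), ((2, 2), (1,))}
        assert all(s.n_drones == 1 for s in sols)
        assert all(s.ambiguous_loci == {"L"} for s in sols)

    def test_incompatible_offspring_yield_empty_with_diagnostics(self):
        # three disjoint heterozygotes cannot share one mother
        inds, calls = build([{"L": (1, 2)}, {"L": (3, 4)}, {"L": (5, 6)}], [])
        res = ColonyPedigree(inds, ploidy_calls=calls, max_drones=5,
                             haploid_mode="constrain").fit()
        assert res.solutions == [] and not res.consistent
        assert "L" in res.diagnostics["most_violated_loci"]

    def test_missing_loci_are_compatible_with_any_drone(self):
        # drone haplotypes differ only where the second offspring is missing
        inds, calls = build(
            [{"L1": (1, 3), "L2": (1, 4)}, {"L1": (1, 3), "L2": None}],
            [{"L1": 1, "L2": 1}, {"L1": 2, "L2": 2}])
        sols = infer_parents(inds, ploidy=calls)
        assert {s.n_drones for s in sols} == {1}

    @pytest.mark.parametrize("mode", ["constrain", "pin"])
    def test_matches_bruteforce_on_random_small_instances(self, mode):
        for dips, haps, _ in random_instances(seed=42, n=25):
            inds, calls = build(dips, haps)
            loci = sorted({l for c in dips for l in c}
                          | {l for c in haps for l in c})
            res = ColonyPedigree(inds, ploidy_calls=calls, max_drones=3,
                                 haploid_mode=mode).fit()
            k_oracle, oracle = brute_force_infer(dips, haps, max_drones=3,
                                                 haploid_mode=mode)
            assert res.n_drones == k_oracle
            assert canonical_solutions(res.solutions, loci) == oracle


class TestDropoutTolerance:
    QUEEN_12 = [{"L1": (1, 3), "L2": (1, 3)},  # clean patriline-0 offspring
                {"L1": (1, 1), "L2": (2, 3)}]  # L1 heterozygote dropped

    def test_strict_mode_splits_dropped_offspring_into_second_patriline(self):
        inds, calls = build(self.QUEEN_12, [{"L1": 1, "L2": 2}, {"L1": 2, "L2": 1}])
        sols = infer_parents(inds, ploidy=calls, max_mismatch_loci=0)
        assert sols[0].n_drones == 2

    def test_one_relaxed_locus_restores_single_drone(self):
        inds, calls = build(self.QUEEN_12, [{"L1": 1, "L2": 2}, {"L1": 2, "L2": 1}])
        sols = infer_parents(inds, ploidy=calls, max_mismatch_loci=1)
        assert len(sols) == 1
        sol = sols[0]
        assert sol.n_drones == 1 and sol.queen == {"L1": (1, 2), "L2": (1, 2)}
        assert sol.drones[0] == {"L1": 3, "L2": 3}
        assert sol.offspring_assignments["d1"] == 0

    def test_offspring_over_budget_flagged_unexplained(self):
        dips = [{"L1": (1, 3), "L2": (1, 3), "L3": (1, 3)},
                {"L1": (1, 1), "L2": (2, 2), "L3": (1, 3)}]  # two dropouts
        inds, calls = build(dips, [{"L1": 1, "L2": 2, "L3": 1},
                                   {"L1": 2, "L2": 1, "L3": 2}])
        sols = infer_parents(inds, ploidy=calls, max_mismatch_loci=1)
        assert sols[0].offspring_assignments["d1"] == "unexplained"
        assert sols[0].offspring_assignments["d0"] == 0


class TestExclusion:
    SOLUTION = PedigreeSolution(
        queen={"L1": (1, 2), "L2": (1, 2)},
        drones=({"L1": 3, "L2": 1}, {"L1": 1, "L2": 3}),
        n_drones=2, offspring_assignments={}, ambiguous_loci=frozenset())

    def test_non_parental_allele_excludes_and_is_listed(self):
        cand, _ = dip("c", {"L1": (1, 9), "L2": (1, 2)})
        res = exclusion_test(cand, self.SOLUTION)
        assert res.verdict == "excluded" and not res.allele_set_ok
        assert res.violating_loci[0][0] == "L1"

    def test_offspring_decomposing_under_one_drone_is_consistent(self):
        cand, _ = dip("c", {"L1": (1, 3), "L2": (1, 1)})
        res = exclusion_test(cand, self.SOLUTION)
        assert res.verdict == "consistent"
        assert res.allele_set_ok and res.patriline_ok

    def test_parental_alleles_but_no_single_patriline_excludes(self):
        # needs drone 0 at L1 but drone 1 at L2
        cand, _ = dip("c", {"L1": (1, 3), "L2": (1, 3)})
        res = exclusion_test(cand, self.SOLUTION)
        assert res.verdict == "excluded"
        assert res.allele_set_ok and not res.patriline_ok

    def test_haploid_candidate_checked_against_queen_only(self):
        from util import hap
        ok_egg, call = hap("e", {"L1": 2, "L2": 1})
        assert exclusion_test(ok_egg, self.SOLUTION,
                              ploidy=call).verdict == "consistent"
        bad_egg, call2 = hap("e2", {"L1": 3, "L2": 1})  # drone allele only
        assert exclusion_test(bad_egg, self.SOLUTION,
                              ploidy=call2).verdict == "excluded"

    def test_simulated_nestmates_never_excluded_without_error(self):
        for seed in (3, 5, 8):
            cfg = SimConfig(seed=seed, k_drones=2, dropout_rate=0.0,
                            n_workers=30, n_haploid_eggs=10,
                            n_diploid_offspring_extra=15)
            pop = simulate_population(cfg)
            inds, truth = simulate_colony(pop, cfg)
            nest = [i for i in inds if not i.id.startswith("X")]
            extras = [i for i in inds if i.id.startswith("X")]
            res = ColonyPedigree(nest, max_drones=4).fit()
            assert res.consistent
            for extra in extras:
                assert res.test_candidate(extra).verdict == "consistent"


class TestCountPatrilines:
    def test_shared_non_maternal_allele_means_one_drone(self):
        inds, calls = build([{"L": (1, 3)}, {"L": (2, 3)}], [])
        out = count_patrilines(inds, {"L": (1, 2)}, ploidy=calls)
        assert out.n_drones == 1 and out.exact

    def test_disjoint_non_maternal_haplotypes_mean_two(self):
        inds, calls = build([{"L": (1, 3)}, {"L": (1, 4)}], [])
        out = count_patrilines(inds, {"L": (1, 1)}, ploidy=calls)
        assert out.n_drones == 2
        assert out.assignments["d0"] != out.assignments["d1"]

    def test_missing_at_discriminating_loci_collapses_to_one(self):
        inds, calls = build(
            [{"L1": (1, 3), "L2": None}, {"L1": None, "L2": (1, 4)}], [])
        out = count_patrilines(inds, {"L1": (1, 1), "L2": (1, 1)},
                               ploidy=calls)
        assert out.n_drones == 1

    def test_offspring_foreign_to_queen_reported_unassignable(self):
        inds, calls = build([{"L": (3, 4)}], [])
        out = count_patrilines(inds, {"L": (1, 2)}, ploidy=calls)
        assert out.unassignable == ("d0",)


class TestResultsSurface:
    def test_summary_reports_mate_number_and_patrilines(self):
        inds, calls = build([{"L": (1, 3)}, {"L": (2, 3)}],
                            [{"L": 1}, {"L": 2}])
        res = ColonyPedigree(inds, ploidy_calls=calls).fit()
        text = res.summary()
        assert "Minimal mate number: 1" in text
        assert "Patriline 0: 2 diploid offspring" in text

    def test_unknown_ploidy_individuals_are_skipped_and_reported(self):
        inds, calls = build([{"L": (1, 3)}], [])
        blank = Individual("u", MultilocusGenotype({"L": None}))
        res = ColonyPedigree(inds + [blank]).fit()
        assert res.diagnostics["skipped_unknown_ploidy"] == ("u",)

    def test_no_offspring_raises(self):
        blank = Individual("u", MultilocusGenotype({"L": None}))
        with pytest.raises(ValueError, match="no offspring"):
            ColonyPedigree([blank]).fit()
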