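"""Queen/drone pedigree reconstruction for a monogynous haplodiploid nest.

Model: the nest descends from a single queen (monogyny is an assumption,
not an inference) mated with ``k`` drones. Haploid offspring (unfertilised
eggs) carry one maternal allele per locus; each diploid offspring carries
one maternal allele plus the allele of the single drone that sired it (its
patriline), consistently across loci. Inference enumerates, for the
smallest viable ``k``, every (queen genotype, drone haplotype set)
configuration that explains all offspring, drawing candidate alleles from
those observed at each locus.

The enumeration is exact while the number of distinct per-offspring
paternal-allele patterns is small (``exact_limit``, default 12); above
that a deterministic first-fit cover heuristic is used and the result is
reported as a bound (``exact=False``). Genotyping error can be tolerated
via ``max_mismatch_loci``: per offspring, up to that many loci recorded
homozygous may be treated as allele dropouts (a heterozygote scored as a
homozygote), the only error mode these data show.

Presented statsmodels-style: :class:`ColonyPedigree` is the model,
``fit()`` returns :class:`PedigreeResults` with the solution set,
diagnostics and a ``summary()``; module-level functions
(:func:`infer_parents`, :func:`exclusion_test`, :func:`count_patrilines`)
wrap it.
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .io import Individual, MISSING
from .ploidy import PloidyCall, call_ploidy_table

__all__ = [
    "PedigreeSolution",
    "ExclusionResult",
    "PatrilineCount",
    "ColonyPedigree",
    "PedigreeResults",
    "infer_parents",
    "exclusion_test",
    "count_patrilines",
]

MATERNAL = "maternal"
UNEXPLAINED = "unexplained"  # over the per-offspring dropout budget
_ANY = None  # wildcard allele set (MISSING locus / unconstrained dropout)


@dataclass(frozen=True)
class PedigreeSolution:
    """One reconstructed (queen, drone set) configuration.

    ``queen`` maps locus -> unordered allele pair (sorted); ``drones`` is a
    tuple of per-locus haplotypes (locus -> allele), sorted for
    determinism. ``offspring_assignments`` maps each offspring id to the
    index of its patriline in ``drones`` (diploids), ``"maternal"``
    (haploids), or ``"unexplained"`` for offspring needing more dropout
    relaxations than the per-offspring budget allows. ``ambiguous_loci``
    are loci where several configurations survive across the returned
    solution set.
    """

    queen: dict
    drones: tuple
    n_drones: int
    offspring_assignments: dict
    ambiguous_loci: frozenset
    consistent: bool = True
    exact: bool = True

    def parental_alleles(self, locus: str) -> set[int]:
        out = set(self.queen.get(locus, ()))
        for d in self.drones:
            a = d.get(locus)
            if a is not None:
                out.add(a)
        return out


@dataclass
class ExclusionResult:
    """Allele-based membership test of a candidate against a pedigree.

    ``violating_loci`` lists ``(locus, candidate_alleles, parental_alleles)``
    for loci where the candidate carries an allele absent from the parental
    set, or — when the allele set is compatible but no single patriline
    explains the genotype — the loci blocking the best patriline.
    ``allele_set_ok`` and ``patriline_ok`` report the two checks separately.
    """

    candidate_id: str
    violating_loci: list
    verdict: str
    allele_set_ok: bool = True
    patriline_ok: bool | None = None


@dataclass
class PatrilineCount:
    """Minimum number of drone haplotypes covering the diploid offspring."""

    n_drones: int
    assignments: dict
    exact: bool
    unassignable: tuple = ()


# ---------------------------------------------------------------------------
# internal machinery


def _split_offspring(offspring, ploidy, loci_filter):
    """Split into diploid/haploid call dicts, per ploidy verdicts."""
    dip, hap, skipped = [], [], []
    for ind in offspring:
        call = ploidy.get(ind.id)
        verdict = call.verdict if call is not None else "unknown"
        calls = {l: p for l, p in ind.genotype.calls.items()
                 if p is not MISSING and (loci_filter is None or l in loci_filter)}
        if verdict == "diploid":
            dip.append((ind.id, calls))
        elif verdict == "haploid":
            hap.append((ind.id, {l: p[0] for l, p in calls.items()}))
        else:
            skipped.append(ind.id)
    return dip, hap, skipped


def _universe(dip, hap, loci=None):
    obs: dict[str, set[int]] = {}
    for _, calls in dip:
        for l, (a, b) in calls.items():
            obs.setdefault(l, set()).update((a, b))
    for _, calls in hap:
        for l, a in calls.items():
            obs.setdefault(l, set()).add(a)
    if loci is not None:
        obs = {l: s for l, s in obs.items() if l in loci}
    return {l: s for l, s in obs.items() if s}


def _queen_candidates_at(locus, universe, hap, dip, haploid_mode, allow_relax):
    """Viable queen allele pairs at one locus, drawn from observed alleles."""
    egg_alleles = sorted({calls[locus] for _, calls in hap if locus in calls})
    alleles = sorted(universe)
    if len(egg_alleles) > 2:
        return []
    if haploid_mode == "pin" and egg_alleles:
        if len(egg_alleles) == 2:
            pairs = [tuple(egg_alleles)]
        else:
            pairs = [(egg_alleles[0], egg_alleles[0])]
    else:
        pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
        if haploid_mode != "ignore":
            pairs = [p for p in pairs if all(e in p for e in egg_alleles)]
    out = []
    for pair in pairs:
        q = set(pair)
        ok = True
        for _, calls in dip:
            if locus not in calls:
                continue
            x, y = calls[locus]
            if x in q or y in q:
                continue
            if allow_relax and x == y:
                continue  # dropout-explainable homozygote
            ok = False
            break
        if ok:
            out.append(pair)
    return out


def _patterns_for_config(queen_cfg, loci, dip, m):
    """Per-offspring paternal-allele patterns under a fixed queen genotype.

    Returns (patterns, members) where patterns[i] is a tuple over loci of
    (strict, relax) allele sets (frozenset or _ANY wildcard) and members[i]
    the offspring ids sharing that pattern; or None when some offspring is
    inconsistent with the queen even under relaxation.
    """
    queen = dict(zip(loci, queen_cfg))
    dedup: dict[tuple, list] = {}
    for oid, calls in dip:
        elems = []
        for l in loci:
            if l not in calls:
                elems.append((_ANY, frozenset()))
                continue
            x, y = calls[l]
            q = set(queen[l])
            if x != y:
                strict = frozenset(a for a, b in ((y, x), (x, y)) if b in q)
                relax = frozenset()
            else:
                if x in q:
                    strict, relax = frozenset((x,)), (_ANY if m > 0 else frozenset())
                else:
                    strict, relax = frozenset(), (frozenset((x,)) if m > 0 else frozenset())
            if not strict and not relax:
                return None
            elems.append((strict, relax))
        dedup.setdefault(tuple(elems), []).append(oid)
    patterns = sorted(dedup, key=_pattern_key)
    return patterns, [dedup[p] for p in patterns]


def _pattern_key(pattern):
    key = []
    for strict, relax in pattern:
        key.append((
            (1, ()) if strict is _ANY else (0, tuple(sorted(strict))),
            (1, ()) if relax is _ANY else (0, tuple(sorted(relax))),
        ))
    return tuple(key)


def _allowed(elem, universe_l):
    strict, relax = elem
    if strict is _ANY or relax is _ANY:
        return set(universe_l)
    return set(strict | relax)


def _intersect_pattern(state, pattern, universe):
    """Intersect a block's per-locus allowed sets with a pattern's; None if empty."""
    new = []
    for allowed, elem, uni in zip(state, pattern, universe):
        s = allowed & _allowed(elem, uni)
        if not s:
            return None
        new.append(s)
    return new


def _enumerate_partitions(patterns, k, universe):
    """All partitions of patterns into exactly k blocks with per-locus
    nonempty allowed-set intersections (restricted-growth order)."""
    n = len(patterns)
    results = []

    def rec(i, blocks, states):
        if n - i < k - len(blocks):
            return
        if i == n:
            if len(blocks) == k:
                results.append([list(b) for b in blocks])
            return
        for j in range(len(blocks)):
            ns = _intersect_pattern(states[j], patterns[i], universe)
            if ns is not None:
                blocks[j].append(i)
                old = states[j]
                states[j] = ns
                rec(i + 1, blocks, states)
                states[j] = old
                blocks[j].pop()
        if len(blocks) < k:
            state0 = _intersect_pattern([set(u) for u in universe],
                                        patterns[i], universe)
            if state0 is not None:
                blocks.append([i])
                states.append(state0)
                rec(i + 1, blocks, states)
                states.pop()
                blocks.pop()

    rec(0, [], [])
    return results


def _greedy_partition(patterns, universe):
    """Deterministic first-fit cover; returns (partition, states)."""
    blocks, states = [], []
    for i, pat in enumerate(patterns):
        placed = False
        for j, st in enumerate(states):
            ns = _intersect_pattern(st, pat, universe)
            if ns is not None:
                blocks[j].append(i)
                states[j] = ns
                placed = True
                break
        if not placed:
            st = _intersect_pattern([set(u) for u in universe], pat, universe)
            if st is None:
                return None, None  # pattern impossible on its own
            blocks.append([i])
            states.append(st)
    return blocks, states


def _block_haplotypes(block, patterns, universe, m):
    """Haplotype options for one block, plus over-budget pattern indices.

    Strict mode (m == 0): the full cross product of per-locus intersection
    sets (every choice is valid) and nothing over budget. Relaxed mode: a
    single deterministic haplotype minimising total relaxation use per
    locus; patterns needing more than ``m`` relaxed loci under that choice
    are reported so their offspring can be flagged as unexplained (a
    dropout-consistent constraint is always one of the true alleles, so
    keeping them in the block never distorts the solution structure).
    """
    state = [set(u) for u in universe]
    for i in block:
        state = _intersect_pattern(state, patterns[i], universe)
        if state is None:
            return None
    if m == 0:
        return [sorted(s) for s in state], []
    elems = {i: patterns[i] for i in block}
    choice = []
    for l, allowed in enumerate(state):
        best = min(sorted(allowed),
                   key=lambda a: (sum(1 for e in elems.values()
                                      if e[l][0] is not _ANY and a not in e[l][0]), a))
        choice.append(best)
    over = [i for i, e in elems.items()
            if sum(1 for l, a in enumerate(choice)
                   if e[l][0] is not _ANY and a not in e[l][0]) > m]
    return [[a] for a in choice], over


def _min_cover(patterns, universe, max_k, m, exact_limit):
    """Smallest k and the partitions achieving it.

    Returns (k, partitions, exact) or (None, [], exact) when no cover with
    <= max_k blocks exists.
    """
    if not patterns:
        return 0, [[]], True
    if len(patterns) <= exact_limit:
        for k in range(1, max_k + 1):
            parts = _enumerate_partitions(patterns, k, universe)
            if parts:
                return k, parts, True
        return None, [], True
    blocks, _ = _greedy_partition(patterns, universe)
    if blocks is None or len(blocks) > max_k:
        return None, [], False
    return len(blocks), [blocks], False


# ---------------------------------------------------------------------------
# model / results


class ColonyPedigree:
    """Single-queen pedigree model for a set of nest offspring.

    Parameters
    ----------
    offspring : sequence of Individual
        Putative progeny of one queen (monogyny assumed).
    ploidy_calls : mapping id -> PloidyCall, optional
        Defaults to zygosity-based calls; ``"unknown"`` individuals are
        left out of the inference and reported in the diagnostics.
    loci : iterable of str, optional
        Restrict inference to these loci (e.g. the 13-locus panel).
    max_drones : int
        Largest mate number considered.
    max_mismatch_loci : int
        Dropout-consistent mismatches tolerated per offspring (default 0,
        i.e. every locus must decompose exactly). When positive, loci
        recorded homozygous may be read as dropped heterozygotes; an
        offspring needing more than this many relaxed loci under the
        solution is flagged ``"unexplained"`` rather than failing the fit.
    haploid_mode : {"pin", "constrain", "ignore"}
        How haploid eggs inform the queen: ``pin`` equates the queen's
        allele set at a locus with the alleles seen in eggs there (two
        distinct egg alleles fix the pair; one egg allele implies a
        homozygous queen), ``constrain`` only requires egg alleles to be
        carried by the queen, ``ignore`` leaves eggs out entirely.
    """

    def __init__(self, offspring: Sequence[Individual],
                 ploidy_calls: Mapping[str, PloidyCall] | None = None,
                 loci=None, max_drones: int = 5, max_mismatch_loci: int = 0,
                 haploid_mode: str = "pin", exact_limit: int = 12,
                 max_queen_configs: int = 20000, max_solutions: int = 2000):
        if haploid_mode not in ("pin", "constrain", "ignore"):
            raise ValueError(f"unknown haploid_mode {haploid_mode!r}")
        self.offspring = list(offspring)
        if ploidy_calls is None:
            ploidy_calls = call_ploidy_table(self.offspring)
        self.ploidy_calls = ploidy_calls
        self.loci_filter = set(loci) if loci is not None else None
        self.max_drones = int(max_drones)
        self.max_mismatch_loci = int(max_mismatch_loci)
        self.haploid_mode = haploid_mode
        self.exact_limit = int(exact_limit)
        self.max_queen_configs = int(max_queen_configs)
        self.max_solutions = int(max_solutions)

    def fit(self) -> "PedigreeResults":
        m = self.max_mismatch_loci
        dip, hap, skipped = _split_offspring(self.offspring, self.ploidy_calls,
                                             self.loci_filter)
        if self.haploid_mode == "ignore":
            hap = []
        if not dip and not hap:
            raise ValueError("no offspring with called loci")
        universe = _universe(dip, hap, self.loci_filter)
        loci = sorted(universe)
        uni_list = [universe[l] for l in loci]

        cand = {}
        no_candidate_loci = []
        for l in loci:
            cand[l] = _queen_candidates_at(l, universe[l], hap, dip,
                                           self.haploid_mode, m > 0)
            if not cand[l]:
                no_candidate_loci.append(l)
        diagnostics = self._diagnostics(loci, universe, dip, hap, skipped,
                                        no_candidate_loci)
        if no_candidate_loci:
            return PedigreeResults(self, [], diagnostics, complete=True)

        configs = itertools.product(*(cand[l] for l in loci))
        capped = list(itertools.islice(configs, self.max_queen_configs + 1))
        complete = len(capped) <= self.max_queen_configs
        capped = capped[: self.max_queen_configs]

        best_k = None
        best: list[tuple] = []  # (queen_cfg, patterns, members, partitions, exact)
        for queen_cfg in capped:
            built = _patterns_for_config(queen_cfg, loci, dip, m)
            if built is None:
                continue
            patterns, members = built
            k, parts, exact = _min_cover(patterns, uni_list, self.max_drones,
                                         m, self.exact_limit)
            if k is None:
                continue
            if best_k is None or k < best_k:
                best_k, best = k, []
            if k == best_k:
                best.append((queen_cfg, patterns, members, parts, exact))

        if best_k is None:
            return PedigreeResults(self, [], diagnostics, complete=complete)

        solutions = self._assemble(best, loci, uni_list, hap, m)
        return PedigreeResults(self, solutions, diagnostics, complete=complete)

    def _assemble(self, best, loci, uni_list, hap, m):
        hap_ids = [oid for oid, _ in hap]
        found: dict[tuple, PedigreeSolution] = {}
        truncated = False
        all_exact = all(e for *_, e in best)
        for queen_cfg, patterns, members, parts, exact in best:
            queen = dict(zip(loci, queen_cfg))
            for part in parts:
                opts = []
                over_budget: set = set()
                ok = True
                for block in part:
                    built_h = _block_haplotypes(block, patterns, uni_list, m)
                    if built_h is None:
                        ok = False
                        break
                    h, over = built_h
                    over_budget.update(over)
                    opts.append(list(itertools.product(*h)))
                if not ok:
                    continue
                for combo in itertools.product(*opts):
                    if len(set(combo)) < len(combo):
                        continue
                    order = sorted(range(len(combo)), key=lambda j: combo[j])
                    drones = tuple(dict(zip(loci, combo[j])) for j in order)
                    key = (queen_cfg, tuple(combo[j] for j in order))
                    if key in found:
                        continue
                    rank = {j: r for r, j in enumerate(order)}
                    assign: dict = {oid: MATERNAL for oid in hap_ids}
                    for bpos, block in enumerate(part):
                        for i in block:
                            label = UNEXPLAINED if i in over_budget else rank[bpos]
                            for oid in members[i]:
                                assign[oid] = label
                    found[key] = PedigreeSolution(
                        queen=queen, drones=drones, n_drones=len(drones),
                        offspring_assignments=assign,
                        ambiguous_loci=frozenset(), exact=exact)
                    if len(found) >= self.max_solutions:
                        truncated = True
                        break
                if truncated:
                    break
            if truncated:
                break
        solutions = [found[k] for k in sorted(found)]
        ambiguous = set()
        for l in loci:
            configs_at = {(s.queen[l], tuple(sorted(d.get(l) for d in s.drones)))
                          for s in solutions}
            if len(configs_at) > 1:
                ambiguous.add(l)
        amb = frozenset(ambiguous)
        return [
            PedigreeSolution(queen=s.queen, drones=s.drones, n_drones=s.n_drones,
                             offspring_assignments=s.offspring_assignments,
                             ambiguous_loci=amb, exact=s.exact and all_exact
                             and not truncated)
            for s in solutions
        ]

    @staticmethod
    def _diagnostics(loci, universe, dip, hap, skipped, no_candidate_loci):
        violations = {}
        for l in loci:
            alleles = sorted(universe[l])
            pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
            best = None
            for pair in pairs:
                q = set(pair)
                bad = sum(1 for _, calls in dip if l in calls
                          and not (set(calls[l]) & q))
                bad += sum(1 for _, calls in hap if l in calls
                           and calls[l] not in q)
                best = bad if best is None else min(best, bad)
            violations[l] = best or 0
        return {
            "n_diploid": len(dip),
            "n_haploid": len(hap),
            "skipped_unknown_ploidy": tuple(skipped),
            "locus_min_violations": violations,
            "most_violated_loci": tuple(sorted(
                (l for l in loci if violations[l] > 0),
                key=lambda l: (-violations[l], l))),
            "no_candidate_loci": tuple(no_candidate_loci),
        }


class PedigreeResults:
    """Fit result: all minimal-mate-number pedigree solutions."""

    def __init__(self, model: ColonyPedigree, solutions, diagnostics,
                 complete: bool = True):
        self.model = model
        self.solutions = list(solutions)
        self.diagnostics = diagnostics
        self.complete = complete

    @property
    def consistent(self) -> bool:
        return bool(self.solutions)

    @property
    def n_drones(self) -> int | None:
        return self.solutions[0].n_drones if self.solutions else None

    @property
    def unique(self) -> bool:
        return len(self.solutions) == 1 and not self.solutions[0].ambiguous_loci

    @property
    def queen(self) -> dict | None:
        """Queen genotype when a unique solution was found, else None."""
        return self.solutions[0].queen if self.unique else None

    def test_candidate(self, candidate: Individual,
                       solution: PedigreeSolution | None = None,
                       ploidy: PloidyCall | None = None) -> ExclusionResult:
        if solution is None:
            if not self.solutions:
                raise ValueError("no consistent pedigree solution to test against")
            solution = self.solutions[0]
        return exclusion_test(candidate, solution, ploidy=ploidy)

    def summary(self) -> str:
        lines = ["Colony pedigree reconstruction",
                 "=" * 34,
                 f"Offspring: {self.diagnostics['n_diploid']} diploid, "
                 f"{self.diagnostics['n_haploid']} haploid"]
        skipped = self.diagnostics["skipped_unknown_ploidy"]
        if skipped:
            lines.append(f"Skipped (unknown ploidy): {len(skipped)}")
        if not self.consistent:
            lines.append("No consistent single-queen solution within "
                         f"max_drones={self.model.max_drones}.")
            worst = self.diagnostics["most_violated_loci"]
            if worst:
                lines.append("Most-violated loci: " + ", ".join(
                    f"{l} ({self.diagnostics['locus_min_violations'][l]})"
                    for l in worst[:5]))
            return "\n".join(lines)
        sol = self.solutions[0]
        lines.append(f"Minimal mate number: {sol.n_drones} "
                     f"({'exact' if sol.exact else 'heuristic bound'})")
        lines.append(f"Solutions: {len(self.solutions)}"
                     + ("" if self.complete else " (search capped)"))
        if sol.ambiguous_loci:
            lines.append("Ambiguous loci: " + ", ".join(sorted(sol.ambiguous_loci)))
        lines.append("Queen genotype" + ("" if self.unique else " (first solution)"))
        for l in sorted(sol.queen):
            q = sol.queen[l]
            drone_alleles = "/".join(str(d.get(l)) for d in sol.drones)
            lines.append(f"  {l:<12} queen {q[0]}/{q[1]:<6} drones {drone_alleles}")
        pat = Counter(v for v in sol.offspring_assignments.values()
                      if v != MATERNAL)
        for j in sorted(pat):
            lines.append(f"Patriline {j}: {pat[j]} diploid offspring")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operation-level convenience wrappers


def infer_parents(offspring: Sequence[Individual],
                  ploidy: Mapping[str, PloidyCall] | None = None,
                  max_drones: int = 5, **kwargs) -> list[PedigreeSolution]:
    """All minimal-mate-number pedigree solutions (empty if inconsistent)."""
    return ColonyPedigree(offspring, ploidy_calls=ploidy,
                          max_drones=max_drones, **kwargs).fit().solutions


def exclusion_test(candidate: Individual, solution: PedigreeSolution,
                   ploidy: PloidyCall | None = None) -> ExclusionResult:
    """Test whether a candidate could be an offspring of the solved pedigree.

    Two checks: (1) every candidate allele at every called locus appears in
    the parental allele set; (2) a diploid candidate decomposes as one
    maternal allele plus a single drone's allele under at least one
    patriline (a haploid candidate must carry only queen alleles).
    """
    from .ploidy import call_ploidy

    if ploidy is None:
        ploidy = call_ploidy(candidate.genotype, id=candidate.id)
    loci = [l for l in candidate.genotype.called_loci if l in solution.queen]
    violations = []
    for l in loci:
        pair = candidate.genotype.alleles(l)
        parental = solution.parental_alleles(l)
        alleles = set(pair) if ploidy.verdict != "haploid" else {pair[0]}
        outside = alleles - parental
        if outside:
            violations.append((l, pair, tuple(sorted(parental))))
    allele_set_ok = not violations

    if ploidy.verdict == "haploid":
        bad = [l for l in loci
               if candidate.genotype.alleles(l)[0] not in solution.queen[l]]
        patriline_ok = not bad
        fail_loci = bad
    else:
        best_fail: list | None = None
        for drone in solution.drones:
            fails = []
            for l in loci:
                x, y = candidate.genotype.alleles(l)
                d = drone.get(l)
                q = solution.queen[l]
                ok = ((x in q and (d is None or y == d))
                      or (y in q and (d is None or x == d)))
                if not ok:
                    fails.append(l)
            if best_fail is None or len(fails) < len(best_fail):
                best_fail = fails
        patriline_ok = best_fail is not None and not best_fail
        fail_loci = best_fail or []

    if allele_set_ok and not patriline_ok:
        for l in fail_loci:
            violations.append((l, candidate.genotype.alleles(l),
                               tuple(sorted(solution.parental_alleles(l)))))
    verdict = "excluded" if violations else "consistent"
    return ExclusionResult(candidate_id=candidate.id, violating_loci=violations,
                           verdict=verdict, allele_set_ok=allele_set_ok,
                           patriline_ok=patriline_ok)


def count_patrilines(offspring: Sequence[Individual], queen: Mapping[str, tuple],
                     ploidy: Mapping[str, PloidyCall] | None = None,
                     max_mismatch_loci: int = 0,
                     exact_limit: int = 12) -> PatrilineCount:
    """Minimum number of drone haplotypes covering the diploid offspring,
    given a fixed queen genotype.

    Exact search over pattern partitions while <= ``exact_limit`` distinct
    non-maternal haplotype patterns; above that a deterministic first-fit
    cover gives an upper bound (``exact=False``; the true minimum is <= the
    reported value >= is not guaranteed). MISSING loci are compatible with
    any drone. Offspring carrying a heterozygous genotype with no queen
    allele are reported as unassignable.
    """
    if ploidy is None:
        ploidy = call_ploidy_table(offspring)
    m = max_mismatch_loci
    loci = sorted(queen)
    dip, hap, _ = _split_offspring(offspring, ploidy, set(loci))
    universe = _universe(dip, hap, set(loci))
    loci = [l for l in loci if l in universe]
    for l, pair in queen.items():
        if l in universe:
            universe[l].update(pair)
    uni_list = [universe[l] for l in loci]

    usable_dip, unassignable = [], []
    queen_cfg = tuple(tuple(sorted(queen[l])) for l in loci)
    for oid, calls in dip:
        built = _patterns_for_config(queen_cfg, loci, [(oid, calls)], m)
        if built is None:
            unassignable.append(oid)
        else:
            usable_dip.append((oid, calls))
    built = _patterns_for_config(queen_cfg, loci, usable_dip, m)
    patterns, members = built if built is not None else ([], [])
    k, parts, exact = _min_cover(patterns, uni_list, max(len(usable_dip), 1),
                                 m, exact_limit)
    assignments: dict = {oid: MATERNAL for oid, _ in hap}
    if k and parts:
        for bpos, block in enumerate(parts[0]):
            built_h = _block_haplotypes(block, patterns, uni_list, m)
            over = set(built_h[1]) if built_h is not None else set()
            for i in block:
                label = UNEXPLAINED if i in over else bpos
                for oid in members[i]:
                    assignments[oid] = label
    return PatrilineCount(n_drones=k or 0, assignments=assignments,
                          exact=exact, unassignable=tuple(unassignable))
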