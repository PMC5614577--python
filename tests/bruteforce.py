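"""Brute-force pedigree enumeration used as an independent oracle.

Enumerates every queen allele pair per locus and every drone haplotype
(cross product of observed alleles), for increasing mate numbers, keeping
the configurations under which each diploid offspring decomposes as one
maternal allele plus a single drone's allele and each haploid offspring
carries a queen allele. No sharing of code with the package's search.
"""

from itertools import combinations, product


def _compatible_diploid(calls, queen, drone):
    for locus, (x, y) in calls.items():
        d = drone[locus]
        q = queen[locus]
        if not ((x in q and y == d) or (y in q and x == d)):
            return False
    return True


def brute_force_infer(dip, hap, max_drones=4, haploid_mode="constrain"):
    """All minimal-mate-number (queen, drone-set) configurations.

    dip: list of dicts locus -> (allele, allele); hap: list of dicts
    locus -> allele. Returns (k, solutions) where solutions is a set of
    (queen_config, frozenset_of_drone_allele_tuples) over the sorted locus
    list, or (None, set()) if nothing fits within max_drones.
    """
    loci = sorted({l for c in dip for l in c} | {l for c in hap for l in c})
    obs = {
        l: sorted({a for c in dip if l in c for a in c[l]}
                  | {c[l] for c in hap if l in c})
        for l in loci
    }

    def queen_options(l):
        eggs = sorted({c[l] for c in hap if l in c})
        if len(eggs) > 2:
            return []
        if haploid_mode == "pin" and eggs:
            return [tuple(eggs)] if len(eggs) == 2 else [(eggs[0], eggs[0])]
        alleles = obs[l]
        pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
        return [p for p in pairs if all(e in p for e in eggs)]

    opts = [queen_options(l) for l in loci]
    haplotypes = [dict(zip(loci, h)) for h in product(*(obs[l] for l in loci))]
    for k in range(1, max_drones + 1):
        solutions = set()
        for qcfg in product(*opts):
            queen = dict(zip(loci, qcfg))
            if any(c[l] not in queen[l] for c in hap for l in c):
                continue
            for idx in combinations(range(len(haplotypes)), k):
                drones = [haplotypes[i] for i in idx]
                if all(any(_compatible_diploid(c, queen, d) for d in drones)
                       for c in dip):
                    key = frozenset(tuple(d[l] for l in loci) for d in drones)
                    solutions.add((qcfg, key))
        if solutions:
            return k, solutions
    return None, set()


def canonical_solutions(solutions, loci):
    """Package PedigreeSolution list -> oracle-comparable canonical set."""
    out = set()
    for s in solutions:
        qcfg = tuple(tuple(s.queen[l]) for l in loci)
        key = frozenset(tuple(d[l] for l in loci) for d in s.drones)
        out.add((qcfg, key))
    return out
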