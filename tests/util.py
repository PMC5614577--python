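"""Shared helpers for building tiny pedigree instances in tests."""

import numpy as np

from colonykin import Individual, MultilocusGenotype
from colonykin.ploidy import PloidyCall


def dip(oid, calls, **kw):
    """Diploid individual with an explicit ploidy call."""
    ind = Individual(oid, MultilocusGenotype(calls), **kw)
    call = PloidyCall(oid, len([p for p in calls.values() if p]), 1, "diploid")
    return ind, call


def hap(oid, calls, **kw):
    """Haploid individual (single allele per locus) with an explicit call."""
    pairs = {l: (a, a) for l, a in calls.items()}
    ind = Individual(oid, MultilocusGenotype(pairs), **kw)
    call = PloidyCall(oid, len(calls), 0, "haploid")
    return ind, call


def build(dips, haps):
    """(individuals, ploidy_calls) from lists of per-locus call dicts."""
    inds, calls = [], {}
    for i, c in enumerate(dips):
        ind, call = dip(f"d{i}", c)
        inds.append(ind)
        calls[ind.id] = call
    for i, c in enumerate(haps):
        ind, call = hap(f"h{i}", c)
        inds.append(ind)
        calls[ind.id] = call
    return inds, calls


def random_instances(seed, n):
    """Deterministic stream of small colony instances for oracle checks.

    Yields (dip, hap, mode): diploid call dicts, haploid call dicts and the
    haploid handling mode. Instances stay within <= 3 loci, <= 3 alleles
    per locus, <= 8 offspring so exhaustive enumeration is cheap.
    """
    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n:
        L = int(rng.integers(1, 4))
        A = int(rng.integers(2, 4))
        k_true = int(rng.integers(1, 3))
        loci = [f"L{i}" for i in range(L)]
        queen = {l: tuple(sorted(rng.choice(range(1, A + 1), 2))) for l in loci}
        drones = [{l: int(rng.choice(range(1, A + 1))) for l in loci}
                  for _ in range(k_true)]
        dips = []
        for _ in range(int(rng.integers(1, 8))):
            j = int(rng.integers(k_true))
            c = {l: tuple(sorted((queen[l][rng.integers(2)], drones[j][l])))
                 for l in loci}
            c = {l: p for l, p in c.items() if rng.random() > 0.1}
            if c:
                dips.append(c)
        haps = [{l: int(queen[l][rng.integers(2)]) for l in loci}
                for _ in range(int(rng.integers(0, 3)))]
        if not dips:
            continue
        produced += 1
        yield dips, haps, ("constrain", "pin")[produced % 2]
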