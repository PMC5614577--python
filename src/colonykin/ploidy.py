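"""Ploidy calling from marker zygosity.

In haplodiploid insects, males normally develop from unfertilised eggs and
are haploid; a haploid amplifies a single allele at every marker and is
scored homozygous everywhere. The calling rule is therefore: any
heterozygous marker makes the sample diploid; homozygosity across all
called markers is taken as haploidy. The rule can misclassify a genuinely
all-homozygous diploid as haploid; under Hardy-Weinberg within each locus
and independence between loci, that "diploid mimic" probability is
``prod_l sum_a p_a(l)^2`` over the called loci, which this module computes
from an allele-frequency table so the rule's reliability is quantifiable.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .io import AlleleFrequencyTable, Individual, MultilocusGenotype

__all__ = ["PloidyCall", "call_ploidy", "call_ploidy_table",
           "haploid_mimic_probability"]


@dataclass
class PloidyCall:
    """Verdict for one individual.

    verdict is ``"diploid"`` iff at least one called locus is heterozygous,
    ``"haploid"`` iff >= 1 locus is called and none is heterozygous, and
    ``"unknown"`` iff no locus is called. ``mimic_probability`` is the
    probability that a random diploid would be homozygous at all of this
    individual's called loci (None when no frequency table was supplied).
    """

    id: str
    n_called_loci: int
    n_het_loci: int
    verdict: str
    mimic_probability: float | None = None


def haploid_mimic_probability(freqs: AlleleFrequencyTable,
                              loci: Sequence[str]) -> float:
    """Probability a random diploid is homozygous at every listed locus.

    Assumes Hardy-Weinberg proportions within each locus and independence
    across loci: ``prod_l sum_a p_a^2``. A monomorphic locus contributes a
    factor of 1. Non-increasing as loci are added.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("empty locus list")
    prob = 1.0
    for locus in loci:
        if locus not in freqs.frequencies:
            raise KeyError(f"locus {locus!r} not in frequency table")
        prob *= sum(p * p for p in freqs.frequencies[locus].values())
    return prob


def call_ploidy(genotype: MultilocusGenotype, id: str = "",
                freqs: AlleleFrequencyTable | None = None) -> PloidyCall:
    """Call ploidy from zygosity across the called loci.

    MISSING loci are ignored; an all-MISSING genotype yields ``"unknown"``.
    When ``freqs`` is given, the diploid-mimic probability over the called
    loci present in the table is attached.
    """
    called = genotype.called_loci
    n_het = sum(1 for l in called if genotype.is_heterozygous(l))
    if not called:
        verdict = "unknown"
    elif n_het >= 1:
        verdict = "diploid"
    else:
        verdict = "haploid"
    mimic = None
    if freqs is not None and called:
        usable = [l for l in called if l in freqs.frequencies]
        if usable:
            mimic = haploid_mimic_probability(freqs, usable)
    return PloidyCall(id=id, n_called_loci=len(called), n_het_loci=n_het,
                      verdict=verdict, mimic_probability=mimic)


def call_ploidy_table(individuals: Iterable[Individual],
                      freqs: AlleleFrequencyTable | None = None,
                      ) -> dict[str, PloidyCall]:
    """Call ploidy for every individual; returns a mapping id -> call."""
    return {ind.id: call_ploidy(ind.genotype, id=ind.id, freqs=freqs)
            for ind in individuals}
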