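"""Per-locus diversity statistics and the paired allele-frequency test.

Gene diversity is Nei's unbiased expected heterozygosity with sample size
``n`` in gene copies, ``H = n/(n-1) * (1 - sum_a (n_a/n)^2)`` — the
statistic FSTAT reports. Allelic richness is rarefaction to a standard
subsample of ``g`` gene copies,
``A_g = sum_a [1 - C(n - n_a, g) / C(n, g)]``,
the expected number of distinct alleles among ``g`` copies drawn without
replacement. With ``g = n`` it equals the observed allele count; for a
monomorphic locus it is 1 for any valid ``g``.

The paired comparison takes every allele observed in a target sample,
pairs its frequency in two reference populations (0 when absent), and runs
a two-tailed paired t-test on the differences — the desk-scale version of
asking which reference population shares the target's alleles at higher
frequency.
"""

from __future__ import annotations

import math
from collections import namedtuple
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlleleFrequencyTable

__all__ = ["gene_diversity", "allelic_richness", "summarize_diversity",
           "paired_allele_frequency_test", "DiversitySummary",
           "PairedFreqTest"]


def gene_diversity(counts: Mapping[int, int]) -> float:
    """Nei's unbiased gene diversity from allele copy counts at one locus.

    Returns NaN when fewer than two gene copies were scored (undefined).
    0 iff the locus is monomorphic; invariant under allele relabelling.
    """
    n = sum(counts.values())
    if n < 2:
        return math.nan
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - sum_p2)


def allelic_richness(counts: Mapping[int, int], g: int) -> float:
    """Rarefaction allelic richness at subsample size ``g`` gene copies."""
    n = sum(c for c in counts.values() if c > 0)
    if not 1 <= g <= n:
        raise ValueError(f"rarefaction size g={g} outside [1, n={n}]")
    denom = math.comb(n, g)
    return sum(1.0 - math.comb(n - c, g) / denom
               for c in counts.values() if c > 0)


PairedFreqTest = namedtuple("PairedFreqTest", ["statistic", "pvalue", "n_pairs"])


def paired_allele_frequency_test(target: AlleleFrequencyTable,
                                 ref_a: AlleleFrequencyTable,
                                 ref_b: AlleleFrequencyTable,
                                 loci: Iterable[str] | None = None,
                                 ) -> PairedFreqTest:
    """Two-tailed paired t-test of target-allele frequencies in two references.

    For every allele present in the target (at loci scorable in both
    references), its frequency in ``ref_a`` is paired with its frequency in
    ``ref_b``; alleles a reference lacks take frequency 0. A positive
    statistic means the target's alleles are at higher frequency in
    ``ref_a``.
    """
    use = set(loci) if loci is not None else None
    fa, fb = [], []
    for locus, freqs in target.frequencies.items():
        if use is not None and locus not in use:
            continue
        if locus not in ref_a.frequencies or locus not in ref_b.frequencies:
            continue
        for allele, p in freqs.items():
            if p <= 0:
                continue
            fa.append(ref_a.frequency(locus, allele))
            fb.append(ref_b.frequency(locus, allele))
    if len(fa) < 2:
        raise ValueError("fewer than 2 allele pairs available for the test")
    if np.allclose(fa, fb):
        return PairedFreqTest(0.0, 1.0, len(fa))
    res = stats.ttest_rel(fa, fb)
    return PairedFreqTest(float(res.statistic), float(res.pvalue), len(fa))


@dataclass
class DiversitySummary:
    """Per-locus N alleles / gene diversity / allelic richness by population.

    ``per_locus`` has loci as rows and a (population, statistic) column
    MultiIndex; ``averages`` holds the unweighted arithmetic means over
    loci with defined values. ``g`` is the rarefaction size used;
    ``flagged_loci`` are loci absent from at least one population (left out
    of the shared-g computation).
    """

    per_locus: pd.DataFrame
    averages: pd.Series
    g: int
    flagged_loci: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        out = self.per_locus.copy()
        out.loc["Average"] = self.averages
        return out


def summarize_diversity(tables: Sequence[AlleleFrequencyTable],
                        g: int | str = "auto",
                        loci: Iterable[str] | None = None) -> DiversitySummary:
    """Table-style diversity summary for one or more populations.

    ``g="auto"`` uses the smallest per-locus gene-copy count across all
    populations (over loci present everywhere), the rarefaction convention
    that makes richness comparable across columns. Loci missing from some
    population are flagged and get NaN entries there.
    """
    if not tables:
        raise ValueError("at least one population required")
    if loci is None:
        seen: list[str] = []
        for t in tables:
            for l in t.loci:
                if l not in seen:
                    seen.append(l)
        loci = seen
    else:
        loci = list(loci)
    shared = [l for l in loci if all(l in t.frequencies for t in tables)]
    flagged = tuple(l for l in loci if l not in shared)
    if g == "auto":
        ns = [t.n[l] for t in tables for l in shared]
        if not ns:
            raise ValueError("no locus shared by all populations")
        g_used = min(ns)
    else:
        g_used = int(g)

    cols = pd.MultiIndex.from_product(
        [[t.population for t in tables],
         ["n_alleles", "gene_diversity", "allelic_richness"]],
        names=["population", "statistic"])
    rows = []
    for l in loci:
        row = []
        for t in tables:
            if l not in t.frequencies:
                row += [math.nan] * 3
                continue
            counts = t.counts(l)
            n = sum(counts.values())
            ar = allelic_richness(counts, g_used) if g_used <= n else math.nan
            row += [float(len([c for c in counts.values() if c > 0])),
                    gene_diversity(counts), ar]
        rows.append(row)
    per_locus = pd.DataFrame(rows, index=pd.Index(loci, name="locus"),
                             columns=cols)
    averages = per_locus.mean(axis=0, skipna=True)
    return DiversitySummary(per_locus=per_locus, averages=averages,
                            g=g_used, flagged_loci=flagged)
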