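"""Likelihood-based assignment of individuals to reference populations.

Each individual's multilocus genotype is scored against per-population
allele-frequency tables: under Hardy-Weinberg proportions a diploid
genotype has per-locus likelihood ``2 p_a p_b`` (heterozygote) or
``p_a^2`` (homozygote); a haploid contributes ``p_a``. Log-likelihoods sum
over called, usable loci; the individual is assigned to the reference with
the highest total. Alleles a reference has never seen take a small floor
frequency (default ``1/(2n+1)`` for that locus, a leave-one-out-style
correction) so a single private allele penalises but does not veto.

This is a self-classification assignment, not an admixture clustering: it
corroborates, at desk scale, the same question a model-based clustering of
reference plus target genotypes answers.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

from .io import AlleleFrequencyTable, Individual
from .ploidy import PloidyCall, call_ploidy

__all__ = ["AssignmentResult", "CohortAssignment", "assign", "cohort_assign"]


@dataclass
class AssignmentResult:
    """Per-individual assignment outcome.

    ``margin`` is the log-likelihood gap between the best and second-best
    reference (>= 0); ties are broken toward the reference listed first.
    """

    id: str
    log_likelihoods: dict
    best: str
    margin: float
    n_loci_used: int


def _locus_floor(ref: AlleleFrequencyTable, locus: str,
                 epsilon: float | None) -> float:
    if epsilon is not None:
        return epsilon
    return 1.0 / (2 * ref.n[locus] + 1)


def assign(individual: Individual, refs: Sequence[AlleleFrequencyTable],
           epsilon: float | None = None, loci: Iterable[str] | None = None,
           ploidy: PloidyCall | None = None) -> AssignmentResult:
    """Assign one individual to the best-supported reference population.

    ``loci`` restricts scoring (e.g. to the usable panel); only loci called
    in the individual and present in every reference are used. Raises when
    no usable locus remains.
    """
    if len(refs) < 2:
        raise ValueError("at least two reference populations required")
    if ploidy is None:
        ploidy = call_ploidy(individual.genotype, id=individual.id)
    haploid = ploidy.verdict == "haploid"
    use = set(loci) if loci is not None else None
    scored = [l for l in individual.genotype.called_loci
              if (use is None or l in use)
              and all(l in r.frequencies for r in refs)]
    if not scored:
        raise ValueError(
            f"individual {individual.id!r} has no called usable locus "
            "shared with all references")
    lls: dict[str, float] = {}
    for ref in refs:
        ll = 0.0
        for l in scored:
            a, b = individual.genotype.alleles(l)
            floor = _locus_floor(ref, l, epsilon)
            pa = ref.frequency(l, a) or floor
            if haploid:
                ll += math.log(pa)
            elif a == b:
                ll += 2 * math.log(pa)
            else:
                pb = ref.frequency(l, b) or floor
                ll += math.log(2 * pa * pb)
        lls[ref.population] = ll
    ordered = sorted(lls.items(), key=lambda kv: -kv[1])
    # stable tie-break: first-listed reference wins
    best_ll = ordered[0][1]
    best = next(r.population for r in refs if lls[r.population] == best_ll)
    second = max((v for k, v in lls.items() if k != best), default=best_ll)
    return AssignmentResult(id=individual.id, log_likelihoods=lls, best=best,
                            margin=best_ll - second, n_loci_used=len(scored))


@dataclass
class CohortAssignment:
    """Assignment table for a cohort plus per-population summary counts."""

    table: pd.DataFrame
    counts: pd.Series


def cohort_assign(individuals: Sequence[Individual],
                  refs: Sequence[AlleleFrequencyTable],
                  epsilon: float | None = None,
                  loci: Iterable[str] | None = None) -> CohortAssignment:
    """Assign every individual; failures become flagged rows, not aborts."""
    rows = []
    for ind in individuals:
        try:
            r = assign(ind, refs, epsilon=epsilon, loci=loci)
            row = {"id": r.id, "best": r.best, "margin": r.margin,
                   "n_loci_used": r.n_loci_used, "error": ""}
            row.update({f"loglik_{k}": v for k, v in r.log_likelihoods.items()})
        except ValueError as exc:
            row = {"id": ind.id, "best": "", "margin": math.nan,
                   "n_loci_used": 0, "error": str(exc)}
        rows.append(row)
    table = pd.DataFrame(rows)
    if rows:
        assigned = table[table["best"] != ""]
        counts = assigned["best"].value_counts()
    else:
        table = pd.DataFrame(columns=["id", "best", "margin", "n_loci_used",
                                      "error"])
        counts = pd.Series(dtype=int)
    return CohortAssignment(table=table, counts=counts)
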