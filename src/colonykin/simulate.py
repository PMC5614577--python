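"""Synthetic monogynous haplodiploid colonies with a CSD locus.

The generator emulates the genetic structure of a single founded nest: one
diploid queen mated with ``k`` haploid drones, diploid offspring drawing
one maternal allele and the allele of a uniformly chosen patriline drone
per marker locus, and haploid eggs drawing one maternal allele. Sex
follows single-locus complementary sex determination (CSD), unlinked to
the marker panel: haploids are male; diploids homozygous at the CSD locus
develop as diploid males, all other diploids as females. With
``force_matched_mating`` one drone carries a queen CSD allele, so half of
that patriline's diploid offspring are expected to be diploid males — the
inbreeding signature of a founder population.

The only genotyping error simulated is allele dropout: with probability
``dropout_rate`` per heterozygous locus, a diploid is recorded homozygous
for one of its two alleles (fair choice). Life-stage labels are metadata
only. Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (AlleleFrequencyTable, Individual, MultilocusGenotype,
                 USABLE_PANEL, write_genotype_table)

__all__ = ["SimConfig", "OffspringTruth", "ColonyTruth", "simulate_population",
           "sample_genotype", "simulate_colony", "observe_with_dropout",
           "make_fixture_nest"]

_DEFAULT_LOCI = tuple(l.name for l in USABLE_PANEL)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated colony.

    Defaults mirror the incursion setting: a 13-marker panel with a few
    alleles per locus drawn from a flat Dirichlet (the invasive source
    population is allele-poor), a singly mated queen, 50 diploid workers
    and 20 haploid eggs, and a ~2% allele-dropout rate, the order reported
    from repeat genotyping in such surveys.
    """

    n_loci: int = 13
    alleles_per_locus: int | tuple = 4
    dirichlet_alpha: float = 1.0
    k_drones: int = 1
    n_workers: int = 50
    n_diploid_offspring_extra: int = 0
    n_haploid_eggs: int = 20
    csd_alleles: int = 10
    force_matched_mating: bool = False
    dropout_rate: float = 0.02
    seed: int = 0
    locus_names: tuple = ()
    population: str = "source"
    n_reference_copies: int = 200

    def __post_init__(self):
        if self.k_drones < 1:
            raise ValueError("k_drones must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.csd_alleles < 2:
            raise ValueError("csd_alleles must be >= 2")
        if min(self.n_workers, self.n_diploid_offspring_extra,
               self.n_haploid_eggs) < 0:
            raise ValueError("offspring counts must be >= 0")
        if not self.locus_names:
            if self.n_loci <= len(_DEFAULT_LOCI):
                names = _DEFAULT_LOCI[: self.n_loci]
            else:
                names = tuple(f"L{i + 1:02d}" for i in range(self.n_loci))
            object.__setattr__(self, "locus_names", names)
        if len(self.locus_names) != self.n_loci:
            raise ValueError("locus_names length must equal n_loci")

    def alleles_at(self, i: int) -> int:
        if isinstance(self.alleles_per_locus, int):
            return self.alleles_per_locus
        return int(self.alleles_per_locus[i])


@dataclass
class OffspringTruth:
    ploidy: int
    patriline: int | None  # drone index for diploids, None for haploids
    csd: tuple
    sex: str  # "female", "male" (haploid) or "diploid_male"
    genotype: dict  # locus -> true allele pair


@dataclass
class ColonyTruth:
    """Ground truth of a simulated colony, for recovery tests.

    Invariants (exact when dropout_rate = 0): every diploid offspring
    carries one queen allele plus its patriline drone's allele at every
    locus; every haploid offspring allele is a queen allele.
    """

    queen_genotype: dict
    queen_csd: tuple
    drone_haplotypes: list
    drone_csd: list
    offspring: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _ser(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.integer):
                return int(o)
            raise TypeError(o)

        return json.dumps(dataclasses.asdict(self), default=_ser, indent=1)


def _allele_ladder(i: int, n_alleles: int) -> list[int]:
    # dinucleotide-repeat-like fragment sizes, distinct base per locus
    base = 100 + 12 * i
    return [base + 2 * j for j in range(n_alleles)]


def simulate_population(config: SimConfig) -> AlleleFrequencyTable:
    """Per-locus allele frequencies from a symmetric Dirichlet draw."""
    rng = np.random.default_rng((config.seed, 0))
    freqs: dict[str, dict[int, float]] = {}
    ns: dict[str, int] = {}
    for i, name in enumerate(config.locus_names):
        k = config.alleles_at(i)
        ladder = _allele_ladder(i, k)
        if k == 1:
            p = np.array([1.0])
        else:
            p = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        freqs[name] = {a: float(x) for a, x in zip(ladder, p)}
        ns[name] = config.n_reference_copies
    return AlleleFrequencyTable(config.population, freqs, ns)


def _draw_allele(freqs: dict, rng) -> int:
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles])
    return int(alleles[rng.choice(len(alleles), p=p / p.sum())])


def sample_genotype(pop: AlleleFrequencyTable, rng,
                    ploidy: int = 2) -> MultilocusGenotype:
    """Random Hardy-Weinberg genotype from a population's frequencies."""
    calls = {}
    for locus, freqs in pop.frequencies.items():
        if ploidy == 1:
            a = _draw_allele(freqs, rng)
            calls[locus] = (a, a)
        else:
            calls[locus] = (_draw_allele(freqs, rng), _draw_allele(freqs, rng))
    return MultilocusGenotype(calls)


def observe_with_dropout(true_calls: dict, dropout_rate: float,
                         rng) -> MultilocusGenotype:
    """Record a diploid genotype with per-heterozygous-locus allele dropout."""
    observed = {}
    for locus, (a, b) in true_calls.items():
        if a != b and dropout_rate > 0 and rng.random() < dropout_rate:
            kept = a if rng.random() < 0.5 else b
            observed[locus] = (kept, kept)
        else:
            observed[locus] = (a, b)
    return MultilocusGenotype(observed)


def simulate_colony(pop: AlleleFrequencyTable, config: SimConfig,
                    rng=None) -> tuple[list[Individual], ColonyTruth]:
    """Simulate one monogynous colony from population frequencies.

    Returns the observed offspring (workers, any extra diploids, haploid
    eggs — with dropout applied to diploid records) and the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 1))
    loci = list(config.locus_names)

    queen = {l: tuple(sorted((_draw_allele(pop.frequencies[l], rng),
                              _draw_allele(pop.frequencies[l], rng))))
             for l in loci}
    csd_pool = list(range(1, config.csd_alleles + 1))
    queen_csd = tuple(int(a) for a in
                      sorted(rng.choice(csd_pool, size=2, replace=False)))
    drones = [{l: _draw_allele(pop.frequencies[l], rng) for l in loci}
              for _ in range(config.k_drones)]
    drone_csd = [int(rng.choice(csd_pool)) for _ in range(config.k_drones)]
    if config.force_matched_mating:
        drone_csd[0] = int(queen_csd[rng.integers(2)])

    truth = ColonyTruth(queen_genotype=queen, queen_csd=queen_csd,
                        drone_haplotypes=drones, drone_csd=drone_csd)
    individuals: list[Individual] = []

    def _diploid(oid: str, stage: str) -> Individual:
        j = int(rng.integers(config.k_drones))
        true_g = {l: tuple(sorted((queen[l][rng.integers(2)], drones[j][l])))
                  for l in loci}
        csd = tuple(sorted((int(queen_csd[rng.integers(2)]), drone_csd[j])))
        sex = "diploid_male" if csd[0] == csd[1] else "female"
        truth.offspring[oid] = OffspringTruth(ploidy=2, patriline=j, csd=csd,
                                              sex=sex, genotype=true_g)
        return Individual(
            id=oid,
            genotype=observe_with_dropout(true_g, config.dropout_rate, rng),
            life_stage=stage,
            morph_sex="male" if sex == "diploid_male" else "female",
            location="nest")

    for i in range(config.n_workers):
        individuals.append(_diploid(f"W{i + 1:03d}", "adult"))
    for i in range(config.n_diploid_offspring_extra):
        individuals.append(_diploid(f"X{i + 1:03d}", "pupa"))
    for i in range(config.n_haploid_eggs):
        oid = f"E{i + 1:03d}"
        true_g = {l: (a := int(queen[l][rng.integers(2)]), a) for l in loci}
        csd = (int(queen_csd[rng.integers(2)]),)
        truth.offspring[oid] = OffspringTruth(ploidy=1, patriline=None,
                                              csd=csd, sex="male",
                                              genotype=true_g)
        individuals.append(Individual(id=oid,
                                      genotype=MultilocusGenotype(true_g),
                                      life_stage="egg", morph_sex="unknown",
                                      location="nest"))
    return individuals, truth


# ---------------------------------------------------------------------------
# fixture nest


def make_fixture_nest(out_dir, seed: int = 20160916,
                      error_free: bool = True) -> dict:
    """Write a small, seeded nest dataset shaped like an incursion case.

    A single-queen, single-drone colony (~95 individuals: adult workers,
    CSD-homozygous diploid "males", haploid eggs) plus three candidate
    outsiders: a colony offspring found elsewhere (``Tetbury2``-like,
    consistent), a same-population non-offspring (``Somerset``-like,
    carrying non-parental alleles) and a further source-population
    individual (``Bath``-like, carrying alleles absent from both the nest
    and the Somerset-like sample). Construction rejects draws until those
    contracts hold, so downstream narratives are reproducible by design.

    Returns a dict of written paths: ``genotypes``, ``truth``,
    ``population``.
    """
    from .pedigree import ColonyPedigree, exclusion_test

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)

    for _attempt in range(100):
        sub = int(master.integers(2**31))
        config = SimConfig(n_loci=13, alleles_per_locus=4, dirichlet_alpha=1.0,
                           k_drones=1, n_workers=80, n_haploid_eggs=15,
                           force_matched_mating=True,
                           dropout_rate=0.0 if error_free else 0.02, seed=sub)
        pop = simulate_population(config)
        nest, truth = simulate_colony(pop, config)
        rng = np.random.default_rng((sub, 2))

        res = ColonyPedigree(nest, max_drones=3).fit()
        if not (res.unique and res.n_drones == 1):
            continue
        # every diploid must be heterozygous somewhere (ploidy rule holds)
        dips = [ind for ind in nest if truth.offspring[ind.id].ploidy == 2]
        if not all(any(ind.genotype.is_heterozygous(l)
                       for l in ind.genotype.called_loci) for ind in dips):
            continue
        if not any(truth.offspring[i.id].sex == "diploid_male" for i in dips):
            continue
        sol = res.solutions[0]

        # Tetbury2-like: a true colony offspring recovered off-site
        j = 0
        t2_calls = {l: tuple(sorted((truth.queen_genotype[l][rng.integers(2)],
                                     truth.drone_haplotypes[j][l])))
                    for l in config.locus_names}
        tetbury2 = Individual(id="Tetbury2", genotype=MultilocusGenotype(t2_calls),
                              life_stage="adult", morph_sex="female",
                              location="Tetbury2")
        if exclusion_test(tetbury2, sol).verdict != "consistent":
            continue

        somerset = None
        for _ in range(200):
            cand = Individual(id="Somerset", genotype=sample_genotype(pop, rng),
                              life_stage="adult", morph_sex="female",
                              location="Somerset")
            if exclusion_test(cand, sol).verdict == "excluded":
                somerset = cand
                break
        if somerset is None:
            continue

        bath = None
        for _ in range(200):
            cand = Individual(id="Bath", genotype=sample_genotype(pop, rng),
                              life_stage="adult", morph_sex="female",
                              location="Bath")
            if exclusion_test(cand, sol).verdict != "excluded":
                continue
            somerset_alleles = {l: set(somerset.genotype.alleles(l))
                                for l in somerset.genotype.called_loci}
            private = any(
                a not in sol.parental_alleles(l) and a not in somerset_alleles.get(l, ())
                for l in cand.genotype.called_loci
                for a in cand.genotype.alleles(l))
            if private:
                bath = cand
                break
        if bath is None:
            continue

        for ind in nest:
            ind.location = "Tetbury nest"
        everyone = nest + [tetbury2, somerset, bath]
        paths = {
            "genotypes": out_dir / "genotypes.csv",
            "truth": out_dir / "truth.json",
            "population": out_dir / "population.csv",
        }
        write_genotype_table(paths["genotypes"], everyone)
        paths["truth"].write_text(truth.to_json())
        pop.write_csv(paths["population"])
        return {k: str(v) for k, v in paths.items()}
    raise RuntimeError("could not construct an identifiable fixture nest")
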