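# Methods

## Setting and assumptions

The package models the genetics of a single monogynous haplodiploid colony
genotyped at a panel of unlinked microsatellite loci. The standing
assumptions, shared by all inference modules:

- one reproductive queen (monogyny is an input assumption, never searched
  over — a failure to fit is reported as diagnostics, not as a multi-queen
  hypothesis);
- haploid offspring arise from unfertilised eggs and carry one maternal
  allele per locus, recorded as a homozygous pair;
- each diploid offspring carries one maternal allele plus the allele of
  exactly one drone (its patriline) at every locus;
- loci are independent (no linkage modelled) and allele identity is the
  integer fragment size in base pairs — no binning or cross-laboratory
  size recalibration is attempted;
- sex follows single-locus complementary sex determination (CSD), unlinked
  to the marker panel: haploids are male, CSD-homozygous diploids develop
  as diploid males, all other diploids as females. The CSD locus is never
  genotyped; it matters only to the simulator's sex labels.

## Ploidy calling

Verdicts follow marker zygosity: `diploid` iff ≥ 1 called locus is
heterozygous, `haploid` iff ≥ 1 locus is called and none is, `unknown`
with no calls. MISSING loci are ignored, and the call records
`n_called_loci` so downstream users can demand a minimum panel. The rule's
failure mode — a true diploid homozygous everywhere — has probability
`∏_l Σ_a p_a²` under within-locus Hardy–Weinberg and between-locus
independence; `haploid_mimic_probability` evaluates it from any
allele-frequency table and `call_ploidy` attaches it to each verdict when
a table is supplied. The product is non-increasing in the number of loci,
which is the quantitative argument for large panels.

## Pedigree reconstruction

`ColonyPedigree.fit()` searches (queen genotype, drone haplotype set,
patriline assignment) configurations, drawing candidate alleles from those
observed at each locus, and returns **all** configurations achieving the
smallest viable mate number `k ≤ max_drones`.

Search organisation:

1. **Queen candidates per locus.** Pairs of observed alleles filtered by
   the haploid mode and by the requirement that every diploid offspring
   share ≥ 1 allele with the queen (a necessary condition for any
   decomposition).
2. **Paternal patterns.** For a fixed queen genotype, each diploid
   offspring reduces to a per-locus set of possible paternal alleles
   (both alleles where the pair lies inside the queen's, the non-maternal
   allele otherwise, a wildcard where MISSING). Offspring with identical
   patterns are deduplicated.
3. **Minimal cover.** Drone sets correspond to partitions of patterns into
   blocks whose per-locus intersections are non-empty; each block's
   haplotypes are the cross product of its intersections. With ≤ 12
   distinct patterns the partition space is enumerated exactly for
   k = 1, 2, … (exhaustive and provably minimal; verified against an
   independent brute-force enumerator in the tests). Above 12 patterns a
   deterministic first-fit cover gives an upper bound on k, and solutions
   carry `exact=False`.

Haploid eggs inform the queen through three selectable modes. `pin`
(default) equates the queen's allele set at a locus with the alleles
observed in eggs there — two distinct egg alleles fix the pair, a single
egg allele implies a homozygous queen. `constrain` only requires egg
alleles to be carried by the queen; `ignore` drops eggs from the
inference. Pinning is the default because without it a queen-homozygous
locus is intrinsically ambiguous — queen (a,a) × drone d produces the same
diploid offspring as queen (a,d) × drone a or d — so a unique
reconstruction is essentially unattainable on a 13-locus panel, whereas a
handful of eggs resolves it (with 20 eggs, a heterozygous queen's second
allele is missed with probability ~2·0.5²⁰ per locus). The non-default
modes exist because field collections do not always include eggs.

**Genotyping error.** Allele dropout (a heterozygote recorded as a
homozygote for one of its alleles) is the tolerated error mode. With
`max_mismatch_loci = m > 0`, loci recorded homozygous may be read as
dropped heterozygotes: a recorded (a,a) with a in the queen's pair leaves
the paternal allele free; with a outside it, the paternal allele must be a
(the recorded allele is necessarily one of the true two, so these relaxed
constraints never distort the solution structure). Each patriline's
haplotype is then chosen per locus to minimise total relaxation use
(ties to the smallest allele), and any offspring needing more than `m`
relaxed loci under that choice is flagged `"unexplained"` in the
assignment rather than failing the fit — under sparse dropout an
occasional multi-dropout offspring is expected and should not veto an
otherwise unanimous pedigree. Strict mode (`m = 0`, the default) keeps the
exact all-solutions enumeration.

**Exclusion.** A candidate is tested twice against a fitted solution:
(1) the allele-set check — every candidate allele at every called locus
must appear among queen ∪ drone alleles; (2) the patriline check — a
diploid candidate must decompose as maternal + one single drone's allele
under at least one patriline (a haploid candidate must carry only queen
alleles). The two outcomes are reported separately because "carries only
parental alleles" and "is a plausible offspring" differ in multi-drone
nests; the verdict is `excluded` iff any violation is recorded.

**Mate counting.** `count_patrilines` answers the same cover question for
a fixed queen: exact for ≤ 12 distinct patterns, first-fit bound above,
with MISSING compatible with any drone and queen-incompatible offspring
reported as unassignable.

## Diversity statistics

Gene diversity uses Nei's unbiased estimator `n/(n−1)(1 − Σ (n_a/n)²)`
with `n` in gene copies (undefined below 2 copies, reported as NaN).
Allelic richness is hypergeometric rarefaction,
`A_g = Σ_a [1 − C(n−n_a, g)/C(n, g)]`, exact via integer binomials.
`summarize_diversity` computes both plus allele counts per locus and
population; `g = "auto"` takes the minimum per-locus copy count across
populations over shared loci, loci absent somewhere are flagged and
excluded from that minimum, and averages are unweighted arithmetic means
over loci with defined values. Whether haploids contribute one copy
(default, unbiased for allele frequencies), two, or are excluded is a
switch on `allele_frequencies`, because published tables are not always
explicit about the convention and the three choices give visibly different
`n`.

The paired comparison takes every allele observed in a target sample,
pairs its frequency in two reference populations (0 where absent), and
applies a two-tailed paired t-test (scipy) to the differences — a compact
test of which reference shares the target's alleles at higher frequency.

## Population assignment

Per-locus genotype likelihoods under Hardy–Weinberg — `2 p_a p_b`
heterozygote, `p_a²` homozygote, `p_a` haploid — summed in log over the
called loci present in every reference. Alleles a reference lacks take the
floor `ε = 1/(2n_l + 1)` (per locus; configurable), a leave-one-out-style
correction that penalises private alleles without vetoing on a single
observation. Ties break toward the first-listed reference,
deterministically. This is self-classification against fixed reference
frequencies, not admixture estimation: no mixture proportions, no joint
clustering, no MCMC. It answers "which reference explains this genotype
better, and by how many log units" — the margin is the evidence scale.

## Simulator

`simulate_population` draws per-locus allele frequencies from a symmetric
Dirichlet over dinucleotide-style allele ladders (distinct size ranges per
locus). `simulate_colony` draws a diploid queen (two distinct CSD
alleles), k drone haplotypes, then offspring by Mendelian sampling;
`force_matched_mating` sets one drone's CSD allele to a queen allele so
half of that patriline's diploids are expected CSD-homozygous males.
Dropout is applied per heterozygous locus of each diploid record with
probability `e` (fair choice of surviving allele); it is the only error
mode simulated — false alleles, null alleles and size miscalls are out of
scope. Everything is deterministic under the config seed.

Defaults are the study conditions the package is built around: 13 usable
loci named after the bundled marker panel, 4 alleles per locus at
Dirichlet α = 1 (an allele-poor invasive source), a singly mated queen, 50
diploid workers and 20 haploid eggs, CSD pool of 10 alleles, and 2%
dropout (repeat-genotyping error in such surveys is reported below 3%).
Recovery checks that stipulate error-free genotyping pass
`dropout_rate=0` explicitly.

`make_fixture_nest` writes a ~98-individual incursion-style dataset: an
identifiable single-drone colony with matched mating (so diploid males
occur), plus three candidates — a true colony offspring located off-site,
a same-population non-offspring carrying non-parental alleles, and a
second outsider additionally carrying alleles absent from both the nest
and the first outsider. Construction is by seeded rejection sampling until
those contracts hold, so the downstream narrative (consistent / excluded /
excluded) is a property of the fixture, not of luck; the fixture is
byte-identical across runs at a given seed.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: amplification artefacts other than dropout,
linkage or family structure in the source population, allele-size
homoplasy between laboratories, stage-dependent sampling biases, and
multi-queen or queen-turnover colonies. Stage labels (egg/larva/pupa/
teneral/adult) are metadata only.

## Numerical and design choices

- Determinism throughout: numpy `default_rng` seeded from explicit config
  fields; solutions ordered lexicographically by (queen genotype, drone
  haplotypes); partition enumeration in restricted-growth order; CLI and
  pipeline runs are byte-reproducible at fixed seed.
- Caps: queen-configuration cross products above 20,000 and solution sets
  above 2,000 are truncated deterministically and reported
  (`complete`/`exact` flags) rather than silently dropped.
- The exact-cover threshold of 12 distinct paternal patterns keeps the
  partition enumeration trivially fast (Stirling numbers up to ~4×10⁶
  states at k ≤ 5) while covering every instance the exactness tests
  exercise; beyond it the first-fit bound is reported as such.
- Problem sizes in the checks — 200 error-free colonies for recovery, 100
  noisy colonies, 10,000 draws for the ploidy and CSD calibrations,
  100,000 Monte-Carlo subsamples for rarefaction, an 80-instance oracle
  grid — keep the full suite and the acceptance script within seconds on
  one CPU while leaving binomial noise well inside the asserted bounds.
- Monte-Carlo agreement checks aggregate per-instance z-scores as a
  chi-square at the 3σ tail instead of vetoing on each instance
  separately, which holds the overall stringency while making the check
  robust to a single unlucky tail draw.

## Limitations

- Monogyny and a closed offspring set are assumptions; violations surface
  only as fit failures with locus-level diagnostics.
- Above 12 distinct paternal patterns the mate number is a deterministic
  upper bound, not a proven minimum (in practice the bound is tight in
  essentially all simulated colonies).
- The relaxed-error mode's per-block haplotype choice is a deterministic
  heuristic; exact all-solutions enumeration holds only at
  `max_mismatch_loci = 0`.
- Assignment requires externally supplied reference frequency tables and
  inherits their sampling error; it is not a substitute for model-based
  clustering when admixture or unsampled source populations are in play.
- F-statistics, Hardy–Weinberg exact tests and linkage disequilibrium are
  deliberately out of scope: a sample dominated by one nest's siblings
  violates their sampling assumptions.
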