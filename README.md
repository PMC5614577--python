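# colonykin

Colony genetics for haplodiploid nest forensics: given multilocus
microsatellite genotypes sampled from a single social-insect nest (hornets,
wasps, bees, ants), `colonykin` answers the questions an invasive-species
surveillance lab asks when a nest turns up where it should not be:

- **Who is haploid?** In haplodiploids, males normally develop from
  unfertilised eggs and carry one allele per locus; any heterozygous marker
  proves diploidy, homozygosity across the panel indicates haploidy.
- **Who founded the nest?** Reconstruct the queen's genotype and the set of
  drone haplotypes from her offspring, and the minimal number of mates
  consistent with the data.
- **Do stray individuals belong to this nest?** Allele-based exclusion of
  candidates found elsewhere — nestmate, same-population outsider, or
  carrier of alleles the nest has never seen.
- **Where did the founders come from?** Per-locus diversity statistics
  (allele counts, gene diversity, rarefaction allelic richness), a paired
  allele-frequency comparison against reference populations, and a
  likelihood-based population assignment.

A built-in simulator produces monogynous colonies with a complementary
sex-determination (CSD) locus and allele-dropout genotyping error, so the
whole chain is testable without any external data.

## The models

**Ploidy rule and its calibration.** A sample is called diploid iff it is
heterozygous at ≥ 1 called locus. The rule fails when a true diploid is
homozygous everywhere; under Hardy–Weinberg proportions and independent
loci that *mimic probability* is

    P(mimic) = ∏_l Σ_a p_{l,a}²

computed from an allele-frequency table so the verdict's reliability is a
number, not a hope.

**Pedigree model.** The nest is assumed monogynous. A haploid offspring
carries one maternal allele per locus; a diploid offspring carries one
maternal allele plus the allele of the single drone that sired it (its
patriline), consistently across loci. `ColonyPedigree(...).fit()`
enumerates, for the smallest viable mate number *k*, every
(queen genotype, drone haplotype set) configuration explaining all
offspring, flags loci where several configurations survive, and reports
diagnostics when nothing fits (a sign of misgrouped individuals or excess
genotyping error). Allele dropout — a heterozygote scored as a homozygote,
the dominant microsatellite error — can be tolerated per offspring via
`max_mismatch_loci`.

**Diversity.** Nei's unbiased gene diversity
`H = n/(n−1) · (1 − Σ p_a²)` and rarefaction allelic richness
`A_g = Σ_a [1 − C(n−n_a, g)/C(n, g)]`, with `g` defaulting to the smallest
per-locus copy count across populations so columns are comparable.

**Assignment.** Per-locus genotype likelihoods under Hardy–Weinberg
(`2 p_a p_b`, `p_a²`, or `p_a` for haploids) summed in log over loci, per
reference population; unseen alleles take a floor of `1/(2n+1)`. This is a
deliberate, documented simplification: model-based admixture clustering of
the combined reference-plus-target genotypes is the standard evidence for
provenance, and this self-classification likelihood corroborates — it does
not replicate — that analysis.

## Worked example

```
colonykin fixture --out-dir demo            # seeded incursion-style nest
colonykin run --config run.yaml             # run.yaml: genotypes/out_dir
```

or in Python:

```python
from colonykin import RunConfig, run_report
run_report(RunConfig(genotypes="demo/genotypes.csv", out_dir="demo/report"))
```

which prints (and writes to `demo/report/summary.txt`):

```
colonykin nest analysis
=======================
Individuals genotyped: 98 (95 at 'Tetbury nest', 3 candidates)
Ploidy: 83 diploid, 15 haploid
Pedigree: 1 queen x 1 drone(s), unique solution
Haploid individuals: E001, E002, ..., E015
Candidate Tetbury2: consistent
Candidate Somerset: excluded
Candidate Bath: excluded
Mean gene diversity (nest sample): 0.437; mean alleles/locus: 2.85 (g = 181)
```

Reading: all 15 all-homozygous individuals are eggs (true haploid males had
not yet emerged as adults); the 83 diploids — including any anatomical
males, which are CSD-homozygous diploids — resolve uniquely to one queen
mated with a single drone; the off-site `Tetbury2` candidate decomposes as
a nest offspring while `Somerset` and `Bath` carry alleles the nest's
parents do not have. Per-stage tables (`ploidy.csv`, `pedigree.json`,
`exclusions.csv`, `diversity.csv`, optional `assignment.csv`) sit next to
the summary in both CSV and JSON.

Real data drop in the same way: a plain CSV with columns
`id,life_stage,morph_sex,location` plus `<locus>_1,<locus>_2` per marker
(blank or `0` = missing), or a supplementary-style spreadsheet via
`read_s1_table` (id / life stage / sex columns followed by two columns per
marker). The bundled 15-marker hornet panel marks the two loci that do not
score repeatably across laboratories as unusable for reference
comparisons; `panel: "13"` restricts any analysis to the clean set.

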