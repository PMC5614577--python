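"""Genotype tables, allele-frequency tables and genotyping-error estimation.

The unit of data is a multilocus microsatellite genotype: for each marker
locus, an ordered pair of allele fragment sizes in base pairs, or MISSING.
Haploid individuals (males developed from unfertilised eggs) amplify a
single allele and are scored as homozygous pairs ``(a, a)``; whether they
contribute one or two gene copies to frequency tables is therefore an
explicit choice (``haploid_mode``).

File dialect: plain CSV with columns ``id, life_stage, morph_sex, location``
followed by two columns per locus named ``<locus>_1`` and ``<locus>_2``.
Empty cells and ``0`` encode missing data, the usual microsatellite
convention. A shim (:func:`read_s1_table`) maps spreadsheet supplements
laid out as id / life stage / sex columns followed by paired marker columns
onto this dialect.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "MISSING",
    "Locus",
    "MultilocusGenotype",
    "Individual",
    "AlleleFrequencyTable",
    "ErrorRateEstimate",
    "DEFAULT_PANEL",
    "USABLE_PANEL",
    "read_genotype_table",
    "write_genotype_table",
    "read_s1_table",
    "allele_frequencies",
    "estimate_error_rate",
]

#: Sentinel for a locus with no genotype call.
MISSING = None

LIFE_STAGES = ("adult", "teneral", "pupa", "pre-pupa", "larva", "egg", "unknown")
MORPH_SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    Parameters
    ----------
    name : str
        Marker label, unique within a panel.
    multiplex_group : int
        PCR multiplex reaction the marker was amplified in (>= 1).
    usable : bool
        False for markers dropped from cross-laboratory comparisons
        because they did not score repeatably.
    """

    name: str
    multiplex_group: int = 1
    usable: bool = True

    def __post_init__(self) -> None:
        if self.multiplex_group < 1:
            raise ValueError("multiplex_group must be >= 1")


#: The 15-marker hornet panel with its multiplex layout; the last two
#: markers did not produce repeatable results across laboratories and are
#: excluded from reference comparisons (``usable=False``).
DEFAULT_PANEL: tuple[Locus, ...] = (
    Locus("LIST2020B", 1),
    Locus("R1-36", 1),
    Locus("R1-80", 2),
    Locus("R4-33", 2),
    Locus("D2-185", 3),
    Locus("R4-114", 3),
    Locus("R1-169", 3),
    Locus("VMA6", 4),
    Locus("LIST2018B", 4),
    Locus("D3-15", 4),
    Locus("LIST2015", 5),
    Locus("R4-26", 5),
    Locus("R1-75", 6),
    Locus("R4-100", 6, usable=False),
    Locus("VMA8", 6, usable=False),
)

#: The 13 markers retained for cross-dataset work.
USABLE_PANEL: tuple[Locus, ...] = tuple(l for l in DEFAULT_PANEL if l.usable)


def _canonical_pair(locus: str, pair) -> tuple[int, int] | None:
    if pair is MISSING:
        return MISSING
    a, b = pair
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValueError(f"allele sizes must be positive at locus {locus}: {pair}")
    return (a, b) if a <= b else (b, a)


class MultilocusGenotype:
    """Mapping locus name -> sorted allele pair (bp) or MISSING."""

    __slots__ = ("calls",)

    def __init__(self, calls: Mapping[str, tuple[int, int] | None]):
        self.calls: dict[str, tuple[int, int] | None] = {
            locus: _canonical_pair(locus, pair) for locus, pair in calls.items()
        }

    def alleles(self, locus: str) -> tuple[int, int] | None:
        return self.calls.get(locus, MISSING)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    @property
    def called_loci(self) -> tuple[str, ...]:
        return tuple(l for l, p in self.calls.items() if p is not MISSING)

    def is_heterozygous(self, locus: str) -> bool | None:
        """True/False for a called locus, None when MISSING."""
        pair = self.calls.get(locus, MISSING)
        if pair is MISSING:
            return None
        return pair[0] != pair[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, MultilocusGenotype) and self.calls == other.calls

    def __repr__(self) -> str:
        called = len(self.called_loci)
        return f"MultilocusGenotype({called}/{len(self.calls)} loci called)"


@dataclass
class Individual:
    """One sampled hornet: identity, stage/sex/location metadata, genotype."""

    id: str
    genotype: MultilocusGenotype
    life_stage: str = "unknown"
    morph_sex: str = "unknown"
    location: str = ""

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life stage {self.life_stage!r}")
        if self.morph_sex not in MORPH_SEXES:
            raise ValueError(f"unknown morphological sex {self.morph_sex!r}")


# ---------------------------------------------------------------------------
# Genotype table IO


def _panel_columns(panel: Sequence[Locus]) -> list[str]:
    cols = ["id", "life_stage", "morph_sex", "location"]
    for locus in panel:
        cols += [f"{locus.name}_1", f"{locus.name}_2"]
    return cols


def _parse_cell(value: str) -> int | None:
    value = str(value).strip()
    if value in ("", "0", "NA", "na", "nan"):
        return None
    return int(float(value))


def read_genotype_table(path, panel: Sequence[Locus] = DEFAULT_PANEL) -> list[Individual]:
    """Read a CSV genotype table into a list of :class:`Individual`.

    Allele pairs are canonicalised (sorted ascending); blank or zero cells
    become MISSING. A locus must be either fully called or fully missing in
    a row; half calls raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = {l.name for l in panel}
    meta_cols = {"id", "life_stage", "morph_sex", "location"}
    allele_stems = Counter()
    for col in df.columns:
        if col in meta_cols:
            continue
        if col.endswith("_1") or col.endswith("_2"):
            stem = col[:-2]
            if stem not in names:
                raise ValueError(f"unknown locus column {col!r}")
            allele_stems[stem] += 1
        else:
            raise ValueError(f"unknown locus column {col!r}")
    for stem, n in allele_stems.items():
        if n != 2:
            raise ValueError(f"locus {stem!r} has {n} allele column(s), expected 2")
    if "id" not in df.columns:
        raise ValueError("genotype table must have an 'id' column")

    present = [l for l in panel if l.name in allele_stems]
    individuals: list[Individual] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        ind_id = str(row["id"]).strip()
        if ind_id in seen:
            raise ValueError(f"duplicate individual id {ind_id!r}")
        seen.add(ind_id)
        calls: dict[str, tuple[int, int] | None] = {}
        for locus in present:
            a = _parse_cell(row[f"{locus.name}_1"])
            b = _parse_cell(row[f"{locus.name}_2"])
            if (a is None) != (b is None):
                raise ValueError(
                    f"half-called locus {locus.name} for individual {ind_id!r}"
                )
            calls[locus.name] = MISSING if a is None else (a, b)
        individuals.append(
            Individual(
                id=ind_id,
                genotype=MultilocusGenotype(calls),
                life_stage=str(row.get("life_stage", "unknown")).strip() or "unknown",
                morph_sex=str(row.get("morph_sex", "unknown")).strip() or "unknown",
                location=str(row.get("location", "")).strip(),
            )
        )
    return individuals


def write_genotype_table(path, individuals: Sequence[Individual],
                         panel: Sequence[Locus] | None = None) -> None:
    """Write individuals to the canonical CSV dialect (inverse of the reader)."""
    if panel is None:
        loci_names: list[str] = []
        for ind in individuals:
            for l in ind.genotype.loci:
                if l not in loci_names:
                    loci_names.append(l)
        panel = tuple(Locus(name) for name in loci_names)
    rows = []
    for ind in individuals:
        row: dict[str, object] = {
            "id": ind.id,
            "life_stage": ind.life_stage,
            "morph_sex": ind.morph_sex,
            "location": ind.location,
        }
        for locus in panel:
            pair = ind.genotype.alleles(locus.name)
            row[f"{locus.name}_1"] = "" if pair is MISSING else pair[0]
            row[f"{locus.name}_2"] = "" if pair is MISSING else pair[1]
        rows.append(row)
    pd.DataFrame(rows, columns=_panel_columns(panel)).to_csv(path, index=False)


def read_s1_table(path, panel: Sequence[Locus] = DEFAULT_PANEL,
                  n_meta_columns: int = 5) -> list[Individual]:
    """Import a supplementary-style spreadsheet genotype table.

    Expected layout: sample id in the first column, life stage in the
    second, morphological sex in the third, then further metadata columns,
    with the marker data in the final ``2 x len(panel)`` columns (two
    adjacent columns per marker, in panel order). Reads ``.xlsx`` (via
    pandas/openpyxl) or CSV with the same layout.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.fillna("")
    n_marker_cols = 2 * len(panel)
    if df.shape[1] < n_meta_columns + n_marker_cols:
        raise ValueError(
            f"expected at least {n_meta_columns + n_marker_cols} columns, "
            f"got {df.shape[1]}"
        )
    marker_block = df.iloc[:, -n_marker_cols:]
    stage_map = {s: s for s in LIFE_STAGES}
    stage_map.update({"prepupa": "pre-pupa", "pre pupa": "pre-pupa",
                      "teneral adult": "teneral"})
    individuals = []
    seen: set[str] = set()
    for i in range(len(df)):
        ind_id = str(df.iloc[i, 0]).strip()
        if not ind_id:
            continue
        if ind_id in seen:
            raise ValueError(f"duplicate individual id {ind_id!r}")
        seen.add(ind_id)
        stage_raw = str(df.iloc[i, 1]).strip().lower()
        sex_raw = str(df.iloc[i, 2]).strip().lower()
        location = str(df.iloc[i, 3]).strip() if n_meta_columns > 3 else ""
        calls: dict[str, tuple[int, int] | None] = {}
        for j, locus in enumerate(panel):
            a = _parse_cell(marker_block.iloc[i, 2 * j])
            b = _parse_cell(marker_block.iloc[i, 2 * j + 1])
            if a is None and b is None:
                calls[locus.name] = MISSING
            elif a is None or b is None:
                # single-allele scoring of a haploid: duplicate the call
                allele = a if a is not None else b
                calls[locus.name] = (allele, allele)
            else:
                calls[locus.name] = (a, b)
        individuals.append(
            Individual(
                id=ind_id,
                genotype=MultilocusGenotype(calls),
                life_stage=stage_map.get(stage_raw, "unknown"),
                morph_sex=sex_raw if sex_raw in MORPH_SEXES else "unknown",
                location=location,
            )
        )
    return individuals


# ---------------------------------------------------------------------------
# Allele frequencies


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies for one population.

    ``frequencies[locus][allele]`` is the relative frequency ``p_a`` and
    ``n[locus]`` the number of gene copies counted at that locus.
    """

    population: str
    frequencies: dict[str, dict[int, float]]
    n: dict[str, int]

    @classmethod
    def from_counts(cls, population: str,
                    counts: Mapping[str, Mapping[int, int]]) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[int, float]] = {}
        ns: dict[str, int] = {}
        for locus, cts in counts.items():
            total = sum(cts.values())
            if total <= 0:
                continue  # zero called copies: locus absent, never zero-divided
            freqs[locus] = {a: c / total for a, c in sorted(cts.items()) if c > 0}
            ns[locus] = total
        return cls(population=population, frequencies=freqs, n=ns)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.frequencies)

    def frequency(self, locus: str, allele: int, default: float = 0.0) -> float:
        return self.frequencies.get(locus, {}).get(allele, default)

    def counts(self, locus: str) -> dict[int, int]:
        """Integer gene-copy counts ``n_a = round(p_a * n)`` at a locus."""
        n = self.n[locus]
        return {a: round(p * n) for a, p in self.frequencies[locus].items()}

    def validate(self, tol: float = 1e-9) -> None:
        for locus, freqs in self.frequencies.items():
            if self.n.get(locus, 0) < 1:
                raise ValueError(f"locus {locus!r}: n must be >= 1")
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=tol):
                raise ValueError(f"locus {locus!r}: frequencies sum to {total}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"population": self.population, "locus": locus, "allele": a,
             "frequency": p, "n": self.n[locus]}
            for locus, freqs in self.frequencies.items()
            for a, p in sorted(freqs.items())
        ]
        return pd.DataFrame(rows, columns=["population", "locus", "allele",
                                           "frequency", "n"])

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {"population": self.population,
             "frequencies": {l: {str(a): p for a, p in f.items()}
                             for l, f in self.frequencies.items()},
             "n": self.n},
            indent=1)


def read_frequency_tables(path) -> dict[str, AlleleFrequencyTable]:
    """Read one or more populations from a frequency CSV
    (columns population, locus, allele, frequency, n)."""
    df = pd.read_csv(path)
    tables: dict[str, AlleleFrequencyTable] = {}
    for pop, sub in df.groupby("population", sort=False):
        freqs: dict[str, dict[int, float]] = {}
        ns: dict[str, int] = {}
        for locus, lsub in sub.groupby("locus", sort=False):
            freqs[locus] = {int(a): float(p)
                            for a, p in zip(lsub["allele"], lsub["frequency"])}
            ns[locus] = int(lsub["n"].iloc[0])
        tables[str(pop)] = AlleleFrequencyTable(str(pop), freqs, ns)
    for t in tables.values():
        t.validate(tol=1e-6)
    return tables


def allele_frequencies(individuals: Sequence[Individual],
                       ploidy_calls: Mapping[str, object] | None = None,
                       population: str = "sample",
                       loci: Iterable[str] | None = None,
                       haploid_mode: str = "one_copy") -> AlleleFrequencyTable:
    """Tabulate allele frequencies from genotyped individuals.

    Diploids contribute two gene copies per called locus. Individuals whose
    ploidy call (``ploidy_calls[id].verdict``) is ``"haploid"`` contribute
    according to ``haploid_mode``: ``"one_copy"`` (default; the duplicated
    allele counted once), ``"two_copies"``, or ``"exclude"``. Without ploidy
    calls every individual is treated as diploid. MISSING loci contribute
    nothing; a locus with zero called copies is absent from the table.
    """
    if haploid_mode not in ("one_copy", "two_copies", "exclude"):
        raise ValueError(f"unknown haploid_mode {haploid_mode!r}")
    counts: dict[str, Counter] = {}
    for ind in individuals:
        verdict = "diploid"
        if ploidy_calls is not None and ind.id in ploidy_calls:
            verdict = getattr(ploidy_calls[ind.id], "verdict", "diploid")
        if verdict == "haploid" and haploid_mode == "exclude":
            continue
        weight = 1 if (verdict == "haploid" and haploid_mode == "one_copy") else 2
        for locus in ind.genotype.called_loci:
            if loci is not None and locus not in loci:
                continue
            a, b = ind.genotype.alleles(locus)
            c = counts.setdefault(locus, Counter())
            if verdict == "haploid":
                c[a] += weight
            else:
                c[a] += 1
                c[b] += 1
    return AlleleFrequencyTable.from_counts(population, counts)


# ---------------------------------------------------------------------------
# Genotyping error from repeat runs


@dataclass
class ErrorRateEstimate:
    """Per-allele genotyping error rate from repeated runs of samples.

    ``rate = n_mismatches / n_allele_comparisons`` over loci called in both
    runs; a heterozygote in one run scored as a matching homozygote in the
    other is classed ``"dropout"``, all other discrepancies ``"other"``.
    """

    n_allele_comparisons: int
    n_mismatches: int
    rate: float
    breakdown: dict[str, int] = field(default_factory=dict)


def estimate_error_rate(
    pairs: Sequence[tuple[MultilocusGenotype, MultilocusGenotype]],
) -> ErrorRateEstimate:
    """Estimate the per-allele error rate from duplicate genotypings.

    Each pair is two independent runs of the same sample. At every locus
    called in both runs the two allele pairs are compared as multisets
    (2 allele comparisons per locus); the number of mismatched alleles is
    ``2 - |intersection|``.
    """
    comparisons = 0
    mismatches = 0
    breakdown: Counter = Counter()
    for run_a, run_b in pairs:
        for locus in run_a.called_loci:
            pa = run_a.alleles(locus)
            pb = run_b.alleles(locus)
            if pb is MISSING:
                continue
            comparisons += 2
            inter = Counter(pa) & Counter(pb)
            n_mis = 2 - sum(inter.values())
            if n_mis == 0:
                continue
            het, hom = None, None
            for p in (pa, pb):
                if p[0] != p[1]:
                    het = p
                else:
                    hom = p
            if het is not None and hom is not None and hom[0] in het:
                breakdown["dropout"] += n_mis
            else:
                breakdown["other"] += n_mis
            mismatches += n_mis
    if comparisons == 0:
        raise ValueError("no loci comparable across any repeat pair")
    return ErrorRateEstimate(
        n_allele_comparisons=comparisons,
        n_mismatches=mismatches,
        rate=mismatches / comparisons,
        breakdown=dict(breakdown),
    )
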