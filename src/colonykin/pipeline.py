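"""End-to-end nest analysis: read -> ploidy -> pedigree -> exclusion ->
diversity -> assignment -> report.

One config drives the whole chain; every stage writes its table (CSV and
JSON) into the output directory and logs row counts, and a human-readable
summary ties the numbers together. Stage failures surface with the stage
name; partial outputs are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assignment import cohort_assign
from .diversity import summarize_diversity
from .io import (DEFAULT_PANEL, USABLE_PANEL, allele_frequencies,
                 read_frequency_tables, read_genotype_table)
from .pedigree import ColonyPedigree
from .ploidy import call_ploidy_table

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger("colonykin")


@dataclass
class RunConfig:
    """Configuration for a full nest-analysis run."""

    genotypes: str
    out_dir: str
    nest_label: str = "Tetbury nest"
    candidate_ids: tuple = ()  # default: everyone not at nest_label
    references: dict = field(default_factory=dict)  # name -> frequency CSV
    panel: str = "15"  # "15", "13" or explicit locus list
    g: str | int = "auto"
    epsilon: float | None = None
    max_drones: int = 5
    max_mismatch_loci: int = 0
    haploid_mode: str = "pin"
    haploid_copies: str = "one_copy"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.candidate_ids, list):
            cfg.candidate_ids = tuple(cfg.candidate_ids)
        return cfg

    def panel_loci(self):
        if isinstance(self.panel, (list, tuple)):
            return tuple(self.panel)
        if str(self.panel) == "13":
            return tuple(l.name for l in USABLE_PANEL)
        return tuple(l.name for l in DEFAULT_PANEL)


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / f"{name}.csv", index=False)
    df.to_json(out_dir / f"{name}.json", orient="records", indent=1)


def run_report(config: RunConfig) -> dict:
    """Run the full chain; returns a summary dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "read"
    try:
        individuals = read_genotype_table(config.genotypes)
        if not individuals:
            raise ValueError("genotype table contains no individuals")
        loci = set(config.panel_loci())
        log.info("read: %d individuals", len(individuals))
        summary["n_individuals"] = len(individuals)
        nest = [i for i in individuals if i.location == config.nest_label]
        if config.candidate_ids:
            candidates = [i for i in individuals if i.id in config.candidate_ids]
        else:
            candidates = [i for i in individuals
                          if i.location != config.nest_label]
        summary["n_nest"] = len(nest)
        summary["n_candidates"] = len(candidates)

        stage = "ploidy"
        calls = call_ploidy_table(individuals)
        ploidy_df = pd.DataFrame(
            [{"id": c.id, "n_called_loci": c.n_called_loci,
              "n_het_loci": c.n_het_loci, "verdict": c.verdict}
             for c in calls.values()])
        _write(ploidy_df, out_dir, "ploidy")
        summary["n_haploid"] = int((ploidy_df["verdict"] == "haploid").sum())
        summary["n_diploid"] = int((ploidy_df["verdict"] == "diploid").sum())
        log.info("ploidy: %d haploid / %d diploid",
                 summary["n_haploid"], summary["n_diploid"])

        stage = "pedigree"
        if not nest:
            raise ValueError(f"no individuals at nest label "
                             f"{config.nest_label!r}")
        res = ColonyPedigree(
            nest, ploidy_calls={i.id: calls[i.id] for i in nest}, loci=loci,
            max_drones=config.max_drones,
            max_mismatch_loci=config.max_mismatch_loci,
            haploid_mode=config.haploid_mode).fit()
        (out_dir / "pedigree.json").write_text(json.dumps({
            "consistent": res.consistent,
            "n_solutions": len(res.solutions),
            "n_drones": res.n_drones,
            "unique": res.unique,
            "solutions": [
                {"queen": {l: list(p) for l, p in s.queen.items()},
                 "drones": [dict(d) for d in s.drones],
                 "ambiguous_loci": sorted(s.ambiguous_loci),
                 "offspring_assignments": s.offspring_assignments,
                 "exact": s.exact}
                for s in res.solutions[:20]],
            "diagnostics": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in res.diagnostics.items()},
        }, indent=1))
        summary["pedigree_consistent"] = res.consistent
        summary["n_drones"] = res.n_drones
        summary["pedigree_unique"] = res.unique
        log.info("pedigree: consistent=%s n_drones=%s unique=%s",
                 res.consistent, res.n_drones, res.unique)

        stage = "exclusion"
        rows = []
        for cand in candidates:
            ex = res.test_candidate(cand, ploidy=calls[cand.id])
            rows.append({"id": cand.id, "verdict": ex.verdict,
                         "allele_set_ok": ex.allele_set_ok,
                         "patriline_ok": ex.patriline_ok,
                         "n_violating_loci": len(ex.violating_loci),
                         "violating_loci": ";".join(v[0] for v in
                                                    ex.violating_loci)})
        excl_df = pd.DataFrame(rows, columns=["id", "verdict", "allele_set_ok",
                                              "patriline_ok",
                                              "n_violating_loci",
                                              "violating_loci"])
        _write(excl_df, out_dir, "exclusions")
        summary["exclusions"] = {r["id"]: r["verdict"] for r in rows}

        stage = "diversity"
        nest_plus = nest + candidates
        freqs = allele_frequencies(
            nest_plus, ploidy_calls=calls, population="nest-sample",
            loci=loci, haploid_mode=config.haploid_copies)
        tables = [freqs]
        ref_tables = {}
        for name, path in config.references.items():
            loaded = read_frequency_tables(path)
            if name in loaded:
                ref_tables[name] = loaded[name]
            elif len(loaded) == 1:
                (ref_tables[name],) = loaded.values()
                ref_tables[name].population = name
            else:
                raise ValueError(
                    f"reference file {path} lacks population {name!r}")
        tables += list(ref_tables.values())
        div = summarize_diversity(tables, g=config.g)
        frame = div.to_frame()
        frame.columns = [f"{p}_{s}" for p, s in frame.columns]
        frame.reset_index().to_csv(out_dir / "diversity.csv", index=False)
        summary["diversity_g"] = div.g
        summary["mean_gene_diversity"] = float(
            div.averages[("nest-sample", "gene_diversity")])
        summary["mean_n_alleles"] = float(
            div.averages[("nest-sample", "n_alleles")])

        stage = "assignment"
        if len(ref_tables) >= 2:
            cohort = cohort_assign(individuals, list(ref_tables.values()),
                                   epsilon=config.epsilon, loci=loci)
            _write(cohort.table, out_dir, "assignment")
            summary["assignment_counts"] = {
                str(k): int(v) for k, v in cohort.counts.items()}

        stage = "report"
        lines = [
            "colonykin nest analysis",
            "=======================",
            f"Individuals genotyped: {summary['n_individuals']} "
            f"({summary['n_nest']} at {config.nest_label!r}, "
            f"{summary['n_candidates']} candidates)",
            f"Ploidy: {summary['n_diploid']} diploid, "
            f"{summary['n_haploid']} haploid",
            "Pedigree: " + (
                f"1 queen x {summary['n_drones']} drone(s)"
                + (", unique solution" if summary["pedigree_unique"] else
                   f" ({len(res.solutions)} solutions)")
                if summary["pedigree_consistent"]
                else "no consistent single-queen solution"),
        ]
        hap_ids = ploidy_df.loc[ploidy_df["verdict"] == "haploid", "id"]
        if len(hap_ids):
            lines.append("Haploid individuals: " + ", ".join(hap_ids))
        for cid, verdict in summary.get("exclusions", {}).items():
            lines.append(f"Candidate {cid}: {verdict}")
        lines.append(f"Mean gene diversity (nest sample): "
                     f"{summary['mean_gene_diversity']:.3f}; mean alleles/locus: "
                     f"{summary['mean_n_alleles']:.2f} (g = {summary['diversity_g']})")
        if "assignment_counts" in summary:
            lines.append("Assignment counts: " + ", ".join(
                f"{k}: {v}" for k, v in summary["assignment_counts"].items()))
        (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
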