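"""Run every analysis stage over a genome panel and emit a report bundle.

Stages run in dependency order; stages whose inputs are absent (e.g. no
chronogram for the informativeness stage) are skipped with an explicit
notice in the manifest.  All tables are TSV with three-decimal display
rounding; a JSON manifest records configuration, seeds and stage notes so
a re-run with the same config reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_usage as cu
from . import composition as comp
from . import gene_order as go
from . import noncoding as nc
from .mitio import GenomeRecord, extract_gene_order, extract_spacers, \
    gene_sequence, spacer_sequence

__all__ = ["RunConfig", "ReportBundle", "run_report"]


@dataclass
class RunConfig:
    seed: int = 0
    min_spacer_len: int = 1
    enc_background_adjusted: bool = True
    stages: tuple = ("composition", "codon_usage", "gene_order", "spacers",
                     "noncoding", "selection", "informativeness")
    ground_pattern: str = "pancrustacean"
    reference_times: tuple = (5.0, 25.0, 50.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "reference_times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    tables: dict = field(default_factory=dict)   # name -> DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.round(3).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)


def _genome_table(genomes: list[GenomeRecord]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        p = comp.composition_stats(g.sequence)
        rows.append({"genome": g.id, "length": len(g), **p.as_dict()})
    return pd.DataFrame(rows)


def _codon_tables(genomes):
    enc_rows, census = [], []
    rscu_rows = []
    for g in genomes:
        for f in g.features_of_kind("PCG"):
            counts = cu.codon_counts(gene_sequence(g, f), gene=f.gene,
                                     genome=g.id, strand=f.strand)
            if counts.total < 30:
                continue
            row = {"genome": g.id, "gene": f.gene, "strand": f.strand,
                   "n_codons": counts.total,
                   "ENC": cu.enc_wright(counts),
                   "GC3": cu.gc3(counts)}
            enc_rows.append(row)
            for codon, val in cu.rscu(counts).items():
                rscu_rows.append({"genome": g.id, "gene": f.gene,
                                  "codon": codon, "RSCU": val})
    census = cu.census_start_stop(genomes)
    return (pd.DataFrame(enc_rows), pd.DataFrame(rscu_rows), census)


def run_report(genomes: list[GenomeRecord], config: RunConfig | None = None,
               alignments: dict | None = None, chronogram=None
               ) -> ReportBundle:
    """Run the configured stages over a panel of annotated genomes.

    ``alignments`` (gene -> :class:`~mitocomp.selection.CodonAlignment`) and
    ``chronogram`` unlock the selection and informativeness stages; when
    absent those stages are skipped and noted.  Deterministic given the
    config and its seed.
    """
    config = config or RunConfig()
    if not genomes:
        raise ValueError("need at least one genome")
    bundle = ReportBundle()
    notes: list[str] = []
    stages = set(config.stages)

    if "composition" in stages:
        bundle.tables["genome_composition"] = _genome_table(genomes)
        bundle.tables["gene_composition"] = pd.concat(
            [comp.per_gene_composition(g) for g in genomes],
            ignore_index=True)

    if "codon_usage" in stages:
        enc, rscu_t, census = _codon_tables(genomes)
        bundle.tables["enc_per_gene"] = enc
        bundle.tables["rscu"] = rscu_t
        bundle.tables["start_stop_census"] = census
        if len(enc) >= 3 and enc["GC3"].nunique() > 1:
            notes.append(
                f"ENC~GC3 Pearson r = {cu.enc_gc3_correlation(enc):.3f}")

    if "gene_order" in stages:
        try:
            orders = {g.id: extract_gene_order(g) for g in genomes}
            ground = (go.pancrustacean_ground_pattern()
                      if config.ground_pattern == "pancrustacean"
                      else go.read_gene_orders(config.ground_pattern).popitem()[1])
            rows = [{"genome": name,
                     "breakpoint_distance_to_ground": go.breakpoint_distance(
                         o, ground)} for name, o in orders.items()]
            bundle.tables["breakpoint_distances"] = pd.DataFrame(rows)
            if len(orders) >= 2:
                blocks = go.conserved_blocks(list(orders.values()))
                notes.append(f"{len(blocks)} conserved block(s); largest "
                             f"{max((len(b) for b in blocks), default=0)} genes")
        except Exception as exc:  # incomplete annotations: skip, don't die
            notes.append(f"gene_order stage skipped: {exc}")

    if "spacers" in stages:
        rows = []
        for g in genomes:
            for sp in extract_spacers(g, config.min_spacer_len):
                rows.append({"genome": g.id, "label": sp.label,
                             "left": sp.left_gene, "right": sp.right_gene,
                             "start": sp.start, "length": sp.length})
        bundle.tables["spacers"] = pd.DataFrame(rows)

    if "noncoding" in stages:
        rows = []
        for g in genomes:
            crs = [f for f in g.features if f.kind == "control_region"]
            for f in crs:
                seq = gene_sequence(g, f)
                rep = nc.scan_control_region(seq)
                rows.append({"genome": g.id, "strand": rep.strand,
                             "n_features_found": rep.n_found,
                             "missing": ",".join(rep.missing) or "none",
                             "n_stem_loops": len(rep.stem_loops)})
            if not crs:
                notes.append(f"{g.id}: no control region annotated")
        bundle.tables["control_region"] = pd.DataFrame(rows)

    if "selection" in stages:
        if alignments:
            from .selection import one_ratio_omega

            rows = []
            for gene, aln in alignments.items():
                if chronogram is None:
                    break
                fit = one_ratio_omega(aln, chronogram.tree
                                      if hasattr(chronogram, "tree")
                                      else chronogram)
                rows.append({"gene": gene, "omega": fit.params.omega,
                             "kappa": fit.params.kappa, "lnL": fit.lnL,
                             "n_codons": fit.n_sites})
            if rows:
                bundle.tables["omega"] = pd.DataFrame(rows)
            else:
                notes.append("selection stage skipped: no chronogram")
        else:
            notes.append("selection stage skipped: no alignments supplied")

    if "informativeness" in stages:
        if alignments and chronogram is not None:
            from .informativeness import (Chronogram, pi_curve,
                                          pi_partition_summary, site_rates)

            chrono = (chronogram if isinstance(chronogram, Chronogram)
                      else Chronogram.from_tree(chronogram))
            grid = np.linspace(0.0, chrono.depth, 101)
            profiles = []
            for gene, aln in alignments.items():
                taxa = aln.taxa
                rows_nt = ["".join(
                    "---" if c < 0 else cu.SENSE_CODONS[c] for c in row)
                    for row in aln.codons]
                rates = site_rates((taxa, rows_nt), chrono, model="HKY")
                profiles.append(pi_curve(rates, grid, partition=gene))
            summary = pi_partition_summary(profiles, config.reference_times)
            bundle.tables["phylogenetic_informativeness"] = summary
        else:
            notes.append(
                "informativeness stage skipped: needs alignments + chronogram")

    bundle.manifest = {
        "config": config.__dict__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "genomes": [g.id for g in genomes],
        "notes": notes,
        "tables": sorted(bundle.tables),
    }
    return bundle
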