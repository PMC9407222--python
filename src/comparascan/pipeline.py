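"""End-to-end orchestration: het -> roh -> scan -> load from one config.

All randomness (the permutation null, the simulator when invoked through
the CLI) flows from the single config seed through named substreams, so a
rerun with the same config and seed writes byte-identical artifacts; the
run log (timestamps, timings) is the only non-reproducible output and is
kept out of the JSON summary.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenomeLayout, SpeciesPanel, VariantTable, tile_windows
from .formats import (
    read_chrom_lengths,
    read_species_panel,
    read_transcripts,
    read_variant_table,
    write_bed,
    write_bedgraph,
    write_tsv,
)
from .heterozygosity import per_site_heterozygosity, window_heterozygosity
from .load import damaging_load, unique_high_impact
from .private_scan import build_flank_windows, scan_genes
from .roh import ROHParams, call_roh, classify_and_summarize

__all__ = ["RunConfig", "PipelineError", "run_all", "load_run_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and artifacts written."""


@dataclass
class RunConfig:
    vcf: str
    gff: str
    panel: str
    layout: str
    focal_species: tuple[str, ...]
    outdir: str
    seed: int = 0
    window_size: int = 100_000
    window_step: int = 10_000
    flank: int = 1000
    alpha: float = 0.01
    pseudocount: float = 1.0
    null: str = "binomial"
    n_perm: int = 10_000
    roh_params: ROHParams = field(default_factory=ROHParams)
    # autosomal summaries by default: the X (when present) is excluded
    excluded_chromosomes: tuple[str, ...] = ("chrX", "X")

    def validate(self) -> None:
        for name in ("vcf", "gff", "panel", "layout"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"config path {name}={path!r} does not exist")
        if not (0 < self.window_step <= self.window_size):
            raise ValueError("need 0 < window_step <= window_size")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def load_run_config(path: str, outdir: str | None = None) -> RunConfig:
    """Build a RunConfig from YAML; relative paths resolve against the
    config file's directory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def _p(key: str) -> str:
        v = raw[key]
        return v if os.path.isabs(v) else os.path.join(base, v)

    roh_kwargs = raw.get("roh", {}) or {}
    return RunConfig(
        vcf=_p("vcf"),
        gff=_p("gff"),
        panel=_p("panel"),
        layout=_p("layout"),
        focal_species=tuple(raw.get("focal", [])),
        outdir=outdir if outdir is not None else raw.get("outdir", "comparascan_out"),
        seed=int(raw.get("seed", 0)),
        window_size=int(raw.get("window_size", 100_000)),
        window_step=int(raw.get("window_step", 10_000)),
        flank=int(raw.get("flank", 1000)),
        alpha=float(raw.get("alpha", 0.01)),
        pseudocount=float(raw.get("pseudocount", 1.0)),
        null=str(raw.get("null", "binomial")),
        n_perm=int(raw.get("n_perm", 10_000)),
        roh_params=ROHParams(**roh_kwargs),
        excluded_chromosomes=tuple(raw.get("excluded_chromosomes", ["chrX", "X"])),
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write all artifacts plus a single
    JSON summary; returns the summary dict."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    written: list[str] = []
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    def _done(name, t0):
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    try:
        t0 = _stage("load-inputs")
        layout = read_chrom_lengths(config.layout)
        panel = read_species_panel(config.panel, focal_species=config.focal_species)
        table = read_variant_table(config.vcf, panel, layout)
        transcripts = read_transcripts(config.gff)
        if config.excluded_chromosomes:
            table = table.subset_chromosomes(
                [n for n in layout.names if n not in set(config.excluded_chromosomes)]
            )
            layout = table.layout
            transcripts = [t for t in transcripts if t.chrom in layout]
        _done("load-inputs", t0)

        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "samples": panel.sample_ids,
        }

        # -- heterozygosity ------------------------------------------------
        t0 = _stage("heterozygosity")
        try:
            windows = tile_windows(layout, config.window_size, config.window_step)
            frames = []
            per_site = {}
            for sample in panel.sample_ids:
                track = window_heterozygosity(table, sample, windows)
                df = track.windows.copy()
                df.insert(0, "sample", sample)
                frames.append(df)
                per_site[sample] = per_site_heterozygosity(
                    table, sample, layout.total_length
                )
            het_df = pd.concat(frames, ignore_index=True)
            p = os.path.join(config.outdir, "het_windows.tsv")
            write_tsv(het_df, p, seed=config.seed)
            written.append(p)
            first = panel.sample_ids[0]
            p = os.path.join(config.outdir, f"het_windows.{first}.bedgraph")
            write_bedgraph(
                windows,
                het_df[het_df["sample"] == first]["het_per_kb"],
                p,
                track_name=f"het_per_kb_{first}",
            )
            written.append(p)
            p = os.path.join(config.outdir, "per_site_het.tsv")
            write_tsv(
                pd.DataFrame(
                    sorted(per_site.items()), columns=["sample", "het_per_kb"]
                ),
                p,
                seed=config.seed,
            )
            written.append(p)
            summary["per_site_het_per_kb"] = {
                k: round(v, 6) for k, v in per_site.items()
            }
        except Exception as exc:
            raise PipelineError(
                f"stage heterozygosity failed ({exc}); artifacts written: {written}"
            ) from exc
        _done("heterozygosity", t0)

        # -- runs of homozygosity -----------------------------------------
        t0 = _stage("roh")
        try:
            bed_rows = []
            roh_table = {}
            for sample in panel.sample_ids:
                segs = call_roh(table, sample, config.roh_params)
                seg_summary = classify_and_summarize(segs, layout)
                roh_table[sample] = seg_summary.as_dict()
                for s in segs:
                    bed_rows.append(
                        (s.chrom, s.start, s.end, s.sample_id, s.n_snps, s.length_class)
                    )
            p = os.path.join(config.outdir, "roh_segments.bed")
            write_bed(bed_rows, p, seed=config.seed)
            written.append(p)
            rows = []
            for sample, d in roh_table.items():
                for cls, cs in d["per_class"].items():
                    rows.append(
                        (
                            sample,
                            cls,
                            cs["n_segments"],
                            cs["summed_length"],
                            round(cs["fraction_of_genome"], 6),
                        )
                    )
                rows.append((sample, "froh", "", d["total_length"], round(d["froh"], 6)))
            p = os.path.join(config.outdir, "roh_summary.tsv")
            write_tsv(
                pd.DataFrame(
                    rows,
                    columns=["sample", "class", "n_segments", "summed_length", "fraction"],
                ),
                p,
                seed=config.seed,
            )
            written.append(p)
            summary["roh"] = roh_table
        except Exception as exc:
            raise PipelineError(
                f"stage roh failed ({exc}); artifacts written: {written}"
            ) from exc
        _done("roh", t0)

        # -- private-allele scan ------------------------------------------
        t0 = _stage("scan")
        try:
            flanks = build_flank_windows(transcripts, config.flank, layout)
            summary["scan"] = {}
            for k, focal in enumerate(config.focal_species):
                records = scan_genes(
                    table,
                    flanks,
                    focal,
                    panel,
                    alpha=config.alpha,
                    pseudocount=config.pseudocount,
                    null=config.null,
                    n_perm=config.n_perm,
                    seed=config.seed + 1000 + k,  # named substream per focal lineage
                )
                df = pd.DataFrame(
                    [
                        (
                            r.gene_id,
                            r.chrom,
                            r.n_private_focal,
                            round(r.mean_variable_other, 6),
                            round(r.ratio, 6),
                            r.p_value,
                            r.significant,
                        )
                        for r in records
                    ],
                    columns=[
                        "gene_id",
                        "chrom",
                        "n_private",
                        "mean_variable_other",
                        "ratio",
                        "p_value",
                        "significant",
                    ],
                )
                p = os.path.join(config.outdir, f"scan_{focal}.tsv")
                write_tsv(df, p, seed=config.seed)
                written.append(p)
                summary["scan"][focal] = {
                    "n_genes": len(records),
                    "significant_genes": sorted(
                        r.gene_id for r in records if r.significant
                    ),
                }
        except Exception as exc:
            raise PipelineError(
                f"stage scan failed ({exc}); artifacts written: {written}"
            ) from exc
        _done("scan", t0)

        # -- load / high-impact -------------------------------------------
        t0 = _stage("load")
        try:
            rows = []
            load_summary = {}
            for sample in panel.sample_ids:
                ls = damaging_load(table, sample)
                rows.append(
                    (
                        sample,
                        ls.n_damaging_hom_derived,
                        ls.n_damaging_het_derived,
                        ls.denominator,
                        ls.n_excluded_no_ancestral,
                    )
                )
                load_summary[sample] = {
                    "hom_derived": ls.n_damaging_hom_derived,
                    "het_derived": ls.n_damaging_het_derived,
                }
            p = os.path.join(config.outdir, "load.tsv")
            write_tsv(
                pd.DataFrame(
                    rows,
                    columns=[
                        "sample",
                        "n_damaging_hom_derived",
                        "n_damaging_het_derived",
                        "denominator",
                        "n_excluded_no_ancestral",
                    ],
                ),
                p,
                seed=config.seed,
            )
            written.append(p)
            summary["load"] = load_summary

            has_impact = any(v is not None for v in table.impact)
            summary["high_impact"] = {}
            if has_impact:
                for focal in config.focal_species:
                    rep = unique_high_impact(table, focal, panel)
                    summary["high_impact"][focal] = {
                        "n_genes": rep.n_genes,
                        "n_variants": rep.n_variants,
                        "genes": sorted(rep.genes),
                    }
            else:
                logger.warning(
                    "no impact annotations in VCF; high-impact report skipped"
                )
        except Exception as exc:
            raise PipelineError(
                f"stage load failed ({exc}); artifacts written: {written}"
            ) from exc
        _done("load", t0)

        p = os.path.join(config.outdir, "summary.json")
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
        logger.info("run complete; %d artifacts", len(written))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
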