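"""Readers and writers for the standard formats the pipeline touches.

VCF is read with cyvcf2; transcript models come from GFF3 (gffutils) or
BED12.  Impact / deleteriousness / gene / ancestral annotations are parsed
from configurable INFO keys (defaults ``IMPACT``, ``DEL``, ``GENE``, ``AA``);
the pipeline consumes them and never computes consequence predictions
itself.

All tabular outputs are tab-separated with a commented header line naming
the pipeline version and, where randomness is involved, the seed.
"""
from __future__ import annotations

import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    GenomeLayout,
    GenomicWindow,
    SpeciesPanel,
    TranscriptModel,
    VariantTable,
)

__all__ = [
    "read_variant_table",
    "write_vcf",
    "read_transcripts",
    "longest_isoform_per_gene",
    "write_gff3",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "read_species_panel",
    "write_species_panel",
    "output_header",
    "write_tsv",
    "write_bed",
    "write_bedgraph",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_table(
    path: str | os.PathLike,
    panel: SpeciesPanel | None = None,
    layout: GenomeLayout | None = None,
    *,
    ancestral_key: str = "AA",
    impact_key: str = "IMPACT",
    deleterious_key: str = "DEL",
    gene_key: str = "GENE",
) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    When *panel* is given, genotype columns are reordered to the panel's
    sample order and every panel sample must appear in the VCF header.
    When *layout* is None it is taken from the header contig lines.
    Multiallelic records are kept unsplit.  Unsorted input is a hard error
    naming the first offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if panel is not None:
        missing = [s for s in panel.sample_ids if s not in vcf_samples]
        if missing:
            raise ValueError(
                f"panel sample {missing[0]!r} not found in VCF header of {path}"
            )
        samples = panel.sample_ids
    else:
        samples = vcf_samples
    col = [vcf_samples.index(s) for s in samples]

    if layout is None:
        seqnames = vcf.seqnames
        seqlens = vcf.seqlens if seqnames else []
        if not seqnames:
            raise ValueError(f"VCF {path} has no contig header lines; pass a layout")
        layout = GenomeLayout(zip(seqnames, seqlens))

    chrom_idx: list[int] = []
    pos: list[int] = []
    ref: list[str] = []
    alts: list[tuple[str, ...]] = []
    gts: list[np.ndarray] = []
    anc: list[str | None] = []
    impact: list[str | None] = []
    delet: list[bool | None] = []
    gene: list[str | None] = []

    last_ci = -1
    last_pos = 0
    seen_chroms: set[int] = set()
    for v in vcf:
        ci = layout.index(v.CHROM)
        if ci != last_ci:
            if ci in seen_chroms or ci < last_ci:
                raise ValueError(
                    f"VCF not sorted: chromosome {v.CHROM} at {v.CHROM}:{v.POS} "
                    "appears out of layout order or more than once as a block"
                )
            seen_chroms.add(ci)
            last_ci = ci
            last_pos = 0
        if v.POS < last_pos:
            raise ValueError(
                f"VCF not sorted: first offending record {v.CHROM}:{v.POS} "
                f"follows position {last_pos}"
            )
        last_pos = v.POS
        chrom_idx.append(ci)
        pos.append(v.POS)
        ref.append(v.REF)
        alts.append(tuple(v.ALT))
        g = np.array(v.genotypes, dtype=np.int16)[:, :2]
        g[(g < 0).any(axis=1)] = -1
        gts.append(g[col])
        anc.append(v.INFO.get(ancestral_key))
        impact.append(v.INFO.get(impact_key))
        d = v.INFO.get(deleterious_key)
        delet.append(bool(d) if d is not None else None)
        gene.append(v.INFO.get(gene_key))

    gt = (
        np.stack(gts)
        if gts
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    return VariantTable(
        layout=layout,
        samples=samples,
        chrom_idx=np.array(chrom_idx, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alts=alts,
        gt=gt,
        ancestral=anc,
        impact=impact,
        deleterious=delet,
        gene_id=gene,
    )


def write_vcf(
    table: VariantTable,
    path: str | os.PathLike,
    *,
    ancestral_key: str = "AA",
    impact_key: str = "IMPACT",
    deleterious_key: str = "DEL",
    gene_key: str = "GENE",
    seed: int | None = None,
) -> None:
    """Write a VariantTable as plain VCF 4.2.

    The emitted text is a pure function of the table (and *seed*, recorded
    as a header line), so identical inputs give byte-identical files.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=comparascan-{__version__}\n")
    if seed is not None:
        buf.write(f"##comparascan_seed={seed}\n")
    for name, length in table.layout.chromosomes:
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write(
        f'##INFO=<ID={ancestral_key},Number=1,Type=String,'
        f'Description="Ancestral allele">\n'
    )
    buf.write(
        f'##INFO=<ID={impact_key},Number=1,Type=String,'
        f'Description="Consequence impact category">\n'
    )
    buf.write(
        f'##INFO=<ID={deleterious_key},Number=0,Type=Flag,'
        f'Description="Annotated deleterious">\n'
    )
    buf.write(
        f'##INFO=<ID={gene_key},Number=1,Type=String,Description="Gene id">\n'
    )
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
        + "\n"
    )
    for i in range(len(table)):
        info_parts = []
        if table.ancestral[i] is not None:
            info_parts.append(f"{ancestral_key}={table.ancestral[i]}")
        if table.impact[i] is not None:
            info_parts.append(f"{impact_key}={table.impact[i]}")
        if table.deleterious[i]:
            info_parts.append(deleterious_key)
        if table.gene_id[i] is not None:
            info_parts.append(f"{gene_key}={table.gene_id[i]}")
        info = ";".join(info_parts) if info_parts else "."
        alt = ",".join(table.alts[i]) if table.alts[i] else "."
        gts = []
        for a, b in table.gt[i]:
            if a < 0 or b < 0:
                gts.append("./.")
            else:
                gts.append(f"{a}/{b}")
        buf.write(
            f"{table.chrom_name(i)}\t{int(table.pos[i])}\t.\t{table.ref[i]}\t"
            f"{alt}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Transcripts (GFF3 / BED12)
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_transcripts(
    path: str | os.PathLike,
    *,
    longest_isoform: bool = True,
    bed_name_delim: str = "|",
) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12.

    GFF3: features of type mRNA/transcript; the gene id is resolved from the
    ``Parent`` attribute (or a ``gene_id`` attribute).  BED12: the name
    column must encode ``gene<delim>transcript``.  A transcript whose gene
    cannot be resolved is a hard error listing the record.

    With *longest_isoform* (the default) one transcript per gene is kept:
    the longest isoform, ties broken by transcript id.
    """
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        transcripts = _read_bed12(p, bed_name_delim)
    else:
        transcripts = _read_gff3(p)
    if longest_isoform:
        transcripts = longest_isoform_per_gene(transcripts)
    return transcripts


def _read_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    if os.path.getsize(path) == 0 or not any(
        line.strip() and not line.startswith("#") for line in open(path)
    ):
        return []
    db = gffutils.create_db(
        path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[TranscriptModel] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in _TRANSCRIPT_TYPES:
            continue
        gene_id = None
        parents = feat.attributes.get("Parent", [])
        if parents:
            gene_id = parents[0]
        elif feat.attributes.get("gene_id"):
            gene_id = feat.attributes["gene_id"][0]
        if gene_id is None:
            raise ValueError(
                f"transcript without resolvable gene id in {path}: "
                f"{feat.seqid}:{feat.start}-{feat.end} id={feat.id!r}"
            )
        tid = feat.id or feat.attributes.get("ID", ["?"])[0]
        out.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return out


def _read_bed12(path: str, delim: str) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 6 columns")
            name = f[3]
            if delim not in name:
                raise ValueError(
                    f"transcript without resolvable gene id in {path}:{lineno}: "
                    f"name {name!r} lacks delimiter {delim!r}"
                )
            gene_id, transcript_id = name.split(delim, 1)
            out.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    chrom=f[0],
                    start=int(f[1]) + 1,  # BED is 0-based half-open
                    end=int(f[2]),
                    strand=f[5],
                )
            )
    return out


def longest_isoform_per_gene(
    transcripts: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """Keep the longest isoform of each gene (ties: lexicographically first
    transcript id), preserving genomic order."""
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if (
            cur is None
            or t.length > cur.length
            or (t.length == cur.length and t.transcript_id < cur.transcript_id)
        ):
            best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: (t.chrom, t.start, t.gene_id))


def write_gff3(
    transcripts: Sequence[TranscriptModel], path: str | os.PathLike
) -> None:
    """Write gene + mRNA features; deterministic, suitable for round trips."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        order: list[str] = []
        for t in transcripts:
            if t.gene_id not in by_gene:
                order.append(t.gene_id)
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid in order:
            ts = by_gene[gid]
            start = min(t.start for t in ts)
            end = max(t.end for t in ts)
            chrom, strand = ts[0].chrom, ts[0].strand
            fh.write(
                f"{chrom}\tcomparascan\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}\n"
            )
            for t in ts:
                fh.write(
                    f"{t.chrom}\tcomparascan\tmRNA\t{t.start}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# Layout / panel TSVs
# ---------------------------------------------------------------------------

def read_chrom_lengths(path: str | os.PathLike) -> GenomeLayout:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            rows.append((name, int(length)))
    return GenomeLayout(rows)


def write_chrom_lengths(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_species_panel(
    path: str | os.PathLike,
    focal_species: Iterable[str] = (),
) -> SpeciesPanel:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, species = line.split("\t")[:2]
            rows.append((sample, species))
    return SpeciesPanel(rows, focal_species=focal_species)


def write_species_panel(panel: SpeciesPanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, species in panel.samples:
            fh.write(f"{sample}\t{species}\n")


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def output_header(seed: int | None = None) -> str:
    h = f"# comparascan {__version__}"
    if seed is not None:
        h += f" seed={seed}"
    return h + "\n"


def write_tsv(
    df: pd.DataFrame, path: str | os.PathLike, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def write_bed(
    rows: Iterable[tuple], path: str | os.PathLike, seed: int | None = None
) -> None:
    """BED3+ writer: each row is (chrom, start, end, *extra)."""
    with open(path, "w") as fh:
        fh.write(output_header(seed))
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(
    windows: Iterable[GenomicWindow],
    values: Iterable[float],
    path: str | os.PathLike,
    track_name: str = "comparascan",
) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for w, v in zip(windows, values):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{v:.6g}\n")
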