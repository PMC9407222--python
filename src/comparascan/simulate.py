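"""Synthetic multi-species diploid genotype panels with known truth.

The generator emulates the statistical regimes the downstream scans assume
in real canid-style panels: per-species background heterozygosity in the
0.3-2 het/kb range, long implanted autozygous tracts in designated inbred
samples, lineage-private derived alleles at a background rate with an
elevated rate inside the 1-kb flanking windows of designated target genes,
ancestral-allele polarization of every injected allele, and categorical
impact annotations with a configurable damaging fraction.

Model
-----
Sites are independent (no linkage): none of the implemented statistics
model LD, so a homogeneous point process keeps every oracle exact.

* Background polymorphism: per species *s* with rate *h*, ``Poisson(h x
  genome length)`` sites placed uniformly; samples of *s* are 0/1 there and
  every other sample is 1/1 (a divergent homozygous-alt background).  The
  expected per-sample heterozygosity per bp is exactly *h* outside
  implanted tracts, and such sites are never private to any species.
* Implanted autozygosity: inside each planned tract the carrier's genotype
  is forced homozygous, so tract boundaries are known exactly.
* Private alleles: injected as derived singletons — one sample of one
  species carries the alternate allele (heterozygous, or homozygous per a
  coin flip), all other samples are 0/0 and the ancestral allele is the
  reference.  They are private by construction.  Each injected allele is
  flagged deleterious with probability ``damaging_fraction``; for
  deleterious alleles the carrier's homozygosity probability is scaled by
  its ``hom_damaging_bias`` multiplier.

Identical seed + config give byte-identical output files.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core import GenomeLayout, SpeciesPanel, TranscriptModel, VariantTable
from .formats import (
    write_chrom_lengths,
    write_gff3,
    write_species_panel,
    write_vcf,
)
from .private_scan import build_flank_windows, private_site_mask
from .load import damaging_load

__all__ = [
    "SpeciesSpec",
    "ROHTract",
    "SimulationConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_transcriptome",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))

DEFAULT_IMPACT_DISTRIBUTION = {
    "MODIFIER": 0.70,
    "LOW": 0.15,
    "MODERATE": 0.10,
    "HIGH": 0.05,
}


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    n_samples: int
    het_rate: float  # expected heterozygous sites per bp per sample

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError(f"species {self.species_id}: n_samples must be >= 1")
        if self.het_rate < 0:
            raise ValueError(f"species {self.species_id}: het_rate must be >= 0")


@dataclass(frozen=True)
class ROHTract:
    """Planned autozygous tract; start/end are 0-based half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int


@dataclass
class SimulationConfig:
    seed: int
    layout: GenomeLayout
    species: list[SpeciesSpec]
    focal_species: tuple[str, ...] = ()
    roh_plan: list[ROHTract] = field(default_factory=list)
    private_background_rate: float = 0.0
    private_species: tuple[str, ...] | None = None  # default: the focal species
    target_genes: tuple[str, ...] = ()
    enrichment_factor: float = 1.0
    #: absolute private-allele rate inside target flanks; overrides
    #: ``private_background_rate * enrichment_factor`` when set, allowing a
    #: zero-background / flank-only regime.
    target_flank_rate: float | None = None
    damaging_fraction: float = 0.0
    hom_damaging_bias: dict[str, float] = field(default_factory=dict)
    impact_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPACT_DISTRIBUTION)
    )
    transcripts: list[TranscriptModel] = field(default_factory=list)
    flank: int = 1000

    def __post_init__(self):
        if self.private_background_rate < 0:
            raise ValueError("private_background_rate must be >= 0")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.target_flank_rate is not None and self.target_flank_rate < 0:
            raise ValueError("target_flank_rate must be >= 0")
        if not (0 <= self.damaging_fraction <= 1):
            raise ValueError("damaging_fraction must be in [0, 1]")
        sample_ids = set(self.panel().sample_ids)
        tracts_by_sample: dict[str, list[ROHTract]] = {}
        for t in self.roh_plan:
            if t.sample_id not in sample_ids:
                raise ValueError(f"roh_plan sample {t.sample_id!r} not in panel")
            length = self.layout.length(t.chrom)
            if not (0 <= t.start < t.end <= length):
                raise ValueError(
                    f"tract {t.chrom}:{t.start}-{t.end} outside chromosome bounds "
                    f"(length {length})"
                )
            tracts_by_sample.setdefault(t.sample_id, []).append(t)
        for sample, ts in tracts_by_sample.items():
            ts = sorted(ts, key=lambda t: (t.chrom, t.start))
            for a, b in zip(ts, ts[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"overlapping implanted tracts for sample {sample} on {a.chrom}"
                    )
        gene_ids = {t.gene_id for t in self.transcripts}
        for g in self.target_genes:
            if g not in gene_ids:
                raise ValueError(f"target gene {g!r} not among config transcripts")

    def panel(self) -> SpeciesPanel:
        samples = [
            (f"{sp.species_id}_{k}", sp.species_id)
            for sp in self.species
            for k in range(1, sp.n_samples + 1)
        ]
        return SpeciesPanel(samples, focal_species=self.focal_species)


@dataclass
class SimTruth:
    """What was actually written, recounted from the final genotype table."""

    implanted_roh: list[ROHTract]
    enriched_gene_ids: list[str]
    private_counts: dict[str, int]
    damaging_hom_derived: dict[str, int]
    high_impact: dict[str, dict]
    het_genotype_counts: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "implanted_roh": [
                {"sample_id": t.sample_id, "chrom": t.chrom, "start": t.start, "end": t.end}
                for t in self.implanted_roh
            ],
            "enriched_gene_ids": sorted(self.enriched_gene_ids),
            "private_counts": dict(sorted(self.private_counts.items())),
            "damaging_hom_derived": dict(sorted(self.damaging_hom_derived.items())),
            "high_impact": {
                k: {"n_variants": v["n_variants"], "genes": sorted(v["genes"])}
                for k, v in sorted(self.high_impact.items())
            },
            "het_genotype_counts": dict(sorted(self.het_genotype_counts.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _uniform_positions(
    rng: np.random.Generator, layout: GenomeLayout, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom_idx, 1-based pos) of n sites uniform over the genome."""
    clens = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    bounds = np.concatenate(([0], np.cumsum(clens)))
    offsets = rng.integers(0, bounds[-1], size=n)
    ci = np.searchsorted(bounds, offsets, side="right") - 1
    pos = offsets - bounds[ci] + 1
    return ci.astype(np.int32), pos.astype(np.int64)


def simulate_panel(config: SimulationConfig) -> tuple[VariantTable, SimTruth]:
    """Generate the genotype panel and its recounted truth."""
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    panel = config.panel()
    samples = panel.sample_ids
    n_samples = len(samples)
    col_of = {s: j for j, s in enumerate(samples)}
    species_cols = {
        sp.species_id: [col_of[s] for s in panel.samples_of(sp.species_id)]
        for sp in config.species
    }

    chrom_idx: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    gts: list[np.ndarray] = []
    anc: list[str | None] = []
    impact: list[str | None] = []
    delet: list[bool | None] = []
    gene: list[str | None] = []

    # --- background heterozygosity, one species at a time ---------------
    for sp in config.species:
        n = int(rng.poisson(sp.het_rate * layout.total_length))
        ci, p = _uniform_positions(rng, layout, n)
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        g = np.ones((n, n_samples, 2), dtype=np.int16)  # others 1/1
        cols = species_cols[sp.species_id]
        g[:, cols, 0] = 0  # species samples 0/1
        chrom_idx.append(ci)
        pos.append(p)
        refs.extend(_BASES[ref_i])
        alts.extend((a,) for a in _BASES[alt_i])
        gts.append(g)
        anc.extend([None] * n)
        impact.extend([None] * n)
        delet.extend([None] * n)
        gene.extend([None] * n)

    # --- private derived singletons --------------------------------------
    private_species = (
        config.private_species
        if config.private_species is not None
        else config.focal_species
    )
    transcripts = config.transcripts
    gene_regions = _gene_regions(transcripts, config.flank, layout)
    target_flanks = build_flank_windows(
        [t for t in transcripts if t.gene_id in set(config.target_genes)],
        config.flank,
        layout,
    )
    flank_windows = [w for f in target_flanks for w in f.windows]
    flank_total = sum(w.length for w in flank_windows)

    imp_cats = sorted(config.impact_distribution)
    imp_probs = np.array([config.impact_distribution[c] for c in imp_cats], dtype=float)
    imp_probs = imp_probs / imp_probs.sum() if imp_probs.sum() else imp_probs

    for species_id in private_species:
        rate = config.private_background_rate
        if rate <= 0:
            n_bg = 0
            ci = np.empty(0, dtype=np.int32)
            p = np.empty(0, dtype=np.int64)
        else:
            n_bg = int(rng.poisson(rate * layout.total_length))
            ci, p = _uniform_positions(rng, layout, n_bg)
        # extra enriched sites inside target-gene flanks, focal species only
        if config.target_flank_rate is not None:
            extra_rate = max(0.0, config.target_flank_rate - rate)
        else:
            extra_rate = rate * (config.enrichment_factor - 1)
        if (
            species_id in config.focal_species
            and extra_rate > 0
            and flank_total > 0
        ):
            n_ex = int(rng.poisson(extra_rate * flank_total))
            wlens = np.array([w.length for w in flank_windows], dtype=float)
            wi = rng.choice(len(flank_windows), size=n_ex, p=wlens / wlens.sum())
            offs = rng.integers(0, 2**62, size=n_ex)
            ex_ci = np.array(
                [layout.index(flank_windows[k].chrom) for k in wi], dtype=np.int32
            )
            ex_p = np.array(
                [
                    flank_windows[k].start + int(o % flank_windows[k].length) + 1
                    for k, o in zip(wi, offs)
                ],
                dtype=np.int64,
            )
            ci = np.concatenate([ci, ex_ci])
            p = np.concatenate([p, ex_p])
        n = len(p)
        if n == 0:
            continue
        cols = species_cols[species_id]
        carrier = rng.integers(0, len(cols), size=n)
        is_del = rng.random(size=n) < config.damaging_fraction
        cats = (
            np.array(imp_cats)[rng.choice(len(imp_cats), size=n, p=imp_probs)]
            if len(imp_cats)
            else np.array(["MODIFIER"] * n)
        )
        u_hom = rng.random(size=n)
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        g = np.zeros((n, n_samples, 2), dtype=np.int16)
        for i in range(n):
            col = cols[carrier[i]]
            bias = config.hom_damaging_bias.get(samples[col], 1.0)
            p_hom = min(1.0, 0.5 * bias) if is_del[i] else 0.5
            if u_hom[i] < p_hom:
                g[i, col, :] = 1
            else:
                g[i, col, 1] = 1
        chrom_idx.append(ci)
        pos.append(p)
        refs.extend(_BASES[ref_i])
        alts.extend((a,) for a in _BASES[alt_i])
        gts.append(g)
        anc.extend(_BASES[ref_i])  # injected alleles are derived; ancestral = ref
        impact.extend(cats)
        delet.extend(bool(d) if d else None for d in is_del)
        gene.extend(
            _locate_gene(gene_regions, int(c), int(q)) for c, q in zip(ci, p)
        )

    # --- assemble, sort, deduplicate --------------------------------------
    if chrom_idx:
        ci_all = np.concatenate(chrom_idx)
        pos_all = np.concatenate(pos)
        gt_all = (
            np.concatenate(gts)
            if gts
            else np.empty((0, n_samples, 2), dtype=np.int16)
        )
    else:
        ci_all = np.empty(0, dtype=np.int32)
        pos_all = np.empty(0, dtype=np.int64)
        gt_all = np.empty((0, n_samples, 2), dtype=np.int16)

    order = np.lexsort((np.arange(len(pos_all)), pos_all, ci_all))
    ci_all, pos_all, gt_all = ci_all[order], pos_all[order], gt_all[order]
    keep = np.ones(len(pos_all), dtype=bool)
    if len(pos_all) > 1:
        dup = (ci_all[1:] == ci_all[:-1]) & (pos_all[1:] == pos_all[:-1])
        keep[1:] = ~dup
    reorder = order[keep]
    table = VariantTable(
        layout=layout,
        samples=samples,
        chrom_idx=ci_all[keep],
        pos=pos_all[keep],
        ref=[refs[i] for i in reorder],
        alts=[alts[i] for i in reorder],
        gt=gt_all[keep],
        ancestral=[anc[i] for i in reorder],
        impact=[impact[i] for i in reorder],
        deleterious=[delet[i] for i in reorder],
        gene_id=[gene[i] for i in reorder],
    )

    # --- implant autozygous tracts ----------------------------------------
    for t in config.roh_plan:
        sl = table.chrom_slice(t.chrom)
        p0 = table.pos[sl] - 1
        lo = sl.start + int(np.searchsorted(p0, t.start, side="left"))
        hi = sl.start + int(np.searchsorted(p0, t.end, side="left"))
        j = col_of[t.sample_id]
        g = table.gt[lo:hi, j, :]
        forced = np.maximum(g[:, 0], g[:, 1])
        forced[(g < 0).any(axis=1)] = -1  # keep missing missing
        table.gt[lo:hi, j, 0] = forced
        table.gt[lo:hi, j, 1] = forced

    truth = _recount_truth(table, panel, config)
    return table, truth


def _gene_regions(
    transcripts: list[TranscriptModel], flank: int, layout: GenomeLayout
) -> dict[int, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Per chromosome index: sorted (starts, ends, gene ids) of transcript
    bodies extended by the flank, for gene-id assignment of injected sites."""
    per: dict[int, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        ci = layout.index(t.chrom)
        s = max(0, t.start - 1 - flank)
        e = min(layout.length(t.chrom), t.end + flank)
        per.setdefault(ci, []).append((s, e, t.gene_id))
    out = {}
    for ci, rows in per.items():
        rows.sort()
        out[ci] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            [r[2] for r in rows],
        )
    return out


def _locate_gene(
    regions: dict[int, tuple[np.ndarray, np.ndarray, list[str]]],
    ci: int,
    pos_1based: int,
) -> str | None:
    reg = regions.get(ci)
    if reg is None:
        return None
    starts, ends, genes = reg
    p0 = pos_1based - 1
    k = int(np.searchsorted(starts, p0, side="right")) - 1
    if k >= 0 and p0 < ends[k]:
        return genes[k]
    return None


def _recount_truth(
    table: VariantTable, panel: SpeciesPanel, config: SimulationConfig
) -> SimTruth:
    private_counts = {
        sp: int(private_site_mask(table, sp, panel).sum()) for sp in panel.species
    }
    damaging = {
        s: damaging_load(table, s).n_damaging_hom_derived for s in panel.sample_ids
    }
    high_impact: dict[str, dict] = {}
    has_impact = any(v is not None for v in table.impact)
    for sp in panel.species:
        if not has_impact:
            high_impact[sp] = {"n_variants": 0, "genes": []}
            continue
        priv = private_site_mask(table, sp, panel)
        high = np.array([v == "HIGH" for v in table.impact])
        idx = np.nonzero(priv & high)[0]
        genes = sorted({table.gene_id[i] for i in idx if table.gene_id[i] is not None})
        high_impact[sp] = {"n_variants": int(len(idx)), "genes": genes}
    het_counts = {s: int(table.het_mask(s).sum()) for s in panel.sample_ids}
    return SimTruth(
        implanted_roh=list(config.roh_plan),
        enriched_gene_ids=list(config.target_genes),
        private_counts=private_counts,
        damaging_hom_derived=damaging,
        high_impact=high_impact,
        het_genotype_counts=het_counts,
    )


def simulate_transcriptome(
    layout: GenomeLayout,
    n_genes: int,
    seed: int,
    min_length: int = 1000,
    max_length: int = 3000,
    flank: int = 1000,
    min_gap: int = 2000,
) -> list[TranscriptModel]:
    """Uniformly placed non-overlapping single-transcript genes.

    Bodies keep >= *min_gap* between neighbours and >= *flank* from
    chromosome ends, so every gene's flanking windows are full-length and
    disjoint from every other gene's.  Deterministic under *seed*.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    caps = []
    for _, length in layout.chromosomes:
        usable = length - 2 * flank
        caps.append(max(0, (usable + min_gap) // (max_length + min_gap)))
    total_cap = int(sum(caps))
    if n_genes > total_cap:
        raise ValueError(
            f"layout too small for {n_genes} genes; maximum feasible count is {total_cap}"
        )
    # largest-remainder allocation proportional to capacity, bounded by it
    quota = [n_genes * c / total_cap for c in caps]
    alloc = [min(int(q), c) for q, c in zip(quota, caps)]
    rem = n_genes - sum(alloc)
    order = sorted(
        range(len(caps)), key=lambda i: (quota[i] - int(quota[i])), reverse=True
    )
    k = 0
    while rem > 0:
        i = order[k % len(order)]
        if alloc[i] < caps[i]:
            alloc[i] += 1
            rem -= 1
        k += 1

    out: list[TranscriptModel] = []
    counter = 1
    for (chrom, length), m in zip(layout.chromosomes, alloc):
        if m == 0:
            continue
        lens = rng.integers(min_length, max_length + 1, size=m)
        usable = length - 2 * flank
        slack = usable - int(lens.sum()) - (m - 1) * min_gap
        u = rng.random(size=m + 1)
        extra = np.floor(u / u.sum() * slack).astype(np.int64)
        strands = rng.integers(0, 2, size=m)
        cur = flank
        for i in range(m):
            cur += int(extra[i])
            start0 = cur
            out.append(
                TranscriptModel(
                    gene_id=f"gene{counter:05d}",
                    transcript_id=f"t{counter:05d}",
                    chrom=chrom,
                    start=start0 + 1,
                    end=start0 + int(lens[i]),
                    strand="+" if strands[i] == 0 else "-",
                )
            )
            counter += 1
            cur += int(lens[i]) + min_gap
    return out


def write_simulation(
    outdir: str | os.PathLike,
    config: SimulationConfig,
    table: VariantTable,
    truth: SimTruth,
) -> dict[str, str]:
    """Write panel VCF, transcript GFF3, chromosome-length TSV, panel TSV
    and truth JSON; returns the path of each artifact.  Byte-identical for
    identical seed + config."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "gff3": os.path.join(outdir, "transcripts.gff3"),
        "chrom_lengths": os.path.join(outdir, "chroms.tsv"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(table, paths["vcf"], seed=config.seed)
    write_gff3(config.transcripts, paths["gff3"])
    write_chrom_lengths(config.layout, paths["chrom_lengths"])
    write_species_panel(config.panel(), paths["panel"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
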