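"""Lineage-private allele enrichment in transcript-flanking windows.

For every (longest-isoform) transcript, two 1-kb windows are taken as a
proxy for proximal regulatory sequence: immediately upstream of the
transcript start and immediately downstream of the transcript end.  Within
each gene's windows the scan counts alleles private to a focal species
(carried by that species and by no other species with a called genotype;
restricted to derived alleles when ancestral states are annotated) and the
average number of within-species variable sites across the remaining
species.  Genes are assigned a one-sided P value for private-allele excess
under a null in which private alleles fall uniformly along the genome at
the observed genome-wide rate — either an exact binomial test on the flank
length, or an empirical permutation null that re-draws flank-sized windows
uniformly from the genome.

The per-gene enrichment statistic is ``n_private_focal /
max(mean_variable_other, pseudocount)``; the pseudocount (default 1)
prevents division by zero without changing ranks among nonzero
denominators.  No multiple-testing correction is applied by default (raw
P < alpha, default 0.01); Benjamini-Hochberg control is optional.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    GenomeLayout,
    GenomicWindow,
    SpeciesPanel,
    TranscriptModel,
    VariantSite,
    VariantTable,
    merge_intervals,
)

__all__ = [
    "FlankWindowSet",
    "GeneScanRecord",
    "GeneSetComparison",
    "build_flank_windows",
    "is_private",
    "private_site_mask",
    "scan_genes",
    "compare_gene_set",
]


@dataclass(frozen=True)
class FlankWindowSet:
    """The regulatory-proxy windows of one gene (its longest transcript)."""

    gene_id: str
    transcript_id: str
    chrom: str
    windows: tuple[GenomicWindow, ...]

    @property
    def total_length(self) -> int:
        return sum(w.length for w in self.windows)


@dataclass(frozen=True)
class GeneScanRecord:
    gene_id: str
    chrom: str
    n_private_focal: int
    mean_variable_other: float
    ratio: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class GeneSetComparison:
    """Per-species proportion of private alleles among all variable sites in
    a gene set's flanking windows, ranked descending."""

    gene_set_id: str
    proportions: dict[str, float]

    @property
    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.proportions.items(), key=lambda kv: (-kv[1], kv[0]))


def build_flank_windows(
    transcripts: Sequence[TranscriptModel],
    flank: int,
    layout: GenomeLayout,
) -> list[FlankWindowSet]:
    """Per transcript: windows [start-flank, start) and [end, end+flank) in
    0-based half-open coordinates, clipped to chromosome bounds; fully
    clipped (empty) windows are dropped and any overlapping pair is merged.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out: list[FlankWindowSet] = []
    for t in transcripts:
        length = layout.length(t.chrom)
        body_start = t.start - 1  # 0-based
        body_end = t.end
        raw = [
            (max(0, body_start - flank), min(body_start, length)),
            (max(0, body_end), min(body_end + flank, length)),
        ]
        ivs = [(s, e) for s, e in raw if e > s]
        ivs = merge_intervals(ivs) if ivs else []
        out.append(
            FlankWindowSet(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                windows=tuple(GenomicWindow(t.chrom, s, e) for s, e in ivs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------

def private_site_mask(
    variants: VariantTable,
    focal_species: str,
    panel: SpeciesPanel,
    polarized: str = "auto",
) -> np.ndarray:
    """Boolean mask: site carries an allele private to *focal_species*.

    An allele is private when >=1 focal-species sample carries it and zero
    samples of every other species with a called genotype do.  Polarity:
    with ``polarized="auto"`` only derived alleles (differing from the
    annotated ancestral allele) are eligible at sites with an ancestral
    annotation, any non-reference allele elsewhere; ``"never"`` ignores
    ancestral annotations.  Sites with no called focal genotype, or where
    all non-focal genotypes are missing, are False.
    """
    if polarized not in ("auto", "never"):
        raise ValueError("polarized must be 'auto' or 'never'")
    focal_samples = panel.samples_of(focal_species)
    focal_cols = [variants.sample_index(s) for s in focal_samples]
    other_cols = [
        variants.sample_index(s)
        for s, sp in panel.samples
        if sp != focal_species
    ]
    n = len(variants)
    if n == 0:
        return np.zeros(0, dtype=bool)
    gf = variants.gt[:, focal_cols, :]
    go = variants.gt[:, other_cols, :]
    focal_called = (gf >= 0).all(axis=2).any(axis=1)
    other_called = (go >= 0).all(axis=2).any(axis=1) if other_cols else np.zeros(n, bool)

    n_alleles = np.array([1 + len(a) for a in variants.alts], dtype=np.int32)
    if polarized == "auto":
        anc_idx = np.array(
            [
                ((variants.ref[i],) + variants.alts[i]).index(variants.ancestral[i])
                if variants.ancestral[i] in ((variants.ref[i],) + variants.alts[i])
                else -1
                for i in range(n)
            ],
            dtype=np.int32,
        )
    else:
        anc_idx = np.full(n, -1, dtype=np.int32)

    private = np.zeros(n, dtype=bool)
    for a in range(int(n_alleles.max())):
        exists = n_alleles > a
        # eligible: derived when polarized (anc known and a != anc),
        # non-reference otherwise
        eligible = np.where(anc_idx >= 0, a != anc_idx, a > 0) & exists
        focal_carries = (gf == a).any(axis=(1, 2))
        other_carries = (go == a).any(axis=(1, 2)) if other_cols else np.zeros(n, bool)
        private |= eligible & focal_carries & ~other_carries
    return private & focal_called & other_called


def is_private(
    site: VariantSite,
    focal_species: str,
    panel: SpeciesPanel,
    polarized: str = "auto",
) -> bool:
    """Single-site form of :func:`private_site_mask`; ``site.genotypes``
    must follow the panel's sample order."""
    species = [sp for _, sp in panel.samples]
    alleles = site.alleles
    anc = site.ancestral if polarized == "auto" else None
    anc_idx = alleles.index(anc) if anc in alleles else -1

    carried_focal: set[int] = set()
    carried_other: set[int] = set()
    focal_called = other_called = False
    for sp, g in zip(species, site.genotypes):
        if g is None:
            continue
        if sp == focal_species:
            focal_called = True
            carried_focal.update(g)
        else:
            other_called = True
            carried_other.update(g)
    if not (focal_called and other_called):
        return False
    for a in carried_focal - carried_other:
        if (a != anc_idx) if anc_idx >= 0 else (a > 0):
            return True
    return False


# ---------------------------------------------------------------------------
# Gene scan
# ---------------------------------------------------------------------------

def _positions_by_chrom(
    variants: VariantTable, mask: np.ndarray
) -> dict[str, np.ndarray]:
    """0-based positions of masked sites, per chromosome (sorted)."""
    out: dict[str, np.ndarray] = {}
    for chrom, _ in variants.layout.chromosomes:
        sl = variants.chrom_slice(chrom)
        out[chrom] = variants.pos[sl][mask[sl]] - 1
    return out


def _count_in_windows(
    pos_by_chrom: Mapping[str, np.ndarray], windows: Iterable[GenomicWindow]
) -> int:
    total = 0
    for w in windows:
        p = pos_by_chrom.get(w.chrom)
        if p is None or len(p) == 0:
            continue
        total += int(
            np.searchsorted(p, w.end, side="left")
            - np.searchsorted(p, w.start, side="left")
        )
    return total


def _binomial_p(
    x: int, length: int, rate: float, mode: str, u: float
) -> float:
    """One-sided P(X >= x) for X ~ Binomial(length, rate).

    ``mode='exact'`` is the conservative exact tail; ``'mid'`` adds half the
    point mass; ``'randomized'`` is the PIT form P(X > x) + U * P(X = x),
    exactly Uniform(0,1) under the null (used for calibration checks).
    """
    if length == 0:
        return 1.0
    rate = min(rate, 1.0)
    upper = float(stats.binom.sf(x - 1, length, rate))  # P(X >= x)
    if mode == "exact":
        return upper
    point = float(stats.binom.pmf(x, length, rate))
    if mode == "mid":
        return max(0.0, upper - 0.5 * point)
    if mode == "randomized":
        return max(0.0, upper - (1.0 - u) * point)
    raise ValueError(f"unknown binomial mode {mode!r}")


def scan_genes(
    variants: VariantTable,
    flanks: Sequence[FlankWindowSet],
    focal: str,
    panel: SpeciesPanel,
    alpha: float = 0.01,
    pseudocount: float = 1.0,
    null: str = "binomial",
    binomial_mode: str = "exact",
    n_perm: int = 10_000,
    seed: int = 0,
    multiple_testing: str = "none",
) -> list[GeneScanRecord]:
    """Score each gene's flanking windows for focal private-allele excess.

    Returns records sorted by (p_value, gene_id).  ``null`` is ``"binomial"``
    (expected count = genome-wide focal private rate x flank length) or
    ``"permutation"`` (empirical rank among ``n_perm`` uniformly re-drawn
    flank-sized windows; seeded).  Genes whose windows were fully clipped
    away get zero counts and p_value 1.
    """
    if null not in ("binomial", "permutation"):
        raise ValueError("null must be 'binomial' or 'permutation'")
    rng = np.random.default_rng(seed)

    priv = private_site_mask(variants, focal, panel)
    priv_pos = _positions_by_chrom(variants, priv)
    genome_len = variants.layout.total_length
    rate = priv.sum() / genome_len

    other_species = [sp for sp in panel.species if sp != focal]
    var_pos: dict[str, dict[str, np.ndarray]] = {}
    for sp in other_species:
        cols = [variants.sample_index(s) for s in panel.samples_of(sp)]
        g = variants.gt[:, cols, :]
        var_mask = (g > 0).any(axis=(1, 2))
        var_pos[sp] = _positions_by_chrom(variants, var_mask)

    x = np.array([_count_in_windows(priv_pos, f.windows) for f in flanks])
    lengths = np.array([f.total_length for f in flanks])

    if null == "permutation":
        perm = _permutation_counts(
            priv_pos, variants.layout, sorted(set(lengths[lengths > 0])), n_perm, rng
        )
        pvals = np.ones(len(flanks))
        for i, f in enumerate(flanks):
            if lengths[i] == 0:
                continue
            counts = perm[lengths[i]]
            pvals[i] = (1 + int((counts >= x[i]).sum())) / (n_perm + 1)
    else:
        us = rng.uniform(size=len(flanks))
        pvals = np.array(
            [
                _binomial_p(int(x[i]), int(lengths[i]), rate, binomial_mode, us[i])
                for i in range(len(flanks))
            ]
        )

    if multiple_testing == "bh":
        adj = np.ones_like(pvals)
        if len(pvals):
            adj = stats.false_discovery_control(pvals, method="bh")
        sig = adj < alpha
    elif multiple_testing == "none":
        # alpha >= 1 disables the filter entirely (exact tests report p = 1.0
        # for empty genes, which a strict inequality would exclude)
        sig = pvals < alpha if alpha < 1 else np.ones(len(pvals), dtype=bool)
    else:
        raise ValueError("multiple_testing must be 'none' or 'bh'")

    records = []
    for i, f in enumerate(flanks):
        mv = (
            float(np.mean([_count_in_windows(var_pos[sp], f.windows) for sp in other_species]))
            if other_species
            else 0.0
        )
        records.append(
            GeneScanRecord(
                gene_id=f.gene_id,
                chrom=f.chrom,
                n_private_focal=int(x[i]),
                mean_variable_other=mv,
                ratio=float(x[i] / max(mv, pseudocount)),
                p_value=float(pvals[i]),
                significant=bool(sig[i]),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.gene_id))
    return records


def _permutation_counts(
    priv_pos: Mapping[str, np.ndarray],
    layout: GenomeLayout,
    lengths: Sequence[int],
    n_perm: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Null distribution of private-site counts in uniformly placed windows,
    one shared distribution per distinct window length."""
    out: dict[int, np.ndarray] = {}
    chroms = [c for c, _ in layout.chromosomes]
    clens = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    for L in lengths:
        weights = np.maximum(0, clens - L + 1).astype(float)
        if weights.sum() == 0:
            out[L] = np.zeros(n_perm, dtype=np.int64)
            continue
        weights /= weights.sum()
        ci = rng.choice(len(chroms), size=n_perm, p=weights)
        counts = np.zeros(n_perm, dtype=np.int64)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            m = int(sel.sum())
            if m == 0:
                continue
            starts = rng.integers(0, clens[k] - L + 1, size=m)
            p = priv_pos.get(chrom, np.empty(0, dtype=np.int64))
            counts[sel] = np.searchsorted(p, starts + L, side="left") - np.searchsorted(
                p, starts, side="left"
            )
        out[L] = counts
    return out


# ---------------------------------------------------------------------------
# Gene-set comparison
# ---------------------------------------------------------------------------

def compare_gene_set(
    variants: VariantTable,
    flanks: Sequence[FlankWindowSet],
    gene_set: Iterable[str],
    panel: SpeciesPanel,
    gene_set_id: str = "gene_set",
) -> GeneSetComparison:
    """Per-species proportion of private alleles among all variable sites in
    the gene set's flanking windows."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    by_gene = {f.gene_id for f in flanks}
    missing = gene_set - by_gene
    if missing:
        raise ValueError(f"gene_set members not in scanned flanks: {sorted(missing)[:5]}")
    windows = [w for f in flanks if f.gene_id in gene_set for w in f.windows]

    any_var = (variants.gt > 0).any(axis=(1, 2))
    total_var = _count_in_windows(_positions_by_chrom(variants, any_var), windows)

    proportions: dict[str, float] = {}
    for sp in panel.species:
        mask = private_site_mask(variants, sp, panel)
        n = _count_in_windows(_positions_by_chrom(variants, mask), windows)
        proportions[sp] = n / total_var if total_var else 0.0
    return GeneSetComparison(gene_set_id=gene_set_id, proportions=proportions)
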