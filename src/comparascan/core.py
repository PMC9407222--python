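"""Core containers and interval arithmetic shared by every scan stage.

Coordinate conventions
----------------------
VCF and GFF3 are 1-based inclusive on disk.  Every in-memory window,
run-of-homozygosity segment and BED-style interval is 0-based half-open.
A variant at VCF position ``p`` falls in window ``[s, e)`` iff
``s <= p - 1 < e``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "SpeciesPanel",
    "GenomicWindow",
    "TranscriptModel",
    "VariantSite",
    "VariantTable",
    "tile_windows",
    "merge_intervals",
    "interval_overlap",
]

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the denominator for every
    genome-fraction statistic (F_ROH, class fractions, private-allele rates).
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(f"chromosome {chrom!r} not in layout")

    def index(self, chrom: str) -> int:
        for i, (n, _) in enumerate(self.chromosomes):
            if n == chrom:
                return i
        raise KeyError(f"chromosome {chrom!r} not in layout")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def drop(self, excluded: Iterable[str]) -> "GenomeLayout":
        """Layout restricted to chromosomes not in *excluded* (e.g. chrX)."""
        excluded = set(excluded)
        kept = [(n, l) for n, l in self.chromosomes if n not in excluded]
        if not kept:
            raise ValueError("excluding these chromosomes leaves an empty layout")
        return GenomeLayout(kept)


@dataclass(frozen=True)
class SpeciesPanel:
    """Sample -> species map with the focal/background partition.

    Focal species are the lineages whose private alleles and unique
    high-impact variants are scanned; background species provide the
    cross-species variability baseline ("the remaining species").
    """

    samples: tuple[tuple[str, str], ...]
    focal_species: frozenset[str] = frozenset()
    background_species: frozenset[str] = frozenset()

    def __init__(
        self,
        samples: Iterable[tuple[str, str]],
        focal_species: Iterable[str] = (),
        background_species: Iterable[str] | None = None,
    ):
        samples = tuple((str(s), str(sp)) for s, sp in samples)
        ids = [s for s, _ in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in panel")
        species_present = {sp for _, sp in samples}
        focal = frozenset(focal_species)
        if background_species is None:
            background = frozenset(species_present - focal)
        else:
            background = frozenset(background_species)
        if focal & background:
            raise ValueError("focal and background species sets must be disjoint")
        for sp in focal | background:
            if sp not in species_present:
                raise ValueError(f"species {sp!r} has no sample in the panel")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "focal_species", focal)
        object.__setattr__(self, "background_species", background)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def species(self) -> list[str]:
        """Species in order of first appearance."""
        seen: dict[str, None] = {}
        for _, sp in self.samples:
            seen.setdefault(sp)
        return list(seen)

    def species_of(self, sample_id: str) -> str:
        for s, sp in self.samples:
            if s == sample_id:
                return sp
        raise KeyError(f"sample {sample_id!r} not in panel")

    def samples_of(self, species_id: str) -> list[str]:
        out = [s for s, sp in self.samples if sp == species_id]
        if not out:
            raise KeyError(f"species {species_id!r} not in panel")
        return out


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid window {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript; start/end are 1-based inclusive as in GFF3."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantSite:
    """One variant record with per-sample unordered diploid genotypes.

    ``genotypes`` holds one ``(a, b)`` allele-index pair per sample, in the
    table's sample order, or ``None`` for a missing (./.) genotype.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[tuple[int, int] | None, ...]
    ancestral: str | None = None
    impact: str | None = None
    deleterious: bool | None = None
    gene_id: str | None = None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


class VariantTable:
    """Columnar store of sorted variant sites for a sample panel.

    Genotypes live in an ``(n_sites, n_samples, 2)`` int16 array with -1
    marking a missing allele; a genotype is heterozygous iff its two allele
    indices differ (multiallelic sites stay unsplit).  Optional per-site
    annotations: ancestral allele, impact category, deleterious flag,
    gene id.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        samples: Sequence[str],
        chrom_idx: np.ndarray,
        pos: np.ndarray,
        ref: Sequence[str],
        alts: Sequence[tuple[str, ...]],
        gt: np.ndarray,
        ancestral: Sequence[str | None] | None = None,
        impact: Sequence[str | None] | None = None,
        deleterious: Sequence[bool | None] | None = None,
        gene_id: Sequence[str | None] | None = None,
    ):
        n = len(pos)
        self.layout = layout
        self.samples = list(samples)
        self.chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alts = [tuple(a) for a in alts]
        self.gt = np.asarray(gt, dtype=np.int16)
        self.ancestral = list(ancestral) if ancestral is not None else [None] * n
        self.impact = list(impact) if impact is not None else [None] * n
        self.deleterious = list(deleterious) if deleterious is not None else [None] * n
        self.gene_id = list(gene_id) if gene_id is not None else [None] * n
        self._validate()

    def _validate(self):
        n = len(self.pos)
        for name, col in (
            ("chrom_idx", self.chrom_idx),
            ("ref", self.ref),
            ("alts", self.alts),
            ("ancestral", self.ancestral),
            ("impact", self.impact),
            ("deleterious", self.deleterious),
            ("gene_id", self.gene_id),
        ):
            if len(col) != n:
                raise ValueError(f"column {name} has length {len(col)}, expected {n}")
        if self.gt.shape != (n, len(self.samples), 2):
            raise ValueError(
                f"genotype array shape {self.gt.shape} != "
                f"({n}, {len(self.samples)}, 2)"
            )
        if n:
            order = np.lexsort((self.pos, self.chrom_idx))
            if not np.array_equal(order, np.arange(n)):
                bad = int(np.nonzero(order != np.arange(n))[0][0])
                raise ValueError(
                    f"sites not sorted by (chromosome, position); first offending "
                    f"record index {bad} at "
                    f"{self.chrom_name(bad)}:{int(self.pos[bad])}"
                )
            lengths = np.array(
                [l for _, l in self.layout.chromosomes], dtype=np.int64
            )
            if (self.pos < 1).any() or (self.pos > lengths[self.chrom_idx]).any():
                bad = int(
                    np.nonzero((self.pos < 1) | (self.pos > lengths[self.chrom_idx]))[0][0]
                )
                raise ValueError(
                    f"position out of chromosome bounds at "
                    f"{self.chrom_name(bad)}:{int(self.pos[bad])}"
                )

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_name(self, i: int) -> str:
        return self.layout.names[int(self.chrom_idx[i])]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in variant table") from None

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous slice of sites on *chrom* (possibly empty)."""
        ci = self.layout.index(chrom)
        lo = int(np.searchsorted(self.chrom_idx, ci, side="left"))
        hi = int(np.searchsorted(self.chrom_idx, ci, side="right"))
        return slice(lo, hi)

    # -- per-sample masks --------------------------------------------------

    def called_mask(self, sample_id: str) -> np.ndarray:
        j = self.sample_index(sample_id)
        return (self.gt[:, j, :] >= 0).all(axis=1)

    def het_mask(self, sample_id: str) -> np.ndarray:
        j = self.sample_index(sample_id)
        g = self.gt[:, j, :]
        return (g[:, 0] != g[:, 1]) & (g >= 0).all(axis=1)

    def subset_chromosomes(self, kept: Iterable[str]) -> "VariantTable":
        """Table restricted to *kept* chromosomes (layout shrinks with it);
        used e.g. to drop the X from autosomal summaries."""
        kept = [n for n in self.layout.names if n in set(kept)]
        sub_layout = GenomeLayout(
            [(n, l) for n, l in self.layout.chromosomes if n in kept]
        )
        mask = np.isin(
            self.chrom_idx, [self.layout.index(n) for n in kept]
        )
        remap = {self.layout.index(n): sub_layout.index(n) for n in kept}
        idx = np.nonzero(mask)[0]
        return VariantTable(
            layout=sub_layout,
            samples=self.samples,
            chrom_idx=np.array([remap[int(c)] for c in self.chrom_idx[idx]], dtype=np.int32),
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alts=[self.alts[i] for i in idx],
            gt=self.gt[idx],
            ancestral=[self.ancestral[i] for i in idx],
            impact=[self.impact[i] for i in idx],
            deleterious=[self.deleterious[i] for i in idx],
            gene_id=[self.gene_id[i] for i in idx],
        )

    # -- record views ------------------------------------------------------

    def site(self, i: int) -> VariantSite:
        g = self.gt[i]
        genotypes = tuple(
            None if (a < 0 or b < 0) else (int(a), int(b)) for a, b in g
        )
        return VariantSite(
            chrom=self.chrom_name(i),
            pos=int(self.pos[i]),
            ref=self.ref[i],
            alts=self.alts[i],
            genotypes=genotypes,
            ancestral=self.ancestral[i],
            impact=self.impact[i],
            deleterious=self.deleterious[i],
            gene_id=self.gene_id[i],
        )

    def sites(self) -> Iterator[VariantSite]:
        for i in range(len(self)):
            yield self.site(i)

    @classmethod
    def from_sites(
        cls,
        sites: Iterable[VariantSite],
        samples: Sequence[str],
        layout: GenomeLayout,
    ) -> "VariantTable":
        sites = list(sites)
        n = len(sites)
        chrom_idx = np.array([layout.index(s.chrom) for s in sites], dtype=np.int32)
        pos = np.array([s.pos for s in sites], dtype=np.int64)
        gt = np.full((n, len(samples), 2), -1, dtype=np.int16)
        for i, s in enumerate(sites):
            if len(s.genotypes) != len(samples):
                raise ValueError(
                    f"site {s.chrom}:{s.pos} has {len(s.genotypes)} genotypes "
                    f"for {len(samples)} samples"
                )
            for j, g in enumerate(s.genotypes):
                if g is not None:
                    gt[i, j, 0], gt[i, j, 1] = g
        return cls(
            layout=layout,
            samples=samples,
            chrom_idx=chrom_idx,
            pos=pos,
            ref=[s.ref for s in sites],
            alts=[s.alts for s in sites],
            gt=gt,
            ancestral=[s.ancestral for s in sites],
            impact=[s.impact for s in sites],
            deleterious=[s.deleterious for s in sites],
            gene_id=[s.gene_id for s in sites],
        )


def tile_windows(layout: GenomeLayout, size: int, step: int) -> list[GenomicWindow]:
    """Sliding windows ``[k*step, k*step+size)`` per chromosome.

    Windows start while ``start < chromosome length``; the terminal window is
    truncated at the chromosome end.  ``step == size`` gives a non-overlapping
    tiling; ``step < size`` gives the sliding scheme in which an interior site
    is covered by exactly ``size/step`` windows.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError(f"step {step} exceeds window size {size}")
    out: list[GenomicWindow] = []
    for chrom, length in layout.chromosomes:
        start = 0
        while start < length:
            out.append(GenomicWindow(chrom, start, min(start + size, length)))
            start += step
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
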