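"""Runs of homozygosity: sliding scan, length classes, genome summaries.

The detector re-implements the classic PLINK ``--homozyg`` scheme: a window
of ``scan_snp_count`` consecutive sites slides along each chromosome and is
a *hit* when it contains at most ``max_het_in_scan`` heterozygous and at
most ``max_missing_in_scan`` missing genotypes for the sample.  Each site's
hit fraction is the proportion of windows covering it that are hits; maximal
runs of sites with hit fraction >= ``hit_threshold`` become segments when
they contain enough sites, span enough sequence, and have no inter-site gap
larger than ``max_gap``.  Segment bounds are site-defined (first/last SNP of
the run), never window-defined.

Length classes follow the three-way split used for wild canid genomes:
short [0.1, 1) Mb, medium [1, 10) Mb, long >= 10 Mb; segments below 0.1 Mb
are discarded (and tallied).  F_ROH is total ROH length over genome length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenomeLayout, VariantTable

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHSummary",
    "call_roh",
    "classify_length",
    "classify_and_summarize",
    "LENGTH_CLASSES",
]

logger = logging.getLogger(__name__)

# class name -> [lower, upper) bounds in bp; boundary values go to the upper
# class ("1 Mb to 10 Mb", ">10 Mb")
LENGTH_CLASSES: dict[str, tuple[int, float]] = {
    "short": (100_000, 1_000_000),
    "medium": (1_000_000, 10_000_000),
    "long": (10_000_000, float("inf")),
}


@dataclass(frozen=True)
class ROHParams:
    scan_snp_count: int = 50
    max_het_in_scan: int = 1
    max_missing_in_scan: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_length: int = 100_000
    max_gap: int = 1_000_000

    def __post_init__(self):
        if self.scan_snp_count < 1 or self.min_snps < 1 or self.min_length < 1:
            raise ValueError("scan_snp_count, min_snps and min_length must be >= 1")
        if self.max_het_in_scan < 0 or self.max_missing_in_scan < 0 or self.max_gap < 0:
            raise ValueError("counts and gaps must be nonnegative")
        if not (0 < self.hit_threshold <= 1):
            raise ValueError("hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run; start/end are 0-based half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_class(self) -> str | None:
        return classify_length(self.length)


def classify_length(length: int) -> str | None:
    """Length class name, or None for sub-threshold (<0.1 Mb) segments."""
    for name, (lo, hi) in LENGTH_CLASSES.items():
        if lo <= length < hi:
            return name
    return None


def call_roh(
    variants: VariantTable, sample: str, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Detect ROH for one sample.  Chromosomes with fewer sites than the
    scanning window are skipped with a warning (not an error)."""
    het = variants.het_mask(sample)
    called = variants.called_mask(sample)
    segments: list[ROHSegment] = []
    for chrom, _ in variants.layout.chromosomes:
        sl = variants.chrom_slice(chrom)
        pos = variants.pos[sl]
        n = len(pos)
        if n == 0:
            continue
        if n < params.scan_snp_count:
            logger.warning(
                "chromosome %s has %d sites < scan_snp_count %d; skipped for %s",
                chrom, n, params.scan_snp_count, sample,
            )
            continue
        qual = _qualifying_sites(het[sl], ~called[sl], params)
        segments.extend(_emit_runs(sample, chrom, pos, qual, params))
    return segments


def _qualifying_sites(
    is_het: np.ndarray, is_missing: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Boolean mask: site hit fraction >= hit_threshold."""
    n = len(is_het)
    w = params.scan_snp_count
    het_c = np.concatenate(([0], np.cumsum(is_het.astype(np.int64))))
    mis_c = np.concatenate(([0], np.cumsum(is_missing.astype(np.int64))))
    # window i covers sites [i, i+w); i in [0, n-w]
    het_in = het_c[w:] - het_c[:-w]
    mis_in = mis_c[w:] - mis_c[:-w]
    hit = (het_in <= params.max_het_in_scan) & (mis_in <= params.max_missing_in_scan)
    hit_c = np.concatenate(([0], np.cumsum(hit.astype(np.int64))))
    idx = np.arange(n)
    first = np.maximum(0, idx - w + 1)   # first window covering site
    last = np.minimum(idx, n - w)        # last window covering site
    n_cover = last - first + 1
    n_hit = hit_c[last + 1] - hit_c[first]
    return n_hit / n_cover >= params.hit_threshold


def _emit_runs(
    sample: str,
    chrom: str,
    pos: np.ndarray,
    qual: np.ndarray,
    params: ROHParams,
) -> list[ROHSegment]:
    segments: list[ROHSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and qual[j + 1]
            and pos[j + 1] - pos[j] <= params.max_gap
        ):
            j += 1
        n_snps = j - i + 1
        start = int(pos[i]) - 1
        end = int(pos[j])
        if n_snps >= params.min_snps and end - start >= params.min_length:
            segments.append(
                ROHSegment(sample_id=sample, chrom=chrom, start=start, end=end, n_snps=n_snps)
            )
        i = j + 1
    return segments


@dataclass
class ClassSummary:
    n_segments: int = 0
    summed_length: int = 0
    fraction_of_genome: float = 0.0


@dataclass
class ROHSummary:
    per_class: dict[str, ClassSummary]
    froh: float
    total_length: int
    n_discarded: int

    def as_dict(self) -> dict:
        return {
            "per_class": {
                k: {
                    "n_segments": v.n_segments,
                    "summed_length": v.summed_length,
                    "fraction_of_genome": v.fraction_of_genome,
                }
                for k, v in self.per_class.items()
            },
            "froh": self.froh,
            "total_length": self.total_length,
            "n_discarded": self.n_discarded,
        }


def classify_and_summarize(
    segments: list[ROHSegment], layout: GenomeLayout
) -> ROHSummary:
    """Three-class summary plus F_ROH.  Segments shorter than the 0.1-Mb
    class floor are excluded and counted in ``n_discarded``."""
    per_class = {name: ClassSummary() for name in LENGTH_CLASSES}
    n_discarded = 0
    total = 0
    for seg in segments:
        cls = classify_length(seg.length)
        if cls is None:
            n_discarded += 1
            continue
        per_class[cls].n_segments += 1
        per_class[cls].summed_length += seg.length
        total += seg.length
    genome = layout.total_length
    for cs in per_class.values():
        cs.fraction_of_genome = cs.summed_length / genome
    return ROHSummary(
        per_class=per_class,
        froh=total / genome,
        total_length=total,
        n_discarded=n_discarded,
    )
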