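"""Per-sample heterozygosity: sliding-window tracks and genome-wide rates.

A genotype is heterozygous iff its two allele indices differ, regardless of
which alleles are involved (multiallelic sites are not split).  Missing
genotypes never count as heterozygous; with a callability mask they are also
subtracted from the window denominator, otherwise the raw window length is
the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicWindow, VariantTable, merge_intervals

__all__ = [
    "WindowTrack",
    "window_heterozygosity",
    "per_site_heterozygosity",
    "plot_window_track",
]


@dataclass
class WindowTrack:
    """Windowed heterozygosity for one sample.

    ``windows`` has one row per window: chrom, start, end, n_het, n_called,
    callable_bp, het_per_kb.  ``het_per_kb`` is n_het over the callable
    window length in kb.
    """

    sample_id: str
    windows: pd.DataFrame

    def mean_het_per_kb(self) -> float:
        """Callable-length-weighted mean rate across windows."""
        bp = self.windows["callable_bp"].to_numpy(dtype=float)
        if bp.sum() == 0:
            return 0.0
        return float(self.windows["n_het"].sum() / bp.sum() * 1000.0)


def _masked_length(
    starts: np.ndarray, ends: np.ndarray, s: int, e: int
) -> int:
    """Total overlap of [s,e) with a merged, sorted interval set."""
    if len(starts) == 0:
        return 0
    lo = int(np.searchsorted(ends, s, side="right"))
    hi = int(np.searchsorted(starts, e, side="left"))
    total = 0
    for i in range(lo, hi):
        total += max(0, min(ends[i], e) - max(starts[i], s))
    return total


def window_heterozygosity(
    variants: VariantTable,
    sample: str,
    windows: Sequence[GenomicWindow],
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> WindowTrack:
    """Count heterozygous genotypes of *sample* in each window.

    A site at 1-based position p belongs to window [s, e) iff s <= p-1 < e.
    *mask* maps chromosome name to callable intervals (0-based half-open);
    when given, the per-window denominator is the masked length minus the
    sample's missing-genotype sites in the window, else the window length.
    """
    het = variants.het_mask(sample)
    called = variants.called_mask(sample)

    merged_mask = (
        {c: merge_intervals(iv) for c, iv in mask.items()} if mask is not None else None
    )

    rows = []
    # group windows by chromosome; site positions per chromosome are sorted
    for w in windows:
        sl = variants.chrom_slice(w.chrom)
        p0 = variants.pos[sl] - 1  # 0-based site coordinates
        lo = int(np.searchsorted(p0, w.start, side="left"))
        hi = int(np.searchsorted(p0, w.end, side="left"))
        n_het = int(het[sl][lo:hi].sum())
        n_called = int(called[sl][lo:hi].sum())
        n_missing = (hi - lo) - n_called
        if merged_mask is not None:
            iv = merged_mask.get(w.chrom, [])
            starts = np.array([s for s, _ in iv], dtype=np.int64)
            ends = np.array([e for _, e in iv], dtype=np.int64)
            callable_bp = max(0, _masked_length(starts, ends, w.start, w.end) - n_missing)
        else:
            callable_bp = w.length
        rate = n_het / callable_bp * 1000.0 if callable_bp > 0 else 0.0
        rows.append((w.chrom, w.start, w.end, n_het, n_called, callable_bp, rate))

    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_het", "n_called", "callable_bp", "het_per_kb"],
    )
    return WindowTrack(sample_id=sample, windows=df)


def plot_window_track(track: WindowTrack, path: str) -> None:
    """Minimal chromosome-panel rendering of a windowed heterozygosity track
    (one subplot per chromosome, het/kb against window midpoint)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = track.windows
    chroms = list(dict.fromkeys(df["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = df[df["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.fill_between(mid, sub["het_per_kb"], step="mid", color="#3b6ea5")
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_xlim(left=0)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle(f"{track.sample_id} heterozygosity (het/kb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def per_site_heterozygosity(
    variants: VariantTable, sample: str, callable_length: int
) -> float:
    """Genome-wide heterozygous genotypes per kb of callable sequence."""
    if callable_length <= 0:
        raise ValueError(f"callable_length must be positive, got {callable_length}")
    n_het = int(variants.het_mask(sample).sum())
    return n_het / callable_length * 1000.0
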