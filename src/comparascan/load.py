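"""Lineage-unique high-impact variants and derived damaging-genotype load.

Both statistics consume upstream annotations (impact category, deleterious
flag, ancestral allele) — nothing is predicted here.  "Derived" always
requires an explicit ancestral allele: the reference genome is an ingroup,
so the reference allele is never assumed ancestral.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpeciesPanel, VariantTable
from .private_scan import private_site_mask

__all__ = ["HighImpactReport", "LoadSummary", "unique_high_impact", "damaging_load"]


@dataclass
class HighImpactReport:
    """HIGH-impact variants private to one focal species, grouped by gene."""

    focal_species: str
    genes: set[str]
    variant_indices: list[int]  # row indices into the scanned VariantTable

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


@dataclass
class LoadSummary:
    sample_id: str
    n_damaging_hom_derived: int
    n_damaging_het_derived: int
    denominator: int  # deleterious sites with ancestral allele and a called genotype
    n_excluded_no_ancestral: int


def unique_high_impact(
    variants: VariantTable, focal: str, panel: SpeciesPanel
) -> HighImpactReport:
    """Variants annotated HIGH impact and private to *focal*, with the
    deduplicated set of genes they hit.  A table with no impact annotations
    at all is a hard error (check the configured impact INFO key)."""
    if all(v is None for v in variants.impact):
        raise ValueError(
            "no impact annotations found on any site; check the impact INFO key "
            "used when reading the VCF (default 'IMPACT')"
        )
    high = np.array([v == "HIGH" for v in variants.impact], dtype=bool)
    priv = private_site_mask(variants, focal, panel)
    idx = np.nonzero(high & priv)[0]
    genes = {
        variants.gene_id[i] for i in idx if variants.gene_id[i] is not None
    }
    return HighImpactReport(
        focal_species=focal, genes=genes, variant_indices=[int(i) for i in idx]
    )


def damaging_load(variants: VariantTable, sample: str) -> LoadSummary:
    """Count genotypes of *sample* at deleterious-annotated sites that are
    homozygous for an allele differing from the ancestral allele; derived
    heterozygotes are tallied separately.  Deleterious sites lacking an
    ancestral allele are excluded and tallied."""
    j = variants.sample_index(sample)
    g = variants.gt[:, j, :]
    called = (g >= 0).all(axis=1)

    delet = np.array([bool(d) for d in variants.deleterious], dtype=bool)
    anc_idx = np.array(
        [
            ((variants.ref[i],) + variants.alts[i]).index(variants.ancestral[i])
            if variants.ancestral[i] in ((variants.ref[i],) + variants.alts[i])
            else -1
            for i in range(len(variants))
        ],
        dtype=np.int32,
    )
    has_anc = anc_idx >= 0
    n_excluded = int((delet & ~has_anc).sum())

    usable = delet & has_anc & called
    hom = g[:, 0] == g[:, 1]
    hom_derived = usable & hom & (g[:, 0] != anc_idx)
    het_derived = usable & ~hom & ((g[:, 0] != anc_idx) | (g[:, 1] != anc_idx))
    return LoadSummary(
        sample_id=sample,
        n_damaging_hom_derived=int(hom_derived.sum()),
        n_damaging_het_derived=int(het_derived.sum()),
        denominator=int(usable.sum()),
        n_excluded_no_ancestral=n_excluded,
    )
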