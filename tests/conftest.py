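"""Shared fixtures: small hand-built panels and tables.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""
from __future__ import annotations

import numpy as np
import pytest

from comparascan.core import (
    GenomeLayout,
    SpeciesPanel,
    VariantSite,
    VariantTable,
)


@pytest.fixture
def layout():
    return GenomeLayout([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def panel():
    return SpeciesPanel(
        [
            ("bd1", "bush_dog"),
            ("bd2", "bush_dog"),
            ("mw1", "maned_wolf"),
            ("fx1", "fox"),
        ],
        focal_species=["bush_dog"],
    )


def build_table(sites, samples, layout) -> VariantTable:
    return VariantTable.from_sites(sites, samples, layout)


def site(chrom, pos, genotypes, ref="A", alts=("T",), **kw) -> VariantSite:
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), genotypes=tuple(genotypes), **kw
    )


@pytest.fixture
def random_fixture_table(layout, panel):
    """~400-site random table with annotations, for brute-force comparisons."""
    rng = np.random.default_rng(42)
    sites = []
    for chrom, clen in layout.chromosomes:
        n = 200
        positions = np.sort(rng.choice(np.arange(1, clen + 1), size=n, replace=False))
        for p in positions:
            genotypes = []
            for _ in panel.sample_ids:
                r = rng.random()
                if r < 0.05:
                    genotypes.append(None)
                elif r < 0.45:
                    genotypes.append((0, 0))
                elif r < 0.75:
                    genotypes.append((0, 1))
                else:
                    genotypes.append((1, 1))
            anc = ["A", "T", None][rng.integers(0, 3)]
            impact = [None, "HIGH", "MODERATE", "LOW", "MODIFIER"][rng.integers(0, 5)]
            delet = bool(rng.random() < 0.3) or None
            gene = f"g{rng.integers(0, 40):03d}" if rng.random() < 0.6 else None
            sites.append(
                site(
                    chrom,
                    int(p),
                    genotypes,
                    ancestral=anc,
                    impact=impact,
                    deleterious=delet,
                    gene_id=gene,
                )
            )
    return build_table(sites, panel.sample_ids, layout)
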