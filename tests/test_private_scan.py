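"""Flank windows, private-allele predicate, gene scan and gene-set ratios."""
import numpy as np
import pytest
from scipy import stats

from comparascan.core import GenomeLayout, SpeciesPanel, TranscriptModel
from comparascan.private_scan import (
    build_flank_windows,
    compare_gene_set,
    is_private,
    private_site_mask,
    scan_genes,
)
from comparascan.simulate import (
    SimulationConfig,
    SpeciesSpec,
    simulate_panel,
    simulate_transcriptome,
)
from tests.conftest import build_table, site


def tmodel(gene, chrom, start, end, strand="+"):
    return TranscriptModel(gene, f"t_{gene}", chrom, start, end, strand)


class TestFlankWindows:
    def test_plain_flanks(self, layout):
        # transcript body [10000, 20000) in 0-based coordinates
        fw = build_flank_windows([tmodel("g", "chr1", 10_001, 20_000)], 1000, layout)[0]
        assert [(w.start, w.end) for w in fw.windows] == [(9000, 10_000), (20_000, 21_000)]
        assert fw.total_length == 2000

    def test_upstream_clipped_at_chromosome_start(self, layout):
        fw = build_flank_windows([tmodel("g", "chr1", 201, 5000)], 1000, layout)[0]
        assert (fw.windows[0].start, fw.windows[0].end) == (0, 200)

    def test_downstream_clipped_at_chromosome_end(self, layout):
        fw = build_flank_windows([tmodel("g", "chr2", 499_001, 499_900)], 1000, layout)[0]
        assert (fw.windows[-1].start, fw.windows[-1].end) == (499_900, 500_000)
        # a transcript flush with the chromosome end loses that flank entirely
        fw2 = build_flank_windows([tmodel("g2", "chr2", 499_901, 500_000)], 1000, layout)[0]
        assert len(fw2.windows) == 1

    def test_short_transcript_flanks_remain_disjoint(self, layout):
        # flanks sit outside the body, so even a 500-bp transcript keeps two
        # non-overlapping windows; the merge step is a no-op here
        fw = build_flank_windows([tmodel("g", "chr1", 10_001, 10_500)], 1000, layout)[0]
        assert len(fw.windows) == 2
        a, b = fw.windows
        assert a.end <= b.start
        assert fw.total_length == 2000


class TestIsPrivate:
    def test_focal_only_alt_is_private(self, layout, panel):
        s = site("chr1", 10, [(0, 1), (0, 0), (0, 0), (0, 0)])
        assert is_private(s, "bush_dog", panel)

    def test_shared_alt_is_not_private(self, layout, panel):
        s = site("chr1", 10, [(0, 1), (0, 0), (0, 0), (0, 1)])
        assert not is_private(s, "bush_dog", panel)

    def test_all_other_species_missing_is_not_private(self, layout, panel):
        s = site("chr1", 10, [(0, 1), (0, 1), None, None])
        assert not is_private(s, "bush_dog", panel)

    def test_derived_reference_allele_can_be_private(self, layout, panel):
        # ancestral is the alt: the reference allele is derived, and only the
        # focal species carries it
        s = site("chr1", 10, [(0, 1), (1, 1), (1, 1), (1, 1)], ancestral="T")
        assert is_private(s, "bush_dog", panel)
        # without polarization the same site is not private (allele 1 shared)
        assert not is_private(s, "bush_dog", panel, polarized="never")

    def test_mask_agrees_with_per_site_predicate(self, random_fixture_table, panel):
        mask = private_site_mask(random_fixture_table, "bush_dog", panel)
        expected = [
            is_private(s, "bush_dog", panel) for s in random_fixture_table.sites()
        ]
        assert mask.tolist() == expected
        assert mask.any()  # fixture exercises both outcomes

    def test_simulated_background_sites_are_never_private(self):
        layout = GenomeLayout([("chr1", 2_000_000)])
        cfg = SimulationConfig(
            seed=3,
            layout=layout,
            species=[SpeciesSpec("a", 2, 1e-3), SpeciesSpec("b", 2, 1e-3)],
            focal_species=("a",),
        )
        table, truth = simulate_panel(cfg)
        panel = cfg.panel()
        assert truth.private_counts == {"a": 0, "b": 0}
        assert not private_site_mask(table, "a", panel).any()
        assert not private_site_mask(table, "b", panel).any()

    def test_every_injected_site_is_private(self):
        layout = GenomeLayout([("chr1", 2_000_000)])
        cfg = SimulationConfig(
            seed=4,
            layout=layout,
            species=[SpeciesSpec("a", 2, 5e-4), SpeciesSpec("b", 2, 5e-4)],
            focal_species=("a",),
            private_background_rate=5e-4,
        )
        table, truth = simulate_panel(cfg)
        mask = private_site_mask(table, "a", cfg.panel())
        injected = np.array([a is not None for a in table.ancestral])
        assert int(mask.sum()) == int(injected.sum()) == truth.private_counts["a"]
        assert (mask == injected).all()


class TestScanGenes:
    def make_scan_inputs(self, seed=5, enrichment=1.0, n_genes=200, rate=2e-3,
                         targets=0, length=4_000_000):
        layout = GenomeLayout([("chr1", length)])
        tr = simulate_transcriptome(layout, n_genes, seed=seed + 1)
        cfg = SimulationConfig(
            seed=seed,
            layout=layout,
            species=[
                SpeciesSpec("focal", 2, 2e-4),
                SpeciesSpec("bg1", 2, 2e-4),
                SpeciesSpec("bg2", 2, 2e-4),
            ],
            focal_species=("focal",),
            private_background_rate=rate,
            enrichment_factor=enrichment,
            target_genes=tuple(t.gene_id for t in tr[:targets]),
            transcripts=tr,
        )
        table, truth = simulate_panel(cfg)
        flanks = build_flank_windows(tr, 1000, layout)
        return table, flanks, cfg, truth

    def test_zero_private_gene_gets_p_one(self, layout, panel):
        t = build_table(
            [site("chr1", 10, [(0, 1), (0, 0), (0, 1), (0, 0)])],
            panel.sample_ids,
            layout,
        )
        flanks = build_flank_windows([tmodel("g", "chr1", 100_001, 102_000)], 1000, layout)
        rec = scan_genes(t, flanks, "bush_dog", panel)[0]
        assert rec.n_private_focal == 0
        assert rec.ratio == 0.0
        assert rec.p_value == 1.0
        assert not rec.significant

    def test_records_sorted_by_p_then_gene(self):
        table, flanks, cfg, _ = self.make_scan_inputs(targets=5, enrichment=10.0)
        recs = scan_genes(table, flanks, "focal", cfg.panel(), seed=0)
        keys = [(r.p_value, r.gene_id) for r in recs]
        assert keys == sorted(keys)

    def test_gene_private_sum_bounded_by_genome_total(self):
        table, flanks, cfg, truth = self.make_scan_inputs(targets=5, enrichment=5.0)
        recs = scan_genes(table, flanks, "focal", cfg.panel(), seed=0)
        assert sum(r.n_private_focal for r in recs) <= truth.private_counts["focal"]

    def test_alpha_one_marks_every_gene_significant(self):
        table, flanks, cfg, _ = self.make_scan_inputs()
        recs = scan_genes(table, flanks, "focal", cfg.panel(), alpha=1.0, seed=0)
        assert all(r.significant for r in recs)

    def test_enriched_targets_rank_first(self):
        table, flanks, cfg, _ = self.make_scan_inputs(targets=10, enrichment=10.0)
        recs = scan_genes(table, flanks, "focal", cfg.panel(), seed=0)
        top = {r.gene_id for r in recs[:10]}
        assert len(top & set(cfg.target_genes)) >= 8

    def test_permutation_and_binomial_agree_on_clear_signal(self):
        table, flanks, cfg, _ = self.make_scan_inputs(targets=10, enrichment=10.0)
        panel = cfg.panel()
        by_gene_b = {
            r.gene_id: r.significant
            for r in scan_genes(table, flanks, "focal", panel, seed=0)
        }
        by_gene_p = {
            r.gene_id: r.significant
            for r in scan_genes(
                table, flanks, "focal", panel, null="permutation", n_perm=2000, seed=0
            )
        }
        agree = sum(by_gene_b[g] == by_gene_p[g] for g in by_gene_b)
        assert agree / len(by_gene_b) >= 0.95


class TestCompareGeneSet:
    def test_single_gene_proportion_arithmetic(self, layout, panel):
        # 4 private focal sites and 16 total variable sites in the flanks
        sites = []
        for i in range(4):
            sites.append(site("chr1", 9_100 + i, [(0, 1), (0, 0), (0, 0), (0, 0)]))
        for i in range(12):
            sites.append(site("chr1", 9_200 + i, [(0, 0), (0, 0), (0, 1), (0, 1)]))
        t = build_table(sites, panel.sample_ids, layout)
        flanks = build_flank_windows([tmodel("g", "chr1", 10_001, 20_000)], 1000, layout)
        cmp_ = compare_gene_set(t, flanks, {"g"}, panel)
        assert cmp_.proportions["bush_dog"] == pytest.approx(4 / 16)

    def test_focal_only_injection_ranks_focal_first(self):
        layout = GenomeLayout([("chr1", 4_000_000)])
        tr = simulate_transcriptome(layout, 50, seed=11)
        cfg = SimulationConfig(
            seed=12,
            layout=layout,
            species=[SpeciesSpec("focal", 2, 5e-4), SpeciesSpec("bg", 2, 5e-4)],
            focal_species=("focal",),
            private_background_rate=0.0,
            target_flank_rate=5e-3,
            target_genes=tuple(t.gene_id for t in tr[:20]),
            transcripts=tr,
        )
        table, _ = simulate_panel(cfg)
        flanks = build_flank_windows(tr, 1000, layout)
        cmp_ = compare_gene_set(table, flanks, set(cfg.target_genes), cfg.panel())
        ranked = cmp_.ranked
        assert ranked[0][0] == "focal"
        assert ranked[0][1] > max(v for k, v in ranked[1:])

    def test_symmetric_rates_give_comparable_proportions(self):
        # identical private rates for every species; proportions should not
        # differ by more than 2x on average across replicate seeds
        layout = GenomeLayout([("chr1", 3_000_000)])
        tr = simulate_transcriptome(layout, 100, seed=21)
        totals = {"a": 0.0, "b": 0.0, "c": 0.0}
        for seed in range(10):
            cfg = SimulationConfig(
                seed=100 + seed,
                layout=layout,
                species=[
                    SpeciesSpec("a", 2, 5e-4),
                    SpeciesSpec("b", 2, 5e-4),
                    SpeciesSpec("c", 2, 5e-4),
                ],
                focal_species=("a",),
                private_species=("a", "b", "c"),
                private_background_rate=2e-3,
                transcripts=tr,
            )
            table, _ = simulate_panel(cfg)
            flanks = build_flank_windows(tr, 1000, layout)
            cmp_ = compare_gene_set(
                table, flanks, {t.gene_id for t in tr}, cfg.panel()
            )
            for k, v in cmp_.proportions.items():
                totals[k] += v
        assert max(totals.values()) / min(totals.values()) <= 2.0

    def test_focal_background_symmetry_in_ratio_distribution(self):
        # swapping which species is focal, with identical rates, leaves the
        # per-gene ratio distribution statistically indistinguishable
        layout = GenomeLayout([("chr1", 3_000_000)])
        tr = simulate_transcriptome(layout, 100, seed=31)
        flanks = None
        ratios = {}
        for focal in ("a", "b"):
            cfg = SimulationConfig(
                seed=55,
                layout=layout,
                species=[SpeciesSpec("a", 2, 5e-4), SpeciesSpec("b", 2, 5e-4)],
                focal_species=(focal,),
                private_species=("a", "b"),
                private_background_rate=2e-3,
                transcripts=tr,
            )
            table, _ = simulate_panel(cfg)
            flanks = build_flank_windows(tr, 1000, layout)
            recs = scan_genes(table, flanks, focal, cfg.panel(), seed=1)
            ratios[focal] = np.array([r.ratio for r in recs])
        ks = stats.ks_2samp(ratios["a"], ratios["b"])
        assert ks.pvalue > 0.01

    def test_empty_gene_set_is_an_error(self, random_fixture_table, panel, layout):
        flanks = build_flank_windows([tmodel("g", "chr1", 10_001, 20_000)], 1000, layout)
        with pytest.raises(ValueError, match="empty"):
            compare_gene_set(random_fixture_table, flanks, set(), panel)
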