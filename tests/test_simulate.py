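"""Simulator: determinism, rate recovery, truth-file conservation."""
import numpy as np
import pytest
from scipy import stats

from comparascan.core import GenomeLayout
from comparascan.private_scan import build_flank_windows
from comparascan.simulate import (
    ROHTract,
    SimulationConfig,
    SpeciesSpec,
    simulate_panel,
    simulate_transcriptome,
    write_simulation,
)


def one_chrom(length=10_000_000):
    return GenomeLayout([("chr1", length)])


def brute_force_private_counts(vcf_path):
    """Independent recount of per-species private-allele sites straight from
    the VCF text (no package parsing code)."""
    samples, species_of = [], {}
    records = []
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            records.append(line.rstrip("\n").split("\t"))
    return samples, records


def count_private(vcf_path, panel_path):
    samples, records = brute_force_private_counts(vcf_path)
    species_of = {}
    for line in open(panel_path):
        s, sp = line.strip().split("\t")
        species_of[s] = sp
    counts = {sp: 0 for sp in set(species_of.values())}
    for rec in records:
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, True)
            for kv in rec[7].split(";")
            if rec[7] != "."
        )
        alleles = [rec[3]] + rec[4].split(",")
        anc = info.get("AA")
        anc_idx = alleles.index(anc) if anc in alleles else -1
        carried = {}
        called_species = set()
        for s, gt in zip(samples, rec[9:]):
            if gt == "./.":
                continue
            sp = species_of[s]
            called_species.add(sp)
            for a in gt.split("/"):
                carried.setdefault(int(a), set()).add(sp)
        for sp in counts:
            if sp not in called_species or not (called_species - {sp}):
                continue
            for a, sps in carried.items():
                derived = (a != anc_idx) if anc_idx >= 0 else (a > 0)
                if derived and sps == {sp}:
                    counts[sp] += 1
                    break
    return counts


class TestSimulatePanel:
    def test_zero_rates_give_zero_heterozygotes(self):
        cfg = SimulationConfig(
            seed=1,
            layout=one_chrom(1_000_000),
            species=[SpeciesSpec("a", 2, 0.0), SpeciesSpec("b", 2, 0.0)],
        )
        table, truth = simulate_panel(cfg)
        assert len(table) == 0
        assert all(v == 0 for v in truth.het_genotype_counts.values())

    def test_het_site_count_matches_poisson_expectation(self):
        cfg = SimulationConfig(
            seed=5,
            layout=one_chrom(10_000_000),
            species=[SpeciesSpec("a", 1, 1e-3)],
        )
        table, truth = simulate_panel(cfg)
        mu = 1e-3 * 10_000_000
        n = truth.het_genotype_counts["a_1"]
        assert abs(n - mu) <= 3 * np.sqrt(mu)

    def test_flank_only_regime_puts_all_privates_in_target_flanks(self):
        layout = one_chrom(10_000_000)
        tr = simulate_transcriptome(layout, 40, seed=2)
        targets = tuple(t.gene_id for t in tr[:20])
        cfg = SimulationConfig(
            seed=3,
            layout=layout,
            species=[SpeciesSpec("focal", 2, 0.0), SpeciesSpec("bg", 2, 0.0)],
            focal_species=("focal",),
            private_background_rate=0.0,
            target_flank_rate=5e-3,
            target_genes=targets,
            transcripts=tr,
        )
        table, truth = simulate_panel(cfg)
        assert truth.private_counts["focal"] == len(table) > 0
        flanks = build_flank_windows(
            [t for t in tr if t.gene_id in set(targets)], 1000, layout
        )
        windows = [(w.chrom, w.start, w.end) for f in flanks for w in f.windows]
        for i in range(len(table)):
            p0 = int(table.pos[i]) - 1
            assert any(
                c == table.chrom_name(i) and s <= p0 < e for c, s, e in windows
            )

    def test_truth_private_counts_match_brute_force_recount(self, tmp_path):
        layout = one_chrom(2_000_000)
        tr = simulate_transcriptome(layout, 30, seed=4)
        cfg = SimulationConfig(
            seed=7,
            layout=layout,
            species=[
                SpeciesSpec("focal", 2, 5e-4),
                SpeciesSpec("bg1", 2, 1e-3),
                SpeciesSpec("bg2", 1, 5e-4),
            ],
            focal_species=("focal",),
            private_background_rate=3e-4,
            target_genes=tuple(t.gene_id for t in tr[:5]),
            enrichment_factor=10.0,
            damaging_fraction=0.4,
            transcripts=tr,
        )
        table, truth = simulate_panel(cfg)
        paths = write_simulation(tmp_path, cfg, table, truth)
        recount = count_private(paths["vcf"], paths["panel"])
        assert recount == truth.private_counts
        assert truth.private_counts["focal"] > 0
        assert truth.private_counts["bg1"] == truth.private_counts["bg2"] == 0

    def test_byte_identical_outputs_for_equal_seed(self, tmp_path):
        layout = one_chrom(1_000_000)
        tr = simulate_transcriptome(layout, 10, seed=9)

        def run(d):
            cfg = SimulationConfig(
                seed=13,
                layout=layout,
                species=[SpeciesSpec("a", 2, 1e-3), SpeciesSpec("b", 1, 5e-4)],
                focal_species=("a",),
                private_background_rate=2e-4,
                damaging_fraction=0.5,
                roh_plan=[ROHTract("a_1", "chr1", 200_000, 600_000)],
                transcripts=tr,
            )
            table, truth = simulate_panel(cfg)
            return write_simulation(d, cfg, table, truth)

        p1 = run(tmp_path / "r1")
        p2 = run(tmp_path / "r2")
        for key in ("vcf", "gff3", "chrom_lengths", "panel", "truth"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_tract_outside_chromosome_is_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            SimulationConfig(
                seed=1,
                layout=one_chrom(1_000_000),
                species=[SpeciesSpec("a", 1, 1e-3)],
                roh_plan=[ROHTract("a_1", "chr1", 500_000, 2_000_000)],
            )

    def test_overlapping_tracts_are_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            SimulationConfig(
                seed=1,
                layout=one_chrom(1_000_000),
                species=[SpeciesSpec("a", 1, 1e-3)],
                roh_plan=[
                    ROHTract("a_1", "chr1", 100_000, 400_000),
                    ROHTract("a_1", "chr1", 300_000, 500_000),
                ],
            )

    def test_forced_homozygosity_inside_tract(self):
        cfg = SimulationConfig(
            seed=21,
            layout=one_chrom(2_000_000),
            species=[SpeciesSpec("a", 2, 1e-3)],
            roh_plan=[ROHTract("a_1", "chr1", 500_000, 1_500_000)],
        )
        table, _ = simulate_panel(cfg)
        het = table.het_mask("a_1")
        inside = (table.pos - 1 >= 500_000) & (table.pos - 1 < 1_500_000)
        assert not het[inside].any()
        assert het[~inside].all()  # single-species sites are het outside


class TestSimulateTranscriptome:
    def test_zero_genes(self):
        assert simulate_transcriptome(one_chrom(), 0, seed=1) == []

    def test_fifty_genes_disjoint_with_flank_gaps(self):
        ts = simulate_transcriptome(one_chrom(10_000_000), 50, seed=3)
        assert len(ts) == 50
        ts_sorted = sorted(ts, key=lambda t: t.start)
        for a, b in zip(ts_sorted, ts_sorted[1:]):
            assert b.start - 1 - a.end >= 2000  # pairwise gap >= 2 kb
        assert ts_sorted[0].start - 1 >= 1000
        assert {t.strand for t in ts} <= {"+", "-"}

    def test_deterministic_under_seed(self):
        a = simulate_transcriptome(one_chrom(), 25, seed=8)
        b = simulate_transcriptome(one_chrom(), 25, seed=8)
        assert a == b

    def test_infeasible_count_reports_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible"):
            simulate_transcriptome(one_chrom(100_000), 1000, seed=1)
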