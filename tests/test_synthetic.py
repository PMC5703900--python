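"""Determinism, planted-truth bookkeeping, and sampling distributions."""

import numpy as np
import pytest

from enhancerscape.chip import bin_reads
from enhancerscape.expression_stats import collapse_replicates, nd_table
from enhancerscape.intervals import GenomicInterval
from enhancerscape.synthetic import (
    CONDITIONS,
    PlantedSite,
    PlantedTruth,
    SyntheticConfig,
    default_config,
    generate_genome_and_transcripts,
    intensity_segments,
    make_enhancer_plan,
    simulate_chip_reads,
    simulate_expression,
)


class TestConfig:
    def test_site_outside_chromosome_names_the_site(self):
        cfg = SyntheticConfig(
            chrom_sizes={"chr1": 10_000},
            enhancer_plan=[PlantedSite("chr1", 9_800, 500, 20.0)],
        )
        with pytest.raises(ValueError, match="chr1:9800"):
            cfg.validate()

    def test_fold_must_exceed_one(self):
        cfg = SyntheticConfig(
            chrom_sizes={"chr1": 10_000},
            enhancer_plan=[PlantedSite("chr1", 1_000, 500, 1.0)],
        )
        with pytest.raises(ValueError, match="fold"):
            cfg.validate()

    def test_dict_round_trip(self):
        cfg = default_config(5)
        back = SyntheticConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestGenomeGeneration:
    def test_empty_gene_counts_give_empty_transcript_list(self):
        cfg = SyntheticConfig(
            n_pcg=0, n_annot_lnc=0, n_novel_lnc=0, n_single_exon_decoys=0,
            n_short_decoys=0, n_coding_decoys=0, n_enhancer_lnc=0,
        )
        cfg.expression.n_specific_per_condition = 0
        cfg.tissue_plan.n_heart_genes = 0
        cfg.conservation_plan.n_conserved_genes = 0
        sizes, models, truth = generate_genome_and_transcripts(cfg)
        assert models == []
        assert sizes == cfg.chrom_sizes

    def test_decoy_bookkeeping_matches_config(self):
        cfg = default_config(2)
        cfg.n_novel_lnc = 10
        cfg.n_single_exon_decoys = 3
        cfg.n_short_decoys = 2
        cfg.n_coding_decoys = 1
        cfg.n_enhancer_lnc = 2
        _, models, truth = generate_genome_and_transcripts(cfg)
        assert len(truth.decoys["single_exon"]) == 3
        assert len(truth.decoys["short"]) == 2
        assert len(truth.decoys["coding_score"]) == 1
        by_id = {m.transcript_id: m for m in models}
        for tid in truth.decoys["single_exon"]:
            assert by_id[tid].n_exons == 1  # fails the >=2-exon filter
        for tid in truth.decoys["short"]:
            assert by_id[tid].length < 200
        for tid in truth.decoys["coding_score"]:
            assert by_id[tid].coding_score > 4

    def test_tss_is_strand_consistent(self, small_genome):
        _, models, _ = small_genome
        for m in models:
            if m.strand == "+":
                assert m.tss == m.exons[0].start
            else:
                assert m.tss == m.exons[-1].end - 1

    def test_truth_json_round_trip_lossless(self, small_genome):
        _, _, truth = small_genome
        back = PlantedTruth.from_json(truth.to_json())
        assert back == truth

    def test_planted_panels_reference_real_genes(self, small_genome):
        _, models, truth = small_genome
        gene_ids = {m.gene_id for m in models}
        for lst in truth.specific_genes.values():
            assert set(lst) <= gene_ids
        assert set(truth.heart_enriched) <= gene_ids
        assert set(truth.conserved_promoters) <= gene_ids


class TestChipSimulation:
    def test_same_seed_identical_reads(self, small_config, small_genome):
        _, _, truth = small_genome
        a = simulate_chip_reads(small_config, truth, "H3K27Ac", "ESC", 1)
        b = simulate_chip_reads(small_config, truth, "H3K27Ac", "ESC", 1)
        assert a.equals(b)

    def test_replicates_differ(self, small_config, small_genome):
        _, _, truth = small_genome
        a = simulate_chip_reads(small_config, truth, "H3K27Ac", "ESC", 1)
        b = simulate_chip_reads(small_config, truth, "H3K27Ac", "ESC", 2)
        assert not a.equals(b)

    def test_unknown_mark_or_condition_rejected(self, small_config, small_genome):
        _, _, truth = small_genome
        with pytest.raises(ValueError, match="mark"):
            simulate_chip_reads(small_config, truth, "H3K9me3", "ESC", 1)
        with pytest.raises(ValueError, match="condition"):
            intensity_segments(small_config, truth, "H3K27Ac", "mesoderm")

    def test_background_counts_poisson_dispersed(self):
        # no planted sites: per-bin counts with variance/mean in [0.8, 1.2]
        cfg = SyntheticConfig(
            seed=4, chrom_sizes={"chr1": 300_000}, reads_per_replicate=150_000,
            n_pcg=0, n_annot_lnc=0, n_novel_lnc=0, n_single_exon_decoys=0,
            n_short_decoys=0, n_coding_decoys=0, n_enhancer_lnc=0,
        )
        truth = PlantedTruth()
        reads = simulate_chip_reads(cfg, truth, "input", "ESC", 1)
        track = bin_reads(reads, cfg.chrom_sizes)
        c = track.counts["chr1"].astype(float)
        assert len(c) >= 10_000
        assert 0.8 <= c.var() / c.mean() <= 1.2

    def test_planted_site_enriched_about_foldfold(self):
        cfg = SyntheticConfig(
            seed=4, chrom_sizes={"chr1": 1_000_000}, reads_per_replicate=1_000_000,
            enhancer_plan=[PlantedSite("chr1", 10_000, 500, 20.0)],
            n_pcg=0, n_annot_lnc=0, n_novel_lnc=0, n_single_exon_decoys=0,
            n_short_decoys=0, n_coding_decoys=0, n_enhancer_lnc=0,
        )
        truth = PlantedTruth(enhancers=list(cfg.enhancer_plan))
        reads = simulate_chip_reads(cfg, truth, "H3K27Ac", "ESC", 1)
        track = bin_reads(reads, cfg.chrom_sizes)
        c = track.counts["chr1"]
        inside = c[10_000 // 25 : 10_500 // 25].mean()
        background = np.concatenate([c[: 9_000 // 25], c[12_000 // 25 :]]).mean()
        assert inside >= 10 * background

    def test_intensity_elevated_exactly_in_active_conditions(self, small_config,
                                                             small_genome):
        _, _, truth = small_genome
        bg = small_config.background_rate
        for site in truth.enhancers:
            mid = site.start + site.width // 2
            for cond in CONDITIONS:
                bounds, rates = intensity_segments(
                    small_config, truth, "H3K27Ac", cond
                )[site.chrom]
                rate = rates[np.searchsorted(bounds, mid, side="right") - 1]
                if cond in site.active_conditions:
                    assert rate == pytest.approx(bg * site.fold)
                else:
                    assert rate == pytest.approx(bg)

    def test_input_track_has_flat_intensity(self, small_config, small_genome):
        _, _, truth = small_genome
        for cond in CONDITIONS:
            segs = intensity_segments(small_config, truth, "input", cond)
            for bounds, rates in segs.values():
                assert (rates == small_config.background_rate).all()


class TestExpressionSimulation:
    def test_noiseless_heart_mean_is_fold_times_base(self, small_genome):
        cfg = default_config(3)
        cfg.expression.cv = 0.0
        cfg.tissue_plan.cv = 0.0
        cfg.tissue_plan.effect_fold = 8.0
        cfg.tissue_plan.base_mean = 5.0
        _, models, truth = small_genome
        _, panel = simulate_expression(cfg, truth, models)
        stranded = panel.T.groupby(level=[0, 1]).sum().T
        by_tissue = stranded.T.groupby(level=0).mean().T
        for g in truth.heart_enriched:
            assert by_tissue.loc[g, "heart"] == pytest.approx(40.0)
            assert by_tissue.loc[g, "liver"] == pytest.approx(5.0)

    def test_strand_counts_sum_to_gene_total(self, small_config, small_genome):
        _, models, truth = small_genome
        _, panel = simulate_expression(small_config, truth, models)
        plus = panel.xs("+", axis=1, level="strand")
        minus = panel.xs("-", axis=1, level="strand")
        total = plus + minus
        assert (total.to_numpy() >= plus.to_numpy()).all()
        # a noiseless rerun reproduces replicate-level totals exactly
        assert np.isfinite(total.to_numpy()).all()

    def test_condition_specific_gene_reaches_nd_bound(self, small_genome):
        cfg = default_config(3)
        cfg.expression.cv = 0.0
        cfg.expression.off_mean = 0.0
        _, models, truth = small_genome
        fpkm, _ = simulate_expression(cfg, truth, models)
        means = collapse_replicates(
            fpkm, {c: c.rsplit("_", 1)[0] for c in fpkm.columns}
        )
        nd = nd_table(means)
        for cond, genes in truth.specific_genes.items():
            for g in genes:
                assert nd[g] == pytest.approx(3.0)
                assert means.loc[g].idxmax() == cond

    def test_same_seed_identical_matrices(self, small_config, small_genome):
        _, models, truth = small_genome
        f1, p1 = simulate_expression(small_config, truth, models)
        f2, p2 = simulate_expression(small_config, truth, models)
        assert f1.equals(f2) and p1.equals(p2)


def test_make_enhancer_plan_cluster_geometry():
    plan = make_enhancer_plan({"chr1": 2_000_000}, seed=0, n_isolated=5, n_clusters=2)
    clusters = {}
    for s in plan:
        if s.se_cluster_id is not None:
            clusters.setdefault(s.se_cluster_id, []).append(s)
    assert len(clusters) == 2
    for sites in clusters.values():
        assert len(sites) >= 3
        span = max(x.start + x.width for x in sites) - min(x.start for x in sites)
        gaps = [
            b.start - (a.start + a.width)
            for a, b in zip(sorted(sites, key=lambda s: s.start),
                            sorted(sites, key=lambda s: s.start)[1:])
        ]
        assert all(g <= 12_500 for g in gaps)
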