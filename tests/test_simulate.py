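"""Ground-truth generator: construction guarantees, planted quantities and
determinism."""

import numpy as np
import pandas as pd
import pytest

from polterm.brdu import brdu_enrichment, smooth_moving_average
from polterm.simulate import (
    CHROM,
    SimulationScenario,
    simulate_brdu_counts,
    simulate_genome,
    simulate_junction_reads,
    simulate_point_coverage,
    simulate_tt_timecourse,
)


class TestGenome:
    def test_requested_spacing_is_respected(self):
        sc = SimulationScenario(seed=1, n_genes=20, gene_spacing=6000,
                                noise_model="none")
        genes, _ = simulate_genome(sc)
        assert len(genes) == 20
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end >= 6000

    def test_zone_placed_at_offset_downstream_of_tes(self, genome, noise_free):
        genes, zones = genome
        by_id = {g.gene_id: g for g in genes}
        for _, z in zones.iterrows():
            g = by_id[z["truth_gene_id"]]
            if g.strand == "+":
                assert z["start"] - g.tes == noise_free.ri_zone_offset
            else:
                assert g.tes - z["end"] == noise_free.ri_zone_offset

    def test_infeasible_packing_rejected(self):
        sc = SimulationScenario(seed=1, n_genes=50, chrom_length=100000)
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_genome(sc)

    def test_same_seed_identical_output(self):
        sc = SimulationScenario(seed=5, n_genes=10)
        g1, z1 = simulate_genome(sc)
        g2, z2 = simulate_genome(sc)
        assert g1 == g2
        pd.testing.assert_frame_equal(z1, z2)


class TestPointCoverage:
    def test_control_post_tes_decay_far_below_body(self, genome, noise_free):
        genes, _ = genome
        cov, _, _ = simulate_point_coverage(genes, noise_free, "control")
        g = genes[0]
        body = cov.region_mean(g.chrom, g.strand, g.start, g.end)
        a, b = g.downstream_interval(2400, 200)
        at_2500 = cov.region_mean(g.chrom, g.strand, a, b)
        assert at_2500 < 0.05 * body

    def test_planted_readthrough_plateau_amplitude(self):
        # flat promoter so the body mean is exactly the plateau density
        sc = SimulationScenario(seed=7, n_genes=20, noise_model="none",
                                pause_height=1.0)
        genes, _ = simulate_genome(sc)
        cov, _, _ = simulate_point_coverage(genes, sc, "perturbed")
        for i, g in enumerate(genes):
            if not sc.is_planted(i):
                continue
            body = cov.region_mean(g.chrom, g.strand, g.start, g.end)
            a, b = g.downstream_interval(0, 2500)
            dog = cov.region_mean(g.chrom, g.strand, a, b)
            assert dog / body == pytest.approx(0.5, rel=0.02)

    def test_spike_tallies_match_spike_fraction(self, genome, noise_free):
        genes, _ = genome
        _, spike, endo = simulate_point_coverage(genes, noise_free, "control")
        frac = spike / (spike + endo)
        assert frac == pytest.approx(noise_free.spike_fraction, rel=0.01)

    def test_poisson_body_mean_recovers_density(self):
        sc = SimulationScenario(seed=11, n_genes=100)
        genes, _ = simulate_genome(sc)
        cov, _, _ = simulate_point_coverage(genes, sc, "control")
        means, n_bins_total = [], 0
        for g in genes:
            b0, b1 = g.tss_interval(sc.pause_width, g.length - sc.pause_width)
            means.append(cov.region_mean(g.chrom, g.strand, b0, b1))
            n_bins_total += (b1 - b0)
        expected = sc.body_density + sc.background_density
        se = np.sqrt(expected / n_bins_total)
        assert abs(np.mean(means) - expected) < 3 * se

    def test_same_seed_identical_coverage(self, scenario):
        genes, _ = simulate_genome(scenario)
        c1, s1, e1 = simulate_point_coverage(genes, scenario, "control")
        c2, s2, e2 = simulate_point_coverage(genes, scenario, "control")
        assert (s1, e1) == (s2, e2)
        for key in c1.values:
            assert np.array_equal(c1.values[key], c2.values[key])


class TestTimecourse:
    def test_wave_suppresses_up_to_front(self):
        sc = SimulationScenario(seed=3, n_genes=4, gene_length=100000,
                                noise_model="none")
        genes, _ = simulate_genome(sc)
        tracks, truth = simulate_tt_timecourse(genes, sc)
        g = genes[0]
        treated = tracks[30.0]
        s0, s1 = g.tss_interval(0, 60000)
        i0, i1 = g.tss_interval(60000, 40000)
        body = sc.body_density
        assert treated.region_mean(g.chrom, g.strand, s0, s1) < 0.1 * body
        assert treated.region_mean(g.chrom, g.strand, i0, i1) == pytest.approx(
            body + sc.background_density)
        assert set(truth.truth_front_bp) == {60000.0}

    def test_time_zero_matches_untreated_profile(self):
        sc = SimulationScenario(seed=3, n_genes=4, gene_length=100000,
                                noise_model="none")
        genes, _ = simulate_genome(sc)
        tracks, _ = simulate_tt_timecourse(
            genes, sc.with_overrides(nvp2_times=(0.0,)))
        t0 = tracks[0.0]
        for key in t0.values:
            assert np.array_equal(t0.values[key], tracks[0.0].values[key])
        g = genes[0]
        assert t0.region_mean(g.chrom, g.strand, g.start, g.end) == pytest.approx(
            sc.body_density + sc.background_density)

    def test_front_clamped_at_gene_end(self):
        sc = SimulationScenario(seed=3, n_genes=4, gene_length=40000,
                                noise_model="none")
        genes, _ = simulate_genome(sc)
        tracks, truth = simulate_tt_timecourse(genes, sc)  # v*t = 60 kb
        assert set(truth.truth_front_bp) == {40000.0}
        g = genes[0]
        assert tracks[30.0].region_mean(g.chrom, g.strand, g.start, g.end) \
            == pytest.approx(sc.residual_fraction * sc.body_density
                             + sc.background_density)


class TestJunctionReads:
    def test_full_splicing_gaps_every_read(self, genome):
        genes, _ = genome
        sc = SimulationScenario(seed=2, n_genes=20, spliced_fraction=1.0,
                                n_junction_reads=500)
        reads = simulate_junction_reads(genes, sc)
        assert reads["blocks"].str.contains(";").all()

    def test_sampled_fraction_near_planted(self, genome):
        genes, _ = genome
        sc = SimulationScenario(seed=2, n_genes=20, spliced_fraction=0.7,
                                n_junction_reads=10000)
        reads = simulate_junction_reads(genes, sc)
        frac = reads["blocks"].str.contains(";").mean()
        assert frac == pytest.approx(0.7, abs=0.02)

    def test_enumeration_mode_exact(self, genome):
        genes, _ = genome
        sc = SimulationScenario(seed=2, n_genes=20, spliced_fraction=0.7,
                                n_junction_reads=1000)
        reads = simulate_junction_reads(genes, sc, mode="enumerate")
        assert reads["blocks"].str.contains(";").mean() == 0.7

    def test_single_exon_genes_skipped_with_warning(self, noise_free):
        from polterm.core import GeneModel
        lonely = [GeneModel("solo", CHROM, 1000, 3000, "+", exons=((1000, 3000),))]
        with pytest.warns(UserWarning, match="< 2 exons"):
            reads = simulate_junction_reads(lonely, noise_free)
        assert len(reads) == 0

    def test_seed_fixes_read_table(self, genome, scenario):
        genes, _ = genome
        r1 = simulate_junction_reads(genes, scenario)
        r2 = simulate_junction_reads(genes, scenario)
        pd.testing.assert_frame_equal(r1, r2)


class TestBrdUCounts:
    def test_uniform_timing_gives_flat_enrichment(self):
        sc = SimulationScenario(seed=9, early_enrichment=1.0, ci_mean=50.0)
        cb, ci = simulate_brdu_counts(2_000_000, sc, "control")
        track = brdu_enrichment(cb, ci)
        smoothed = smooth_moving_average(track.eb, m=10)
        med = np.nanmedian(np.abs(smoothed - 1.0))
        assert med < 0.1

    def test_early_enrichment_ratio_recovered(self):
        sc = SimulationScenario(seed=9, early_enrichment=3.0, ci_mean=50.0)
        L = 2_000_000
        cb, ci = simulate_brdu_counts(L, sc, "control")
        track = brdu_enrichment(cb, ci)
        from polterm.simulate import replication_weights
        w = replication_weights(sc, cb.size)
        early = w > 1
        ratio = np.nanmean(track.eb[early]) / np.nanmean(track.eb[~early])
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_same_seed_identical_counts(self, scenario):
        a = simulate_brdu_counts(500000, scenario, "perturbed",
                                 defective_regions=[(10000, 20000)])
        b = simulate_brdu_counts(500000, scenario, "perturbed",
                                 defective_regions=[(10000, 20000)])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_attenuation_lowers_defective_bins(self):
        sc = SimulationScenario(seed=9, early_enrichment=1.0, noise_model="none")
        cb_c, _ = simulate_brdu_counts(200000, sc, "control")
        cb_p, _ = simulate_brdu_counts(200000, sc, "perturbed",
                                       defective_regions=[(50000, 60000)])
        assert np.all(cb_p[50:60] < cb_c[50:60])
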