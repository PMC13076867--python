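"""Termination index, pausing index, elongation index, splicing efficiency
and metagene geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polterm.core import GeneModel, StrandedCoverage
from polterm.metrics import (
    TerminationComparison,
    classify_ndt_nit,
    elongation_index_profile,
    metagene_matrix,
    pausing_index,
    quantify_region,
    splicing_efficiency,
    termination_index,
)
from polterm.simulate import SimulationScenario, simulate_genome, simulate_point_coverage


def _flat_coverage(value=1.0, n_bins=2000, bin_width=10, both_strands=True):
    cov = StrandedCoverage(bin_width=bin_width)
    cov.set_track("chr1", "+", np.full(n_bins, float(value)))
    if both_strands:
        cov.set_track("chr1", "-", np.full(n_bins, float(value)))
    return cov


class TestQuantifyRegion:
    def test_library_normalized_density(self):
        cov = StrandedCoverage(bin_width=10)
        cov.set_track("chr1", "+", np.full(250, 0.4))  # 1000 counts over 2500 bp
        d = quantify_region(cov, "chr1", "+", 0, 2500, library_total=5e7, per=1e8)
        assert d == pytest.approx(0.8)

    def test_region_outside_data_is_zero(self):
        cov = _flat_coverage()
        assert quantify_region(cov, "chr1", "+", 10**6, 10**6 + 100) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            quantify_region(_flat_coverage(), "chr1", "+", 100, 100)

    def test_invariant_to_bin_refinement(self):
        vals = np.repeat([1.0, 3.0, 2.0], 40)
        coarse = StrandedCoverage(bin_width=30)
        coarse.set_track("chr1", "+", np.repeat([1.0, 3.0, 2.0], 4))
        fine = StrandedCoverage(bin_width=10)
        fine.set_track("chr1", "+", np.repeat([1.0, 3.0, 2.0], 12))
        assert quantify_region(coarse, "chr1", "+", 0, 360) == pytest.approx(
            quantify_region(fine, "chr1", "+", 0, 360))


class TestTerminationIndex:
    def test_uniform_track_gives_zero(self):
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        call = termination_index(_flat_coverage(2.0), g)
        assert call.ti == pytest.approx(0.0, abs=1e-12)

    def test_quarter_ratio_gives_minus_two(self):
        cov = StrandedCoverage(bin_width=10)
        track = np.zeros(2000)
        track[200:1200] = 0.4        # body [2000, 12000)
        track[1200:1450] = 0.1       # DoG [12000, 14500)
        cov.set_track("chr1", "+", track)
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        assert termination_index(cov, g).ti == pytest.approx(-2.0, abs=1e-12)

    def test_minus_strand_dog_extends_genomically_left(self):
        cov = StrandedCoverage(bin_width=10)
        track = np.zeros(2000)
        track[500:1500] = 0.4        # body [5000, 15000)
        track[250:500] = 0.1         # DoG [2500, 5000)
        cov.set_track("chr1", "-", track)
        g = GeneModel("g", "chr1", 5000, 15000, "-")
        assert termination_index(cov, g).ti == pytest.approx(-2.0, abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_global_rescaling(self, scalar):
        cov = StrandedCoverage(bin_width=10)
        rng = np.random.default_rng(1)
        cov.set_track("chr1", "+", rng.random(2000) + 0.1)
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        base = termination_index(cov, g).ti
        scaled = termination_index(cov.scaled(scalar, "spike-scaled"), g).ti
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_body_flagged_unclassifiable(self):
        cov = StrandedCoverage(bin_width=10)
        track = np.zeros(2000)
        track[1200:1300] = 1.0
        cov.set_track("chr1", "+", track)
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        call = termination_index(cov, g)
        assert math.isnan(call.ti) and not call.ok

    def test_zero_dog_gives_minus_infinity_sentinel(self):
        cov = StrandedCoverage(bin_width=10)
        track = np.zeros(2000)
        track[200:1200] = 1.0
        cov.set_track("chr1", "+", track)
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        call = termination_index(cov, g)
        assert call.ti == -math.inf and not call.ok

    def test_perturbed_ti_exceeds_control_on_simulation(self):
        sc = SimulationScenario(seed=21, n_genes=100, perturbed_fraction=1.0)
        genes, _ = simulate_genome(sc)
        ctrl, _, _ = simulate_point_coverage(genes, sc, "control")
        pert, _, _ = simulate_point_coverage(genes, sc, "perturbed")
        wins = sum(
            termination_index(pert, g).ti > termination_index(ctrl, g).ti
            for g in genes
        )
        assert wins >= 99

    def test_monotone_in_readthrough_amplitude(self):
        tis = []
        for amp in (0.1, 0.3, 0.5, 0.8):
            sc = SimulationScenario(seed=3, n_genes=4, noise_model="none",
                                    readthrough_amplitude=amp,
                                    perturbed_fraction=1.0)
            genes, _ = simulate_genome(sc)
            cov, _, _ = simulate_point_coverage(genes, sc, "perturbed")
            tis.append(termination_index(cov, genes[0]).ti)
        assert tis == sorted(tis)
        assert len(set(tis)) == len(tis)


class TestClassifyNdtNit:
    def test_strict_threshold_boundary(self):
        comps = [
            TerminationComparison("a", ti_control=-2.0, ti_perturbed=0.0),
            TerminationComparison("b", ti_control=-2.0, ti_perturbed=-1.0),
            TerminationComparison("c", ti_control=math.nan, ti_perturbed=0.0),
        ]
        out = classify_ndt_nit(comps, delta_threshold=1.0)
        assert [c.label for c in out] == ["NDT", "NIT", "unclassified"]


class TestPausingIndex:
    def test_uniform_coverage_gives_unity(self):
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        call = pausing_index(_flat_coverage(3.0), g, pause_window=300)
        assert call.pausing_index == pytest.approx(1.0)

    def test_boxcar_fold_recovered_exactly(self):
        cov = StrandedCoverage(bin_width=10)
        track = np.ones(2000)
        track[200:230] = 10.0        # [2000, 2300) = pause window
        cov.set_track("chr1", "+", track)
        g = GeneModel("g", "chr1", 2000, 12000, "+")
        call = pausing_index(cov, g, pause_window=300)
        assert call.pausing_index == pytest.approx(10.0)

    def test_simulated_pause_height_recovered(self):
        sc = SimulationScenario(seed=5, n_genes=4, noise_model="none")
        genes, _ = simulate_genome(sc)
        cov, _, _ = simulate_point_coverage(genes, sc, "control")
        for g in genes:
            call = pausing_index(cov, g, pause_window=sc.pause_width)
            assert call.pausing_index == pytest.approx(sc.pause_height, rel=0.05)

    def test_gene_shorter_than_window_rejected(self):
        g = GeneModel("g", "chr1", 0, 200, "+")
        with pytest.raises(ValueError, match="shorter than pause window"):
            pausing_index(_flat_coverage(), g, pause_window=300)


class TestElongationIndex:
    @staticmethod
    def _genes():
        return [GeneModel("a", "chr1", 2000, 12000, "+"),
                GeneModel("b", "chr1", 14000, 19000, "-")]

    def test_constant_ratio_gives_flat_profile(self):
        tt = _flat_coverage(4.0)
        point = _flat_coverage(2.0)
        prof = elongation_index_profile(tt, point, self._genes(), n_bins=40)
        assert np.allclose(prof.profile, 2.0)

    def test_zero_occupancy_bin_masked_locally(self):
        tt = _flat_coverage(4.0)
        point = _flat_coverage(2.0)
        point.track("chr1", "+")[200:225] = 0.0  # first body bin of gene a
        prof = elongation_index_profile(tt, point, self._genes(), n_bins=40)
        assert prof.mask[0, 0]
        assert not prof.mask[0, 1:].any() and not prof.mask[1].any()
        assert np.allclose(prof.matrix[0, 1:], 2.0)

    def test_halved_occupancy_doubles_ei(self):
        tt = _flat_coverage(4.0)
        full = _flat_coverage(2.0)
        half = _flat_coverage(1.0)
        p_full = elongation_index_profile(tt, full, self._genes()).profile
        p_half = elongation_index_profile(tt, half, self._genes()).profile
        assert np.allclose(p_half / p_full, 2.0, rtol=0.05)


class TestSplicing:
    @staticmethod
    def _reads(n_gapped, n_plain):
        rows = []
        for i in range(n_gapped):
            rows.append((f"g{i}", "chr1", 950, 1550, "+", "950-1000;1500-1550"))
        for i in range(n_plain):
            rows.append((f"p{i}", "chr1", 950, 1050, "+", "950-1050"))
        return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end",
                                           "strand", "blocks"])

    @staticmethod
    def _unit(strand="+"):
        return pd.DataFrame([("u", "chr1", 900, 1600, strand)],
                            columns=["name", "chrom", "start", "end", "strand"])

    def test_seven_of_ten_gives_point_seven(self):
        (call,) = splicing_efficiency(self._reads(7, 3), self._unit())
        assert call.efficiency == pytest.approx(0.7)

    def test_all_gapped_gives_one(self):
        (call,) = splicing_efficiency(self._reads(5, 0), self._unit())
        assert call.efficiency == 1.0

    def test_strand_mismatch_excluded_and_zero_total_flagged(self):
        (call,) = splicing_efficiency(self._reads(7, 3), self._unit(strand="-"))
        assert call.total_reads == 0 and not call.ok
        assert math.isnan(call.efficiency)


class TestMetagene:
    @staticmethod
    def _regions():
        return pd.DataFrame(
            [("chr1", 2000, 6000, "+"), ("chr1", 10000, 16000, "-")],
            columns=["chrom", "start", "end", "strand"],
        )

    def test_flat_input_gives_flat_profile(self):
        _, prof = metagene_matrix(_flat_coverage(3.0), self._regions(),
                                  body_bins=40, up_bins=10, down_bins=10)
        assert np.allclose(prof, 3.0)

    def test_matrix_width_is_exact(self):
        m, prof = metagene_matrix(_flat_coverage(), self._regions(),
                                  body_bins=40, up_bins=25, down_bins=15)
        assert m.shape == (2, 80) and prof.size == 80

    def test_mirrored_minus_region_matches_plus_row(self):
        rng = np.random.default_rng(2)
        vals = rng.random(400)
        cov = StrandedCoverage(bin_width=10)
        cov.set_track("chr1", "+", vals)
        cov.set_track("chr1", "-", vals[::-1])
        # region on '-' mirrored around the track midpoint (4000 bp total)
        regions = pd.DataFrame(
            [("chr1", 1000, 2000, "+"), ("chr1", 2000, 3000, "-")],
            columns=["chrom", "start", "end", "strand"],
        )
        m, _ = metagene_matrix(cov, regions, body_bins=50, up_bins=20,
                               down_bins=30)
        assert np.allclose(m[0], m[1])
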