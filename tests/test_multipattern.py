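"""Multi-pattern detection: reciprocal mapping, DDV histograms, AMPD,
baseline fit, Ewald cap and the K statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshcarto.core import AnalysisConfig
from meshcarto.multipattern import (
    ampd_local_minima,
    baseline_slope,
    classify_multipattern,
    cumulative_histogram,
    ddv_histogram,
    ewald_cap_area,
    k_statistic,
    spots_to_reciprocal,
)
from meshcarto.simulate import (
    CrystalSpec,
    SimulationConfig,
    simulate_mesh,
    typical_mx_geometry,
)


class TestSpotsToReciprocal:
    def test_beam_centre_maps_to_origin(self, geometry):
        q = spots_to_reciprocal(np.array([[*geometry.beam_centre, 1.0]]), geometry)
        assert np.allclose(q, 0.0, atol=1e-15)

    def test_two_theta_30_degrees_oracle(self, geometry):
        """Hand trigonometry: at 2theta = 30 deg and lambda = 1 A,
        |q| = 2 sin(15 deg) = 0.51764."""
        r_mm = geometry.detector_distance * np.tan(np.radians(30.0))
        px, py = geometry.beam_centre
        spot = np.array([[px + r_mm / geometry.pixel_size, py, 1.0]])
        q = spots_to_reciprocal(spot, geometry)
        assert np.linalg.norm(q[0]) == pytest.approx(
            2.0 * np.sin(np.radians(15.0)), rel=1e-10
        )

    def test_q_length_invariant_under_azimuthal_rotation(self, geometry):
        px, py = geometry.beam_centre
        r = 300.0  # pixels
        lengths = []
        for ang in np.linspace(0, 2 * np.pi, 7, endpoint=False):
            spot = np.array([[px + r * np.cos(ang), py + r * np.sin(ang), 1.0]])
            lengths.append(np.linalg.norm(spots_to_reciprocal(spot, geometry)))
        assert np.ptp(lengths) < 1e-12


class TestDDVHistogram:
    def test_single_pair_bin_arithmetic(self):
        """|q1-q2| = 0.0102 with 100 bins over [0, 0.04) lands in bin 25."""
        q = np.array([[0.0, 0.0, 0.0], [0.0102, 0.0, 0.0]])
        hist = ddv_histogram(q, bins=100, hist_max=0.04)
        assert hist.counts.sum() == 1
        assert hist.counts[25] == 1

    def test_identical_vectors_fill_bin_zero(self):
        q = np.tile([[0.01, 0.02, 0.0]], (7, 1))
        hist = ddv_histogram(q)
        assert hist.counts[0] == 7 * 6 // 2
        assert hist.counts[1:].sum() == 0

    def test_matches_brute_force_pair_oracle(self):
        rng = np.random.default_rng(12)
        q = rng.uniform(-0.03, 0.03, size=(50, 3))
        hist = ddv_histogram(q, bins=100, hist_max=0.04)
        oracle = np.zeros(100, dtype=int)
        width = 0.04 / 100
        for i in range(50):
            for j in range(i + 1, 50):
                length = np.linalg.norm(q[i] - q[j])
                if length < 0.04:
                    oracle[int(length // width)] += 1
        assert np.array_equal(hist.counts, oracle)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_counts_conservation(self, seed, n):
        """Histogram counts plus overflow equal C(N,2) exactly."""
        rng = np.random.default_rng(seed)
        q = rng.uniform(-0.05, 0.05, size=(n, 3))
        hist = ddv_histogram(q, bins=100, hist_max=0.04)
        from scipy.spatial.distance import pdist

        overflow = int((pdist(q) >= 0.04).sum())
        assert hist.counts.sum() + overflow == n * (n - 1) // 2

    def test_cumulative_equals_sum_of_node_histograms(self, three_crystal_scan, config):
        scan, _, _ = three_crystal_scan
        total = cumulative_histogram(scan, config)
        oracle = np.zeros(config.hist_bins, dtype=int)
        for node in scan:
            arr = node.spot_array()
            if len(arr) < 2:
                continue
            q = spots_to_reciprocal(arr, scan.geometry)
            oracle += ddv_histogram(q, config.hist_bins, config.hist_max).counts
        assert np.array_equal(total.counts, oracle)


class TestAMPD:
    def test_sine_minima_match_brute_force_oracle(self):
        k = np.arange(100)
        signal = np.sin(2 * np.pi * k / 20)
        # exhaustive oracle on the noiseless signal
        oracle = [
            i
            for i in range(1, 99)
            if signal[i] < signal[i - 1] and signal[i] < signal[i + 1]
        ]
        assert oracle == [15, 35, 55, 75, 95]
        assert list(ampd_local_minima(signal)) == oracle

    def test_strictly_increasing_has_no_minima(self):
        assert len(ampd_local_minima(np.arange(50.0))) == 0

    def test_flat_signal_has_no_minima(self):
        assert len(ampd_local_minima(np.full(64, 3.0))) == 0

    @pytest.mark.parametrize("trial", range(5))
    def test_small_noise_keeps_minima_count(self, trial):
        k = np.arange(100)
        signal = np.sin(2 * np.pi * k / 20)
        rng = np.random.default_rng(trial)
        noisy = signal + 0.01 * rng.standard_normal(100)
        assert len(ampd_local_minima(noisy)) == 5

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ampd_local_minima(np.array([1.0, 2.0, 1.0]))


class TestBaselineSlope:
    def _hist(self, counts):
        from meshcarto.multipattern import DDVHistogram

        edges = np.linspace(0, 0.04, len(counts) + 1)
        return DDVHistogram(edges, np.asarray(counts))

    def test_exact_line_recovered(self):
        centres = np.linspace(0, 0.04, 101)
        centres = 0.5 * (centres[:-1] + centres[1:])
        counts = 5 + 1000.0 * centres
        hist = self._hist(counts)
        slope = baseline_slope(hist, np.arange(100), fit_range=(1e-3, 40e-3))
        assert slope == pytest.approx(1000.0, rel=1e-9)

    def test_constant_counts_give_zero_slope(self):
        slope = baseline_slope(self._hist(np.full(100, 7.0)), np.arange(100))
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_ols_oracle(self):
        counts = np.zeros(100)
        bins = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 95])
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        counts[bins] = values
        hist = self._hist(counts)
        x = hist.bin_centres[bins]
        xbar, ybar = x.mean(), values.mean()
        oracle = ((x - xbar) * (values - ybar)).sum() / ((x - xbar) ** 2).sum()
        assert baseline_slope(hist, bins) == pytest.approx(oracle, rel=1e-12)

    def test_too_few_bins_is_invalid(self):
        hist = self._hist(np.zeros(100))
        assert baseline_slope(hist, np.array([50, 51])) is None


class TestEwaldCap:
    def test_forward_scattering_limit(self):
        q = np.array([[1e-9, 0, 0]])
        assert ewald_cap_area(q, 1.0) < 1e-15

    def test_right_angle_closed_form(self):
        # 2theta = 90 deg: |q| = 2 sin 45 = sqrt(2); S = 2 pi
        q = np.array([[np.sqrt(2), 0.0, 0.0]])
        assert ewald_cap_area(q, 1.0) == pytest.approx(2 * np.pi, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_oracle(self, seed):
        from scipy.integrate import quad

        rng = np.random.default_rng(seed)
        q = rng.uniform(-0.3, 0.3, size=(25, 3))
        lam = 0.97
        s = ewald_cap_area(q, lam)
        two_theta_max = 2 * np.arcsin(np.linalg.norm(q, axis=1).max() * lam / 2)
        oracle, _ = quad(lambda t: 2 * np.pi * np.sin(t) / lam**2, 0, two_theta_max)
        assert s == pytest.approx(oracle, rel=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ewald_cap_area(np.empty((0, 3)), 1.0)


class TestKStatistic:
    def test_zero_slope_gives_zero(self):
        assert k_statistic(0.0, 100, 1.0) == 0.0

    def test_direct_substitution(self):
        assert k_statistic(2.0, 200, 0.5) == pytest.approx(2.5e-5, rel=1e-12)

    def test_linear_in_slope(self):
        assert k_statistic(4.0, 150, 0.8) == pytest.approx(
            2 * k_statistic(2.0, 150, 0.8), rel=1e-12
        )

    def test_invariant_under_spot_reordering(self, single_lattice_image, geometry,
                                             config):
        spots, _, _ = single_lattice_image
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(spots))
        for arr in (spots, spots[perm]):
            q = spots_to_reciprocal(arr, geometry)
            hist = ddv_histogram(q, config.hist_bins, config.hist_max)
            s = ewald_cap_area(q, geometry.wavelength)
        q0 = spots_to_reciprocal(spots, geometry)
        h0 = ddv_histogram(q0, config.hist_bins, config.hist_max)
        assert np.array_equal(hist.counts, h0.counts)
        assert s == ewald_cap_area(q0, geometry.wavelength)


class TestClassify:
    def test_single_lattice_nodes_not_flagged(self, three_crystal_scan, config):
        scan, _, _ = three_crystal_scan
        results = classify_multipattern(scan, config)
        flagged = [k for k, v in results.items() if v.is_multipattern]
        assert flagged == []

    def test_overlap_nodes_flagged_exactly(self, satellite_scan, config):
        scan, truth, _ = satellite_scan
        results = classify_multipattern(scan, config)
        flagged = sorted(k for k, v in results.items() if v.is_multipattern)
        overlap = sorted(k for k, v in truth.contributors.items() if len(v) == 2)
        assert flagged == overlap

    def test_empty_spot_list_is_invalid(self, config):
        geom = typical_mx_geometry(grid_shape=(2, 2))
        spec = CrystalSpec(centre=(0, 0), semi_axes=(0.5, 0.5), peak_score=5)
        scan, _ = simulate_mesh(SimulationConfig(geometry=geom, crystals=[spec]))
        results = classify_multipattern(scan, config)
        assert not results[(1, 1)].valid
        assert not results[(1, 1)].is_multipattern
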