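"""Smoothness estimation, RFT thresholds, clustering and the pipeline."""

import numpy as np
import pytest
from scipy import integrate, ndimage, optimize, stats
from scipy.special import gammaln

from athresh import evaluation, mixture, simulation, topology
from athresh.exceptions import InputError, NumericError, ParameterError
from conftest import flood_fill_components


class TestSmoothness:
    def test_white_noise_fwhm(self):
        # independent unit voxels: first-difference variance 2
        frames = np.random.default_rng(0).standard_normal((30, 64, 64))
        est = topology.estimate_smoothness(frames, df=28)
        expected = np.sqrt(4 * np.log(2) / 2)
        assert np.allclose(est.fwhm, expected, atol=0.05)

    def test_recovers_generating_kernel_width(self, replicate08):
        est = replicate08["smoothness"]
        assert np.all(est.fwhm > 5.4) and np.all(est.fwhm < 6.6)

    def test_resels_halve_when_fwhm_doubles(self):
        a = topology.box_smoothness((64, 64), 6.0, 78)
        b = topology.box_smoothness((64, 64), 12.0, 78)
        assert a.resels == pytest.approx(b.resels * 2 ** a.dim)
        assert a.resel_counts[-1] == pytest.approx(
            b.resel_counts[-1] * 2 ** a.dim)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InputError):
            topology.estimate_smoothness(np.zeros((2, 8, 8)), df=1)

    def test_empty_mask_rejected(self):
        frames = np.random.default_rng(0).standard_normal((5, 8, 8))
        with pytest.raises(InputError):
            topology.estimate_smoothness(frames, df=3,
                                         mask=np.zeros((8, 8), bool))

    def test_box_resel_counts_match_closed_form(self):
        r = topology.resel_counts(np.ones((128, 128), bool),
                                  np.array([6.0, 6.0]))
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(2 * 127 / 6.0)
        assert r[2] == pytest.approx(127 * 127 / 36.0)


class TestThresholds:
    def test_t_threshold_printed_value(self):
        # upper-0.001 Student-t quantile at the simulation df
        assert topology.t_threshold_uncorrected(0.001, 78) == pytest.approx(
            3.19, abs=0.01)

    def test_t_threshold_median_is_zero(self):
        for df in (1, 10, 78):
            assert topology.t_threshold_uncorrected(0.5, df) == pytest.approx(
                0.0, abs=1e-12)

    def test_t_threshold_quadrature_oracle(self):
        def sf(u):
            val, _ = integrate.quad(lambda t: stats.t.pdf(t, 78), u, np.inf)
            return val

        u = optimize.brentq(lambda u: sf(u) - 0.001, 1.0, 10.0, xtol=1e-10)
        assert topology.t_threshold_uncorrected(0.001, 78) == pytest.approx(
            u, abs=1e-6)

    def test_t_threshold_rejects_bad_p(self):
        with pytest.raises(ParameterError):
            topology.t_threshold_uncorrected(1.5, 78)

    def test_fwe_threshold_simulation_field(self):
        # 128x128 field, FWHM 6, df 78, p=0.05 under the expected-EC formula
        sm = topology.box_smoothness((128, 128), 6.0, 78)
        u = topology.rft_fwe_threshold(0.05, sm)
        oracle = optimize.brentq(
            lambda t: topology.expected_ec(t, sm) - 0.05, 1, 50, xtol=1e-10)
        assert u == pytest.approx(oracle, abs=1e-4)
        assert u == pytest.approx(4.50, abs=0.01)

    def test_fwe_threshold_monotone_in_area(self):
        small = topology.box_smoothness((64, 64), 6.0, 78)
        large = topology.box_smoothness((128, 128), 6.0, 78)
        assert topology.rft_fwe_threshold(0.05, large) > \
            topology.rft_fwe_threshold(0.05, small)

    def test_fwe_threshold_monotone_in_p(self):
        sm = topology.box_smoothness((128, 128), 6.0, 78)
        assert topology.rft_fwe_threshold(0.05, sm) > \
            topology.rft_fwe_threshold(0.10, sm)


class TestClusters:
    def test_diagonal_pixels_are_one_cluster(self):
        field = np.zeros((5, 5))
        field[1, 1] = field[2, 2] = 5.0
        clusters = topology.label_clusters(field, 1.0)
        assert len(clusters) == 1
        assert clusters[0].extent == 2

    def test_all_below_threshold_gives_empty_set(self):
        assert topology.label_clusters(np.zeros((5, 5)), 1.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_component_count_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        field = rng.random((30, 30))
        clusters = topology.label_clusters(field, 0.7)
        assert len(clusters) == flood_fill_components(field > 0.7)

    def test_ordering_deterministic_by_sum(self):
        field = np.zeros((10, 10))
        field[1, 1:3] = 3.0     # sum 6
        field[7:9, 7] = 5.0     # sum 10
        clusters = topology.label_clusters(field, 2.0)
        assert clusters[0].sum_t > clusters[1].sum_t


class TestExtentP:
    @staticmethod
    def _oracle(extent_voxels, u, sm):
        # independent transcription of the closed-form extent probability
        nu = sm.df
        c = (1 + u ** 2 / nu) ** (-(nu - 1) / 2)
        rho0 = stats.t.sf(u, nu)
        rho1 = np.sqrt(4 * np.log(2)) / (2 * np.pi) * c
        rho2 = (4 * np.log(2)) / (2 * np.pi) ** 1.5 * c * u \
            * np.exp(gammaln((nu + 1) / 2) - gammaln(nu / 2)) \
            / np.sqrt(nu / 2)
        R = sm.resel_counts
        Em = R[0] * rho0 + R[1] * rho1 + R[2] * rho2
        EN = sm.resels * rho0
        beta = (np.exp(gammaln(2.0)) / (EN / Em)) ** 1.0
        k = extent_voxels / (sm.fwhm[0] * sm.fwhm[1])
        return np.exp(-beta * k)

    @pytest.mark.parametrize("extent", [10, 50, 200])
    def test_matches_independent_transcription(self, extent):
        sm = topology.box_smoothness((128, 128), 6.0, 78)
        c = topology.Cluster(voxel_ids=(np.zeros(extent, int),) * 2,
                             extent=extent, peak=4.0, sum_t=4.0 * extent,
                             peak_coord=(0, 0))
        p = topology.cluster_extent_p(c, 3.19, sm)
        assert p == pytest.approx(self._oracle(extent, 3.19, sm), abs=1e-10)

    def test_decreasing_in_extent_and_bounded(self):
        sm = topology.box_smoothness((128, 128), 6.0, 78)
        ps = []
        for extent in (1, 5, 20, 100, 500):
            c = topology.Cluster(voxel_ids=(np.zeros(extent, int),) * 2,
                                 extent=extent, peak=4.0, sum_t=1.0,
                                 peak_coord=(0, 0))
            ps.append(topology.cluster_extent_p(c, 3.19, sm))
        assert all(0 < p <= 1 for p in ps)
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestClusterFDR:
    def _clusters(self, pvals):
        out = []
        for i, p in enumerate(pvals):
            c = topology.Cluster(voxel_ids=(np.array([i]), np.array([0])),
                                 extent=1, peak=5.0, sum_t=5.0,
                                 peak_coord=(i, 0))
            c.p_uncorrected = p
            out.append(c)
        return out

    def test_all_tiny_p_survive(self):
        cl = topology.fdr_over_clusters(self._clusters([1e-9] * 4), 0.05)
        assert all(c.survives for c in cl)

    def test_step_up_example(self):
        cl = topology.fdr_over_clusters(
            self._clusters([0.01, 0.02, 0.04, 0.2]), 0.05)
        assert [c.survives for c in cl] == [True, True, False, False]

    def test_single_cluster_reduces_to_plain_level(self):
        cl = topology.fdr_over_clusters(self._clusters([0.06]), 0.05)
        assert not cl[0].survives

    def test_fallback_picks_highest_sum(self):
        a = topology.Cluster((np.array([0]), np.array([0])), 1, 3.0, 10.0,
                             (0, 0))
        b = topology.Cluster((np.array([1]), np.array([0])), 1, 3.0, 12.0,
                             (1, 0))
        topology.fallback_select([a, b])
        assert (a.survives, b.survives) == (False, True)

    def test_fallback_tie_broken_by_peak(self):
        a = topology.Cluster((np.array([0]), np.array([0])), 1, 3.5, 7.0,
                             (0, 0))
        b = topology.Cluster((np.array([1]), np.array([0])), 1, 4.1, 7.0,
                             (1, 0))
        topology.fallback_select([a, b])
        assert (a.survives, b.survives) == (False, True)

    def test_fallback_single_cluster_survives(self):
        a = topology.Cluster((np.array([0]), np.array([0])), 1, 3.0, 5.0,
                             (0, 0))
        assert topology.fallback_select([a])[0].survives


class TestThresholdMap:
    def test_fixed_p_reports_printed_forming_threshold(self, replicate08):
        _, report = topology.threshold_map(
            replicate08["glm"].tmap, smoothness=replicate08["smoothness"],
            mode="fixed-p", fixed_p=0.001)
        assert report["forming_threshold"] == pytest.approx(3.198, abs=0.001)

    def test_mask_is_supra_threshold_subset(self, replicate16):
        t = replicate16["glm"].tmap
        mask, report = topology.threshold_map(
            t, smoothness=replicate16["smoothness"], mode="adaptive")
        assert mask.any()
        assert (t[mask] > report["forming_threshold"]).all()

    def test_deterministic_given_inputs(self, replicate08):
        args = dict(smoothness=replicate08["smoothness"], mode="adaptive")
        m1, r1 = topology.threshold_map(replicate08["glm"].tmap, **args)
        m2, r2 = topology.threshold_map(replicate08["glm"].tmap, **args)
        assert np.array_equal(m1, m2)
        assert r1["forming_threshold"] == r2["forming_threshold"]

    def test_pure_noise_usually_empty_via_model1(self):
        # noise tail fluctuations on smoothed fields occasionally reward a
        # signal model, so the empty-map rate is high but not perfect
        empties = 0
        for rep in range(10):
            spec = simulation.SimulationSpec(signal_height=0.0)
            rng = np.random.default_rng(
                np.random.SeedSequence(101, spawn_key=(0, rep)))
            glm = simulation.fit_glm(simulation.simulate_dataset(spec, rng))
            sm = topology.estimate_smoothness(glm.residuals, glm.df)
            mask, _ = topology.threshold_map(glm.tmap, smoothness=sm,
                                             mode="adaptive")
            empties += not mask.any()
        assert empties >= 8

    def test_strong_signal_recovers_squares(self):
        spec = simulation.SimulationSpec(signal_height=0.64, seed=55)
        dataset = simulation.simulate_dataset(spec)
        glm = simulation.fit_glm(dataset)
        sm = topology.estimate_smoothness(glm.residuals, glm.df)
        _, report = topology.threshold_map(glm.tmap, smoothness=sm,
                                           mode="adaptive")
        surviving = [c for c in report["_cluster_objects"] if c.survives]
        err = evaluation.cluster_errors(surviving, dataset.square_masks)
        assert err.fn_clusters <= 1  # at least 5 of 6 squares overlapped

    def test_global_shift_leaves_adaptive_mask_stable(self, replicate16):
        t = replicate16["glm"].tmap
        sm = replicate16["smoothness"]
        m0, r0 = topology.threshold_map(t, smoothness=sm, mode="adaptive")
        m1, r1 = topology.threshold_map(t + 1.3, smoothness=sm,
                                        mode="adaptive")
        assert r1["forming_threshold"] - r0["forming_threshold"] == \
            pytest.approx(1.3, abs=0.1)
        assert evaluation.dice(m0, m1) >= 0.95

    def test_unknown_mode_rejected(self, replicate08):
        with pytest.raises(ParameterError):
            topology.threshold_map(replicate08["glm"].tmap,
                                   smoothness=replicate08["smoothness"],
                                   mode="bogus")
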