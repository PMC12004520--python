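"""Interaction counting, voxelization, porosity, pore network and PSD."""

import numpy as np
import pytest

from gelcraft.core_model import ChainTopology, DomainError, SystemState, minimum_image
from gelcraft.forces import ConfigurationError
from gelcraft.io import (SPHERE_PACK_DIAMETER_NM, SPHERE_PACK_SOLID_FRACTION,
                         make_fixture)
from gelcraft.structure_analysis import (BinaryImage, EmptyNetworkError,
                                         NotGelledWarning,
                                         aggregation_onset_time,
                                         count_interactions,
                                         experimental_psd_to_counts,
                                         extract_pore_network,
                                         normalize_kinetics,
                                         porosity_from_densities,
                                         porosity_image, psd_from_network,
                                         voxelize)


class TestCountInteractions:
    def test_single_chain_has_no_interchain_pairs(self):
        st = make_fixture("single_chain")
        count, coord = count_interactions(st, 1.5)
        assert count == 0 and np.all(coord == 0)

    def test_parallel_pair_all_nine_contacts(self, parallel_pair):
        # two parallel 3-bead chains 0.5 nm apart: all 9 cross distances
        # (0.5, 0.680, 1.0497 nm) fall within d_int = 1.5 nm
        count, coord = count_interactions(parallel_pair, 1.5)
        assert count == 9
        assert np.all(coord == 3)

    def test_parallel_pair_tight_distance(self, parallel_pair):
        # at d_int = 0.6 only the three lateral 0.5 nm pairs remain
        count, coord = count_interactions(parallel_pair, 0.6)
        assert count == 3
        assert np.all(coord == 1)

    def test_matches_brute_force_minimum_image(self, rng):
        topo = ChainTopology(20, 20)
        pos = rng.uniform(0, 12.0, (400, 3))
        st = SystemState(pos, np.zeros_like(pos), topo, 12.0)
        count, coord = count_interactions(st, 1.5)
        dr = minimum_image(pos[None] - pos[:, None], 12.0)
        d = np.sqrt((dr**2).sum(-1))
        chain = topo.chain_index
        expect = 0
        expect_coord = np.zeros(400, dtype=int)
        for i in range(400):
            for j in range(i + 1, 400):
                if chain[i] != chain[j] and d[i, j] <= 1.5:
                    expect += 1
                    expect_coord[i] += 1
                    expect_coord[j] += 1
        assert count == expect
        assert np.array_equal(coord, expect_coord)

    def test_rejects_oversized_interaction_distance(self, parallel_pair):
        with pytest.raises(ConfigurationError):
            count_interactions(parallel_pair, parallel_pair.box_nm)


class TestNormalizeKinetics:
    def test_constant_series(self):
        assert np.allclose(normalize_kinetics(np.array([7.0, 7.0, 7.0])), 1.0)

    def test_simple_ramp(self):
        out = normalize_kinetics(np.array([0.0, 5.0, 10.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_divides_by_final_value_not_running_max(self):
        out = normalize_kinetics(np.array([0.0, 5.0, 20.0, 10.0]))
        assert np.allclose(out, [0.0, 0.5, 2.0, 1.0])

    def test_not_gelled_flagged(self):
        with pytest.warns(NotGelledWarning):
            out = normalize_kinetics(np.array([3.0, 1.0, 0.0]))
        assert np.array_equal(out, [3.0, 1.0, 0.0])


class TestAggregationOnset:
    def _log(self, times, series):
        from gelcraft.integrator import KineticsLog
        log = KineticsLog()
        log.time_ps = list(times)
        log.interactions = list(series)
        return log

    def test_interpolated_crossing(self):
        log = self._log([0, 10, 20, 30], [100, 100, 150, 200])
        # threshold 125 crossed midway between t=10 and t=20
        assert aggregation_onset_time(log, 1.25) == pytest.approx(15.0)

    def test_censored_when_no_growth(self):
        log = self._log([0, 10, 20], [100, 104, 98])
        assert aggregation_onset_time(log, 1.25) == 20.0


class TestVoxelize:
    def _empty_state(self, box=2.0):
        topo = ChainTopology(1, 1)
        pos = np.array([[box / 2] * 3])
        return SystemState(pos, np.zeros((1, 3)), topo, box)

    def test_single_centered_bead_fills_one_voxel(self):
        # bead of d = 0.4615 nm centered on a voxel center: neighbors at
        # 0.25 nm exceed the 0.23075 nm radius
        topo = ChainTopology(1, 1)
        pos = np.array([[1.125, 1.125, 1.125]])
        st = SystemState(pos, np.zeros((1, 3)), topo, 2.0)
        img = voxelize(st, 0.25, 0.4615)
        assert img.grid.sum() == 1
        assert img.grid[4, 4, 4]

    def test_bead_straddling_box_face_marks_both_sides(self):
        topo = ChainTopology(1, 1)
        pos = np.array([[0.0, 1.0, 1.0]])
        st = SystemState(pos, np.zeros((1, 3)), topo, 2.0)
        img = voxelize(st, 0.25, 0.4615)
        assert img.grid[0].any() and img.grid[-1].any()

    def test_grid_dimensions(self):
        st = self._empty_state(box=2.1)
        img = voxelize(st, 0.25, 0.1)
        assert img.grid.shape == (9, 9, 9)

    def test_voxel_larger_than_box_rejected(self):
        with pytest.raises(ConfigurationError):
            voxelize(self._empty_state(), 5.0, 0.4615)


class TestPorosity:
    def test_all_pore_image(self):
        img = BinaryImage(np.zeros((4, 4, 4), dtype=bool), 0.25)
        assert porosity_image(img) == 100.0

    def test_one_solid_of_eight(self):
        grid = np.zeros((2, 2, 2), dtype=bool)
        grid[0, 0, 0] = True
        assert porosity_image(BinaryImage(grid, 0.25)) == pytest.approx(87.5)

    def test_porosity_plus_solid_fraction_conserved(self, rng):
        grid = rng.random((10, 10, 10)) > 0.5
        phi = porosity_image(BinaryImage(grid, 0.25))
        assert phi + 100.0 * grid.mean() == pytest.approx(100.0)

    def test_aerogel_densities_give_85_percent(self):
        # skeletal 1.52, envelope 0.23 g/cm3 -> ~85 %
        assert porosity_from_densities(1.52, 0.23) == pytest.approx(84.868, abs=1e-3)
        assert porosity_from_densities(1.52, 0.23) == pytest.approx(85.0, abs=0.2)

    def test_limits_and_validation(self):
        assert porosity_from_densities(1.0, 1.0) == 0.0
        assert porosity_from_densities(2.0, 0.5) == pytest.approx(75.0)
        with pytest.raises(DomainError):
            porosity_from_densities(1.0, 2.0)

    def test_sphere_pack_phantom_round_trip(self):
        # voxelized porosity matches the analytic solid fraction within 2%
        st = make_fixture("sphere_pack_phantom")
        img = voxelize(st, 0.25, SPHERE_PACK_DIAMETER_NM)
        solid_frac = 1.0 - porosity_image(img) / 100.0
        assert solid_frac == pytest.approx(SPHERE_PACK_SOLID_FRACTION, rel=0.02)


def _solid_with_spherical_cavity(n=24, radius_vox=4.0, center=None):
    """Digital sphere centered on a voxel center, periodic minimum-image."""
    grid = np.ones((n, n, n), dtype=bool)
    c = np.array(center if center is not None else [n // 2 + 0.5] * 3)
    idx = np.indices((n, n, n)).reshape(3, -1).T + 0.5
    delta = idx - c
    delta -= n * np.round(delta / n)
    inside = (delta**2).sum(1) <= radius_vox**2
    grid.ravel()[inside] = False
    return grid


class TestPoreNetwork:
    def test_single_spherical_cavity(self):
        img = BinaryImage(_solid_with_spherical_cavity(radius_vox=4.0), 0.25)
        net = extract_pore_network(img)
        assert net.n_pores == 1
        # diameter 8 voxels = 2 nm, within one voxel (0.25 nm); the digital
        # sphere's distance peak sits half a voxel past the nominal radius
        assert net.pore_diameters_nm[0] == pytest.approx(8 * 0.25, abs=0.26)
        assert len(net.throats) == 0

    def test_two_cavities_joined_by_channel(self):
        n = 40
        grid = np.ones((n, n, n), dtype=bool)
        idx = np.indices((n, n, n)).reshape(3, -1).T + 0.5
        for c in ([10, 20, 20], [30, 20, 20]):
            inside = ((idx - np.array(c)) ** 2).sum(1) <= 5.0**2
            grid.ravel()[inside] = False
        # thin straight channel of radius 1.5 voxels along x
        dist_axis = ((idx[:, 1] - 20) ** 2 + (idx[:, 2] - 20) ** 2)
        channel = (dist_axis <= 1.5**2) & (idx[:, 0] > 10) & (idx[:, 0] < 30)
        grid.ravel()[channel] = False
        net = extract_pore_network(BinaryImage(grid, 0.25))
        assert net.n_pores == 2
        assert len(net.throats) == 1
        assert net.throat_diameters_nm[0] < min(net.pore_diameters_nm)

    def test_all_pore_periodic_image_single_spanning_pore(self):
        img = BinaryImage(np.zeros((16, 16, 16), dtype=bool), 0.25)
        net = extract_pore_network(img)
        assert net.n_pores == 1
        assert net.pore_volumes_nm3[0] == pytest.approx(16**3 * 0.25**3)

    def test_all_solid_image_rejected(self):
        img = BinaryImage(np.ones((8, 8, 8), dtype=bool), 0.25)
        with pytest.raises(EmptyNetworkError):
            extract_pore_network(img)

    def test_cavity_across_periodic_boundary(self):
        # cavity wrapped across the box corner: periodic extraction sees the
        # same single pore as the centered cavity
        img = BinaryImage(_solid_with_spherical_cavity(center=[0.5, 0.5, 0.5]),
                          0.25)
        net = extract_pore_network(img, periodic=True)
        assert net.n_pores == 1
        assert net.pore_diameters_nm[0] == pytest.approx(2.0, abs=0.26)

    def test_network_volume_bounded_by_image_pore_volume(self):
        st = make_fixture("mini_gel", seed=3)
        img = voxelize(st, 0.25, 0.4615)
        net = extract_pore_network(img)
        image_pore_volume = img.n_pore * img.voxel_nm**3
        assert net.pore_volumes_nm3.sum() <= image_pore_volume * (1 + 1e-9)


class TestPoreSizeDistribution:
    def _net(self, diameters):
        d = np.asarray(diameters, dtype=float)
        centers = np.zeros((len(d), 3))
        vols = np.pi / 6 * d**3
        return __import__("gelcraft.structure_analysis", fromlist=["PoreNetwork"]
                          ).PoreNetwork(centers, d, vols, np.empty((0, 2), int),
                                        np.array([]))

    def test_single_pore_sphere_volume(self):
        psd = psd_from_network(self._net([10.0]), [5.0, 15.0])
        assert psd.counts.tolist() == [1]
        assert psd.incremental_volumes_nm3[0] == pytest.approx(np.pi / 6 * 1000)

    def test_two_equal_pores_mean_width(self):
        psd = psd_from_network(self._net([8.0, 8.0]), [0.0, 20.0])
        assert psd.mean_pore_width_nm == pytest.approx(8.0)

    def test_volume_conserved_across_window_choices(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(2.0, 30.0, 50)
        net = self._net(d)
        total = np.sum(np.pi / 6 * d**3)
        for edges in ([0, 31], [0, 10, 20, 31], np.linspace(0, 31, 12)):
            psd = psd_from_network(net, edges)
            assert psd.counts.sum() == 50
            assert psd.total_volume_nm3 == pytest.approx(total, rel=1e-9)

    def test_overflow_pores_reported(self):
        with pytest.warns(UserWarning, match="overflow"):
            psd = psd_from_network(self._net([2.0, 50.0]), [1.0, 10.0])
        assert psd.overflow_count == 1
        assert psd.counts.sum() == 1

    def test_rejects_non_increasing_windows(self):
        with pytest.raises(DomainError):
            psd_from_network(self._net([5.0]), [10.0, 10.0])


class TestImageExport:
    def test_tiff_round_trip(self, tmp_path, rng):
        import tifffile
        grid = rng.random((6, 6, 6)) > 0.5
        img = BinaryImage(grid, 0.25)
        p = tmp_path / "img.tiff"
        img.save_tiff(p)
        back = tifffile.imread(p)
        assert np.array_equal(back > 0, grid)


class TestExperimentalPSD:
    def test_csv_reader_feeds_count_conversion(self, tmp_path):
        from gelcraft.structure_analysis import read_experimental_psd
        p = tmp_path / "bjh.csv"
        p.write_text("pore_width_nm,incremental_pore_volume_cm3_per_g\n"
                     "5.0,0.4\n12.0,1.2\n28.0,2.0\n")
        df = read_experimental_psd(p)
        n = experimental_psd_to_counts(
            df["incremental_pore_volume_cm3_per_g"], df["pore_width_nm"],
            porosity_percent=85.0, v_rve_nm3=1e6)
        assert np.sum(n * np.pi / 6 * df["pore_width_nm"]**3) == pytest.approx(
            0.85e6, rel=1e-9)

    def test_csv_reader_rejects_missing_columns(self, tmp_path):
        from gelcraft.structure_analysis import read_experimental_psd
        p = tmp_path / "bad.csv"
        p.write_text("width,volume\n1,2\n")
        with pytest.raises(DomainError):
            read_experimental_psd(p)


    def test_single_window_unit_count(self):
        # phi*V_rve equals one spherical pore volume -> n = 1
        d = 10.0
        v_sphere = np.pi / 6 * d**3
        n = experimental_psd_to_counts([0.02], [d], porosity_percent=50.0,
                                       v_rve_nm3=2 * v_sphere)
        assert n[0] == pytest.approx(1.0)

    def test_linear_in_rve_volume(self):
        v = [0.5, 1.5, 1.0]
        d = [5.0, 10.0, 20.0]
        n1 = experimental_psd_to_counts(v, d, 85.0, 1e6)
        n2 = experimental_psd_to_counts(v, d, 85.0, 2e6)
        assert np.allclose(n2, 2 * n1)

    def test_total_volume_conserved(self):
        # synthetic BJH-like table: counts must reproduce phi*V_rve exactly
        rng = np.random.default_rng(1)
        d = np.sort(rng.uniform(3, 40, 12))
        v = rng.uniform(0.1, 1.0, 12)
        phi, v_rve = 85.0, 1e6
        n = experimental_psd_to_counts(v, d, phi, v_rve)
        assert np.sum(n * np.pi / 6 * d**3) == pytest.approx(
            phi / 100 * v_rve, rel=1e-9)

    def test_rejects_zero_diameter(self):
        with pytest.raises(DomainError):
            experimental_psd_to_counts([1.0], [0.0], 85.0, 1e6)
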