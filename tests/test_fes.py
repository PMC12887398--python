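"""Surface reconstruction, basin analysis, and end-to-end gap recovery."""

import numpy as np
import pytest

from stemopen import (
    FESGrid,
    HillsLog,
    LangevinSettings,
    MetadParams,
    MetadSampler,
    ToyPotential,
    basin_delta_g,
    bias_to_fes,
    convergence_diagnostic,
    evaluate_bias,
    find_basins,
    label_stem_basins,
    reconstruct_fes,
    recover_delta_g,
    sum_hills,
)
from stemopen.metad import KB_KJ, KJ_PER_KCAL
from stemopen.fes import grid_from_hills


def one_hill(height=1.0, center=(3.0, 50.0), biasf=15.0, time=1.0):
    return HillsLog(np.array([time]), np.array([center[0]]), np.array([center[1]]),
                    np.array([0.5]), np.array([10.0]), np.array([height]), biasf)


def centered_grid(center=(3.0, 50.0), half=(2.5, 50.0), n=(81, 81)):
    """Grid whose nodes include the hill center exactly."""
    return (
        np.linspace(center[0] - half[0], center[0] + half[0], n[0]),
        np.linspace(center[1] - half[1], center[1] + half[1], n[1]),
    )


def analytic_double_well(delta=3.0):
    """Gridded two-well surface with known minima (kcal/mol)."""
    x = np.linspace(0.0, 12.0, 121)
    y = np.linspace(0.0, 120.0, 121)
    X, Y = np.meshgrid(x, y, indexing="ij")
    F = (
        10.0
        - 10.0 * np.exp(-((X - 2.0) ** 2) / 4.0 - ((Y - 90.0) ** 2) / 500.0)
        - (10.0 + delta) * np.exp(-((X - 9.0) ** 2) / 4.0 - ((Y - 20.0) ** 2) / 500.0)
    )
    F -= F.min()
    return FESGrid(x, y, F, 15.0)


class TestSumHills:
    def test_single_hill_matches_analytic_gaussian_everywhere(self):
        log = one_hill(height=0.9)
        grid = (np.linspace(0, 6, 61), np.linspace(0, 110, 56))
        bias = sum_hills(log, grid)
        X, Y = np.meshgrid(grid[0], grid[1], indexing="ij")
        ref = 0.9 * np.exp(-((X - 3.0) ** 2) / (2 * 0.25) - ((Y - 50.0) ** 2) / 200.0)
        np.testing.assert_allclose(bias, ref, atol=1e-12)

    def test_empty_log_gives_zero_grid(self):
        empty = HillsLog(np.array([]), np.array([]), np.array([]), np.array([]),
                         np.array([]), np.array([]), 15.0)
        bias = sum_hills(empty, (np.linspace(0, 1, 5), np.linspace(0, 1, 5)))
        assert np.all(bias == 0.0)

    def test_linearity_over_concatenated_logs(self):
        a = one_hill(0.8, (2.5, 40.0), time=1.0)
        b = one_hill(0.5, (3.5, 60.0), time=2.0)
        grid = (np.linspace(-1, 7, 41), np.linspace(-15, 125, 57))
        np.testing.assert_allclose(
            sum_hills(HillsLog.concat(a, b), grid),
            sum_hills(a, grid) + sum_hills(b, grid),
            atol=1e-14,
        )

    def test_matches_pointwise_bias_evaluation(self):
        rng = np.random.default_rng(0)
        n = 30
        log = HillsLog(np.arange(1.0, n + 1), rng.uniform(1, 5, n), rng.uniform(20, 80, n),
                       np.full(n, 0.5), np.full(n, 10.0), rng.uniform(0.1, 1.0, n), 15.0)
        grid = grid_from_hills(log, shape=(40, 40))
        bias = sum_hills(log, grid)
        X, Y = np.meshgrid(grid[0], grid[1], indexing="ij")
        np.testing.assert_allclose(bias, evaluate_bias((X, Y), log), atol=1e-12)

    def test_undersized_grid_rejected_and_coarse_grid_warns(self):
        log = one_hill()
        with pytest.raises(ValueError):
            sum_hills(log, (np.linspace(2, 4, 10), np.linspace(0, 110, 50)))
        with pytest.warns(UserWarning):
            sum_hills(log, (np.linspace(0, 6, 4), np.linspace(-1, 110, 50)))


class TestBiasToFes:
    def test_constant_bias_maps_to_flat_zero_surface(self):
        grid = (np.linspace(0, 1, 5), np.linspace(0, 1, 6))
        fes = bias_to_fes(np.full((5, 6), 3.7), 15.0, grid)
        assert np.all(fes.free_energy == 0.0)

    def test_single_hill_depth_carries_wt_prefactor(self):
        h = 0.8
        log = one_hill(height=h)
        grid = centered_grid()  # nodes include the hill center exactly
        fes = bias_to_fes(sum_hills(log, grid), 15.0, grid)
        far = fes.free_energy[0, 0]  # > 5 sigma from the hill
        depth = far - fes.free_energy.min()
        assert fes.free_energy.min() == 0.0
        assert depth == pytest.approx((15.0 / 14.0) * h / KJ_PER_KCAL, rel=1e-4)

    def test_infinite_bias_factor_limit_is_minus_bias(self):
        log = one_hill(height=1.0)
        grid = grid_from_hills(log, shape=(50, 50))
        bias = sum_hills(log, grid)
        fes = bias_to_fes(bias, 1e12, grid)
        expected = (-bias + bias.max()) / KJ_PER_KCAL
        np.testing.assert_allclose(fes.free_energy, expected, atol=1e-9)

    def test_offset_invariance_after_shift(self):
        log = one_hill(height=1.0)
        grid = grid_from_hills(log, shape=(50, 50))
        bias = sum_hills(log, grid)
        a = bias_to_fes(bias, 15.0, grid)
        b = bias_to_fes(bias + 12.3, 15.0, grid)
        np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-9)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            bias_to_fes(np.zeros((3, 3)), 1.0, (np.arange(3.0), np.arange(3.0)))


class TestBasins:
    def test_double_well_yields_two_basins_at_constructed_centers(self):
        fes = analytic_double_well()
        basins = find_basins(fes, min_barrier=1.0)
        assert len(basins) == 2
        locs = sorted(b.min_location for b in basins)
        assert locs[0][0] == pytest.approx(2.0, abs=0.1)
        assert locs[0][1] == pytest.approx(90.0, abs=1.0)
        assert locs[1][0] == pytest.approx(9.0, abs=0.1)
        assert locs[1][1] == pytest.approx(20.0, abs=1.0)

    def test_single_paraboloid_is_one_basin(self):
        x = np.linspace(-1, 1, 41)
        y = np.linspace(-1, 1, 41)
        X, Y = np.meshgrid(x, y, indexing="ij")
        fes = FESGrid(x, y, X**2 + Y**2, 15.0)
        assert len(find_basins(fes, min_barrier=0.1)) == 1

    def test_high_merge_threshold_collapses_the_wells(self):
        fes = analytic_double_well()
        # saddle sits ~10 kcal above the shallower minimum
        assert len(find_basins(fes, min_barrier=50.0)) == 1

    def test_monotone_surface_has_no_basin_issue(self):
        x = np.linspace(0, 1, 20)
        y = np.linspace(0, 1, 20)
        X, _ = np.meshgrid(x, y, indexing="ij")
        fes = FESGrid(x, y, X.copy(), 15.0)
        basins = find_basins(fes, min_barrier=0.0)
        # a tilted plane has its minimum along one edge: a single basin
        assert len(basins) == 1

    def test_hairpin_open_labels_follow_coordination_number(self):
        fes = analytic_double_well()
        named = label_stem_basins(find_basins(fes, 1.0))
        assert named["hairpin"].min_location[1] > named["open"].min_location[1]


class TestBasinDeltaG:
    def test_symmetric_double_well_gap_is_zero(self):
        fes = analytic_double_well(delta=0.0)
        named = label_stem_basins(find_basins(fes, 1.0))
        report = basin_delta_g(fes, named["hairpin"], named["open"])
        assert report.delta_g == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("delta", [1.5, 4.0])
    def test_constructed_depth_difference_recovered(self, delta):
        fes = analytic_double_well(delta=delta)
        named = label_stem_basins(find_basins(fes, 1.0))
        report = basin_delta_g(fes, named["hairpin"], named["open"])
        assert report.delta_g == pytest.approx(delta, abs=0.05)
        assert report.barrier > 0
        integral = basin_delta_g(fes, named["hairpin"], named["open"], method="integral")
        assert integral.delta_g == pytest.approx(delta, abs=0.4)

    def test_report_json_round_trip(self, tmp_path):
        fes = analytic_double_well(delta=2.0)
        named = label_stem_basins(find_basins(fes, 1.0))
        report = basin_delta_g(fes, named["hairpin"], named["open"])
        path = tmp_path / "basins.json"
        report.write_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["delta_g_kcal"] == pytest.approx(report.delta_g)
        assert "convention" in data


class TestFesIO:
    def test_fes_file_round_trip(self, tmp_path):
        fes = analytic_double_well(delta=1.0)
        path = tmp_path / "fes.dat"
        fes.write(path)
        back = FESGrid.read(path)
        np.testing.assert_allclose(back.free_energy, fes.free_energy, atol=1e-7)
        assert back.bias_factor == 15.0


class TestHarmonicClosedForm:
    def test_reconstructed_surface_matches_half_k_s_squared(self):
        """Well-tempered reconstruction of a harmonic well agrees with the
        closed form within 0.3 kJ/mol (RMS over the central +/-2 sigma
        region) at desk scale."""
        kbt = KB_KJ * 300.0
        kx, ky = kbt / 9.0, kbt / 1600.0  # thermal sigmas (3 A, 40 CN)
        pot = ToyPotential("harmonic", {"kx": kx, "ky": ky, "cx": 0.0, "cy": 0.0},
                           ((-9.0, 9.0), (-120.0, 120.0)), (0.0, 0.0))
        params = MetadParams(w0=0.5, pace=50, bias_factor=4.0)
        sampler = MetadSampler(pot, params, LangevinSettings(seed=3, mobility=(8.02, 802.0)),
                               exact_heights=False)
        sampler.run(8_000_000)
        grid = grid_from_hills(sampler.hills, shape=(150, 150))
        fes = reconstruct_fes(sampler.hills, grid=grid, avg_fraction=0.7, n_checkpoints=41)
        X, Y = np.meshgrid(grid[0], grid[1], indexing="ij")
        target = (0.5 * kx * X**2 + 0.5 * ky * Y**2) / KJ_PER_KCAL
        mask = (np.abs(X) <= 6.0) & (np.abs(Y) <= 80.0)
        diff = (fes.free_energy - target) * KJ_PER_KCAL
        diff = diff - diff[mask].mean()
        assert np.sqrt(np.mean(diff[mask] ** 2)) < 0.3


class TestEndToEndRecovery:
    @pytest.mark.parametrize("delta_g", [2.0, 5.0, 9.86, 12.0, 15.0])
    def test_known_gap_recovered_from_seeded_run(self, delta_g):
        pot = ToyPotential.hairpin_landscape(delta_g_kcal=delta_g)
        result = recover_delta_g(pot, MetadParams(), LangevinSettings(seed=1),
                                 chunk_steps=200_000, max_chunks=12)
        tol = max(0.5, 0.07 * delta_g)
        assert result["delta_g_kcal"] == pytest.approx(delta_g, abs=tol)

    def test_convergence_diagnostic_gap_change_settles(self):
        """Early in a run the half-vs-full basin gap still swings by over a
        kcal/mol; once both wells are repeatedly crossed it settles."""
        pot = ToyPotential.hairpin_landscape()
        sampler = MetadSampler(pot, MetadParams(), LangevinSettings(seed=2))
        sampler.run(400_000)
        early = convergence_diagnostic(sampler.hills)
        sampler.run(1_600_000)
        late = convergence_diagnostic(sampler.hills)
        assert early["fes_rms_kcal"] > 0
        assert late["fes_rms_kcal"] > 0
        assert abs(late["delta_g_change_kcal"]) < abs(early["delta_g_change_kcal"])
        assert abs(late["delta_g_change_kcal"]) < 0.5
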