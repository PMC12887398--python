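"""RMSD, switching-function coordination number, base-pair distances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from stemopen import (
    Conformer,
    base_pair_distances,
    compute_cv_series,
    coordination_number,
    gen_hairpin_conformer,
    kabsch_rmsd,
    switching_value,
)
from stemopen.structure import (
    CVSeries,
    read_colvar,
    read_trajectory_pdb,
    write_colvar,
    write_trajectory_pdb,
)


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def toy_conformer(coords, names=None):
    n = len(coords)
    names = names or [f"C{i}'" for i in range(n)]
    return Conformer(names, np.ones(n, dtype=int), ["C"] * n, np.asarray(coords, float))


def rmsd_rotation_search(X, Y):
    """Implementation-independent oracle: coarse Euler-angle grid plus
    Nelder-Mead polish of the superposition RMSD."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        d = X @ R.T - Y
        return np.sqrt(np.mean(np.sum(d**2, axis=1)))

    best, best_val = None, np.inf
    grid = np.deg2rad(np.arange(0, 360, 12))
    half = np.deg2rad(np.arange(0, 181, 12))
    for a in grid:
        for b in half:
            for c in grid:
                v = rmsd_of([a, b, c])
                if v < best_val:
                    best_val, best = v, [a, b, c]
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    return float(res.fun)


class TestKabschRmsd:
    def test_identity_is_zero(self, closed_conformer):
        assert kabsch_rmsd(closed_conformer, closed_conformer) == pytest.approx(0.0, abs=1e-10)

    def test_invariant_under_rigid_motion(self, closed_conformer, rng):
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = closed_conformer.transformed(R, t)
            assert kabsch_rmsd(moved, closed_conformer) == pytest.approx(0.0, abs=1e-8)

    def test_three_atom_pair_matches_rotation_grid_oracle(self, rng):
        X = rng.uniform(-3, 3, (3, 3))
        Y = X + rng.normal(0, 0.7, (3, 3))  # distorted copy: rmsd > 0
        a = toy_conformer(X)
        b = toy_conformer(Y)
        got = kabsch_rmsd(a, b, selection=None)
        oracle = rmsd_rotation_search(X, Y)
        assert got > 0.1
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_mismatched_selection_rejected(self, closed_conformer):
        trimmed = Conformer(
            closed_conformer.atom_names[:-3],
            closed_conformer.residue_indices[:-3],
            closed_conformer.elements[:-3],
            closed_conformer.coords[:-3],
        )
        with pytest.raises(ValueError):
            kabsch_rmsd(trimmed, closed_conformer)

    def test_open_vs_closed_backbone_rmsd_large(self, closed_conformer, open_conformer):
        assert kabsch_rmsd(open_conformer, closed_conformer) > 5.0


class TestSwitchingFunction:
    def test_contact_limit_is_one(self):
        assert switching_value(0.0, d0=0.0, r0=3.0) == 1.0
        assert switching_value(1.5, d0=2.0, r0=3.0) == 1.0  # r <= d0

    def test_analytic_limit_at_singular_point(self):
        # (1 - x^6)/(1 - x^12) -> 1/2 as x -> 1
        assert switching_value(3.0, d0=0.0, r0=3.0) == pytest.approx(0.5, abs=1e-12)
        assert switching_value(5.0, d0=2.0, r0=3.0) == pytest.approx(0.5, abs=1e-12)

    def test_rational_value_at_twice_cutoff(self):
        assert switching_value(6.0, d0=0.0, r0=3.0) == pytest.approx(1.0 / 65.0, abs=1e-12)

    def test_agrees_with_unsimplified_rational_form(self):
        r = np.linspace(0.01, 12.0, 400)
        x = r / 3.0
        x = x[np.abs(x - 1.0) > 1e-6]
        direct = (1 - x**6) / (1 - x**12)
        np.testing.assert_allclose(switching_value(x * 3.0, 0.0, 3.0), direct, atol=1e-12)

    def test_strictly_decreasing_for_separated_atoms(self):
        r = np.linspace(2.0, 12.0, 2001)
        vals = np.asarray(switching_value(r, d0=0.0, r0=3.0))
        assert np.all(np.diff(vals) < 0)

    def test_continuous_through_the_singular_point(self):
        # dense sampling around x = (r - d0)/r0 = 1: no jump at the
        # removable singularity
        eps = np.concatenate([-np.geomspace(1e-12, 1e-3, 40)[::-1], [0.0],
                              np.geomspace(1e-12, 1e-3, 40)])
        vals = np.asarray(switching_value(3.0 + 3.0 * eps, d0=0.0, r0=3.0))
        assert np.max(np.abs(vals - 0.5)) < 1e-2
        assert np.all(np.diff(vals) <= 0)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            switching_value(1.0, d0=0.0, r0=0.0)


def coordination_double_loop(conf, group_a, group_b, d0, r0):
    """Independent brute-force pairwise loop."""
    total = 0.0
    for i in range(len(conf)):
        if conf.residue_indices[i] not in group_a:
            continue
        for j in range(len(conf)):
            if conf.residue_indices[j] not in group_b:
                continue
            r = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
            x = max(0.0, (r - d0) / r0)
            total += 1.0 / (1.0 + x**6)
    return total


class TestCoordinationNumber:
    def test_two_single_atoms_at_contact_offset(self):
        conf = Conformer(["C1'", "C1'"], np.array([1, 15]), ["C", "C"],
                         np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        assert coordination_number(conf, {1}, {15}, d0=2.0, r0=3.0) == pytest.approx(1.0)

    def test_closed_over_open_contrast_at_least_tenfold(self, closed_conformer, open_conformer):
        cn_closed = coordination_number(closed_conformer)
        cn_open = coordination_number(open_conformer)
        assert cn_closed / cn_open >= 10.0

    def test_matches_double_loop_oracle_exactly(self, closed_conformer, open_conformer):
        for conf in (closed_conformer, open_conformer):
            fast = coordination_number(conf, d0=0.5, r0=3.0)
            slow = coordination_double_loop(conf, set(range(1, 5)), set(range(12, 16)), 0.5, 3.0)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_additive_over_partition_of_group_b(self, closed_conformer):
        whole = coordination_number(closed_conformer, {1, 2, 3, 4}, {12, 13, 14, 15})
        parts = coordination_number(closed_conformer, {1, 2, 3, 4}, {12, 13}) + \
            coordination_number(closed_conformer, {1, 2, 3, 4}, {14, 15})
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_invariant_under_rigid_motion(self, closed_conformer, rng):
        R, t = random_rigid(rng)
        moved = closed_conformer.transformed(R, t)
        assert coordination_number(moved) == pytest.approx(
            coordination_number(closed_conformer), rel=1e-9
        )

    def test_overlapping_or_empty_groups_rejected(self, closed_conformer):
        with pytest.raises(ValueError):
            coordination_number(closed_conformer, {1, 2}, {2, 3})
        with pytest.raises(ValueError):
            coordination_number(closed_conformer, set(), {12})


class TestBasePairDistances:
    def test_symmetric_toy_conformer_all_three_angstrom(self):
        names, rids, coords = [], [], []
        for i in range(1, 16):
            names.append("BC")
            rids.append(i)
            x = 0.0 if i <= 7 else 3.0
            z = (i - 1) if i <= 7 else (15 - i)
            coords.append([x, 0.0, float(z)])
        conf = Conformer(names, np.array(rids), ["C"] * 15, np.array(coords))
        np.testing.assert_allclose(base_pair_distances(conf), [3.0, 3.0, 3.0, 3.0])

    def test_open_distances_exceed_closed(self, closed_conformer, open_conformer):
        assert np.all(base_pair_distances(open_conformer) > base_pair_distances(closed_conformer))

    def test_pairing_order_equivariance(self, closed_conformer):
        fwd = base_pair_distances(closed_conformer, [(1, 15), (2, 14), (3, 13)])
        rev = base_pair_distances(closed_conformer, [(3, 13), (1, 15), (2, 14)])
        np.testing.assert_allclose(rev, fwd[[2, 0, 1]])

    def test_out_of_range_pair_rejected(self, closed_conformer):
        with pytest.raises(ValueError):
            base_pair_distances(closed_conformer, [(1, 16)])


class TestConformerIO:
    def test_pdb_round_trip(self, tmp_path, closed_conformer):
        path = tmp_path / "closed.pdb"
        closed_conformer.to_pdb(path)
        back = Conformer.from_pdb(path)
        assert back.atom_names == closed_conformer.atom_names
        np.testing.assert_allclose(back.coords, closed_conformer.coords, atol=1e-3)

    def test_multi_model_trajectory_round_trip(self, tmp_path, closed_conformer, open_conformer):
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb([closed_conformer, open_conformer], path)
        frames = read_trajectory_pdb(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[1].coords, open_conformer.coords, atol=1e-3)

    def test_cv_series_and_colvar_round_trip(self, tmp_path, closed_conformer, open_conformer):
        series = compute_cv_series([closed_conformer, open_conformer], closed_conformer)
        assert series.rmsd[0] == pytest.approx(0.0, abs=1e-8)
        assert series.cn[0] > 10 * series.cn[1]
        path = tmp_path / "colvar.dat"
        write_colvar(series, path)
        back = read_colvar(path)
        np.testing.assert_allclose(back.rmsd, series.rmsd, atol=1e-6)
        np.testing.assert_allclose(back.cn, series.cn, atol=1e-6)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            CVSeries(np.array([0]), np.array([-1.0]), np.array([0.0]))
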