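"""Unfolded-EMD disagreement statistic and its LP transport oracle."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from dwiseg.segmentation import EnsemblePrediction
from dwiseg.uncertainty import (
    EmptyMassError,
    compute_u,
    downsample,
    emd_unfolded,
    flag_inaccurate,
    uncertainty_report,
    unfold,
    unfold_coordinates,
    unit_sum_normalize,
)


def lp_transport_cost(p, q, cost_matrix):
    """Exact optimal-transport cost by linear programming (oracle)."""
    n, m = len(p), len(q)
    c = cost_matrix.reshape(-1)
    A_eq = []
    for i in range(n):  # row marginals
        row = np.zeros((n, m))
        row[i, :] = 1.0
        A_eq.append(row.reshape(-1))
    for j in range(m):  # column marginals
        col = np.zeros((n, m))
        col[:, j] = 1.0
        A_eq.append(col.reshape(-1))
    b_eq = np.concatenate([p, q])
    res = linprog(c, A_eq=np.asarray(A_eq), b_eq=b_eq, bounds=(0, None),
                  method="highs")
    assert res.success
    return res.fun


class TestDownsample:
    def test_factor_one_is_identity(self):
        vol = np.random.default_rng(0).random((5, 6, 7))
        np.testing.assert_array_equal(downsample(vol, 1), vol)

    def test_constant_volume_stays_constant(self):
        out = downsample(np.full((8, 8, 8), 0.4), 4)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out, 0.4, atol=1e-9)

    def test_linear_ramp_sampled_at_coarse_coordinates(self):
        n = 16
        ramp = np.broadcast_to(np.linspace(0, 1, n)[:, None, None],
                               (n, n, n)).copy()
        out = downsample(ramp, 4)
        # grid_mode cubic interpolation: coarse voxel centers sit at the
        # average of the fine coordinates they cover
        fine = np.linspace(0, 1, n)
        expected = fine.reshape(4, 4).mean(axis=1)
        np.testing.assert_allclose(out[:, 0, 0], expected, atol=1e-3)

    def test_values_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        vol = (rng.random((12, 12, 12)) > 0.5).astype(float)
        out = downsample(vol, 4)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.ones((4, 4, 4)), 0)


class TestUnitSum:
    def test_total_becomes_one(self):
        vol = np.full((3, 3, 3), 5.0 / 27)
        assert unit_sum_normalize(vol).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_voxel_gets_all_mass(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 2, 0] = 0.3
        out = unit_sum_normalize(vol)
        assert out[1, 2, 0] == pytest.approx(1.0)

    def test_matches_elementwise_division(self):
        vol = np.random.default_rng(2).random((4, 4, 4))
        np.testing.assert_allclose(unit_sum_normalize(vol), vol / vol.sum())

    def test_zero_mass_is_an_error(self):
        with pytest.raises(EmptyMassError):
            unit_sum_normalize(np.zeros((2, 2, 2)))


class TestUnfold:
    def test_1d_is_identity(self):
        v = np.arange(5.0)
        np.testing.assert_array_equal(unfold(v), v)

    def test_3x3_serpentine_order(self):
        grid = np.arange(9.0).reshape(3, 3, 1)  # grid[x, y, 0] = 3x + y...
        # row-by-row: y=0 left-to-right in x, y=1 right-to-left, y=2 l-t-r
        out = unfold(grid)
        expected = [grid[0, 0, 0], grid[1, 0, 0], grid[2, 0, 0],
                    grid[2, 1, 0], grid[1, 1, 0], grid[0, 1, 0],
                    grid[0, 2, 0], grid[1, 2, 0], grid[2, 2, 0]]
        np.testing.assert_array_equal(out, expected)

    def test_consecutive_positions_grid_adjacent_all_small_shapes(self):
        for shape in itertools.product(range(1, 6), repeat=3):
            coords = unfold_coordinates(shape)
            steps = np.abs(np.diff(coords, axis=0)).sum(axis=1)
            assert (steps == 1).all(), f"non-adjacent step in {shape}"

    def test_covers_every_voxel_once(self):
        vol = np.arange(60.0).reshape(3, 4, 5)
        assert sorted(unfold(vol).tolist()) == sorted(vol.reshape(-1).tolist())


class TestEMD:
    def test_identical_distributions_zero(self):
        p = unit_sum_normalize(np.random.default_rng(3).random((4, 4, 4)))
        assert emd_unfolded(p, p) == 0.0

    def test_1d_endpoint_transport(self):
        L = 9
        p = np.zeros(L)
        q = np.zeros(L)
        p[0] = 1.0
        q[-1] = 1.0
        assert emd_unfolded(p, q) == pytest.approx(L - 1)

    def test_matches_lp_oracle_on_random_1d(self):
        """Unfolding is exact in 1D: cumulative-sum distance equals the
        LP optimal-transport cost with |i−j| ground metric."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            L = int(rng.integers(2, 13))
            p = unit_sum_normalize(rng.random(L) + 1e-3)
            q = unit_sum_normalize(rng.random(L) + 1e-3)
            cost = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
            assert emd_unfolded(p, q) == pytest.approx(
                lp_transport_cost(p, q, cost.astype(float)), abs=1e-8
            )

    def test_symmetry_and_nonnegativity_on_3d(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            shape = tuple(rng.integers(2, 7, size=3))
            p = unit_sum_normalize(rng.random(shape))
            q = unit_sum_normalize(rng.random(shape))
            d_pq = emd_unfolded(p, q)
            assert d_pq >= 0.0
            assert d_pq == pytest.approx(emd_unfolded(q, p), abs=1e-12)

    def test_triangle_inequality_1d(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            L = int(rng.integers(3, 12))
            p, q, r = (unit_sum_normalize(rng.random(L)) for _ in range(3))
            assert emd_unfolded(p, r) <= (
                emd_unfolded(p, q) + emd_unfolded(q, r) + 1e-12
            )

    def test_mass_and_shape_mismatch_rejected(self):
        p = unit_sum_normalize(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            emd_unfolded(p, np.ones((2, 2, 2)))  # not unit-sum
        with pytest.raises(ValueError):
            emd_unfolded(p, unit_sum_normalize(np.ones((3, 2, 2))))

    def test_l2_mode_bounded_by_abs_mode(self):
        rng = np.random.default_rng(7)
        p = unit_sum_normalize(rng.random((3, 3, 3)))
        q = unit_sum_normalize(rng.random((3, 3, 3)))
        assert emd_unfolded(p, q, mode="l2") <= emd_unfolded(p, q, mode="abs")


def _ensemble_from_maps(maps):
    members = [m[..., None] for m in maps]
    return EnsemblePrediction(members=members,
                              subsets=[None] * len(members))


class TestComputeU:
    def test_identical_members_give_zero(self):
        m = np.zeros((8, 4, 4))
        m[2:4, 1:3, 1:3] = 1.0
        ens = _ensemble_from_maps([m, m, m])
        emds, u = compute_u(ens, 0, downsample_factor=1)
        assert u == 0.0
        assert emds == [0.0, 0.0, 0.0]

    def test_translated_members_cost_half_the_shift(self):
        """Two members that are translates by t steps along the fastest
        unfolding axis disagree by u = t/2 (each is t/2 from the mean)."""
        L, t = 12, 4
        a = np.zeros((L, 1, 1))
        b = np.zeros((L, 1, 1))
        a[2, 0, 0] = 1.0
        b[2 + t, 0, 0] = 1.0
        _, u = compute_u(_ensemble_from_maps([a, b]), 0, downsample_factor=1)
        assert u == pytest.approx(t / 2)

    def test_u_is_mean_of_member_emds(self):
        rng = np.random.default_rng(8)
        maps = [rng.random((4, 4, 4)) for _ in range(3)]
        ens = _ensemble_from_maps(maps)
        emds, u = compute_u(ens, 0, downsample_factor=1)
        mean_map = unit_sum_normalize(np.mean(maps, axis=0))
        expected = [emd_unfolded(unit_sum_normalize(m), mean_map) for m in maps]
        np.testing.assert_allclose(emds, expected, atol=1e-10)
        assert u == pytest.approx(np.mean(expected))

    def test_empty_member_recorded_as_nan(self):
        m = np.zeros((4, 4, 4))
        full = np.ones((4, 4, 4)) * 0.5
        emds, u = compute_u(_ensemble_from_maps([m, full]), 0,
                            downsample_factor=1)
        assert np.isnan(emds[0]) and not np.isnan(emds[1])
        assert not np.isnan(u)


class TestFlagging:
    def test_zero_u_not_flagged(self):
        assert flag_inaccurate(0.0, 0.30) is False

    def test_just_above_default_threshold_flagged(self):
        assert flag_inaccurate(0.31, 0.30) is True
        assert flag_inaccurate(0.30, 0.30) is False

    def test_undefined_u_flagged(self):
        assert flag_inaccurate(float("nan"), 0.30) is True

    def test_threshold_sweep_sensitivity_monotone(self):
        """Sensitivity (fraction of 'bad' cases flagged) can only fall
        as the threshold rises."""
        rng = np.random.default_rng(9)
        u_values = rng.random(100)
        bad = u_values > 0.5  # ground truth: large-u cases are bad
        sens = []
        for thr in np.sort(u_values):
            flagged = u_values > thr
            sens.append((flagged & bad).sum() / bad.sum())
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))


def test_report_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    maps = [rng.random((8, 8, 8)) for _ in range(3)]
    ens = _ensemble_from_maps(maps)
    report = uncertainty_report(ens, threshold=0.3, downsample_factor=2)
    report.save(tmp_path / "u.json", tmp_path / "u.csv")
    assert (tmp_path / "u.json").exists()
    frame = report.to_frame()
    assert set(frame.columns) >= {"label", "u", "flag", "n"}
    emds, u = compute_u(ens, 0, downsample_factor=2)
    assert report.u[0] == pytest.approx(u)
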