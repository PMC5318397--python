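"""Magnitude ordering, path windows, linear predictors, and rollouts."""

from __future__ import annotations

import numpy as np
import pytest

from placegrid.arena import ArenaConfig, build_bag_dataset, lattice_points, place_boxes
from placegrid.analysis import response_tensor
from placegrid.autoencoder import init_weights
from placegrid.prediction import (
    ActivityField,
    PathWindowSet,
    build_path_windows,
    continue_prediction,
    edge_seed_windows,
    field_peaks,
    fine_grid_activities,
    fit_pls,
    fit_pseudoinverse,
    magnitude_order,
    predict_next,
    render_prediction_field,
)
from tests.test_autoencoder import toy_config

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def make_field(values: np.ndarray, resolution: int, L: int = 18) -> ActivityField:
    cfg = ArenaConfig(grid_cells=2, n_boxes=1, n_directions=L,
                      direction_spacing=360.0 / L)
    return ActivityField(values=values, resolution=resolution, config=cfg)


def sinusoid_field(resolution=40, m=4, period_steps=10, L=18) -> ActivityField:
    """Planted periodic field: activities depend sinusoidally on x.

    Channels are ordered scalings of the same phase signal, so magnitude
    ordering leaves them descending already.
    """
    pts = lattice_points(resolution)
    phase = 2 * np.pi * pts[:, 0] * resolution / period_steps
    base = 0.5 * (1 + np.cos(phase))
    scales = np.linspace(1.0, 0.4, m)
    vals = base[:, None] * scales[None, :] + 0.05
    return make_field(np.repeat(vals[:, None, :], L, axis=1), resolution, L)


def window_count_oracle(resolution: int, direction_deg: float, n: int) -> int:
    """Exhaustive start-point enumeration with the same inside test."""
    pts = lattice_points(resolution)
    ang = np.deg2rad(direction_deg)
    step = np.array([np.cos(ang), np.sin(ang)]) / resolution
    count = 0
    tol = 1e-9
    for p in pts:
        q = p + n * step
        if -tol <= q[0] <= 1 + tol and -tol <= q[1] <= 1 + tol:
            count += 1
    return count


def random_windows(rng, t=60, n=2, m=3) -> PathWindowSet:
    R = rng.normal(size=(t, n * m))
    Rn = rng.normal(size=(t, m))
    return PathWindowSet(R=R, R_next=Rn, direction_deg=0.0, n_steps=n,
                         starts=np.zeros((t, 2)))


# ---------------------------------------------------------------------------
# magnitude ordering
# ---------------------------------------------------------------------------


class TestMagnitudeOrder:
    def test_simple_sort(self):
        np.testing.assert_array_equal(
            magnitude_order(np.array([0.1, 0.5, 0.3])), [0.5, 0.3, 0.1]
        )

    def test_permutation_invariant(self, rng):
        v = rng.normal(size=12)
        for _ in range(5):
            perm = rng.permutation(12)
            np.testing.assert_array_equal(magnitude_order(v[perm]), magnitude_order(v))

    def test_matches_sort_oracle_many_trials(self, rng):
        V = rng.normal(size=(10_000, 6))
        out = magnitude_order(V)
        expect = np.array([sorted(row, reverse=True) for row in V])
        np.testing.assert_array_equal(out, expect)

    def test_idempotent(self, rng):
        v = rng.normal(size=9)
        once = magnitude_order(v)
        np.testing.assert_array_equal(magnitude_order(once), once)


# ---------------------------------------------------------------------------
# fine grid
# ---------------------------------------------------------------------------


class TestFineGrid:
    def test_default_resolution_point_count(self):
        assert lattice_points(150).shape == (22_801, 2)

    def test_resolution_one(self):
        assert lattice_points(1).shape == (4, 2)

    def test_consistency_with_coarse_tensor(self):
        # same lattice resolution: fine activities must equal the response
        # tensor collected through the coarse dataset path
        cfg = ArenaConfig(grid_cells=4, n_boxes=6, seed=8)
        boxes = place_boxes(cfg)
        ds = build_bag_dataset(cfg, boxes, v=1, normalize=True)
        net = toy_config(dims=(ds.X.shape[1], 3, ds.X.shape[1]), sparsity=(None,), seed=0)
        w = init_weights(net)
        tensor = response_tensor(w, ds)
        field = fine_grid_activities(w, cfg, boxes, resolution=4, v=1, normalize=True)
        n = cfg.grid_cells + 1
        for p in range(field.n_points):
            iy, ix = divmod(p, n)
            np.testing.assert_allclose(
                field.values[p], tensor.values[ix, iy], atol=1e-12
            )


# ---------------------------------------------------------------------------
# path windows
# ---------------------------------------------------------------------------


class TestBuildPathWindows:
    def test_impossible_length_empty_with_warning(self):
        field = sinusoid_field(resolution=10)
        with pytest.warns(UserWarning, match="no admissible"):
            w = build_path_windows(field, 0.0, 100)
        assert w.n_windows == 0

    def test_count_matches_enumeration_oracle_axis_aligned(self):
        field = sinusoid_field(resolution=30)
        w = build_path_windows(field, 0.0, 10)
        assert w.n_windows == window_count_oracle(30, 0.0, 10) == 31 * 21

    def test_count_matches_oracle_oblique(self):
        field = sinusoid_field(resolution=30)
        for direction in (20.0, 140.0, 260.0):
            w = build_path_windows(field, direction, 7)
            assert w.n_windows == window_count_oracle(30, direction, 7)

    def test_all_window_positions_inside_arena(self):
        field = sinusoid_field(resolution=25)
        w = build_path_windows(field, 300.0, 9)
        ang = np.deg2rad(300.0)
        step = np.array([np.cos(ang), np.sin(ang)]) / 25
        for s in w.starts[:: max(1, len(w.starts) // 50)]:
            for j in range(10):
                q = s + j * step
                assert -1e-9 <= q[0] <= 1 + 1e-9 and -1e-9 <= q[1] <= 1 + 1e-9

    def test_rows_are_magnitude_ordered(self):
        field = sinusoid_field(resolution=20)
        w = build_path_windows(field, 0.0, 5)
        steps = w.R.reshape(w.n_windows, 5, w.m)
        assert np.all(np.diff(steps, axis=2) <= 1e-15)
        assert np.all(np.diff(w.R_next, axis=1) <= 1e-15)

    def test_non_lattice_direction_rejected(self):
        field = sinusoid_field(resolution=10)
        with pytest.raises(ValueError, match="headings"):
            build_path_windows(field, 33.3, 3)


# ---------------------------------------------------------------------------
# pseudoinverse predictor
# ---------------------------------------------------------------------------


class TestPseudoinverse:
    def test_recovers_planted_linear_dynamics(self, rng):
        m = 4
        A = rng.normal(size=(m, m))
        states = rng.normal(size=(200, m))
        w = PathWindowSet(R=states, R_next=states @ A.T, direction_deg=0.0,
                          n_steps=1, starts=np.zeros((200, 2)))
        pred = fit_pseudoinverse(w)
        np.testing.assert_allclose(pred.M, A, atol=1e-8)

    def test_identity_continuation_zero_residual(self, rng):
        w = random_windows(rng, t=80, n=2, m=3)
        w = PathWindowSet(R=w.R, R_next=w.R[:, :3], direction_deg=0.0,
                          n_steps=2, starts=w.starts)
        pred = fit_pseudoinverse(w)
        np.testing.assert_allclose(pred.predict(w.R), w.R_next, atol=1e-8)

    def test_residual_matches_normal_equations_oracle(self, rng):
        w = random_windows(rng, t=100, n=3, m=2)
        pred = fit_pseudoinverse(w)
        # oracle: solve (R^T R) M^T = R^T R_next directly
        Mo = np.linalg.solve(w.R.T @ w.R, w.R.T @ w.R_next)
        r_fit = np.linalg.norm(w.R @ pred.M.T - w.R_next)
        r_oracle = np.linalg.norm(w.R @ Mo - w.R_next)
        assert abs(r_fit - r_oracle) < 1e-8
        np.testing.assert_allclose(pred.M.T, Mo, atol=1e-8)

    def test_homogeneity_and_zero_window(self, rng):
        w = random_windows(rng)
        pred = fit_pseudoinverse(w)
        window = rng.normal(size=w.R.shape[1])
        np.testing.assert_allclose(
            predict_next(pred, 2 * window), 2 * predict_next(pred, window), atol=1e-10
        )
        np.testing.assert_allclose(predict_next(pred, 0 * window), 0, atol=1e-12)

    def test_length_mismatch_raises(self, rng):
        pred = fit_pseudoinverse(random_windows(rng))
        with pytest.raises(ValueError, match="length"):
            pred.predict(np.zeros(5))


# ---------------------------------------------------------------------------
# PLS predictor
# ---------------------------------------------------------------------------


class TestPLS:
    def test_full_rank_equals_least_squares(self, rng):
        w = random_windows(rng, t=150, n=2, m=3)
        pls = fit_pls(w, n_components=w.R.shape[1])
        ls = np.linalg.lstsq(
            np.column_stack([w.R, np.ones(len(w.R))]), w.R_next, rcond=None
        )[0]
        pred_ls = np.column_stack([w.R, np.ones(len(w.R))]) @ ls
        np.testing.assert_allclose(pls.predict(w.R), pred_ls, atol=1e-6)

    def test_constant_sequences_predict_constant(self):
        c = np.array([3.0, 2.0, 1.0])
        R = np.tile(c, (50, 2)) + 0.0
        Rn = np.tile(c, (50, 1))
        # tiny jitter keeps the PLS deflation well posed
        rng = np.random.default_rng(0)
        R += 1e-8 * rng.normal(size=R.shape)
        w = PathWindowSet(R=R, R_next=Rn, direction_deg=0.0, n_steps=2,
                          starts=np.zeros((50, 2)))
        pred = fit_pls(w, n_components=1)
        np.testing.assert_allclose(pred.predict(R[:1])[0], c, atol=1e-5)

    def test_sinusoid_one_step_prediction(self):
        # pure sinusoid obeys a 2nd-order linear recurrence: with n=2 history
        # steps the predictor should be near exact
        t = np.arange(300)
        sig = np.cos(2 * np.pi * t / 25)
        m = 3
        chans = np.stack([sig * s for s in (1.0, 0.7, 0.4)], axis=1) + 2.0
        R = np.column_stack([chans[:-2], chans[1:-1]])
        Rn = chans[2:]
        w = PathWindowSet(R=R, R_next=Rn, direction_deg=0.0, n_steps=2,
                          starts=np.zeros((len(R), 2)))
        pred = fit_pls(w, n_components=4)
        err = np.abs(pred.predict(R) - Rn).max()
        assert err < 0.01  # < 1% of unit amplitude

    def test_component_bound_enforced(self, rng):
        w = random_windows(rng, t=20, n=2, m=3)
        with pytest.raises(ValueError, match="out of range"):
            fit_pls(w, n_components=7)

    def test_pinv_residual_never_exceeds_pls_residual(self, rng):
        # PLS fits an intercept, the raw pseudoinverse does not; on centered
        # data both are intercept-free and least squares is optimal
        w = random_windows(rng, t=120, n=3, m=4)
        Rc = w.R - w.R.mean(axis=0)
        Rnc = w.R_next - w.R_next.mean(axis=0)
        wc = PathWindowSet(R=Rc, R_next=Rnc, direction_deg=0.0, n_steps=3,
                           starts=w.starts)
        pinv_pred = fit_pseudoinverse(wc)
        r_pinv = np.linalg.norm(Rc @ pinv_pred.M.T - Rnc)
        for k in (1, 3, 6, 12):
            pls = fit_pls(wc, n_components=k)
            r_pls = np.linalg.norm(pls.predict(Rc) - Rnc)
            assert r_pinv <= r_pls + 1e-6


# ---------------------------------------------------------------------------
# rollouts
# ---------------------------------------------------------------------------


class TestContinuePrediction:
    def test_cyclic_shift_dynamics_reproduce_cycle(self):
        m, n = 3, 1
        # predictor = cyclic shift of the channel values
        P = np.roll(np.eye(m), 1, axis=0)
        from placegrid.prediction import PseudoinversePredictor

        pred = PseudoinversePredictor(M=P)
        seed = np.array([1.0, 2.0, 3.0])
        roll = continue_prediction(pred, seed, steps=9)
        expect = [np.roll(seed, k + 1) for k in range(9)]
        np.testing.assert_allclose(roll.steps, expect)

    def test_zero_seed_zero_rollout(self, rng):
        pred = fit_pseudoinverse(random_windows(rng))
        roll = continue_prediction(pred, np.zeros(6), steps=5)
        np.testing.assert_allclose(roll.steps, 0)
        np.testing.assert_allclose(roll.fade, 0)

    def test_nonfinite_truncates_with_warning(self):
        from placegrid.prediction import PseudoinversePredictor

        pred = PseudoinversePredictor(M=np.full((2, 2), 1e200))
        with pytest.warns(UserWarning, match="truncat"):
            roll = continue_prediction(pred, np.ones(2), steps=10)
        assert roll.truncated and len(roll.steps) < 10

    def test_planted_period_continues_three_periods(self):
        # predictor trained inside the arena continues the planted period
        # beyond it with small phase error
        period = 10
        field = sinusoid_field(resolution=40, period_steps=period)
        windows = build_path_windows(field, 0.0, 6)
        pred = fit_pseudoinverse(windows)
        seeds, ends = edge_seed_windows(field, 0.0, 6)
        roll = continue_prediction(pred, seeds[0], steps=4 * period)
        lead = roll.steps[:, 0]
        # peaks of the continued signal should be period steps apart
        peaks = [
            i for i in range(1, len(lead) - 1)
            if lead[i] > lead[i - 1] and lead[i] >= lead[i + 1] and lead[i] > 0.5
        ]
        assert len(peaks) >= 3
        gaps = np.diff(peaks)
        assert np.all(np.abs(gaps - period) <= 0.05 * period)


class TestPredictionField:
    def test_single_rollout_field(self):
        field = sinusoid_field(resolution=20)
        windows = build_path_windows(field, 0.0, 4)
        pred = fit_pseudoinverse(windows)
        out = render_prediction_field(pred, field, 0.0, 4, steps=12)
        n_edge = len(edge_seed_windows(field, 0.0, 4)[0])
        assert out.leading.shape == (n_edge, 12)

    def test_field_positions_leave_arena(self):
        field = sinusoid_field(resolution=20)
        windows = build_path_windows(field, 80.0, 4)
        pred = fit_pseudoinverse(windows)
        out = render_prediction_field(pred, field, 80.0, 4, steps=30)
        pos = out.positions()
        assert pos[:, -1, 1].min() > 1.0  # mostly-upward heading exits the top

    def test_planted_period_recovered_from_peaks(self):
        period = 8
        field = sinusoid_field(resolution=32, period_steps=period)
        windows = build_path_windows(field, 0.0, 6)
        pred = fit_pseudoinverse(windows)
        out = render_prediction_field(pred, field, 0.0, 6, steps=40)
        peaks = field_peaks(out, min_value=0.3)
        assert len(peaks) > 0
        # distances between consecutive peaks along each path row
        z = out.leading
        row = z[z.shape[0] // 2]
        idx = [i for i in range(1, 39) if row[i] > row[i - 1] and row[i] >= row[i + 1] and row[i] > 0.3]
        assert len(idx) >= 2
        assert np.all(np.abs(np.diff(idx) - period) <= 1)


class TestLeadingComponentOscillates:
    def test_variance_along_multi_field_path(self):
        field = sinusoid_field(resolution=30, period_steps=6)
        w = build_path_windows(field, 0.0, 20)
        lead = w.R.reshape(w.n_windows, 20, w.m)[0, :, 0]
        assert np.var(lead) > 1e-3
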