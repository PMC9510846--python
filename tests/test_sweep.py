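import io

import numpy as np
import pandas as pd
import pytest

from bpsweep import (
    AccuracySurface,
    ConfigurationError,
    GradientSeries,
    GridSpec,
    NoFitError,
    Trajectory,
    best_fit,
    cramer_solve,
    fit_pair,
    make_grid,
    sweep_surface,
)
from bpsweep.bp import analytic_gradients, bp_terms
from bpsweep.trajectories import estimate_gradients


def _surface_from_rows(rows):
    frame = pd.DataFrame(rows, columns=["a", "b", "p", "q", "sse", "n_failed_trials"])
    return AccuracySurface(frame=frame, provenance={})


class TestMakeGrid:
    def test_tiny_integer_grid(self):
        grid = make_grid(GridSpec(step=1.0, b_max=3.0))
        assert {tuple(g) for g in grid} == {(1, 2), (1, 3), (2, 3)}

    def test_lexicographic_order(self):
        grid = make_grid(GridSpec(step=0.5, b_max=2.0))
        assert [tuple(np.round(g, 6)) for g in grid] == [
            (0.5, 1.0), (0.5, 1.5), (0.5, 2.0),
            (1.0, 1.5), (1.0, 2.0), (1.5, 2.0),
        ]

    def test_region_filter(self):
        spec = GridSpec(step=1.0, b_max=3.0, region_filter=lambda a, b: a >= 2)
        assert {tuple(g) for g in make_grid(spec)} == {(2, 3)}

    def test_empty_grid_is_configuration_error(self):
        spec = GridSpec(step=1.0, b_max=3.0, region_filter=lambda a, b: False)
        with pytest.raises(ConfigurationError):
            make_grid(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            GridSpec(step=-0.01)
        with pytest.raises(ConfigurationError):
            GridSpec(step=0.05, a_min=0.01)
        with pytest.raises(ConfigurationError):
            GridSpec(step=0.05, b_max=0.04)

    def test_points_are_integer_multiples_of_step(self):
        """Grid values come from integer indices, not accumulated increments."""
        grid = make_grid(GridSpec(step=0.05, b_max=3.0, a_min=1.0))
        ratios = grid / 0.05
        np.testing.assert_allclose(ratios, np.round(ratios), atol=1e-9)


class TestFitPair:
    def test_zero_gradient_targets_force_zero_coefficients(self):
        """Zero targets zero every Cramer numerator, so p = q = 0 and SSE = 0."""
        traj = Trajectory([0, 1, 2, 3], [1.0, 2.0, 4.0, 8.0])
        grads = GradientSeries(traj.times, np.zeros(4))
        fit = fit_pair(traj, grads, 1.0, 2.0, trials=10, rng=np.random.default_rng(0))
        assert fit.p == 0.0 and fit.q == 0.0 and fit.sse == 0.0
        assert fit.n_failed_trials == 0

    def test_recovers_logistic_coefficients_at_true_exponents(self, logistic_traj,
                                                              logistic_params):
        grads = analytic_gradients(logistic_traj, logistic_params)
        fit = fit_pair(logistic_traj, grads, 1.0, 2.0, trials=20,
                       rng=np.random.default_rng(1))
        assert fit.p == pytest.approx(logistic_params.p, rel=1e-6)
        assert fit.q == pytest.approx(logistic_params.q, rel=1e-6)
        assert fit.sse <= 1e-12 * float(np.sum(grads.dvdt**2))

    def test_wrong_exponents_score_strictly_worse(self, logistic_traj, logistic_params):
        grads = analytic_gradients(logistic_traj, logistic_params)
        right = fit_pair(logistic_traj, grads, 1.0, 2.0, trials=20,
                         rng=np.random.default_rng(2))
        wrong = fit_pair(logistic_traj, grads, 2.9, 3.0, trials=20,
                         rng=np.random.default_rng(2))
        assert wrong.sse > right.sse

    def test_trials_agree_with_cramer_solve(self, center_traj):
        """The vectorized 2x2 trial solve is the same arithmetic as the
        general Cramer solver applied to the winning design."""
        grads = estimate_gradients(center_traj)
        for a, b in [(1.2, 2.1), (1.6, 2.45), (2.0, 3.0)]:
            fit = fit_pair(center_traj, grads, a, b, trials=20,
                           rng=np.random.default_rng(3))
            i, j = fit.win_idx
            v = center_traj.volumes
            Z = np.array([[v[i] ** a, v[j] ** a], [v[i] ** b, v[j] ** b]])
            Y = np.array([grads.dvdt[i], grads.dvdt[j]])
            c = cramer_solve(Z, Y)
            assert fit.p == pytest.approx(c[0], rel=1e-12)
            assert fit.q == pytest.approx(-c[1], rel=1e-12)

    def test_winning_pair_interpolates_its_timepoints(self, center_traj):
        """Exact-interpolation contract: the stored (p, q) reproduces the
        gradient targets at the two winning timepoints."""
        grads = estimate_gradients(center_traj)
        rng = np.random.default_rng(4)
        for a, b in [(1.1, 1.5), (1.5, 2.5), (2.5, 3.0)]:
            fit = fit_pair(center_traj, grads, a, b, trials=20, rng=rng)
            for k in fit.win_idx:
                ta, tb = bp_terms(center_traj.volumes[k], a, b)
                pred = fit.p * ta - fit.q * tb
                assert pred == pytest.approx(grads.dvdt[k], rel=1e-8)

    def test_best_of_trials_is_min_of_trial_sses(self, center_traj):
        grads = estimate_gradients(center_traj)
        fit = fit_pair(center_traj, grads, 1.3, 2.2, trials=20,
                       rng=np.random.default_rng(5), keep_trials=True)
        assert fit.sse == np.min(fit.trial_sses)
        # more trials from the same stream can only improve the minimum
        assert np.min(fit.trial_sses) <= np.min(fit.trial_sses[:5])

    def test_all_singular_trials_yield_infinite_sse(self):
        # constant volumes make every 2x2 design rank-1
        traj = Trajectory([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        grads = GradientSeries(traj.times, np.ones(4))
        fit = fit_pair(traj, grads, 1.0, 2.0, trials=7,
                       rng=np.random.default_rng(6))
        assert np.isinf(fit.sse)
        assert fit.n_failed_trials == 7
        assert fit.win_idx is None


class TestSweepSurface:
    def test_deterministic_under_fixed_seed(self, center_traj):
        grads = estimate_gradients(center_traj)
        spec = GridSpec(step=0.25, b_max=3.0, a_min=1.0)
        s1 = sweep_surface(center_traj, grads, spec, trials=20, seed=123)
        s2 = sweep_surface(center_traj, grads, spec, trials=20, seed=123)
        pd.testing.assert_frame_equal(s1.frame, s2.frame)
        s3 = sweep_surface(center_traj, grads, spec, trials=20, seed=124)
        assert not s1.frame.equals(s3.frame)

    def test_one_entry_per_grid_pair_and_finite_sses_nonnegative(self, center_traj):
        grads = estimate_gradients(center_traj)
        spec = GridSpec(step=0.25, b_max=3.0)
        surface = sweep_surface(center_traj, grads, spec, trials=5, seed=0)
        assert len(surface) == len(make_grid(spec))
        sse = surface.sse
        assert np.all(sse[np.isfinite(sse)] >= 0)

    def test_every_stored_fit_interpolates_its_winning_timepoints(self, center_traj):
        grads = estimate_gradients(center_traj)
        spec = GridSpec(step=0.25, b_max=3.0, a_min=1.0)
        surface = sweep_surface(center_traj, grads, spec, trials=20, seed=9)
        v, y = center_traj.volumes, grads.dvdt
        for k in range(len(surface)):
            fit = surface.result_at(k)
            if not np.isfinite(fit.sse):
                continue
            for idx in fit.win_idx:
                pred = fit.p * v[idx] ** fit.a - fit.q * v[idx] ** fit.b
                assert pred == pytest.approx(y[idx], rel=1e-8), (fit.a, fit.b)

    def test_csv_roundtrip(self, center_traj, tmp_path):
        grads = estimate_gradients(center_traj)
        surface = sweep_surface(center_traj, grads, GridSpec(step=0.5, b_max=3.0),
                                trials=5, seed=0)
        path = tmp_path / "surface.csv"
        surface.to_csv(path)
        back = AccuracySurface.from_csv(path)
        pd.testing.assert_frame_equal(
            back.frame, surface.frame[back.frame.columns], check_dtype=False
        )


class TestBestFit:
    def test_picks_minimum_sse(self):
        surf = _surface_from_rows([
            (1.0, 2.0, 0.1, 0.01, 3.0, 0),
            (1.0, 2.5, 0.1, 0.01, 1.0, 0),
            (2.0, 2.5, 0.1, 0.01, 2.0, 0),
        ])
        assert best_fit(surf).sse == 1.0

    def test_tie_broken_lexicographically(self):
        surf = _surface_from_rows([
            (1.0, 2.0, 0.1, 0.01, 1.0, 0),
            (1.0, 2.5, 0.2, 0.02, 1.0, 0),
        ])
        fit = best_fit(surf)
        assert (fit.a, fit.b) == (1.0, 2.0)

    def test_all_infinite_raises(self):
        surf = _surface_from_rows([
            (1.0, 2.0, np.nan, np.nan, np.inf, 20),
            (1.0, 2.5, np.nan, np.nan, np.inf, 20),
        ])
        with pytest.raises(NoFitError):
            best_fit(surf)

    def test_infinite_entries_skipped(self):
        surf = _surface_from_rows([
            (1.0, 2.0, np.nan, np.nan, np.inf, 20),
            (1.5, 2.5, 0.3, 0.02, 4.0, 0),
        ])
        assert best_fit(surf).sse == 4.0
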