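import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glvfit import (
    CVaRSpec,
    GridSpec,
    PriorSpec,
    build_design,
    build_grid,
    cvar_objective_value,
    draw_parameters,
    generate_dataset,
    transcribe,
)
from glvfit.exceptions import SpecificationError
from glvfit.models import simulate_experiment
from glvfit.synthetic import MeasurementSet
from glvfit.transcription import (
    DiscretizationCheck,
    ParameterBounds,
    check_discretization,
    implicit_euler_propagate,
)

from conftest import COARSE, population_prior_mean


class TestGrid:
    def test_mono_node_count_unrefined(self):
        e = build_design(1).experiment("mono-sp01")
        grid = build_grid(e, mono_substeps=1)
        assert grid.n_nodes == 49
        assert grid.times[0] == 0.0
        assert grid.times[-1] == 24.0

    def test_refined_grid_nests_original(self):
        e = build_design(1).experiment("mono-sp01")
        g1 = build_grid(e, mono_substeps=1)
        g2 = build_grid(e, mono_substeps=2)
        assert np.all(np.isin(np.round(g1.times, 9), np.round(g2.times, 9)))

    def test_pairwise_dilution_nodes_doubled(self):
        e = build_design(2).experiment("pair-sp01-sp02")
        grid = build_grid(e, pairwise_n_intervals=120)
        for t in (24.0, 48.0, 72.0):
            assert np.sum(np.isclose(grid.times, t)) == 2
        assert grid.n_nodes == 121 + 3

    def test_sampling_times_on_grid_exactly(self):
        e = build_design(2).experiment("pair-sp01-sp02")
        grid = build_grid(e, pairwise_n_intervals=120)
        for t in e.sampling_times_h:
            grid.node_of(t)  # raises if off-grid

    def test_default_resolution_is_tenth_hour(self):
        d = build_design(2)
        gm = build_grid(d.experiment("mono-sp01"))
        gp = build_grid(d.experiment("pair-sp01-sp02"))
        assert np.max(np.diff(gm.times)) == pytest.approx(0.1)
        hp = np.diff(gp.times)
        assert np.max(hp) == pytest.approx(0.1)

    def test_invalid_refinement_rejected(self):
        e = build_design(1).experiment("mono-sp01")
        with pytest.raises(SpecificationError):
            build_grid(e, mono_substeps=0)


class TestBounds:
    def test_biological_ranges(self):
        b = ParameterBounds.biological(2)
        # layout: mu1 a11 a12 mu2 a21 a22
        assert b.lower[0] == pytest.approx(0.09)
        assert b.upper[0] == pytest.approx(2.1)
        assert (b.lower[1], b.upper[1]) == (-10.0, 0.0)
        assert (b.lower[2], b.upper[2]) == (-10.0, 10.0)

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(SpecificationError):
            ParameterBounds(lower=[1.0], upper=[0.5])


class TestTranscribe:
    def test_variable_and_constraint_bookkeeping(self):
        design = build_design(3)
        params = draw_parameters(3, seed=1)
        data = generate_dataset(params, design, seed=2)
        nlp = transcribe("glv", design, data, grid=COARSE)
        assert nlp.n_theta == 12
        # states==constraints per experiment, so dof = parameters
        assert nlp.n_vars - nlp.n_eq == nlp.degrees_of_freedom == 12

    def test_degrees_of_freedom_with_cvar(self, community2):
        _, design, data = community2
        nlp = transcribe(
            "glv", design, data, cvar=CVaRSpec(enabled=True, beta=0.9), grid=COARSE
        )
        assert nlp.degrees_of_freedom == nlp.n_theta + 1

    def test_s12_has_156_parameter_variables(self):
        # structure only: no data needed beyond an empty-compatible table
        design = build_design(12)
        params = draw_parameters(12, seed=0)
        import pandas as pd

        rows = []
        for e in design:
            for t in e.sampling_times_h[:1]:
                for s in e.member_species:
                    rows.append((e.experiment_id, s, float(t), 0.1, 0.05))
        data = MeasurementSet(
            pd.DataFrame(rows, columns=list(MeasurementSet.COLUMNS))
        )
        nlp = transcribe("glv", design, data, grid=GridSpec(1, 8))
        assert nlp.n_theta == 156
        assert nlp.n_vars - nlp.n_eq == 156

    def test_propagated_states_satisfy_constraints(self, community2):
        params, design, data = community2
        nlp = transcribe("glv", design, data, grid=COARSE)
        w = nlp.initial_point()
        w[nlp.theta_slice] = params.theta("glv")
        for blk in nlp.blocks:
            X = implicit_euler_propagate(blk.experiment, blk.grid, params)
            w[blk.var_offset: blk.var_offset + blk.n_states] = X.ravel()
        res = nlp.constraints(w)
        assert np.abs(res[: nlp.n_state_rows]).max() < 1e-11

    def test_single_implicit_step_quadratic_root(self):
        # xdot = -x^2 from x0=1, h=1: implicit step root (sqrt(5)-1)/2
        from glvfit.models import CommunityParameters, Experiment
        from glvfit.transcription import Grid, EULER

        p = CommunityParameters(("a",), [0.0], [[-1.0]])
        e = Experiment("one", ("a",), 1.0, np.array([1.0]), np.array([1.0]))
        grid = Grid(np.array([0.0, 1.0]), np.array([EULER]))
        X = implicit_euler_propagate(e, grid, p)
        assert X[1, 0] == pytest.approx((np.sqrt(5) - 1) / 2, abs=1e-10)

    def test_objective_zero_at_prior_mean_and_exact_fit(self, community2):
        _, design, data = community2
        nlp = transcribe(
            "glv", design, data,
            prior=PriorSpec(form="l2", mean=population_prior_mean(2), std=1 / 50),
            grid=COARSE,
        )
        w = np.zeros(nlp.n_vars)
        w[nlp.theta_slice] = nlp.theta_mean
        w[nlp.meas_idx] = nlp.meas_eta
        assert nlp.objective(w) == pytest.approx(0.0, abs=1e-12)

    def test_single_residual_contributes_half(self, community2):
        _, design, data = community2
        nlp = transcribe("glv", design, data, prior=PriorSpec(form="none"), grid=COARSE)
        w = np.zeros(nlp.n_vars)
        w[nlp.meas_idx] = nlp.meas_eta
        w[nlp.meas_idx[0]] = nlp.meas_eta[0] + nlp.meas_sig[0]
        assert nlp.objective(w) == pytest.approx(0.5)

    def test_off_grid_measurement_time_rejected(self, community2):
        _, design, data = community2
        df = data.records.copy()
        df.loc[df.index[0], "time_h"] = 0.123456
        with pytest.raises(SpecificationError, match="0.123456"):
            transcribe("glv", design, MeasurementSet(df), grid=COARSE)

    def test_derivatives_match_finite_differences(self, community2):
        params, design, data = community2
        nlp = transcribe(
            "glv", design, data,
            prior=PriorSpec(form="l2", mean=population_prior_mean(2), std=1 / 50),
            grid=COARSE,
        )
        rng = np.random.default_rng(0)
        w = nlp.initial_point() + 0.01 * rng.standard_normal(nlp.n_vars)
        g, J = nlp.gradient(w), nlp.jacobian(w)
        lam = rng.standard_normal(nlp.n_eq)
        H = nlp.hess_lagrangian(w, lam)

        def grad_lagrangian(x):
            return nlp.gradient(x) + nlp.jacobian(x).T @ lam

        eps = 1e-6
        for i in rng.choice(nlp.n_vars, 25, replace=False):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fd_g = (nlp.objective(wp) - nlp.objective(wm)) / (2 * eps)
            assert fd_g == pytest.approx(g[i], rel=1e-5, abs=1e-6)
            fd_j = (nlp.constraints(wp) - nlp.constraints(wm)) / (2 * eps)
            assert np.abs(fd_j - J[:, [i]].toarray().ravel()).max() < 1e-6
            fd_h = (grad_lagrangian(wp) - grad_lagrangian(wm)) / (2 * eps)
            assert np.abs(fd_h - H[:, [i]].toarray().ravel()).max() < 1e-5

    def test_saturable_derivatives_match_finite_differences(self):
        params = draw_parameters(2, seed=1, saturations=True)
        design = build_design(2)
        data = generate_dataset(params, design, seed=3, model_form="saturable")
        nlp = transcribe("saturable", design, data, grid=COARSE)
        rng = np.random.default_rng(1)
        w = nlp.initial_point() + 0.01 * rng.standard_normal(nlp.n_vars)
        J = nlp.jacobian(w)
        lam = rng.standard_normal(nlp.n_eq)
        H = nlp.hess_lagrangian(w, lam)

        def grad_lagrangian(x):
            return nlp.gradient(x) + nlp.jacobian(x).T @ lam

        eps = 1e-6
        for i in rng.choice(nlp.n_vars, 20, replace=False):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fd_j = (nlp.constraints(wp) - nlp.constraints(wm)) / (2 * eps)
            assert np.abs(fd_j - J[:, [i]].toarray().ravel()).max() < 1e-6
            fd_h = (grad_lagrangian(wp) - grad_lagrangian(wm)) / (2 * eps)
            assert np.abs(fd_h - H[:, [i]].toarray().ravel()).max() < 1e-5

    def test_euler_convergence_is_first_order(self):
        params = draw_parameters(2, seed=13)
        design = build_design(2)
        pair = design.experiment("pair-sp01-sp02")
        ref = simulate_experiment(params, pair)
        errs, hs = [], []
        for n_int in (120, 240, 480, 960):
            grid = build_grid(pair, pairwise_n_intervals=n_int)
            X = implicit_euler_propagate(pair, grid, params)
            exact = np.vstack([ref.at([t])[0] for t in pair.sampling_times_h])
            approx = np.vstack(
                [X[grid.node_of(t)] for t in pair.sampling_times_h]
            )
            errs.append(np.abs(exact - approx).max())
            hs.append(96.0 / n_int)
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 0.8 <= order <= 1.2


class TestCVaRValue:
    def test_top_decile_of_1_to_10(self):
        v = cvar_objective_value(np.arange(1.0, 11.0), beta=0.9)
        assert v.cvar == pytest.approx(10.0)

    def test_beta_zero_is_sum(self):
        e = np.array([3.0, 1.0, 4.0, 1.5])
        v = cvar_objective_value(e, beta=0.0)
        assert v.minimized_value == pytest.approx(e.sum())

    def test_constant_vector_any_beta(self):
        for beta in (0.0, 0.5, 0.9):
            assert cvar_objective_value(np.full(7, 2.5), beta).cvar == pytest.approx(2.5)

    def test_matches_brute_force_gamma_grid(self):
        rng = np.random.default_rng(5)
        e = rng.exponential(2.0, 40)
        beta = 0.8
        K = e.size
        gammas = np.linspace(e.min() - 1, e.max() + 1, 20001)
        brute = np.min(
            [K * g + np.maximum(e - g, 0).sum() / (1 - beta) for g in gammas]
        )
        v = cvar_objective_value(e, beta)
        assert v.minimized_value == pytest.approx(brute, rel=1e-6)

    @given(
        errors=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=30),
        b1=st.floats(0.0, 0.98),
        b2=st.floats(0.0, 0.98),
    )
    @settings(max_examples=60, deadline=None)
    def test_minimized_cvar_nondecreasing_in_beta(self, errors, b1, b2):
        lo, hi = sorted((b1, b2))
        e = np.asarray(errors)
        assert (
            cvar_objective_value(e, hi).cvar
            >= cvar_objective_value(e, lo).cvar - 1e-9
        )

    def test_beta_near_one_approaches_max(self):
        e = np.array([1.0, 5.0, 2.0])
        assert cvar_objective_value(e, 0.99).cvar == pytest.approx(5.0)


class TestDiscretizationCheck:
    def test_identical_estimates_pass(self):
        check = check_discretization(lambda gs: np.array([1.0, 2.0]), GridSpec(1, 8))
        assert check.passed

    def test_relative_criterion(self):
        thetas = iter([np.array([1.0]), np.array([1.005])])
        check = check_discretization(lambda gs: next(thetas), GridSpec(1, 8))
        assert check.passed  # relative 0.005 < 0.01

    def test_both_criteria_fail(self):
        thetas = iter([np.array([0.5]), np.array([0.53])])
        check = check_discretization(lambda gs: next(thetas), GridSpec(1, 8))
        assert not check.passed  # abs 0.03 > 0.01 and rel 0.06 > 0.01
        assert check.worst_index == 0
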