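import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from glvfit import PriorSpec, build_design, draw_parameters, generate_dataset, transcribe
from glvfit.exceptions import SolverError, SpecificationError
from glvfit.kkt import (
    BBDSystem,
    assemble_kkt,
    bbd_inertia,
    build_bbd,
    inertia,
    observability_test,
    schur_solve,
)
from glvfit.models import Experiment
from glvfit.solve import solve
from glvfit.synthetic import ExperimentDesign

from conftest import COARSE


def random_bbd(rng, n_blocks=None, definite=False):
    """Random symmetric BBD system (blocks a.s. nonsingular).

    With ``definite=True`` the experiment blocks are positive definite, i.e.
    they carry the healthy inertia their dims ``(n_k, 0)`` promise.
    """
    n_g = int(rng.integers(2, 5))
    n_blocks = n_blocks or int(rng.integers(2, 4))
    K_theta = rng.standard_normal((n_g, n_g))
    K_theta = K_theta + K_theta.T
    if definite:
        K_theta = K_theta @ K_theta.T + np.eye(n_g)
    Ks, Bs, dims = [], [], []
    for _ in range(n_blocks):
        sz = int(rng.integers(3, 10))
        A = rng.standard_normal((sz, sz))
        K = A @ A.T + np.eye(sz) if definite else A + A.T
        Ks.append(sp.csc_matrix(K))
        Bs.append(rng.standard_normal((n_g, sz)))
        dims.append((sz, 0))
    return BBDSystem(
        K_theta=K_theta,
        K_blocks=Ks,
        B_blocks=Bs,
        block_labels=[f"b{i}" for i in range(n_blocks)],
        block_dims=dims,
        permutation=np.arange(n_g + sum(K.shape[0] for K in Ks)),
        n_border_vars=n_g,
        n_border_rows=0,
    )


class TestInertia:
    def test_identity(self):
        assert inertia(np.eye(5)) == (5, 0, 0)

    def test_mixed_diagonal(self):
        assert inertia(np.diag([2.0, -5.0, 0.0])) == (1, 1, 1)

    def test_matches_eigendecomposition_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            A = rng.standard_normal((20, 20))
            A = A + A.T
            ev = np.linalg.eigvalsh(A)
            assert inertia(A) == (int((ev > 0).sum()), int((ev < 0).sum()), 0)

    def test_wide_dynamic_range(self):
        # saddle structure with 1e9 scale spread: equilibration keeps the
        # tiny true negative eigenvalue from being declared zero
        A = np.array([[1e9, 1.0], [1.0, 0.0]])
        assert inertia(A) == (1, 1, 0)

    def test_asymmetric_rejected(self):
        with pytest.raises(SpecificationError):
            inertia(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestAssembleKKT:
    def test_residual_small_at_optimum(self, logistic_map_solution):
        nlp, res = logistic_map_solution
        kkt = assemble_kkt(nlp, res)
        assert kkt.kkt_residual < 1e-3  # 10x solver tolerance on the gradient scale
        assert (abs(kkt.matrix - kkt.matrix.T)).max() == 0.0

    def test_regularization_shifts_variable_diagonal(self, logistic_map_solution):
        nlp, res = logistic_map_solution
        m0 = assemble_kkt(nlp, res, kappa_w=0.0).matrix
        m1 = assemble_kkt(nlp, res, kappa_w=1.0).matrix
        d = (m1 - m0).toarray()
        expect = np.zeros(m0.shape[0])
        expect[: nlp.n_vars] = 1.0
        assert np.allclose(np.diag(d), expect)
        assert np.allclose(d - np.diag(np.diag(d)), 0.0)

    def test_monotone_regularization(self, logistic_map_solution):
        nlp, res = logistic_map_solution
        prev_plus, prev_rest = -1, None
        for kap in (0.0, 1e-2, 1e2):
            i = inertia(assemble_kkt(nlp, res, kappa_w=kap).matrix)
            assert i[0] >= prev_plus
            if prev_rest is not None:
                assert i[1] + i[2] <= prev_rest
            prev_plus, prev_rest = i[0], i[1] + i[2]

    def test_missing_multipliers_rejected(self, logistic_map_solution):
        import dataclasses

        nlp, res = logistic_map_solution
        bad = dataclasses.replace(res, lam_eq=np.empty(0))
        with pytest.raises(SpecificationError):
            assemble_kkt(nlp, bad)


class TestBBD:
    def test_permutation_equivalence(self, logistic_map_solution):
        nlp, res = logistic_map_solution
        kkt = assemble_kkt(nlp, res)
        bbd = build_bbd(nlp, kkt)
        P = bbd.permutation
        assert (abs(bbd.assemble() - kkt.matrix.tocsr()[P][:, P])).max() == 0.0

    def test_haynsworth_additivity_random_systems(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            bbd = random_bbd(rng)
            M = bbd.assemble().toarray()
            ev = np.linalg.eigvalsh(M)
            dense = (int((ev > 0).sum()), int((ev < 0).sum()), 0)
            rep = bbd_inertia(bbd)
            assert (rep.n_plus, rep.n_minus, rep.n_zero) == dense

    def test_schur_solve_matches_direct(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            bbd = random_bbd(rng)
            M = bbd.assemble().tocsc()
            rhs = rng.standard_normal(M.shape[0])
            x = schur_solve(bbd, rhs)
            direct = spla.spsolve(M, rhs)
            assert np.linalg.norm(x - direct) <= 1e-8 * np.linalg.norm(direct)

    def test_zero_rhs_gives_zero(self):
        rng = np.random.default_rng(9)
        bbd = random_bbd(rng)
        assert np.all(schur_solve(bbd, np.zeros(bbd.assemble().shape[0])) == 0.0)

    def test_single_block_equals_block_elimination(self):
        rng = np.random.default_rng(10)
        bbd = random_bbd(rng, n_blocks=1)
        M = bbd.assemble().toarray()
        rhs = rng.standard_normal(M.shape[0])
        assert schur_solve(bbd, rhs) == pytest.approx(np.linalg.solve(M, rhs), rel=1e-8)

    def test_duplicated_parameter_column_not_observable(self):
        # theta_1 and theta_2 enter only as a sum: zero eigenvalue in S
        rng = np.random.default_rng(11)
        bbd = random_bbd(rng, definite=True)
        for B in bbd.B_blocks:
            B[1] = B[0]  # second border row duplicates the first
        bbd.K_theta[1] = bbd.K_theta[0]
        bbd.K_theta[:, 1] = bbd.K_theta[:, 0]
        rep = bbd_inertia(bbd)
        assert rep.schur_inertia[2] >= 1
        assert rep.verdict == "not_observable"


class TestObservability:
    def test_informative_mono_data_is_observable(self, logistic_noprior_solution):
        nlp, res = logistic_noprior_solution
        report, cov = observability_test(nlp, res)
        assert report.verdict == "observable"
        assert cov is not None and cov.shape == (2, 2)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_uncultured_species_parameters_not_observable(self):
        labels = ("sp01", "sp02")
        e = Experiment(
            "mono-sp01", ("sp01",), 24.0, np.arange(0.5, 24.01, 0.5), np.array([0.01])
        )
        design = ExperimentDesign(labels, (e,))
        params = draw_parameters(2, seed=3)
        data = generate_dataset(params, design, seed=5)
        nlp = transcribe("glv", design, data, prior=PriorSpec(form="none"))
        res = solve(nlp)
        assert res.is_optimal
        report, cov = observability_test(nlp, res)
        assert report.verdict == "not_observable"
        # mu2, alpha_12, alpha_21, alpha_22 never enter any residual
        assert report.schur_inertia[2] == 4
        assert cov is None

    def test_l2_prior_restores_observability(self):
        labels = ("sp01", "sp02")
        e = Experiment(
            "mono-sp01", ("sp01",), 24.0, np.arange(0.5, 24.01, 0.5), np.array([0.01])
        )
        design = ExperimentDesign(labels, (e,))
        params = draw_parameters(2, seed=3)
        data = generate_dataset(params, design, seed=5)
        nlp = transcribe("glv", design, data, prior=PriorSpec(form="l2", mean=0.3, std=1 / 50))
        res = solve(nlp)
        rep = bbd_inertia(build_bbd(nlp, assemble_kkt(nlp, res)))
        assert rep.verdict == "observable"

    def test_covariance_matches_linear_gaussian_formula(self, logistic_noprior_solution):
        """On (nearly) linear problems the reduced-Hessian inverse equals
        (G^T Sigma^-1 G)^-1 built from output sensitivities."""
        nlp, res = logistic_noprior_solution
        _, cov = observability_test(nlp, res)
        # output sensitivities by finite differences through the implicit model
        from glvfit.models import CommunityParameters, simulate_experiment
        from glvfit.transcription import implicit_euler_propagate

        blk = nlp.blocks[0]
        exp = blk.experiment
        theta0 = res.theta_star

        def outputs(theta):
            p = CommunityParameters.from_theta(theta, ("sp01",), "glv")
            X = implicit_euler_propagate(exp, blk.grid, p)
            return np.array([X[blk.grid.node_of(t), 0] for t in exp.sampling_times_h])

        eps = 1e-6
        G = np.column_stack(
            [
                (outputs(theta0 + eps * np.eye(2)[i]) - outputs(theta0 - eps * np.eye(2)[i]))
                / (2 * eps)
                for i in range(2)
            ]
        )
        sig = nlp.meas_sig
        fisher = G.T @ (G / sig[:, None] ** 2)
        assert cov == pytest.approx(np.linalg.inv(fisher), rel=1e-2)

    def test_requires_optimal_result(self, logistic_noprior_solution):
        import dataclasses

        nlp, res = logistic_noprior_solution
        with pytest.raises(SolverError):
            observability_test(nlp, dataclasses.replace(res, status="max_iter"))


class TestExport:
    def test_coo_roundtrip(self, tmp_path):
        from glvfit.kkt import save_coo

        A = sp.random(8, 8, density=0.3, random_state=1)
        save_coo(A, tmp_path / "m.txt")
        data = np.loadtxt(tmp_path / "m.txt")
        B = sp.coo_matrix(
            (data[:, 2], (data[:, 0].astype(int), data[:, 1].astype(int))), shape=(8, 8)
        )
        assert abs(A - B).max() < 1e-15
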