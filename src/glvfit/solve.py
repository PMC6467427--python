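"""Interior-point solution of transcribed estimation problems.

The package supplies exact sparse first and second derivatives and delegates
the optimization itself — barrier schedule, step acceptance, inertia
correction — to an established large-scale solver behind a thin contract
(:func:`solve`).  The default backend is SciPy's ``trust-constr``, an
interior-point/trust-region method that consumes the sparse Jacobian and
Lagrangian Hessian callbacks directly.

Multipliers used by the downstream KKT analysis are recovered from the
first-order stationarity conditions at the returned point (sparse least
squares on the rows of variables away from their bounds), which is exact at
an optimum and independent of backend sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from .exceptions import SolverError, SpecificationError
from .transcription import TranscribedNLP

__all__ = [
    "SolverOptions",
    "SolveResult",
    "WarmStart",
    "solve",
    "default_initialization",
    "multistart",
    "warm_start_from",
    "recover_multipliers",
]


@dataclass(frozen=True)
class SolverOptions:
    """Backend configuration.

    ``tol`` is the first-order optimality (gradient) tolerance;
    ``constr_tol`` the accepted equality-constraint violation at a point
    reported optimal.
    """

    max_iterations: int = 3000
    tol: float = 1e-6
    constr_tol: float = 1e-6
    xtol: float = 1e-10
    backend: str = "trust-constr"
    hessian: str = "exact"  # "exact" | "limited-memory"
    verbose: int = 0
    # barrier parameter for warm-started re-solves (None: backend default for
    # cold starts, 1e-6 when starting from a WarmStart near an optimum)
    initial_barrier_parameter: float | None = None

    def __post_init__(self):
        if self.tol <= 0 or self.constr_tol <= 0:
            raise SpecificationError("solver tolerances must be positive")
        if self.hessian not in ("exact", "limited-memory"):
            raise SpecificationError("hessian mode must be 'exact' or 'limited-memory'")


@dataclass
class SolveResult:
    """Solution bundle: primal point, extracted parameters, multipliers."""

    w_star: np.ndarray
    theta_star: np.ndarray
    lam_eq: np.ndarray
    lam_ineq: np.ndarray
    nu_lower: np.ndarray
    nu_upper: np.ndarray
    objective: float
    status: str  # optimal | max_iter | infeasible | error
    n_iterations: int
    constr_violation: float
    optimality: float
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class WarmStart:
    """Primal/dual starting information for a nearby re-solve."""

    w: np.ndarray
    lam_eq: np.ndarray
    lam_ineq: np.ndarray
    nu_lower: np.ndarray
    nu_upper: np.ndarray


def default_initialization(nlp: TranscribedNLP, seed: int | None = None) -> np.ndarray:
    """Measurement-interpolating initial point (deterministic given seed)."""
    return nlp.initial_point(seed=seed)


def recover_multipliers(nlp: TranscribedNLP, w, active_tol: float = 1e-7):
    """First-order multiplier recovery at a (near-)stationary point.

    Solves ``min_lam || grad(f) + J^T lam ||`` over the stationarity rows of
    variables strictly inside their bounds, then reads the bound multipliers
    off the residual at (near-)active bounds.  Inequality (CVaR) rows enter
    only when active.
    """
    w = np.asarray(w, dtype=float)
    g = nlp.gradient(w)
    J = nlp.jacobian(w)
    blocks = [J]
    if nlp.n_ineq:
        ci = nlp.constraints_ineq(w)
        Ji = nlp.jacobian_ineq(w)
        active = ci <= active_tol * (1.0 + np.abs(ci))
        mask = sp.diags(active.astype(float))
        blocks.append(mask @ Ji)
    A = sp.vstack(blocks).tocsr()
    lb, ub = nlp.bounds()
    scale = 1.0 + np.abs(w)
    inactive = (w - lb > active_tol * scale) & (ub - w > active_tol * scale)
    sel = sp.diags(inactive.astype(float))
    lam = spla.lsqr(sel @ A.T, -(inactive * g), atol=1e-12, btol=1e-12)[0]
    lam_eq = lam[: nlp.n_eq]
    lam_ineq = lam[nlp.n_eq:]
    resid = g + A.T @ lam
    nu_lower = np.where(~inactive & (np.abs(w - lb) <= np.abs(ub - w)), resid, 0.0)
    nu_upper = np.where(~inactive & (np.abs(ub - w) < np.abs(w - lb)), -resid, 0.0)
    return lam_eq, lam_ineq, nu_lower, nu_upper


def solve(
    nlp: TranscribedNLP,
    initial_point=None,
    options: SolverOptions | None = None,
) -> SolveResult:
    """Solve a transcribed NLP to a KKT point.

    ``initial_point`` may be a primal vector or a :class:`WarmStart`;
    points outside the bounds are projected inward before the backend runs.
    """
    if options is None:
        options = SolverOptions()
    if options.backend != "trust-constr":
        raise SolverError(
            f"backend {options.backend!r} unavailable; install it or use 'trust-constr'"
        )
    lb, ub = nlp.bounds()
    if np.any(lb >= ub):
        raise SpecificationError("contradictory bounds: lower >= upper")

    if initial_point is None:
        w0 = nlp.initial_point()
    elif isinstance(initial_point, WarmStart):
        w0 = initial_point.w.copy()
    else:
        w0 = np.asarray(initial_point, dtype=float).copy()
    margin = 1e-8 * (1.0 + np.abs(w0))
    w0 = np.clip(w0, lb + np.where(np.isfinite(lb), margin, 0.0),
                 ub - np.where(np.isfinite(ub), margin, 0.0))

    constraints = [
        NonlinearConstraint(
            nlp.constraints, 0.0, 0.0, jac=nlp.jacobian, hess=lambda x, v: nlp.hess_eq(x, v)
        )
    ]
    if nlp.n_ineq:
        constraints.append(
            NonlinearConstraint(
                nlp.constraints_ineq,
                0.0,
                np.inf,
                jac=nlp.jacobian_ineq,
                hess=lambda x, v: nlp.hess_ineq(x, v),
            )
        )
    hess = nlp.hess_objective if options.hessian == "exact" else "2-point"
    backend_opts = dict(
        gtol=options.tol,
        xtol=options.xtol,
        maxiter=options.max_iterations,
        verbose=options.verbose,
    )
    ibp = options.initial_barrier_parameter
    if ibp is None and isinstance(initial_point, WarmStart):
        ibp = 1e-6  # skip most of the barrier schedule near an optimum
    if ibp is not None:
        backend_opts["initial_barrier_parameter"] = ibp
    try:
        res = minimize(
            nlp.objective,
            w0,
            jac=nlp.gradient,
            hess=hess,
            bounds=Bounds(lb, ub),
            constraints=constraints,
            method="trust-constr",
            options=backend_opts,
        )
    except FloatingPointError as err:
        return SolveResult(
            w_star=w0,
            theta_star=nlp.extract_theta(w0),
            lam_eq=np.zeros(nlp.n_eq),
            lam_ineq=np.zeros(nlp.n_ineq),
            nu_lower=np.zeros(nlp.n_vars),
            nu_upper=np.zeros(nlp.n_vars),
            objective=np.nan,
            status="error",
            n_iterations=0,
            constr_violation=np.nan,
            optimality=np.nan,
            message=str(err),
        )

    if res.status in (1, 2) and res.constr_violation <= options.constr_tol:
        status = "optimal"
    elif res.status == 0:
        status = "max_iter"
    elif res.constr_violation > options.constr_tol:
        status = "infeasible"
    else:
        status = "error"

    lam_eq, lam_ineq, nu_lo, nu_up = recover_multipliers(nlp, res.x)
    return SolveResult(
        w_star=res.x,
        theta_star=nlp.extract_theta(res.x),
        lam_eq=lam_eq,
        lam_ineq=lam_ineq,
        nu_lower=nu_lo,
        nu_upper=nu_up,
        objective=float(res.fun),
        status=status,
        n_iterations=int(res.niter),
        constr_violation=float(res.constr_violation),
        optimality=float(res.optimality),
        message=str(res.message),
    )


def solve_robust(nlp: TranscribedNLP, options: SolverOptions | None = None):
    """Solve a CVaR-objective problem via a standard-MAP warmup stage.

    The minimax-like CVaR geometry is hard for the backend from a cold start;
    solving the plain MAP problem first and starting the CVaR solve from its
    states and parameters (with the auxiliaries set consistently) is robust.
    Returns ``(cvar_result, warmup_result)``; for a non-CVaR problem the
    single solve is returned with ``warmup_result=None``.
    """
    if not nlp.cvar_enabled:
        return solve(nlp, options=options), None
    from .transcription import transcribe

    nlp_std = transcribe(
        nlp.model_form,
        nlp.design,
        nlp.data,
        prior=nlp.prior,
        cvar=None,
        bounds=nlp.bounds_theta,
        grid=nlp.grids,
    )
    warmup = solve(nlp_std, options=options)
    w0 = nlp.initial_point()
    if warmup.is_optimal:
        w0[: nlp_std.n_vars] = warmup.w_star
        e = nlp.experiment_errors(w0)
        g0 = float(np.quantile(e, nlp.cvar.beta))
        K = nlp.n_experiments
        w0[nlp.gamma_index] = g0
        w0[nlp.slack_offset: nlp.slack_offset + K] = np.maximum(e - g0, 0.0) + 1e-3
        w0[nlp.terr_offset: nlp.terr_offset + K] = e + 1e-6
    return solve(nlp, w0, options), warmup


def multistart(
    nlp: TranscribedNLP,
    n_starts: int,
    seed: int = 0,
    options: SolverOptions | None = None,
):
    """Best-of-``n_starts`` solves; parameter components of starts 2..n are
    drawn uniformly inside the bounds box.

    Returns ``(best, results)``.  The first start is the default
    initialization; infinite bound edges are truncated to a width-10 box for
    sampling.
    """
    if n_starts < 1:
        raise SpecificationError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    base = nlp.initial_point()
    for i in range(n_starts):
        w0 = base.copy()
        if i > 0:
            lo = nlp.bounds_theta.lower
            hi = np.minimum(nlp.bounds_theta.upper, lo + 10.0)
            w0[nlp.theta_slice] = rng.uniform(lo, hi)
        results.append(solve(nlp, w0, options))
    optimal = [r for r in results if r.is_optimal]
    if not optimal:
        raise SolverError(
            f"all {n_starts} starts failed: statuses {[r.status for r in results]}"
        )
    best = min(optimal, key=lambda r: r.objective)
    return best, results


def warm_start_from(result: SolveResult) -> WarmStart:
    """Package an optimal solution's primal and dual values for re-solves."""
    if not result.is_optimal:
        raise SolverError("warm starts require an optimal source solve")
    return WarmStart(
        w=result.w_star.copy(),
        lam_eq=result.lam_eq.copy(),
        lam_ineq=result.lam_ineq.copy(),
        nu_lower=result.nu_lower.copy(),
        nu_upper=result.nu_upper.copy(),
    )
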