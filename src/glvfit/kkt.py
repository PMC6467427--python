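"""KKT-system assembly, inertia, and observability analysis.

At a solution ``w*`` of the transcribed problem the augmented (KKT) matrix

    M(kappa_w) = [[ H + kappa_w I,  J^T ],
                  [ J,              0   ]],
    H = hess(Lagrangian) + W^{-1} V

is nonsingular with inertia ``(n, m, 0)`` exactly when the constraint
Jacobian ``J`` has full row rank and the reduced Hessian (the Hessian
projected onto the null space of ``J``) is positive definite — which
certifies that the estimated parameters are locally unique (observable).
The null-space basis is never formed: the inertia is read off a symmetric
indefinite (LDL^T) factorization.

Because parameters are the only variables shared across experiments, a
symmetric permutation of ``M`` has block-bordered-diagonal (arrowhead) form
with one block ``K_k = [[H_k, J_k^T], [J_k, 0]]`` per experiment and the
parameter block on the border.  The Schur complement

    S = K_theta - sum_k B_k K_k^{-1} B_k^T

has the dimension of the parameter vector; by Haynsworth's inertia
additivity, ``Inertia(M) = sum_k Inertia(K_k) + Inertia(S)``, so
observability reduces to ``Inertia(K_k) = (n_k, m_k, 0)`` for every
experiment and ``S`` positive definite.  At the no-prior solution ``S`` is
the reduced Hessian, and its inverse approximates the parameter posterior
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import SolverError, SpecificationError
from .solve import SolveResult
from .transcription import TranscribedNLP

__all__ = [
    "KKTSystem",
    "BBDSystem",
    "InertiaReport",
    "assemble_kkt",
    "inertia",
    "build_bbd",
    "schur_solve",
    "bbd_inertia",
    "posterior_covariance",
    "observability_test",
]

_PIVOT_RTOL = 1e-8  # |pivot| below this times max|pivot| counts as zero


@dataclass
class KKTSystem:
    """Augmented matrix at a solution, plus the pieces it was built from."""

    matrix: sp.csr_matrix  # symmetric (n+m) x (n+m)
    hessian: sp.csr_matrix  # H = hess_lagrangian + W^{-1}V + kappa_w I
    jacobian: sp.csr_matrix
    kappa_w: float
    mu_b: float
    n: int
    m: int
    kkt_residual: float


@dataclass
class BBDSystem:
    """Block-bordered-diagonal permutation of the augmented matrix."""

    K_theta: np.ndarray  # dense (n_g, n_g) border block
    K_blocks: list  # per-experiment sparse [[H_k, J_k^T],[J_k, 0]]
    B_blocks: list  # per-experiment dense (n_g, n_k + m_k) borders
    block_labels: list  # experiment ids
    block_dims: list  # per-experiment (n_k, m_k)
    permutation: np.ndarray  # M = P M_bbd P^T reordering (bbd index -> M index)
    n_border_vars: int
    n_border_rows: int

    @property
    def n_border(self) -> int:
        return self.n_border_vars + self.n_border_rows

    def assemble(self) -> sp.csr_matrix:
        """Explicit BBD matrix (for permutation-equivalence checks)."""
        rows = []
        top = [sp.csr_matrix(self.K_theta)] + [sp.csr_matrix(B) for B in self.B_blocks]
        rows.append(sp.hstack(top))
        sizes = [K.shape[0] for K in self.K_blocks]
        for k, K in enumerate(self.K_blocks):
            row = [sp.csr_matrix(self.B_blocks[k].T)]
            for j, sz in enumerate(sizes):
                row.append(K if j == k else sp.csr_matrix((K.shape[0], sz)))
            rows.append(sp.hstack(row))
        return sp.vstack(rows).tocsr()


@dataclass
class InertiaReport:
    """Inertia of the augmented system and the observability verdict."""

    n_plus: int
    n_minus: int
    n_zero: int
    expected: tuple
    schur_inertia: tuple
    block_inertias: list
    verdict: str  # observable | not_observable | rank_deficient_jacobian
    active_bounds: int = 0

    def to_dict(self):
        return {
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "n_zero": self.n_zero,
            "expected": list(self.expected),
            "schur_inertia": list(self.schur_inertia),
            "verdict": self.verdict,
            "active_bounds": self.active_bounds,
        }


# ---------------------------------------------------------------------------


def save_coo(matrix, path) -> None:
    """Write a sparse matrix as whitespace-separated (i, j, value) text."""
    coo = sp.coo_matrix(matrix)
    np.savetxt(
        path,
        np.column_stack([coo.row, coo.col, coo.data]),
        fmt=["%d", "%d", "%.17g"],
        header=f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}",
    )


def assemble_kkt(
    nlp: TranscribedNLP,
    result: SolveResult,
    kappa_w: float = 0.0,
    mu_b: float = 0.0,
) -> KKTSystem:
    """Build the augmented matrix ``M(kappa_w)`` at a solution.

    ``mu_b`` is the barrier parameter used for the ``W^{-1}V`` bound term
    (``mu_b / slack^2`` on each finitely-bounded variable); the default 0
    drops bound curvature entirely, which is the convention for the pure
    observability test (bounds inactive at the solution contribute
    negligibly).
    """
    if result.lam_eq is None or result.lam_eq.size != nlp.n_eq:
        raise SpecificationError("result carries no equality multipliers")
    w = result.w_star
    H = nlp.hess_lagrangian(w, result.lam_eq, result.lam_ineq if nlp.n_ineq else None)
    n = nlp.n_vars
    if mu_b > 0.0:
        lb, ub = nlp.bounds()
        d = np.zeros(n)
        lo_gap = np.where(np.isfinite(lb), np.maximum(w - lb, 1e-12), np.inf)
        hi_gap = np.where(np.isfinite(ub), np.maximum(ub - w, 1e-12), np.inf)
        with np.errstate(divide="ignore"):
            d = np.where(np.isfinite(lo_gap), mu_b / lo_gap**2, 0.0)
            d += np.where(np.isfinite(hi_gap), mu_b / hi_gap**2, 0.0)
        H = H + sp.diags(d)
    if kappa_w:
        H = H + kappa_w * sp.identity(n)
    J = nlp.jacobian(w)
    M = sp.bmat([[H, J.T], [J, None]], format="csr")
    grad_res = nlp.gradient(w) + J.T @ result.lam_eq
    if nlp.n_ineq:
        grad_res = grad_res + nlp.jacobian_ineq(w).T @ result.lam_ineq
    grad_res = grad_res - result.nu_lower + result.nu_upper
    kkt_res = max(
        float(np.abs(grad_res).max(initial=0.0)),
        float(np.abs(nlp.constraints(w)).max(initial=0.0)),
    )
    return KKTSystem(
        matrix=M,
        hessian=H.tocsr(),
        jacobian=J,
        kappa_w=kappa_w,
        mu_b=mu_b,
        n=n,
        m=nlp.n_eq,
        kkt_residual=kkt_res,
    )


def _equilibrate(A: np.ndarray, n_iter: int = 5) -> np.ndarray:
    """Symmetric Ruiz scaling D A D; congruence leaves the inertia unchanged
    (Sylvester's law) while compressing the pivot dynamic range."""
    d = np.ones(A.shape[0])
    B = A.copy()
    for _ in range(n_iter):
        r = np.max(np.abs(B), axis=1)
        s = np.ones_like(r)
        np.divide(1.0, np.sqrt(r, where=r > 0, out=np.ones_like(r)), where=r > 0, out=s)
        B = B * s[:, None] * s[None, :]
        d *= s
    return B


def inertia(matrix, pivot_rtol: float = _PIVOT_RTOL) -> tuple:
    """(n_plus, n_minus, n_zero) of a symmetric matrix via LDL^T.

    The matrix is symmetrically equilibrated (inertia-preserving congruence)
    and Bunch-Kaufman factorized; eigenvalue signs are counted from the 1x1 /
    2x2 diagonal blocks, declaring a pivot zero when its magnitude falls
    below ``pivot_rtol`` times the largest pivot magnitude.
    """
    A = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise SpecificationError("inertia requires a square matrix")
    if not np.allclose(A, A.T, rtol=1e-10, atol=1e-12):
        raise SpecificationError("inertia requires a symmetric matrix")
    if A.shape[0] == 0:
        return (0, 0, 0)
    A = _equilibrate(0.5 * (A + A.T))
    try:
        _, D, _ = scipy.linalg.ldl(A)
    except Exception as err:  # pragma: no cover - LAPACK breakdown
        raise SolverError(f"LDL^T factorization failed ({err}); try regularizing") from err
    n = A.shape[0]
    eigs = []
    i = 0
    while i < n:
        if i + 1 < n and (D[i + 1, i] != 0.0 or D[i, i + 1] != 0.0):
            blk = D[i: i + 2, i: i + 2]
            eigs.extend(np.linalg.eigvalsh(blk))
            i += 2
        else:
            eigs.append(D[i, i])
            i += 1
    eigs = np.asarray(eigs)
    tol = pivot_rtol * np.max(np.abs(eigs), initial=0.0)
    n_zero = int(np.sum(np.abs(eigs) <= tol))
    n_plus = int(np.sum(eigs > tol))
    return (n_plus, n - n_plus - n_zero, n_zero)


# ---------------------------------------------------------------------------
# BBD structure


def build_bbd(nlp: TranscribedNLP, kkt: KKTSystem) -> BBDSystem:
    """Permute the augmented matrix into block-bordered-diagonal form.

    Border variables are the parameters plus any global auxiliaries (L1
    splits, CVaR gamma); each experiment contributes its states, per-
    experiment auxiliaries, and constraint rows.
    """
    H, J = kkt.hessian, kkt.jacobian
    n, m = kkt.n, kkt.m
    border_vars = list(range(nlp.theta_offset, n))
    if nlp.cvar_enabled:
        # per-experiment CVaR slacks and error variables move into their
        # experiment blocks; gamma stays on the border
        per_exp = set(range(nlp.slack_offset, nlp.slack_offset + nlp.n_experiments))
        per_exp |= set(range(nlp.terr_offset, nlp.terr_offset + nlp.n_experiments))
        border_vars = [i for i in border_vars if i not in per_exp]
    border_rows = list(range(nlp.n_state_rows, m))
    if nlp.cvar_enabled:
        exp_rows = set(range(nlp.cvar_row0, nlp.cvar_row0 + nlp.n_experiments))
        border_rows = [r for r in border_rows if r not in exp_rows]
    border = np.asarray(border_vars + [n + r for r in border_rows], dtype=int)
    n_g = border.size

    Hc = H.tocsc()
    Jc = J.tocsc()
    M = kkt.matrix.tocsc()

    K_blocks, B_blocks, labels, dims = [], [], [], []
    perm_blocks = []
    for k, blk in enumerate(nlp.blocks):
        vidx = np.arange(blk.var_offset, blk.var_offset + blk.n_states)
        ridx = np.arange(blk.row_offset, blk.row_offset + blk.n_rows)
        if nlp.cvar_enabled:
            vidx = np.concatenate([vidx, [nlp.slack_offset + k, nlp.terr_offset + k]])
            ridx = np.concatenate([ridx, [nlp.cvar_row0 + k]])
        Hk = Hc[np.ix_(vidx, vidx)]
        Jk = Jc[np.ix_(ridx, vidx)]
        Kk = sp.bmat([[Hk, Jk.T], [Jk, None]], format="csc")
        # border rows: Q_k = H[border_vars, vidx], T_k = J[ridx, border_vars]
        Q = Hc[np.ix_(border_vars, vidx)].toarray()
        T = Jc[np.ix_(ridx, border_vars)].toarray()
        top = np.hstack([Q, T.T])
        extra_rows = len(border) - len(border_vars)
        if extra_rows:
            # L1 link rows touch only theta/p/q (border), never experiment vars
            top = np.vstack([top, np.zeros((extra_rows, top.shape[1]))])
        K_blocks.append(Kk)
        B_blocks.append(top)
        labels.append(blk.experiment.experiment_id)
        dims.append((vidx.size, ridx.size))
        perm_blocks.append(np.concatenate([vidx, n + ridx]))

    K_theta = M[np.ix_(border, border)].toarray()
    permutation = np.concatenate([border] + perm_blocks)
    return BBDSystem(
        K_theta=K_theta,
        K_blocks=K_blocks,
        B_blocks=B_blocks,
        block_labels=labels,
        block_dims=dims,
        permutation=permutation,
        n_border_vars=len(border_vars),
        n_border_rows=len(border_rows),
    )


def _schur_complement(bbd: BBDSystem):
    """S = K_theta - sum_k B_k K_k^{-1} B_k^T, plus the block factorizations."""
    S = bbd.K_theta.copy()
    lus = []
    for k, (Kk, Bk) in enumerate(zip(bbd.K_blocks, bbd.B_blocks)):
        try:
            lu = spla.splu(Kk.tocsc())
            X = lu.solve(Bk.T)  # K_k^{-1} B_k^T, dense (n_k+m_k, n_g)
        except RuntimeError as err:
            raise SolverError(
                f"experiment block {bbd.block_labels[k]!r} is singular: {err}"
            ) from err
        if not np.all(np.isfinite(X)):
            raise SolverError(f"experiment block {bbd.block_labels[k]!r} is singular")
        S -= Bk @ X
        lus.append(lu)
    return S, lus


def schur_solve(bbd: BBDSystem, rhs) -> np.ndarray:
    """Solve the BBD system by Schur-complement elimination.

    ``rhs`` is ordered like the BBD matrix (border first, then per-experiment
    blocks).  Per-experiment factorizations and back-substitutions are
    independent of each other (parallelizable by contract).
    """
    rhs = np.asarray(rhs, dtype=float)
    n_g = bbd.n_border
    S, lus = _schur_complement(bbd)
    r_g = rhs[:n_g].copy()
    offs = []
    off = n_g
    for k, lu in enumerate(lus):
        sz = bbd.K_blocks[k].shape[0]
        offs.append(off)
        r_g -= bbd.B_blocks[k] @ lu.solve(rhs[off: off + sz])
        off += sz
    try:
        d_g = np.linalg.solve(S, r_g)
    except np.linalg.LinAlgError as err:
        raise SolverError(
            "Schur complement is singular (parameters not observable)"
        ) from err
    out = np.empty_like(rhs)
    out[:n_g] = d_g
    for k, lu in enumerate(lus):
        sz = bbd.K_blocks[k].shape[0]
        off = offs[k]
        out[off: off + sz] = lu.solve(rhs[off: off + sz] - bbd.B_blocks[k].T @ d_g)
    return out


def bbd_inertia(bbd: BBDSystem, pivot_rtol: float = _PIVOT_RTOL) -> InertiaReport:
    """Inertia of the full system by Haynsworth additivity over the BBD blocks.

    The verdict is ``observable`` when every experiment block has the healthy
    saddle inertia ``(n_k, m_k, 0)`` and the Schur complement's inertia is
    ``(n_border_vars, n_border_rows, 0)`` (positive definite in the standard
    case where the border holds only the parameters).
    """
    S, _ = _schur_complement(bbd)
    block_in = [inertia(K.toarray(), pivot_rtol) for K in bbd.K_blocks]
    schur_in = inertia(S, pivot_rtol)
    total = tuple(int(x) for x in np.sum(block_in, axis=0) + np.asarray(schur_in))
    n_total = bbd.n_border_vars + sum(nk for nk, _ in bbd.block_dims)
    m_total = bbd.n_border_rows + sum(mk for _, mk in bbd.block_dims)
    blocks_ok = all(
        bi == (nk, mk, 0) for bi, (nk, mk) in zip(block_in, bbd.block_dims)
    )
    schur_ok = schur_in == (bbd.n_border_vars, bbd.n_border_rows, 0)
    if not blocks_ok:
        verdict = "rank_deficient_jacobian"
    elif not schur_ok:
        verdict = "not_observable"
    else:
        verdict = "observable"
    return InertiaReport(
        n_plus=total[0],
        n_minus=total[1],
        n_zero=total[2],
        expected=(n_total, m_total, 0),
        schur_inertia=schur_in,
        block_inertias=block_in,
        verdict=verdict,
    )


def posterior_covariance(nlp: TranscribedNLP, result: SolveResult) -> np.ndarray:
    """Parameter covariance approximation at a solution.

    Inverse of the parameter-space Schur complement (reduced Hessian) of the
    KKT system, *including* whatever prior the problem carries — i.e. the
    Gaussian posterior covariance in the linear limit.  Use
    :func:`observability_test` (no-prior problem) for the uniqueness check.
    """
    kkt = assemble_kkt(nlp, result, kappa_w=0.0, mu_b=0.0)
    bbd = build_bbd(nlp, kkt)
    S, _ = _schur_complement(bbd)
    try:
        cov = np.linalg.inv(S)
    except np.linalg.LinAlgError as err:
        raise SolverError("reduced Hessian is singular; parameters not observable") from err
    return cov[: nlp.n_theta, : nlp.n_theta]


def observability_test(nlp: TranscribedNLP, result: SolveResult):
    """Inertia-based local-uniqueness test at a no-prior MAP solution.

    Returns ``(InertiaReport, covariance)`` where the covariance is the
    inverse Schur complement (reduced-Hessian inverse) when the verdict is
    observable, else ``None``.  Build ``nlp`` with ``PriorSpec(form="none")``
    to test observability; with the prior left in, the prior precision is
    added to the reduced Hessian and regularizes the verdict.
    """
    if not result.is_optimal:
        raise SolverError("observability test requires an optimal solve result")
    kkt = assemble_kkt(nlp, result, kappa_w=0.0, mu_b=0.0)
    bbd = build_bbd(nlp, kkt)
    report = bbd_inertia(bbd)
    lb, ub = nlp.bounds()
    w = result.w_star
    scale = 1.0 + np.abs(w)
    active = int(np.sum((w - lb <= 1e-7 * scale) | (ub - w <= 1e-7 * scale)))
    report.active_bounds = active
    cov = None
    if report.verdict == "observable":
        S, _ = _schur_complement(bbd)
        n_theta = nlp.n_theta
        cov = np.linalg.inv(S)[:n_theta, :n_theta]
    return report, cov
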