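"""Generalized Lotka-Volterra community models and a reference simulator.

Two model forms are supported:

* **gLV**: ``dx_s/dt = (mu_s + sum_{s'} alpha_{ss'} x_{s'}) x_s`` — per-capita
  growth linear in all abundances.
* **saturable gLV**: ``dx_s/dt = (mu_s + sum_{s'} alpha_{ss'} x_{s'} /
  (K_{ss'} + x_{s'})) x_s`` — each pairwise interaction saturates in the donor
  abundance, at the cost of ``S^2`` extra parameters.

``alpha_{ss'}`` follows the recipient-row / donor-column convention: row ``s``
collects the effects *on* species ``s``.

The reference simulator integrates experiments with a stiff-capable adaptive
method and applies instantaneous dilution jumps (batch passaging) at scheduled
times.  It is used to synthesize data and to validate the implicit-Euler
transcription; the estimation path itself never calls it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import SimulationError, SpecificationError

__all__ = [
    "CommunityParameters",
    "Experiment",
    "Trajectory",
    "glv_rhs",
    "saturable_rhs",
    "simulate_experiment",
    "parameters_to_csv",
    "parameters_from_csv",
]

MODEL_FORMS = ("glv", "saturable")


def n_parameters(n_species: int, model_form: str) -> int:
    """Number of free parameters: S^2+S for gLV, 2S^2+S for saturable."""
    if model_form == "glv":
        return n_species * (n_species + 1)
    if model_form == "saturable":
        return 2 * n_species**2 + n_species
    raise SpecificationError(f"unknown model form {model_form!r}")


@dataclass(frozen=True)
class CommunityParameters:
    """Growth rates, interaction matrix, and optional saturation constants.

    Parameters
    ----------
    species_labels
        Ordered identifiers of the S community members.
    growth_rates
        ``mu_s`` per species, 1/h.
    interactions
        ``alpha_{ss'}`` (S x S), 1/(abundance*h); row = recipient, column = donor.
    saturations
        ``K_{ss'}`` (S x S, abundance units), saturable model only; all > 0.
    """

    species_labels: tuple
    growth_rates: np.ndarray
    interactions: np.ndarray
    saturations: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "species_labels", tuple(self.species_labels))
        mu = np.asarray(self.growth_rates, dtype=float)
        alpha = np.asarray(self.interactions, dtype=float)
        S = len(self.species_labels)
        if mu.shape != (S,):
            raise SpecificationError(f"growth_rates must have shape ({S},), got {mu.shape}")
        if alpha.shape != (S, S):
            raise SpecificationError(f"interactions must have shape ({S},{S}), got {alpha.shape}")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(alpha))):
            raise SpecificationError("parameters must be finite")
        object.__setattr__(self, "growth_rates", mu)
        object.__setattr__(self, "interactions", alpha)
        if self.saturations is not None:
            K = np.asarray(self.saturations, dtype=float)
            if K.shape != (S, S):
                raise SpecificationError(f"saturations must have shape ({S},{S}), got {K.shape}")
            if not np.all(np.isfinite(K)) or np.any(K <= 0):
                raise SpecificationError("saturations must be finite and strictly positive")
            object.__setattr__(self, "saturations", K)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    def member_indices(self, members) -> np.ndarray:
        idx = []
        for label in members:
            try:
                idx.append(self.species_labels.index(label))
            except ValueError:
                raise SpecificationError(f"unknown species label {label!r}") from None
        return np.asarray(idx, dtype=int)

    def theta(self, model_form: str = "glv") -> np.ndarray:
        """Flatten to the canonical parameter vector.

        Ordering: ``(mu_1, alpha_11..alpha_1S, ..., mu_S, alpha_S1..alpha_SS)``,
        followed by ``K`` row-major for the saturable form.
        """
        S = self.n_species
        blocks = np.concatenate(
            [np.concatenate(([self.growth_rates[s]], self.interactions[s])) for s in range(S)]
        )
        if model_form == "glv":
            return blocks
        if model_form == "saturable":
            if self.saturations is None:
                raise SpecificationError("saturable form requires saturation constants")
            return np.concatenate([blocks, self.saturations.ravel()])
        raise SpecificationError(f"unknown model form {model_form!r}")

    @classmethod
    def from_theta(cls, theta, species_labels, model_form: str = "glv") -> "CommunityParameters":
        species_labels = tuple(species_labels)
        S = len(species_labels)
        theta = np.asarray(theta, dtype=float)
        if theta.size != n_parameters(S, model_form):
            raise SpecificationError(
                f"theta has {theta.size} entries, expected {n_parameters(S, model_form)}"
            )
        blocks = theta[: S * (S + 1)].reshape(S, S + 1)
        mu, alpha = blocks[:, 0], blocks[:, 1:]
        K = theta[S * (S + 1):].reshape(S, S) if model_form == "saturable" else None
        return cls(species_labels, mu, alpha, K)

    @staticmethod
    def theta_labels(species_labels, model_form: str = "glv") -> list:
        labels = []
        for s in species_labels:
            labels.append(f"mu[{s}]")
            labels.extend(f"alpha[{s},{sp}]" for sp in species_labels)
        if model_form == "saturable":
            for s in species_labels:
                labels.extend(f"K[{s},{sp}]" for sp in species_labels)
        return labels


@dataclass(frozen=True)
class Experiment:
    """One mono- or pairwise-culture experiment.

    ``sampling_times_h`` are the measurement times (strictly increasing, in
    ``(0, duration_h]``); ``dilution_times_h`` are passaging events inside
    ``(0, duration_h)`` at which all abundances are multiplied by
    ``dilution_factor``.
    """

    experiment_id: str
    member_species: tuple
    duration_h: float
    sampling_times_h: np.ndarray
    initial_abundances: np.ndarray
    dilution_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    dilution_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "member_species", tuple(self.member_species))
        ts = np.asarray(self.sampling_times_h, dtype=float)
        x0 = np.asarray(self.initial_abundances, dtype=float)
        td = np.asarray(self.dilution_times_h, dtype=float)
        if ts.ndim != 1 or np.any(np.diff(ts) <= 0):
            raise SpecificationError("sampling times must be strictly increasing")
        if ts.size and (ts[0] <= 0 or ts[-1] > self.duration_h + 1e-12):
            raise SpecificationError("sampling times must lie in (0, duration]")
        if x0.shape != (len(self.member_species),):
            raise SpecificationError("one initial abundance per member species required")
        if np.any(x0 < 0):
            raise SpecificationError("initial abundances must be nonnegative")
        if td.size and (np.any(np.diff(td) <= 0) or td[0] <= 0 or td[-1] >= self.duration_h):
            raise SpecificationError("dilution times must be increasing and inside (0, duration)")
        if not 0 < self.dilution_factor <= 1:
            raise SpecificationError("dilution factor must lie in (0, 1]")
        object.__setattr__(self, "sampling_times_h", ts)
        object.__setattr__(self, "initial_abundances", x0)
        object.__setattr__(self, "dilution_times_h", td)

    @property
    def n_members(self) -> int:
        return len(self.member_species)


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on a time grid.

    Dilution times appear twice in ``times_h`` (pre- and post-dilution state).
    """

    times_h: np.ndarray
    states: np.ndarray
    member_species: tuple

    def at(self, times) -> np.ndarray:
        """States at requested times (must be grid points).

        At duplicated dilution nodes the *pre*-dilution value is returned:
        sampling happens before the medium is passaged.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((times.size, self.states.shape[1]))
        for i, t in enumerate(times):
            j = int(np.searchsorted(self.times_h, t - 1e-9, side="left"))
            if j >= self.times_h.size or abs(self.times_h[j] - t) > 1e-9:
                raise SpecificationError(f"time {t} is not on the trajectory grid")
            out[i] = self.states[j]
        return out


# ---------------------------------------------------------------------------
# Right-hand sides


def _local(params: CommunityParameters, members):
    idx = params.member_indices(members)
    mu = params.growth_rates[idx]
    alpha = params.interactions[np.ix_(idx, idx)]
    K = params.saturations[np.ix_(idx, idx)] if params.saturations is not None else None
    return mu, alpha, K


def glv_rhs(state, params: CommunityParameters, members) -> np.ndarray:
    """gLV time derivative restricted to the cultured species.

    Species outside ``members`` are absent (abundance 0), so their interaction
    terms drop out exactly.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(members),):
        raise SpecificationError("state length must equal member count")
    mu, alpha, _ = _local(params, members)
    return (mu + alpha @ x) * x


def saturable_rhs(state, params: CommunityParameters, members) -> np.ndarray:
    """Saturable-gLV time derivative: interactions scale as x'/(K + x')."""
    x = np.asarray(state, dtype=float)
    if x.shape != (len(members),):
        raise SpecificationError("state length must equal member count")
    mu, alpha, K = _local(params, members)
    if K is None:
        raise SpecificationError("saturable model requires saturation constants")
    return (mu + (alpha * (x / (K + x))).sum(axis=1)) * x


# ---------------------------------------------------------------------------
# Vectorized local models (derivatives for transcription)


class GLVLocal:
    """gLV right-hand side of one experiment with analytic derivatives.

    Operates on a local parameter vector ``theta_loc = (mu_local, alpha_local
    row-major)`` covering only the cultured species; all arrays are vectorized
    over grid nodes (leading axis).
    """

    def __init__(self, n: int):
        self.n = n
        self.n_theta = n + n * n

    def unpack(self, theta_loc):
        n = self.n
        return theta_loc[:n], theta_loc[n:].reshape(n, n)

    def f(self, X, theta_loc):
        mu, A = self.unpack(theta_loc)
        return (mu + X @ A.T) * X

    def jac_x(self, X, theta_loc):
        mu, A = self.unpack(theta_loc)
        m, n = X.shape
        r = mu + X @ A.T
        J = np.einsum("ms,ab->mab", np.ones((m, n)), np.zeros((n, n)))
        J = A[None, :, :] * X[:, :, None]
        J[:, np.arange(n), np.arange(n)] += r
        return J

    def jac_theta(self, X, theta_loc):
        m, n = X.shape
        J = np.zeros((m, n, self.n_theta))
        ar = np.arange(n)
        J[:, ar, ar] = X  # d f_s / d mu_s
        # d f_s / d alpha_{s,c} = x_c x_s
        for s in range(n):
            J[:, s, n + s * n: n + (s + 1) * n] = X * X[:, [s]]
        return J

    def hess_blocks(self, X, theta_loc, lam):
        """Multiplier-contracted second derivatives sum_s lam_s * d2 f_s.

        Returns (Hxx, Hxt, Htt) with shapes (m,n,n), (m,n,p), (p,p).
        """
        mu, A = self.unpack(theta_loc)
        m, n = X.shape
        Hxx = lam[:, :, None] * A[None, :, :]
        Hxx = Hxx + np.swapaxes(Hxx, 1, 2)
        Hxt = np.zeros((m, n, self.n_theta))
        ar = np.arange(n)
        Hxt[:, ar, ar] = lam  # x_a -- mu_a
        # d2 f_r / dx_a dA_{r,c} = delta_{ac} x_r + delta_{ar} x_c
        # (n <= 2 in practice, clarity over speed)
        for r in range(n):
            for c in range(n):
                col = n + r * n + c
                Hxt[:, c, col] += lam[:, r] * X[:, r]
                Hxt[:, r, col] += lam[:, r] * X[:, c]
        Htt = np.zeros((self.n_theta, self.n_theta))
        return Hxx, Hxt, Htt


class SaturableLocal:
    """Saturable-gLV local model; ``theta_loc = (mu, alpha row-major, K row-major)``."""

    def __init__(self, n: int):
        self.n = n
        self.n_theta = n + 2 * n * n

    def unpack(self, theta_loc):
        n = self.n
        return (
            theta_loc[:n],
            theta_loc[n: n + n * n].reshape(n, n),
            theta_loc[n + n * n:].reshape(n, n),
        )

    @staticmethod
    def _sat(X, K):
        # G[m,s,c] = x_c / (K_sc + x_c) and its partials in x_c and K_sc
        D = K[None, :, :] + X[:, None, :]
        G = X[:, None, :] / D
        Gx = K[None, :, :] / D**2
        Gxx = -2.0 * K[None, :, :] / D**3
        GK = -X[:, None, :] / D**2
        GKK = 2.0 * X[:, None, :] / D**3
        GxK = (X[:, None, :] - K[None, :, :]) / D**3
        return G, Gx, Gxx, GK, GKK, GxK

    def f(self, X, theta_loc):
        mu, A, K = self.unpack(theta_loc)
        G = self._sat(X, K)[0]
        return (mu + (A[None] * G).sum(axis=2)) * X

    def jac_x(self, X, theta_loc):
        mu, A, K = self.unpack(theta_loc)
        m, n = X.shape
        G, Gx, *_ = self._sat(X, K)
        r = mu + (A[None] * G).sum(axis=2)
        J = A[None] * Gx * X[:, :, None]
        J[:, np.arange(n), np.arange(n)] += r
        return J

    def jac_theta(self, X, theta_loc):
        mu, A, K = self.unpack(theta_loc)
        m, n = X.shape
        G, Gx, Gxx, GK, *_ = self._sat(X, K)
        J = np.zeros((m, n, self.n_theta))
        ar = np.arange(n)
        J[:, ar, ar] = X
        for s in range(n):
            J[:, s, n + s * n: n + (s + 1) * n] = G[:, s, :] * X[:, [s]]
            J[:, s, n + n * n + s * n: n + n * n + (s + 1) * n] = (
                A[s][None, :] * GK[:, s, :] * X[:, [s]]
            )
        return J

    def hess_blocks(self, X, theta_loc, lam):
        mu, A, K = self.unpack(theta_loc)
        m, n = X.shape
        p = self.n_theta
        G, Gx, Gxx, GK, GKK, GxK = self._sat(X, K)
        ar = np.arange(n)

        # Hxx[a,b] = lam_a A_ab Gx[a,b] + lam_b A_ba Gx[b,a]
        #            + delta_ab sum_s lam_s x_s A_sa Gxx[s,a]
        T = lam[:, :, None] * A[None] * Gx
        Hxx = T + np.swapaxes(T, 1, 2)
        diag = (lam * X)[:, :, None] * A[None] * Gxx  # sum over s of [m,s,a]
        Hxx[:, ar, ar] += diag.sum(axis=1)

        Hxt = np.zeros((m, n, p))
        Hxt[:, ar, ar] = lam
        for r in range(n):
            colA = n + r * n
            colK = n + n * n + r * n
            for c in range(n):
                # alpha_{r,c}: delta_{ra} G[r,c] + x_r Gx[r,c] delta_{ac}
                Hxt[:, r, colA + c] += lam[:, r] * G[:, r, c]
                Hxt[:, c, colA + c] += lam[:, r] * X[:, r] * Gx[:, r, c]
                # K_{r,c}: delta_{ra} A_rc GK[r,c] + x_r A_rc GxK[r,c] delta_{ac}
                Hxt[:, r, colK + c] += lam[:, r] * A[r, c] * GK[:, r, c]
                Hxt[:, c, colK + c] += lam[:, r] * X[:, r] * A[r, c] * GxK[:, r, c]

        Htt = np.zeros((m, p, p))
        for r in range(n):
            colA = n + r * n
            colK = n + n * n + r * n
            for c in range(n):
                ak = lam[:, r] * X[:, r] * GK[:, r, c]
                kk = lam[:, r] * X[:, r] * A[r, c] * GKK[:, r, c]
                Htt[:, colA + c, colK + c] += ak
                Htt[:, colK + c, colA + c] += ak
                Htt[:, colK + c, colK + c] += kk
        return Hxx, Hxt, Htt.sum(axis=0)


def local_model(n_members: int, model_form: str):
    if model_form == "glv":
        return GLVLocal(n_members)
    if model_form == "saturable":
        return SaturableLocal(n_members)
    raise SpecificationError(f"unknown model form {model_form!r}")


def local_theta_indices(species_labels, members, model_form: str) -> np.ndarray:
    """Global theta indices of the parameters entering an experiment.

    Order matches the local layout ``(mu, alpha row-major[, K row-major])``.
    """
    labels = list(species_labels)
    S = len(labels)
    idx = [labels.index(m) for m in members]
    out = []
    for s in idx:
        out.append(s * (S + 1))
    for s in idx:
        for c in idx:
            out.append(s * (S + 1) + 1 + c)
    if model_form == "saturable":
        base = S * (S + 1)
        for s in idx:
            for c in idx:
                out.append(base + s * S + c)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# Reference simulator


def simulate_experiment(
    params: CommunityParameters,
    experiment: Experiment,
    model_form: str = "glv",
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> Trajectory:
    """Integrate one experiment with an adaptive stiff-capable method (LSODA).

    Integration proceeds between dilution events; at each event the state jumps
    to ``dilution_factor`` times its pre-dilution value and both values are
    recorded.  All sampling times appear on the output grid.
    """
    if rel_tol <= 0 or abs_tol <= 0:
        raise SpecificationError("integrator tolerances must be positive")
    members = experiment.member_species
    mu, alpha, K = _local(params, members)
    if model_form == "saturable":
        if K is None:
            raise SpecificationError("saturable model requires saturation constants")

        def rhs(t, x):
            return (mu + (alpha * (x / (K + x))).sum(axis=1)) * x
    elif model_form == "glv":

        def rhs(t, x):
            return (mu + alpha @ x) * x
    else:
        raise SpecificationError(f"unknown model form {model_form!r}")

    events = np.concatenate([[0.0], experiment.dilution_times_h, [experiment.duration_h]])
    times_out, states_out = [0.0], [experiment.initial_abundances.copy()]
    x = experiment.initial_abundances.copy()
    for a, b in zip(events[:-1], events[1:]):
        interior = experiment.sampling_times_h[
            (experiment.sampling_times_h > a + 1e-12) & (experiment.sampling_times_h < b - 1e-12)
        ]
        t_eval = np.unique(np.concatenate([interior, [b]]))
        if np.allclose(x, 0.0):
            sol_y = np.zeros((len(members), t_eval.size))
        else:
            sol = solve_ivp(
                rhs, (a, b), x, method="LSODA", t_eval=t_eval, rtol=rel_tol, atol=abs_tol
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed in experiment {experiment.experiment_id!r}: "
                    f"{sol.message}",
                    experiment_id=experiment.experiment_id,
                    time_h=float(sol.t[-1]) if sol.t.size else a,
                )
            sol_y = sol.y
        times_out.extend(t_eval.tolist())
        states_out.extend(list(sol_y.T))
        x = sol_y[:, -1].copy()
        if b < experiment.duration_h:  # dilution event at b
            x = x * experiment.dilution_factor
            times_out.append(b)
            states_out.append(x.copy())
    states = np.clip(np.asarray(states_out), 0.0, None)
    return Trajectory(np.asarray(times_out), states, members)


# ---------------------------------------------------------------------------
# CSV serialization


def parameters_to_csv(params: CommunityParameters, growth_path, interaction_path) -> None:
    """Write a (species, mu) table and a (recipient, donor, alpha[, K]) table."""
    pd.DataFrame(
        {"species": params.species_labels, "mu": params.growth_rates}
    ).to_csv(growth_path, index=False)
    rows = []
    for i, s in enumerate(params.species_labels):
        for j, sp in enumerate(params.species_labels):
            row = {"recipient": s, "donor": sp, "alpha": params.interactions[i, j]}
            if params.saturations is not None:
                row["K"] = params.saturations[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(interaction_path, index=False)


def parameters_from_csv(growth_path, interaction_path) -> CommunityParameters:
    growth = pd.read_csv(growth_path)
    inter = pd.read_csv(interaction_path)
    labels = tuple(growth["species"].astype(str))
    S = len(labels)
    pos = {s: i for i, s in enumerate(labels)}
    alpha = np.zeros((S, S))
    K = np.zeros((S, S)) if "K" in inter.columns else None
    for _, row in inter.iterrows():
        i, j = pos[str(row["recipient"])], pos[str(row["donor"])]
        alpha[i, j] = row["alpha"]
        if K is not None:
            K[i, j] = row["K"]
    return CommunityParameters(labels, growth["mu"].to_numpy(), alpha, K)
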