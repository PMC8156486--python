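"""Exact master-equation machinery for categorical distributions.

A categorical system is a probability vector ``p`` evolving under a linear
master equation ``dp/dt = L p``, where ``L`` is a transition rate matrix
(columns sum to zero, off-diagonal entries non-negative).  The stationary
distribution ``p_inf`` is the normalized right singular vector of ``L`` with
zero singular value.  Writing ``Lambda = diag(p_inf)^-1`` and
``A = L Lambda^-1``, the rate matrix splits into a solenoidal
(skew-symmetric) part ``Q = (A - A^T)/2`` and a dissipative (symmetric)
part ``Gamma = -(A + A^T)/2`` with ``L = (Q - Gamma) Lambda`` — the
categorical analogue of a Helmholtz decomposition.  Relative to ``p_inf``
the variational free energy

    F(p) = p . (ln p - ln p_inf) + z_inf

is a Lyapunov function of the full flow; the solenoidal component conserves
(a linearization of) it, while the dissipative component descends it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import svd

__all__ = [
    "CategoricalDistribution",
    "RateMatrix",
    "FlowDecomposition",
    "Trajectory",
    "FreeEnergyReport",
    "MasterEquationError",
    "InvalidRateMatrixError",
    "ReducibleChainError",
    "SupportViolationError",
    "steady_state",
    "decompose",
    "free_energy",
    "linearized_free_energy",
    "simulate",
    "simulate_mode",
    "integrate_to_steady_state",
    "random_rate_matrix",
    "detailed_balance_rate_matrix",
]

#: default relative / absolute tolerances for every ODE integration in the
#: package (a single stiff-capable integrator contract; enzymatic systems
#: downstream are stiff).
RTOL = 1e-8
ATOL = 1e-10
ODE_METHOD = "LSODA"

#: singular values below ``NULLSPACE_RTOL * sigma_max`` count as zero.
NULLSPACE_RTOL = 1e-10

#: steady state is declared when ||dp/dt||_inf stays below this, sustained
#: over one time unit of open-ended integration.
STEADY_STATE_TOL = 1e-8


class MasterEquationError(ValueError):
    """Base class for errors raised by the categorical dynamics layer."""


class InvalidRateMatrixError(MasterEquationError):
    """The matrix has no zero singular value, or violates rate-matrix shape."""


class ReducibleChainError(MasterEquationError):
    """More than one zero singular value: the chain has multiple closed sets."""


class SupportViolationError(MasterEquationError):
    """p puts mass where the reference distribution is zero: F is infinite."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CategoricalDistribution:
    """A probability vector over named states.

    ``unnormalized=True`` suspends the simplex check; solenoidal-mode
    trajectories conserve free energy but not positivity, and are allowed
    to leave the simplex.
    """

    probs: np.ndarray
    labels: list[str] | None = None
    unnormalized: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.labels is not None and len(self.labels) != self.probs.size:
            raise ValueError("labels and probs disagree in length")
        if not self.unnormalized:
            if np.any(self.probs < -1e-9):
                raise ValueError("negative probability entries")
            if abs(self.probs.sum() - 1.0) > 1e-9:
                raise ValueError("probabilities do not sum to 1")

    def __len__(self) -> int:
        return self.probs.size


@dataclass
class RateMatrix:
    """Transition rate matrix: columns sum to 0, off-diagonals >= 0."""

    entries: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n, m = self.entries.shape
        if n != m:
            raise InvalidRateMatrixError("rate matrix must be square")
        if not np.all(np.isfinite(self.entries)):
            raise InvalidRateMatrixError("non-finite entries in rate matrix")
        col_sums = self.entries.sum(axis=0)
        if np.max(np.abs(col_sums)) > 1e-9 * max(1.0, np.abs(self.entries).max()):
            raise InvalidRateMatrixError(
                f"columns must sum to 0 (max |sum| = {np.max(np.abs(col_sums)):.3g})"
            )
        off = self.entries - np.diag(np.diag(self.entries))
        if off.min() < -1e-12:
            raise InvalidRateMatrixError("negative off-diagonal rate")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels and entries disagree in length")

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]


@dataclass
class FlowDecomposition:
    """Helmholtz-style split of a rate matrix: L = (Q - Gamma) Lambda."""

    Q: np.ndarray
    Gamma: np.ndarray
    Lambda: np.ndarray  # diagonal matrix diag(p_inf)^-1
    A: np.ndarray  # L Lambda^-1

    def reconstruct(self) -> np.ndarray:
        return (self.Q - self.Gamma) @ self.Lambda


@dataclass
class Trajectory:
    """Time-indexed sequence of state vectors with optional free energy.

    ``states`` is an array of shape (len(times), n); rows are categorical
    probability vectors here, or concentration vectors in the kinetics
    modules.
    """

    times: np.ndarray
    states: np.ndarray
    labels: list[str] | None = None
    free_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.size:
            raise ValueError("times and states disagree in length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class FreeEnergyReport:
    """Per-time free energies plus the additive evidence constant z_inf."""

    values: np.ndarray
    evidence_constant: float = 0.0


# ---------------------------------------------------------------------------
# steady state and decomposition
# ---------------------------------------------------------------------------


def steady_state(L: RateMatrix, tol: float = NULLSPACE_RTOL) -> CategoricalDistribution:
    """Stationary distribution of ``dp/dt = L p``.

    Identified as the right singular vector of ``L`` whose singular value is
    zero (scale-invariant threshold ``tol * sigma_max``), sign-flipped to be
    non-negative and normalized to sum to one.

    Raises
    ------
    InvalidRateMatrixError
        if no singular value falls below the threshold.
    ReducibleChainError
        if more than one does (multiple communicating classes; the choice of
        stationary distribution would be arbitrary, so it is reported).
    """
    M = L.entries
    _, s, Vt = svd(M)
    smax = s[0] if s.size else 0.0
    null = np.flatnonzero(s <= tol * smax) if smax > 0 else np.arange(s.size)
    if null.size == 0:
        raise InvalidRateMatrixError(
            f"no zero singular value (smallest = {s[-1]:.3g}); not a valid rate matrix"
        )
    if null.size > 1:
        raise ReducibleChainError(
            f"{null.size} zero singular values: reducible chain with multiple "
            "stationary distributions"
        )
    v = Vt[null[0]]
    # the null vector of an irreducible rate matrix is single-signed
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    p = v / v.sum()
    residual = np.max(np.abs(M @ p))
    if residual > 1e-8:
        raise InvalidRateMatrixError(
            f"stationary residual ||L p||_inf = {residual:.3g} exceeds 1e-8"
        )
    return CategoricalDistribution(p, labels=L.labels)


def decompose(L: RateMatrix, p_inf: CategoricalDistribution) -> FlowDecomposition:
    """Split ``L`` into solenoidal ``Q`` and dissipative ``Gamma`` parts.

    ``Lambda = diag(p_inf)^-1`` requires a strictly positive stationary
    distribution.
    """
    p = p_inf.probs
    if np.any(p <= 0):
        raise MasterEquationError(
            "p_inf has zero entries: Lambda = diag(p_inf)^-1 is undefined"
        )
    A = L.entries @ np.diag(p)  # L Lambda^-1
    Q = 0.5 * (A - A.T)
    Gamma = -0.5 * (A + A.T)
    Lambda = np.diag(1.0 / p)
    return FlowDecomposition(Q=Q, Gamma=Gamma, Lambda=Lambda, A=A)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------


def free_energy(
    p: CategoricalDistribution | np.ndarray,
    p_inf: CategoricalDistribution | np.ndarray,
    z_inf: float = 0.0,
) -> float:
    """Variational free energy ``F(p) = p.(ln p - ln p_inf) + z_inf``.

    With ``z_inf = 0`` (the default, appropriate for a closed system) this is
    the Kullback-Leibler divergence from ``p_inf`` to ``p``.  The convention
    0 ln 0 = 0 applies; mass of ``p`` outside the support of ``p_inf`` makes
    F infinite and raises :class:`SupportViolationError`.
    """
    pv = p.probs if isinstance(p, CategoricalDistribution) else np.asarray(p, float)
    rv = (
        p_inf.probs
        if isinstance(p_inf, CategoricalDistribution)
        else np.asarray(p_inf, float)
    )
    active = pv > 0
    if np.any(rv[active] <= 0):
        raise SupportViolationError(
            "p has mass where p_inf = 0: free energy is infinite"
        )
    F = float(np.sum(pv[active] * (np.log(pv[active]) - np.log(rv[active]))))
    return F + z_inf


def linearized_free_energy(
    p: np.ndarray, p_inf: CategoricalDistribution | np.ndarray
) -> float:
    """Quadratic functional ``0.5 * p . Lambda p`` with ``Lambda = diag(p_inf)^-1``.

    This is the functional whose gradient ``Lambda p`` linearizes the exact
    free-energy gradient around ``Lambda p = 1``; the solenoidal flow
    ``dp/dt = Q Lambda p`` conserves it exactly (x.Qx = 0 for skew Q).  It is
    a diagnostic for :func:`simulate_mode` only — exact free energies are
    always reported via :func:`free_energy`.
    """
    rv = (
        p_inf.probs
        if isinstance(p_inf, CategoricalDistribution)
        else np.asarray(p_inf, float)
    )
    p = np.asarray(p, float)
    return float(0.5 * np.sum(p * p / rv))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _integrate_linear(
    M: np.ndarray, p0: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Integrate dp/dt = M p through the package's common ODE contract."""
    times = np.asarray(times, dtype=float)
    t0, t1 = float(times[0]), float(times[-1])
    if t1 == t0:
        return np.tile(p0, (times.size, 1))
    sol = solve_ivp(
        lambda _t, p: M @ p,
        (t0, t1),
        np.asarray(p0, float),
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
        jac=lambda _t, _p: M,
    )
    if not sol.success:  # pragma: no cover - LSODA on linear systems
        raise MasterEquationError(f"integration failed: {sol.message}")
    return sol.y.T


def simulate(
    L: RateMatrix,
    p0: CategoricalDistribution,
    times: Sequence[float],
    z_inf: float = 0.0,
    annotate_free_energy: bool = True,
) -> Trajectory:
    """Integrate the master equation ``dp/dt = L p`` at the requested times.

    The trajectory is annotated with the exact free energy relative to the
    stationary distribution (non-increasing along the flow, up to integrator
    tolerance) unless ``annotate_free_energy`` is false or the stationary
    distribution has zero entries.
    """
    times = np.asarray(times, dtype=float)
    states = _integrate_linear(L.entries, p0.probs, times)
    fe = None
    if annotate_free_energy:
        try:
            p_inf = steady_state(L)
            fe = np.array([free_energy(row, p_inf, z_inf) for row in states])
        except MasterEquationError:
            fe = None
    return Trajectory(times=times, states=states, labels=L.labels, free_energy=fe)


Mode = Literal["full", "solenoidal", "dissipative"]


def simulate_mode(
    L: RateMatrix,
    p_inf: CategoricalDistribution,
    p0: CategoricalDistribution,
    times: Sequence[float],
    mode: Mode = "full",
) -> Trajectory:
    """Integrate one component of the decomposed flow.

    ``full`` integrates ``(Q - Gamma) Lambda p`` (identical to ``L p``);
    ``solenoidal`` integrates ``Q Lambda p``, which conserves the linearized
    free energy but is *not* clamped to the simplex (entries may go
    negative); ``dissipative`` integrates ``-Gamma Lambda p``, which descends
    the free energy to its minimum at ``p_inf``.
    """
    dec = decompose(L, p_inf)
    if mode == "full":
        M = (dec.Q - dec.Gamma) @ dec.Lambda
    elif mode == "solenoidal":
        M = dec.Q @ dec.Lambda
    elif mode == "dissipative":
        M = -dec.Gamma @ dec.Lambda
    else:
        raise ValueError(f"unknown mode {mode!r}")
    times = np.asarray(times, dtype=float)
    states = _integrate_linear(M, p0.probs, times)
    fe = None
    if mode != "solenoidal" and np.all(states > 0):
        fe = np.array([free_energy(row, p_inf) for row in states])
    return Trajectory(times=times, states=states, labels=L.labels, free_energy=fe)


def integrate_to_steady_state(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    u0: np.ndarray,
    horizon: float = 1e4,
    tol: float = STEADY_STATE_TOL,
    chunk: float = 10.0,
    jac: Callable | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Open-ended integration until ``||du/dt||_inf < tol`` sustained over one
    time unit, or the horizon is reached.

    Returns ``(u_final, time_used, converged)``.  Shared by every module that
    needs steady-state attainment (exact chains, mean-field systems, reaction
    networks), so the declaration criterion is uniform across the package.
    """
    u = np.asarray(u0, dtype=float)
    t = 0.0
    quiet_since: float | None = None
    while t < horizon:
        t_next = min(t + chunk, horizon)
        sol = solve_ivp(
            rhs,
            (t, t_next),
            u,
            method=ODE_METHOD,
            rtol=RTOL,
            atol=ATOL,
            jac=jac,
            dense_output=True,
        )
        if not sol.success:
            warnings.warn(f"steady-state integration failed at t={t:g}: {sol.message}")
            return sol.y[:, -1], t_next, False
        # examine the derivative across the chunk at unit spacing
        ts = np.arange(t, t_next + 1e-12, 1.0) if t_next - t >= 1.0 else [t_next]
        quiet = True
        for tt in ts:
            du = np.asarray(rhs(tt, sol.sol(tt)))
            if np.max(np.abs(du)) >= tol:
                quiet = False
        u = sol.y[:, -1]
        if quiet:
            if quiet_since is None:
                quiet_since = t
            if t_next - quiet_since >= 1.0:
                return u, t_next, True
        else:
            quiet_since = None
        t = t_next
    return u, horizon, False


# ---------------------------------------------------------------------------
# constructors used by tests, examples and the acceptance suite
# ---------------------------------------------------------------------------


def random_rate_matrix(
    n: int, rng: np.random.Generator, scale: float = 1.0
) -> RateMatrix:
    """Random irreducible rate matrix: positive off-diagonal rates, columns
    summing to zero."""
    off = rng.uniform(0.1, 1.0, size=(n, n)) * scale
    np.fill_diagonal(off, 0.0)
    M = off - np.diag(off.sum(axis=0))
    return RateMatrix(M)


def detailed_balance_rate_matrix(
    n: int, rng: np.random.Generator
) -> RateMatrix:
    """Random rate matrix satisfying detailed balance ``L_ij p_j = L_ji p_i``.

    Built from a symmetric positive matrix K and target distribution p via
    ``L_ij = K_ij p_i`` (i != j); its solenoidal component vanishes.
    """
    K = rng.uniform(0.2, 1.0, size=(n, n))
    K = 0.5 * (K + K.T)
    p = rng.dirichlet(np.ones(n) * 5.0)
    M = K * p[:, None]
    np.fill_diagonal(M, 0.0)
    M -= np.diag(M.sum(axis=0))
    return RateMatrix(M)
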