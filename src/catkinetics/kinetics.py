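"""From probabilistic dynamics to chemical kinetics.

Present-probabilities ``q1_i`` map to concentrations through
``u_i = N q1_i / V`` (N = maximum molecule count, V = volume; in the
reduced units used throughout, concentrations are dimensionless multiples
of N/V).  Under this mapping the mean-field marginal dynamics of
a reaction-structured generative model become the law of mass action,

    du_i/dt = (rho_i - sigma_i) (kappa_f prod_j u_j^sigma_j
                                 - kappa_r prod_j u_j^rho_j),

with rate constants that are closed-form functions of the model parameters
(alpha's, the timescale split z, the throughput c).  The enzymatic system
S + E <-> C <-> P + E with constant substrate production and product
removal at rate c admits a quasi-equilibrium (Michaelis-Menten) reduction
``r(u_S) = v_max u_S / (k_m + u_S)`` when binding/unbinding is fast
relative to catalysis (z near 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .master import ATOL, ODE_METHOD, RTOL, Trajectory, integrate_to_steady_state

__all__ = [
    "ScaleParams",
    "MassActionReaction",
    "EnzymaticSystem",
    "MichaelisMentenReaction",
    "to_concentration",
    "to_marginal",
    "mass_action_rhs",
    "simulate_mass_action",
    "table1_constants",
    "table2_constants",
    "enzymatic_rhs",
    "simulate_enzymatic",
    "mm_reduce",
    "simulate_mm_open",
]


@dataclass(frozen=True)
class ScaleParams:
    """Scale factors linking probabilities to concentrations.

    N: maximum molecule count; V: volume; lam: base rate lambda setting the
    time unit.  All strictly positive.
    """

    N: float = 1.0
    V: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.N <= 0 or self.V <= 0 or self.lam <= 0:
            raise ValueError("N, V and lambda must all be positive")


def to_concentration(q1: np.ndarray | Sequence[float], scale: ScaleParams) -> np.ndarray:
    """Map present-probabilities to concentrations, u = N q1 / V."""
    return scale.N * np.asarray(q1, dtype=float) / scale.V


def to_marginal(u: np.ndarray | Sequence[float], scale: ScaleParams) -> np.ndarray:
    """Inverse of :func:`to_concentration` (exact bijection)."""
    return scale.V * np.asarray(u, dtype=float) / scale.N


# ---------------------------------------------------------------------------
# mass action
# ---------------------------------------------------------------------------


@dataclass
class MassActionReaction:
    """A reversible mass-action reaction sum sigma_i S_i <-> sum rho_i S_i.

    ``substrates`` and ``products`` map species name -> stoichiometric count
    (sigma and rho).  A species present on both sides with equal counts is a
    catalyst: net coefficient zero, but it still enters the rate product.
    Set ``kr = 0`` for an irreversible reaction.
    """

    substrates: dict[str, int]
    products: dict[str, int]
    kf: float = 1.0
    kr: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0:
            raise ValueError("rate constants must be non-negative")
        if not self.substrates and not self.products:
            raise ValueError("reaction needs at least one substrate or product")

    def net(self, species: str) -> int:
        return self.products.get(species, 0) - self.substrates.get(species, 0)


def mass_action_rhs(
    u: np.ndarray,
    reactions: Sequence[MassActionReaction],
    species: Sequence[str],
) -> np.ndarray:
    """Net concentration derivatives Omega . r(u) for a reaction list."""
    u = np.asarray(u, dtype=float)
    if np.any(u < -1e-9):
        raise ValueError("negative concentrations")
    idx = {s: k for k, s in enumerate(species)}
    du = np.zeros_like(u)
    for rxn in reactions:
        fwd = rxn.kf
        for s, m in rxn.substrates.items():
            fwd *= u[idx[s]] ** m
        rev = rxn.kr
        for s, m in rxn.products.items():
            rev *= u[idx[s]] ** m
        flux = fwd - rev
        for s in set(rxn.substrates) | set(rxn.products):
            du[idx[s]] += rxn.net(s) * flux
    return du


def simulate_mass_action(
    reactions: Sequence[MassActionReaction],
    species: Sequence[str],
    u0: Sequence[float],
    times: Sequence[float],
    source: dict[str, float] | None = None,
) -> Trajectory:
    """Integrate mass-action kinetics at the requested times."""
    times = np.asarray(times, dtype=float)
    src = np.zeros(len(species))
    if source:
        for s, v in source.items():
            src[list(species).index(s)] = v

    def rhs(_t, u):
        return mass_action_rhs(np.clip(u, 0.0, None), reactions, species) + src

    sol = solve_ivp(
        rhs,
        (float(times[0]), float(times[-1])),
        np.asarray(u0, float),
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"mass-action integration failed: {sol.message}")
    return Trajectory(times=times, states=sol.y.T, labels=list(species))


# ---------------------------------------------------------------------------
# model-derived rate constants
# ---------------------------------------------------------------------------


def table1_constants(
    alpha1: float, alpha2: float, z: float, scale: ScaleParams = ScaleParams()
) -> tuple[float, float, float, float]:
    """Rate constants of the coupled pair S1+S2 <-> S3 <-> S4+S5.

    kappa1 = lam N^-1 V z alpha1^-2 alpha2^-1 (alpha2 - alpha1)
    kappa2 = lam z
    kappa3 = lam (1 - z)
    kappa4 = lam N^-1 V (1-z) alpha1^-2 alpha2 (1-alpha2)^-2 (alpha2 - alpha1)

    Requires alpha2 >= alpha1 so the (alpha2 - alpha1) factor keeps kappa1
    and kappa4 non-negative.  The implied steady-state marginals are
    q1 = q2 = alpha1, q3 = 1 - alpha1/alpha2, q4 = q5 = alpha1(1-alpha2)/alpha2.
    """
    for nm, a in (("alpha1", alpha1), ("alpha2", alpha2), ("z", z)):
        if not 0.0 < a < 1.0:
            raise ValueError(f"{nm} must lie strictly in (0, 1)")
    if alpha2 < alpha1:
        raise ValueError("alpha2 must be >= alpha1 for non-negative constants")
    lam, NV = scale.lam, scale.V / scale.N
    k1 = lam * NV * z * alpha1**-2 * alpha2**-1 * (alpha2 - alpha1)
    k2 = lam * z
    k3 = lam * (1.0 - z)
    k4 = lam * NV * (1.0 - z) * alpha1**-2 * alpha2 * (1.0 - alpha2) ** -2 * (alpha2 - alpha1)
    return k1, k2, k3, k4


@dataclass(frozen=True)
class EnzymaticSystem:
    """Parameterized open enzymatic reaction S + E <-> C <-> P + E.

    alpha1: steady-state probability that the enzyme is free (the complex
    carries 1 - alpha1); alpha2: probability the substrate is present given
    a free enzyme; z: share of the base rate on the fast (binding) side;
    c: throughput — constant production of substrate and removal of product
    (concentration per time), bounded by c <= (1-z)(1-alpha1) so all rate
    constants stay non-negative.
    """

    alpha1: float
    alpha2: float
    z: float
    c: float = 0.0
    scale: ScaleParams = field(default_factory=ScaleParams)

    def __post_init__(self) -> None:
        for nm, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2), ("z", self.z)):
            if not 0.0 < a < 1.0:
                raise ValueError(f"{nm} must lie strictly in (0, 1)")
        if self.c < 0:
            raise ValueError("throughput c must be non-negative")
        bound = (1.0 - self.z) * (1.0 - self.alpha1)
        if self.c > bound + 1e-12:
            raise ValueError(
                f"c = {self.c:g} exceeds (1-z)(1-alpha1) = {bound:g}; "
                "rate constants would go negative"
            )

    @property
    def kappas(self) -> tuple[float, float, float, float]:
        return table2_constants(self)

    def steady_marginals(self) -> dict[str, float]:
        """Target present-probabilities (independent of z and c)."""
        a1, a2 = self.alpha1, self.alpha2
        return {"S": a1 * a2, "E": a1, "C": 1.0 - a1, "P": a1 * (1.0 - a2)}

    def steady_concentrations(self) -> np.ndarray:
        m = self.steady_marginals()
        return to_concentration([m["S"], m["E"], m["C"], m["P"]], self.scale)


def table2_constants(system: EnzymaticSystem) -> tuple[float, float, float, float]:
    """Rate constants of the open enzymatic reaction.

    kappa1 = lam N^-1 V (z - alpha1 z + c) alpha1^-2 alpha2^-1
    kappa2 = lam z
    kappa3 = lam (1 - z)
    kappa4 = lam N^-1 V ((1-z)(1-alpha1) - c) alpha1^-2 (1-alpha2)^-1

    All non-negative whenever c <= (1-z)(1-alpha1); with these constants the
    marginals q_S = a1 a2, q_E = a1, q_C = 1-a1, q_P = a1(1-a2) carry a net
    flux of exactly c through both reaction pairs.
    """
    a1, a2, z, c = system.alpha1, system.alpha2, system.z, system.c
    lam, NV = system.scale.lam, system.scale.V / system.scale.N
    k1 = lam * NV * (z - a1 * z + c) * a1**-2 * a2**-1
    k2 = lam * z
    k3 = lam * (1.0 - z)
    k4 = lam * NV * ((1.0 - z) * (1.0 - a1) - c) * a1**-2 * (1.0 - a2) ** -1
    return k1, k2, k3, k4


ENZYME_SPECIES = ["S", "E", "C", "P"]

#: stoichiometry of S + E <-> C <-> P + E, species x directed reactions
#: (bind, unbind, catalyze, reverse-catalyze)
ENZYME_STOICH = np.array(
    [
        [-1, 1, 0, 0],
        [-1, 1, 1, -1],
        [1, -1, -1, 1],
        [0, 0, 1, -1],
    ],
    dtype=float,
)


def enzymatic_rhs(
    u: np.ndarray,
    kappas: tuple[float, float, float, float],
    c: float = 0.0,
) -> np.ndarray:
    """Derivatives of (u_S, u_E, u_C, u_P) for the open enzymatic system.

    Four mass-action reactions (bind, unbind, catalyze, reverse-catalyze)
    plus a constant source +c on the substrate and a constant sink -c on the
    product; the sink ramps off smoothly (scale 1e-9) as the product is
    exhausted so concentrations cannot be driven negative while the
    right-hand side stays smooth for the integrator.  The reaction terms
    conserve the enzyme moiety u_E + u_C exactly, and source and sink cancel
    in the substrate moiety u_S + u_C + u_P.
    """
    uS, uE, uC, uP = u
    k1, k2, k3, k4 = kappas
    rates = np.array([k1 * uS * uE, k2 * uC, k3 * uC, k4 * uP * uE])
    du = ENZYME_STOICH @ rates
    du[0] += c
    du[3] -= c * _soft_positive(uP)
    return du


def _soft_positive(x: float, eps: float = 1e-9) -> float:
    """Smooth indicator of positivity: 0 at x <= 0, ~1 for x >> eps."""
    if x <= 0.0:
        return 0.0
    return x / (x + eps)


def simulate_enzymatic(
    system: EnzymaticSystem,
    u0: Sequence[float],
    times: Sequence[float],
) -> Trajectory:
    """Integrate the full four-species enzymatic system."""
    kap = system.kappas
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda _t, u: enzymatic_rhs(u, kap, system.c),
        (float(times[0]), float(times[-1])),
        np.asarray(u0, float),
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"enzymatic integration failed: {sol.message}")
    return Trajectory(times=times, states=sol.y.T, labels=list(ENZYME_SPECIES))


# ---------------------------------------------------------------------------
# Michaelis-Menten reduction
# ---------------------------------------------------------------------------


@dataclass
class MichaelisMentenReaction:
    """Saturating rate law r(u_S) = v_max u_S / (k_m + u_S)."""

    substrate: str
    product: str | None
    v_max: float
    k_m: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.v_max < 0:
            raise ValueError("v_max must be non-negative")
        if self.k_m <= 0:
            raise ValueError("k_m must be positive")

    def rate(self, u_S: float) -> float:
        return self.v_max * u_S / (self.k_m + u_S)


def mm_reduce(
    system: EnzymaticSystem, enzyme_total: float
) -> MichaelisMentenReaction:
    """Quasi-equilibrium reduction of the enzymatic system.

    Fast binding equilibrium kappa1 u_S u_E = kappa2 u_C gives
    u_C = e0 u_S / (k_m + u_S) with k_m = kappa2 / kappa1 and
    e0 = u_E + u_C the conserved enzyme moiety; the slow product-formation
    rate kappa3 u_C then saturates at v_max = kappa3 e0.  (An alternative
    convention, v_max = kappa1 kappa3 e0, circulates; the form used here is
    the one consistent with the full system's quasi-equilibrium dynamics —
    see docs/methods.md.)

    Validity requires timescale separation: z close to 1 (binding and
    unbinding much faster than catalysis).  A violation degrades the
    approximation continuously, so it warns rather than fails.
    """
    k1, k2, k3, _ = system.kappas
    if k2 < 10.0 * k3:  # unbinding not much faster than catalysis: z not near 1
        warnings.warn(
            "quasi-equilibrium separation is weak (z not close to 1); the "
            "Michaelis-Menten reduction may be inaccurate",
            stacklevel=2,
        )
    return MichaelisMentenReaction(
        substrate="S", product="P", v_max=k3 * enzyme_total, k_m=k2 / k1
    )


def simulate_mm_open(
    reaction: MichaelisMentenReaction,
    c: float,
    uS0: float,
    uP0: float,
    times: Sequence[float],
) -> Trajectory:
    """Reduced open system: du_S = c - r(u_S); du_P = r(u_S) - c."""
    times = np.asarray(times, dtype=float)

    def rhs(_t, u):
        r = reaction.rate(max(u[0], 0.0))
        sink = c * _soft_positive(u[1])
        return np.array([c - r, r - sink])

    sol = solve_ivp(
        rhs,
        (float(times[0]), float(times[-1])),
        [uS0, uP0],
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"reduced-system integration failed: {sol.message}")
    return Trajectory(times=times, states=sol.y.T, labels=["S", "P"])
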