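"""Multi-reaction networks: assembly, steady states, lesions, diaschisis.

A reaction network is a species list, a set of *directed* reactions (each
reversible reaction contributes two directed columns of the stoichiometry
matrix Omega), and a constant source/sink vector.  Dynamics are
``du/dt = Omega r(u) + s`` with mass-action or Michaelis-Menten rate laws.
Conserved moieties are left null vectors of Omega supported on source-free
species.  A lesion zeroes one reaction's rate constant (v_max or kappa)
without touching the stoichiometry; diaschisis compares the pre- and
post-lesion steady states species by species — a localized change of the
implicit generative model whose consequences spread through the whole
network.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .master import ATOL, ODE_METHOD, RTOL, Trajectory, integrate_to_steady_state
from .kinetics import MassActionReaction, MichaelisMentenReaction

__all__ = [
    "DirectedReaction",
    "ReactionNetwork",
    "SteadyStateReport",
    "DiaschisisReport",
    "assemble",
    "simulate",
    "find_steady_state",
    "lesion",
    "diaschisis",
    "export_sbml",
    "fig4_reactions",
    "fig6_network",
    "throughput_balance",
]


@dataclass
class DirectedReaction:
    """One directed reaction column: sigma -> rho at a single rate law.

    ``kind='mass_action'`` uses rate_constant * prod u^sigma;
    ``kind='michaelis_menten'`` uses rate_constant * u_S / (k_m + u_S) on its
    single substrate.  ``rate_constant`` doubles as kappa or v_max and is the
    quantity a lesion zeroes.
    """

    name: str
    substrates: dict[str, int]
    products: dict[str, int]
    kind: Literal["mass_action", "michaelis_menten"] = "mass_action"
    rate_constant: float = 1.0
    k_m: float | None = None

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"reaction {self.name}: negative rate constant")
        if self.kind == "michaelis_menten":
            if len(self.substrates) != 1 or any(v != 1 for v in self.substrates.values()):
                raise ValueError(
                    f"reaction {self.name}: Michaelis-Menten form needs exactly "
                    "one unit-stoichiometry substrate"
                )
            if self.k_m is None or self.k_m <= 0:
                raise ValueError(f"reaction {self.name}: k_m must be positive")

    def net(self, species: str) -> int:
        return self.products.get(species, 0) - self.substrates.get(species, 0)

    def rate(self, u: np.ndarray, idx: dict[str, int]) -> float:
        if self.kind == "mass_action":
            r = self.rate_constant
            for s, m in self.substrates.items():
                r *= max(u[idx[s]], 0.0) ** m
            return r
        (sname,) = self.substrates
        uS = max(u[idx[sname]], 0.0)
        return self.rate_constant * uS / (self.k_m + uS)


@dataclass
class ReactionNetwork:
    """Species, directed reactions, stoichiometry and source/sink terms.

    ``sources`` maps species to a constant influx (positive) or efflux
    (negative), concentration per time.  ``sensory`` and ``active`` name the
    species exchanging with the environment (external influx and efflux,
    respectively) — bookkeeping for the open-system interpretation.
    """

    species: list[str]
    reactions: list[DirectedReaction]
    sources: dict[str, float] = field(default_factory=dict)
    sensory: list[str] = field(default_factory=list)
    active: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise ValueError("reaction names must be unique")
        known = set(self.species)
        for r in self.reactions:
            bad = (set(r.substrates) | set(r.products)) - known
            if bad:
                raise ValueError(f"reaction {r.name}: unknown species {sorted(bad)}")
        bad = set(self.sources) - known
        if bad:
            raise ValueError(f"sources attach to unknown species {sorted(bad)}")

    @property
    def index(self) -> dict[str, int]:
        return {s: k for k, s in enumerate(self.species)}

    @property
    def stoichiometry(self) -> np.ndarray:
        """Omega, species x directed reactions, integer net coefficients."""
        omega = np.zeros((len(self.species), len(self.reactions)))
        idx = self.index
        for j, r in enumerate(self.reactions):
            for s in set(r.substrates) | set(r.products):
                omega[idx[s], j] = r.net(s)
        return omega

    @property
    def source_vector(self) -> np.ndarray:
        s = np.zeros(len(self.species))
        for name, v in self.sources.items():
            s[self.index[name]] = v
        return s

    def reaction(self, name: str) -> DirectedReaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(f"unknown reaction {name!r}")

    def rates(self, u: np.ndarray) -> np.ndarray:
        idx = self.index
        return np.array([r.rate(u, idx) for r in self.reactions])

    def rhs(self, _t: float, u: np.ndarray) -> np.ndarray:
        return self.stoichiometry @ self.rates(u) + self.source_vector

    def conserved_moieties(self) -> np.ndarray:
        """Left null vectors of Omega restricted to source-free species.

        Rows of the returned array are moiety vectors m (zero on species
        with sources/sinks) with m . u constant along closed dynamics.
        """
        closed = [k for k, s in enumerate(self.species) if s not in self.sources]
        if not closed:
            return np.zeros((0, len(self.species)))
        sub = self.stoichiometry[closed, :]
        ns = null_space(sub.T)
        out = np.zeros((ns.shape[1], len(self.species)))
        out[:, closed] = ns.T
        return out


@dataclass
class SteadyStateReport:
    """Steady-state concentrations with convergence diagnostics."""

    species: list[str]
    concentrations: np.ndarray
    residual: float
    converged: bool
    time_used: float

    def __post_init__(self) -> None:
        if self.converged and self.residual >= 1e-8:
            raise ValueError("converged report must have residual < 1e-8")


SignClass = Literal["lost", "decreased", "unchanged", "increased"]


@dataclass
class DiaschisisReport:
    """Per-species steady-state change after a lesion."""

    species: list[str]
    pre: np.ndarray
    post: np.ndarray
    change: np.ndarray
    sign_class: list[SignClass]

    def classes(self) -> dict[str, SignClass]:
        return dict(zip(self.species, self.sign_class))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def assemble(spec: dict) -> ReactionNetwork:
    """Build a network from a declarative dict (the YAML/JSON schema).

    Reversible mass-action reactions (``kr`` > 0) become two directed
    columns, ``<name>_fwd`` and ``<name>_rev``.
    """
    species = list(spec["species"])
    reactions: list[DirectedReaction] = []
    for r in spec.get("reactions", []):
        kind = r.get("kind", "mass_action")
        name = r["id"]
        subs = {k: int(v) for k, v in r.get("substrates", {}).items()}
        prods = {k: int(v) for k, v in r.get("products", {}).items()}
        if kind == "mass_action":
            kf = float(r.get("kf", 1.0))
            kr = float(r.get("kr", 0.0))
            if kr > 0:
                reactions.append(
                    DirectedReaction(f"{name}_fwd", subs, prods, "mass_action", kf)
                )
                reactions.append(
                    DirectedReaction(f"{name}_rev", prods, subs, "mass_action", kr)
                )
            else:
                reactions.append(DirectedReaction(name, subs, prods, "mass_action", kf))
        elif kind == "michaelis_menten":
            reactions.append(
                DirectedReaction(
                    name,
                    subs,
                    prods,
                    "michaelis_menten",
                    float(r.get("vmax", 1.0)),
                    k_m=float(r.get("km", 1.0)),
                )
            )
        else:
            raise ValueError(f"unknown reaction kind {kind!r}")
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        sources={k: float(v) for k, v in spec.get("sources", {}).items()},
        sensory=list(spec.get("sensory", [])),
        active=list(spec.get("active", [])),
    )


def simulate(
    network: ReactionNetwork, u0: Sequence[float], times: Sequence[float]
) -> Trajectory:
    """Integrate the network dynamics at the requested times."""
    u0 = np.asarray(u0, dtype=float)
    if np.any(u0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        network.rhs,
        (float(times[0]), float(times[-1])),
        u0,
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(
            f"network integration failed: {sol.message}; final state {sol.y[:, -1]}"
        )
    return Trajectory(times=times, states=sol.y.T, labels=list(network.species))


def find_steady_state(
    network: ReactionNetwork,
    u0: Sequence[float],
    horizon: float = 1e4,
) -> SteadyStateReport:
    """Integrate to the sustained-quiescence steady state or the horizon.

    Non-convergence (e.g. oscillatory networks) is a reported state, not an
    exception; the residual ``||Omega r + s||_inf`` is reported either way.
    """
    u0 = np.asarray(u0, dtype=float)
    if np.any(u0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    u, t_used, converged = integrate_to_steady_state(network.rhs, u0, horizon=horizon)
    residual = float(np.max(np.abs(network.rhs(0.0, u))))
    return SteadyStateReport(
        species=list(network.species),
        concentrations=u,
        residual=residual,
        converged=converged and residual < 1e-8,
        time_used=t_used,
    )


def lesion(network: ReactionNetwork, reaction_id: str) -> ReactionNetwork:
    """Copy of the network with one reaction's rate constant set to zero.

    Only the rate parameter changes (v_max or kappa); the stoichiometry is
    untouched.  Idempotent on already-silent reactions.
    """
    network.reaction(reaction_id)  # raises KeyError if unknown
    out = copy.deepcopy(network)
    out.reaction(reaction_id).rate_constant = 0.0
    return out


def diaschisis(
    pre: SteadyStateReport,
    post: SteadyStateReport,
    threshold: float = 1e-6,
) -> DiaschisisReport:
    """Classify per-species steady-state changes between two converged runs.

    'lost': present before, essentially zero after; 'unchanged': |change|
    within the threshold; otherwise 'increased'/'decreased' by sign.
    """
    if pre.species != post.species:
        raise ValueError("steady-state reports cover different species")
    if not (pre.converged and post.converged):
        raise ValueError("diaschisis requires two converged steady states")
    change = post.concentrations - pre.concentrations
    classes: list[SignClass] = []
    for a, b, d in zip(pre.concentrations, post.concentrations, change):
        if a > threshold and b <= threshold:
            classes.append("lost")
        elif abs(d) <= threshold:
            classes.append("unchanged")
        elif d > 0:
            classes.append("increased")
        else:
            classes.append("decreased")
    return DiaschisisReport(
        species=list(pre.species),
        pre=pre.concentrations.copy(),
        post=post.concentrations.copy(),
        change=change,
        sign_class=classes,
    )


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def export_sbml(network: ReactionNetwork, path) -> None:
    """Write the network as SBML Level 3 Version 2 (write-only; no import).

    Mass-action columns carry k * prod(S^sigma) kinetic laws; Michaelis-
    Menten columns carry vmax * S / (km + S).  Constant sources become
    creation/degradation pseudo-reactions.
    """
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": "catkinetics_network"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{_SBML_NS}}}compartment",
        {"id": "cell", "constant": "true", "size": "1"},
    )
    los = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in network.species:
        ET.SubElement(
            los,
            f"{{{_SBML_NS}}}species",
            {
                "id": s,
                "compartment": "cell",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    lop = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    lor = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for j, r in enumerate(network.reactions):
        pid = f"k_{r.name}"
        ET.SubElement(
            lop,
            f"{{{_SBML_NS}}}parameter",
            {"id": pid, "value": repr(float(r.rate_constant)), "constant": "true"},
        )
        if r.kind == "michaelis_menten":
            ET.SubElement(
                lop,
                f"{{{_SBML_NS}}}parameter",
                {"id": f"km_{r.name}", "value": repr(float(r.k_m)), "constant": "true"},
            )
        rx = ET.SubElement(
            lor, f"{{{_SBML_NS}}}reaction", {"id": r.name, "reversible": "false"}
        )
        if r.substrates:
            lrs = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for s, m in r.substrates.items():
                ET.SubElement(
                    lrs,
                    f"{{{_SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": str(m), "constant": "true"},
                )
        if r.products:
            lps = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for s, m in r.products.items():
                ET.SubElement(
                    lps,
                    f"{{{_SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": str(m), "constant": "true"},
                )
        kl = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        math = ET.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math"
        )
        if r.kind == "mass_action":
            formula = " * ".join(
                [pid] + [f"{s}^{m}" if m > 1 else s for s, m in r.substrates.items()]
            )
        else:
            (s,) = r.substrates
            formula = f"{pid} * {s} / (km_{r.name} + {s})"
        ci = ET.SubElement(math, "{http://www.w3.org/1998/Math/MathML}ci")
        ci.text = formula
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# bundled networks
# ---------------------------------------------------------------------------


def fig4_reactions(
    alpha1: float, alpha2: float, z: float, scale=None
) -> list[MassActionReaction]:
    """Coupled reversible pair S1 + S2 <-> S3 <-> S4 + S5.

    Rate constants from the generative-model parameterization
    (:func:`catkinetics.kinetics.table1_constants`); implied steady-state
    marginals q1 = q2 = alpha1, q3 = 1 - alpha1/alpha2,
    q4 = q5 = alpha1 (1 - alpha2) / alpha2, which satisfy the conservation
    q1 + q3 + q4 = 1 (and likewise with S2/S5).
    """
    from .kinetics import ScaleParams, table1_constants

    k1, k2, k3, k4 = table1_constants(alpha1, alpha2, z, scale or ScaleParams())
    return [
        MassActionReaction({"S1": 1, "S2": 1}, {"S3": 1}, kf=k1, kr=k2, name="bind"),
        MassActionReaction({"S3": 1}, {"S4": 1, "S5": 1}, kf=k3, kr=k4, name="split"),
    ]


def fig6_network(influx: float = 0.1) -> ReactionNetwork:
    """Bundled seven-species metabolic network with a sensory input on S3.

    Topology (all reactions Michaelis-Menten): source -> S3 -> S2 -> S1 in a
    reversible trunk; two irreversible branches S1 -> S4 -> S5 -> sink and
    S1 -> S6 -> S7 -> sink.  S3 is sensory (external influx); S5 and S7 are
    active (external efflux).  Parameters are chosen so the pre-lesion
    steady state has every species strictly positive; lesioning the
    reaction ``S1_to_S4`` abolishes S4 and S5 and raises S2 and S6 through
    back-pressure and flux diversion.
    """
    mm = lambda name, s, p, vmax: DirectedReaction(  # noqa: E731
        name, {s: 1}, {p: 1} if p else {}, "michaelis_menten", vmax, k_m=1.0
    )
    reactions = [
        mm("S3_to_S2", "S3", "S2", 1.0),
        mm("S2_to_S3", "S2", "S3", 0.5),
        mm("S2_to_S1", "S2", "S1", 1.0),
        mm("S1_to_S2", "S1", "S2", 0.5),
        mm("S1_to_S4", "S1", "S4", 1.0),
        mm("S4_to_S5", "S4", "S5", 1.0),
        mm("S1_to_S6", "S1", "S6", 1.0),
        mm("S6_to_S7", "S6", "S7", 1.0),
        mm("S5_efflux", "S5", None, 1.0),
        mm("S7_efflux", "S7", None, 1.0),
    ]
    return ReactionNetwork(
        species=[f"S{k}" for k in range(1, 8)],
        reactions=reactions,
        sources={"S3": influx},
        sensory=["S3"],
        active=["S5", "S7"],
    )


def throughput_balance(network: ReactionNetwork, u: np.ndarray) -> float:
    """|total source influx - total sink efflux| at a state u.

    Sink efflux counts source entries with negative sign plus the rates of
    reactions with no products (pure efflux columns).
    """
    src = network.source_vector
    influx = float(src[src > 0].sum())
    efflux = float(-src[src < 0].sum())
    idx = network.index
    for r in network.reactions:
        if not r.products:
            efflux += r.rate(u, idx)
    return abs(influx - efflux)
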