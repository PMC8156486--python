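"""Factorized steady-state (generative) models over binary chemical species.

A generative model prescribes the *target* of the dynamics: a joint
steady-state distribution over binary species (index 0 = present,
index 1 = absent), factorized into conditional probability tables.  From it
we compute exact joint steady states, Markov blankets, and mean-field
transition operators of the form

    L_i = lambda_i * a * v_i,     a = [1, -1]^T,

where the row vector ``v_i`` lives in a basis of Kronecker indicator
products over subsets of the species, restricted to the Markov blanket of
species i, and is constrained to annihilate the steady state.  The
resulting marginal dynamics are nonlinear (products of marginals) even
though the underlying joint master equation is linear.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .master import (
    ATOL,
    ODE_METHOD,
    RTOL,
    CategoricalDistribution,
    Trajectory,
)

__all__ = [
    "ConditionalFactor",
    "GenerativeModel",
    "MeanFieldOperator",
    "MarginalState",
    "ModelStructureError",
    "joint_steady_state",
    "marginals_of_joint",
    "markov_blanket",
    "corrected_beta",
    "build_operator",
    "meanfield_simulate",
    "meanfield_free_energy",
    "two_substrate_two_product_model",
    "enzymatic_model",
    "chain_model",
]


class ModelStructureError(ValueError):
    """The factor graph violates the model invariants (cycles, orphans...)."""


# ---------------------------------------------------------------------------
# model declaration
# ---------------------------------------------------------------------------


@dataclass
class ConditionalFactor:
    """One factor P(children | parents) of the steady-state joint.

    ``table`` has one row per joint child configuration (2**len(children),
    ordered with the leftmost child varying slowest; bit 0 = present) and
    one normalized column per parent configuration (same ordering over
    parents; a single column when there are no parents).
    """

    children: list[str]
    parents: list[str] = field(default_factory=list)
    table: np.ndarray = field(default_factory=lambda: np.array([[1.0]]))

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim == 1:
            self.table = self.table[:, None]
        rows = 2 ** len(self.children)
        cols = max(1, 2 ** len(self.parents))
        if self.table.shape != (rows, cols):
            raise ModelStructureError(
                f"factor over {self.children}|{self.parents}: table shape "
                f"{self.table.shape} != ({rows}, {cols})"
            )
        if np.any(self.table < -1e-12) or np.any(self.table > 1 + 1e-12):
            raise ModelStructureError("table entries must lie in [0, 1]")
        if np.max(np.abs(self.table.sum(axis=0) - 1.0)) > 1e-9:
            raise ModelStructureError("each table column must sum to 1")

    @property
    def members(self) -> list[str]:
        return list(self.children) + list(self.parents)


@dataclass
class GenerativeModel:
    """Binary species plus the factors of their joint steady state.

    Joint ordering convention: species are ordered as declared and the
    leftmost species varies slowest in the joint index (matching a
    left-to-right Kronecker product of per-species two-vectors).
    """

    species: list[str]
    factors: list[ConditionalFactor]
    lambdas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ModelStructureError("species names must be unique")
        seen: dict[str, int] = {}
        for k, f in enumerate(self.factors):
            for s in f.children:
                if s in seen:
                    raise ModelStructureError(f"{s} is a child of two factors")
                seen[s] = k
            for s in f.members:
                if s not in self.species:
                    raise ModelStructureError(f"unknown species {s!r} in factor")
        missing = set(self.species) - set(seen)
        if missing:
            raise ModelStructureError(f"species never generated: {sorted(missing)}")
        self._check_acyclic(seen)

    def _check_acyclic(self, child_factor: dict[str, int]) -> None:
        # edges parent-block -> child-block between factors
        deps = {
            k: {child_factor[p] for p in f.parents} for k, f in enumerate(self.factors)
        }
        state: dict[int, int] = {}

        def visit(k: int) -> None:
            if state.get(k) == 1:
                raise ModelStructureError("cyclic factor graph")
            if state.get(k) == 2:
                return
            state[k] = 1
            for j in deps[k]:
                visit(j)
            state[k] = 2

        for k in deps:
            visit(k)

    def index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise ModelStructureError(f"unknown species {name!r}") from None

    def lambda_of(self, name: str) -> float:
        return float(self.lambdas.get(name, 1.0))

    @property
    def n(self) -> int:
        return len(self.species)


#: per-species two-vectors [q_present, q_absent]
MarginalState = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# joint steady state and blankets
# ---------------------------------------------------------------------------


def _bits_of(index: int, n: int) -> tuple[int, ...]:
    """Joint index -> per-species bits, leftmost species slowest."""
    return tuple((index >> (n - 1 - i)) & 1 for i in range(n))


def joint_steady_state(model: GenerativeModel) -> CategoricalDistribution:
    """Exact joint steady state: the product of the factor tables.

    Returns a categorical distribution over the 2**n joint states, indexed
    with the leftmost declared species varying slowest (bit 0 = present).
    """
    n = model.n
    p = np.ones(2**n)
    for jdx in range(2**n):
        bits = _bits_of(jdx, n)
        val = 1.0
        for f in model.factors:
            row = 0
            for s in f.children:
                row = 2 * row + bits[model.index(s)]
            col = 0
            for s in f.parents:
                col = 2 * col + bits[model.index(s)]
            val *= f.table[row, col]
        p[jdx] = val
    labels = ["".join("pa"[b] for b in _bits_of(j, n)) for j in range(2**n)]
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ModelStructureError(f"joint mass {total:.6g} != 1; invalid factors")
    return CategoricalDistribution(p / total, labels=labels)


def marginals_of_joint(joint: np.ndarray, model: GenerativeModel) -> MarginalState:
    """Per-species present/absent marginals of a joint probability vector."""
    n = model.n
    joint = np.asarray(joint, float)
    out: MarginalState = {}
    for i, name in enumerate(model.species):
        q1 = sum(joint[j] for j in range(2**n) if _bits_of(j, n)[i] == 0)
        out[name] = np.array([q1, joint.sum() - q1])
    return out


def markov_blanket(model: GenerativeModel, species: str) -> set[str]:
    """Markov blanket of a species under the factorized steady state.

    The union, over every factor in which the species appears (as child or
    parent), of all that factor's members — i.e. co-children, parents,
    children, and children's co-parents — minus the species itself.
    """
    model.index(species)  # validates the name
    blanket: set[str] = set()
    for f in model.factors:
        if species in f.members:
            blanket.update(f.members)
    blanket.discard(species)
    return blanket


# ---------------------------------------------------------------------------
# mean-field operators
# ---------------------------------------------------------------------------


def corrected_beta(alpha: float, n_substrates: int, n_products: int) -> float:
    """Mean-field-corrected rate ratio ``alpha**n_s / (1-alpha)**n_p``.

    The uncorrected ratio alpha/(1-alpha) leaves the marginal fixed point
    inconsistent with the model's marginals under the mean-field product
    approximation; raising numerator and denominator to the number of
    substrates and products respectively restores consistency.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    return alpha**n_substrates / (1.0 - alpha) ** n_products


@dataclass
class MeanFieldOperator:
    """Marginal dynamics for one species: dq1_i/dt = lambda_i * v(q).

    ``terms`` maps a subset of species (a tuple of names; the empty tuple is
    the constant beta_1 term) to its coefficient; ``v(q)`` is the sum over
    terms of coefficient * prod of present-marginals in the subset.  The row
    vector over joint states that this represents is orthogonal to
    ``steady_reference`` (the exact joint for beta solved against it, the
    mean-field product for marginal-corrected beta) whenever the
    non-equilibrium constant is zero.
    """

    species: str
    lambda_: float
    terms: dict[tuple[str, ...], float]
    steady_reference: np.ndarray
    model: GenerativeModel
    nonequilibrium_const: float = 0.0

    def v_row(self) -> np.ndarray:
        """Materialize v (without the injected constant) as a row vector over
        the 2**n joint states."""
        n = self.model.n
        row = np.zeros(2**n)
        for subset, coeff in self.terms.items():
            idxs = [self.model.index(s) for s in subset]
            for j in range(2**n):
                bits = _bits_of(j, n)
                if all(bits[i] == 0 for i in idxs):
                    row[j] += coeff
        return row

    def orthogonality_residual(self) -> float:
        """|v . p| against the operator's own steady reference (the injected
        non-equilibrium constant is excluded; it deliberately breaks
        orthogonality)."""
        return float(abs(self.v_row() @ self.steady_reference))

    def rate(self, q1: dict[str, float]) -> float:
        """Evaluate v at a product (mean-field) state given present-marginals."""
        total = self.nonequilibrium_const
        for subset, coeff in self.terms.items():
            prod = coeff
            for s in subset:
                prod *= q1[s]
            total += prod
        return total


def _presence_partition(
    model: GenerativeModel, species: str, allowed: set[str], joint: np.ndarray
) -> tuple[set[str], set[str]] | None:
    """Split the blanket into co-present and anti-present partners.

    Returns (S, P) where every support state has the S species in the same
    presence state as ``species`` and the P species in the opposite one, or
    None when the support does not have that two-sided reaction structure.
    """
    n = model.n
    i = model.index(species)
    support = [_bits_of(j, n) for j in np.flatnonzero(joint > 1e-12)]
    S, P = {species}, set()
    for other in allowed - {species}:
        k = model.index(other)
        if all(b[k] == b[i] for b in support):
            S.add(other)
        elif all(b[k] == 1 - b[i] for b in support):
            P.add(other)
        else:
            return None
    if not P:
        return None
    return S, P


def build_operator(
    model: GenerativeModel,
    species: str,
    lambda_: float | None = None,
    nonequilibrium_const: float = 0.0,
    correction: Literal["marginal", "exact"] = "marginal",
) -> MeanFieldOperator:
    """Construct the mean-field transition operator for one species.

    The operator's indicator basis is restricted to subsets of the species'
    Markov blanket (plus the species itself); coefficients on any term
    involving species outside the blanket are identically zero.

    When the steady state has the two-sided reaction structure (a set of
    species always co-present with the target, another always anti-present),
    the operator is the reaction form ``beta * r_P - r_S`` with beta either
    the exact-orthogonality ratio (``correction='exact'``:
    v . p_inf = 0 against the true joint) or the mean-field-corrected power
    form (``correction='marginal'``: the marginal fixed point matches the
    model's marginals).  Otherwise beta coefficients are obtained from the
    null space of the orthogonality constraints over the blanket basis, with
    a deterministic sign/scale convention (first coefficient in basis order
    = -1, mirroring the substrate term of the reaction form).

    ``nonequilibrium_const`` injects a constant beta_1 term (production or
    removal at a fixed rate), deliberately breaking orthogonality as in open
    systems.
    """
    i = model.index(species)
    lam = model.lambda_of(species) if lambda_ is None else float(lambda_)
    joint = joint_steady_state(model).probs
    blanket = markov_blanket(model, species)
    allowed = blanket | {species}
    marg = marginals_of_joint(joint, model)

    part = _presence_partition(model, species, allowed, joint)
    if part is not None:
        S, P = part
        # one shared reaction flux J = r_B * beta - r_A for all members, so
        # that substrate and product marginals change in equal and opposite
        # amounts (the summed presence probability is conserved).  Side A is
        # the one holding the earliest-declared species; beta corrects for
        # the mean-field product approximation.
        r_S = tuple(s for s in model.species if s in S)
        r_P = tuple(s for s in model.species if s in P)
        first = min(model.index(s) for s in S | P)
        if model.index(r_S[0]) == first or (r_S and model.species[first] in S):
            side_A, side_B = r_S, r_P
        else:
            side_A, side_B = r_P, r_S
        if correction == "marginal":
            num = float(np.prod([marg[s][0] for s in side_A]))
            den = float(np.prod([marg[s][0] for s in side_B]))
            beta = num / den
            reference = _product_joint(model, marg)
        else:
            mask_A = _indicator_row(model, side_A)
            mask_B = _indicator_row(model, side_B)
            beta = float(mask_A @ joint) / float(mask_B @ joint)
            reference = joint
        if species in set(side_A):
            terms: dict[tuple[str, ...], float] = {side_B: beta, side_A: -1.0}
        else:
            terms = {side_A: 1.0, side_B: -beta}
    elif not blanket:
        # isolated species: relaxation to its own steady marginal,
        # v = q_bar - indicator(present); the exact two-state master equation.
        qbar = float(marg[species][0])
        terms = {(): qbar, (species,): -1.0}
        reference = joint if correction == "exact" else _product_joint(model, marg)
    else:
        terms = _nullspace_terms(model, species, allowed, joint, correction, marg)
        reference = (
            joint if correction == "exact" else _product_joint(model, marg)
        )
    return MeanFieldOperator(
        species=species,
        lambda_=lam,
        terms=terms,
        steady_reference=reference,
        model=model,
        nonequilibrium_const=float(nonequilibrium_const),
    )


def _indicator_row(model: GenerativeModel, subset: Sequence[str]) -> np.ndarray:
    n = model.n
    idxs = [model.index(s) for s in subset]
    row = np.zeros(2**n)
    for j in range(2**n):
        bits = _bits_of(j, n)
        if all(bits[k] == 0 for k in idxs):
            row[j] = 1.0
    return row


def _product_joint(model: GenerativeModel, marg: MarginalState) -> np.ndarray:
    out = np.array([1.0])
    for s in model.species:
        out = np.kron(out, marg[s])
    return out


def _nullspace_terms(
    model: GenerativeModel,
    species: str,
    allowed: set[str],
    joint: np.ndarray,
    correction: str,
    marg: MarginalState,
) -> dict[tuple[str, ...], float]:
    """Generic beta solve over the blanket-restricted indicator basis.

    Basis: subsets of blanket plus self, enumerated by size then declaration
    order, with the constant (empty subset, beta_1) first.  Constraints:
    v annihilates the exact joint and the mean-field product state.  The
    null direction (smallest singular value of the constraint matrix) is a
    deterministic, reproducible tie-break among the many admissible beta
    combinations; the sign is fixed so the operator is locally restoring in
    its own coordinate and the scale so the largest coefficient has unit
    magnitude.
    """
    ordered = [s for s in model.species if s in allowed]
    basis: list[tuple[str, ...]] = [()]
    for size in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, size):
            basis.append(combo)
    rows = []
    rows.append([float(_indicator_row(model, b) @ joint) for b in basis])
    prod = _product_joint(model, marg)
    rows.append([float(_indicator_row(model, b) @ prod) for b in basis])
    C = np.array(rows)
    _, s, Vt = np.linalg.svd(C)
    null_dim = len(basis) - np.sum(s > 1e-12 * max(s[0], 1.0))
    if null_dim < 1:
        raise ModelStructureError(
            f"orthogonality unsatisfiable over the blanket basis for {species!r}"
        )
    v = Vt[-1]  # smallest singular value direction
    if np.max(np.abs(v)) < 1e-12:  # pragma: no cover
        raise ModelStructureError("degenerate null space")
    v = v / np.max(np.abs(v))
    # restoring sign: d(rate)/dq_i at the steady marginals must be negative
    grad = 0.0
    for k, subset in enumerate(basis):
        if species in subset:
            g = v[k]
            for s_ in subset:
                if s_ != species:
                    g *= marg[s_][0]
            grad += g
    if grad > 0:
        v = -v
    return {basis[k]: float(v[k]) for k in range(v.size) if abs(v[k]) > 1e-14}


# ---------------------------------------------------------------------------
# mean-field simulation
# ---------------------------------------------------------------------------


def meanfield_simulate(
    operators: Sequence[MeanFieldOperator],
    q0: MarginalState,
    times: Sequence[float],
) -> Trajectory:
    """Integrate the coupled marginal dynamics dq1_i/dt = lambda_i v_i(q).

    The state is the vector of present-probabilities (absent = complement).
    Marginals of a closed system stay on their simplices; the summed
    presence probability of a closed reaction system is conserved.
    """
    names = [op.species for op in operators]
    if len(set(names)) != len(names):
        raise ValueError("duplicate operator species")
    model = operators[0].model
    missing = set(model.species) - set(names)
    if missing:
        raise ValueError(f"operators missing for species: {sorted(missing)}")
    for name in names:
        q = np.asarray(q0[name], float)
        if q.size != 2 or abs(q.sum() - 1.0) > 1e-9 or np.any(q < -1e-12):
            raise ValueError(f"q0[{name!r}] is not on the 1-simplex")

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        q1 = {name: x[k] for k, name in enumerate(names)}
        out = np.empty_like(x)
        for k, op in enumerate(operators):
            out[k] = op.lambda_ * op.rate(q1)
        return out

    x0 = np.array([float(np.asarray(q0[name], float)[0]) for name in names])
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        rhs,
        (float(times[0]), float(times[-1])),
        x0,
        method=ODE_METHOD,
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    states = sol.y.T
    if np.any(states < -1e-6) or np.any(states > 1 + 1e-6):
        warnings.warn(
            "mean-field marginals left the simplex; the initial conserved mass "
            "may be inconsistent with the target steady state"
        )
    return Trajectory(times=times, states=states, labels=names)


def meanfield_free_energy(
    traj: Trajectory, model: GenerativeModel
) -> np.ndarray:
    """Free energy of a mean-field trajectory against the model's marginals.

    Under the mean-field product approximation the joint KL divergence to
    the product-form steady state splits into a sum of per-species binary
    KLs, sum_i KL(q_i(t) || q_i(inf)) — the form the free energy takes for
    a closed system, which decreases to zero as the marginals attain the
    generative model's steady state.  (The exact joint typically has
    restricted support, so the KL against it is infinite for product
    states; the mean-field functional is the meaningful Lyapunov quantity
    here.)
    """
    if traj.labels is None:
        raise ValueError("trajectory must carry species labels")
    marg = marginals_of_joint(joint_steady_state(model).probs, model)
    out = np.zeros(traj.times.size)
    for k, name in enumerate(traj.labels):
        qbar = float(marg[name][0])
        q1 = np.clip(traj.states[:, k], 0.0, 1.0)
        for x, y in ((q1, qbar), (1.0 - q1, 1.0 - qbar)):
            pos = x > 0
            out[pos] += x[pos] * np.log(x[pos] / y)
    return out


# ---------------------------------------------------------------------------
# bundled model constructors
# ---------------------------------------------------------------------------


def two_substrate_two_product_model(alpha: float = 0.25) -> GenerativeModel:
    """S1 + S2 <-> S3 + S4 with substrate pair prior Cat([alpha 0 0 1-alpha]).

    Both substrates are present (probability alpha) or both absent; the
    product pair is deterministically the complement of the substrate pair.
    """
    f1 = ConditionalFactor(
        children=["S1", "S2"],
        table=np.array([alpha, 0.0, 0.0, 1.0 - alpha]),
    )
    # columns ordered over (S1, S2) configs, S1 slowest: pp, pa, ap, aa.
    # Zero-mass parent configs (pa, ap) get an arbitrary valid column.
    both_absent = np.array([0.0, 0.0, 0.0, 1.0])
    both_present = np.array([1.0, 0.0, 0.0, 0.0])
    f2 = ConditionalFactor(
        children=["S3", "S4"],
        parents=["S1", "S2"],
        table=np.column_stack([both_absent, both_absent, both_present, both_present]),
    )
    return GenerativeModel(species=["S1", "S2", "S3", "S4"], factors=[f1, f2])


def enzymatic_model(alpha1: float, alpha2: float) -> GenerativeModel:
    """Substrate/enzyme/complex/product model for S + E <-> C <-> P + E.

    The enzyme-complex block has mass only on (enzyme present, complex
    absent) — probability alpha1 — and (complex present, enzyme absent) —
    probability 1 - alpha1.  Given a free enzyme, the substrate is present
    with probability alpha2 and the product with probability 1 - alpha2;
    given the complex, both are absent.  Marginals: q_S = alpha1*alpha2,
    q_E = alpha1, q_C = 1 - alpha1, q_P = alpha1*(1 - alpha2).
    """
    # C x E block, C slowest: pp, pa, ap, aa
    f1 = ConditionalFactor(
        children=["C", "E"],
        table=np.array([0.0, 1.0 - alpha1, alpha1, 0.0]),
    )
    sub_cols = {
        "pp": [0.0, 1.0],
        "pa": [0.0, 1.0],  # complex present -> substrate absent
        "ap": [alpha2, 1.0 - alpha2],  # free enzyme -> substrate w.p. alpha2
        "aa": [0.0, 1.0],  # zero-mass parent config
    }
    prod_cols = {
        "pp": [0.0, 1.0],
        "pa": [0.0, 1.0],
        "ap": [1.0 - alpha2, alpha2],
        "aa": [0.0, 1.0],
    }
    order = ["pp", "pa", "ap", "aa"]
    f2 = ConditionalFactor(
        children=["S"],
        parents=["C", "E"],
        table=np.column_stack([sub_cols[k] for k in order]),
    )
    f3 = ConditionalFactor(
        children=["P"],
        parents=["C", "E"],
        table=np.column_stack([prod_cols[k] for k in order]),
    )
    return GenerativeModel(species=["S", "E", "C", "P"], factors=[f1, f2, f3])


def chain_model(
    a: float = 0.6,
    b: tuple[float, float] = (0.7, 0.2),
    c: tuple[float, float] = (0.8, 0.3),
) -> GenerativeModel:
    """Three-species chain A -> B -> C with arbitrary conditional tables.

    ``b = (P(B present | A present), P(B present | A absent))`` and likewise
    for ``c`` given B.  Used for blanket and orthogonality checks on models
    without reaction structure.
    """
    fA = ConditionalFactor(children=["A"], table=np.array([a, 1 - a]))
    fB = ConditionalFactor(
        children=["B"],
        parents=["A"],
        table=np.array([[b[0], b[1]], [1 - b[0], 1 - b[1]]]),
    )
    fC = ConditionalFactor(
        children=["C"],
        parents=["B"],
        table=np.array([[c[0], c[1]], [1 - c[0], 1 - c[1]]]),
    )
    return GenerativeModel(species=["A", "B", "C"], factors=[fA, fB, fC])
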