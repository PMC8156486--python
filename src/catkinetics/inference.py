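"""Inferential reading of enzymatic kinetics: implicit beliefs.

In the open enzymatic system S + E <-> C <-> P + E, the linear functions

    q~_S = alpha2 - q_P        (encoded by the product concentration)
    q~_P = alpha2 - q_S        (encoded by the substrate concentration)

behave as beliefs each side of the reaction holds about the other: as the
non-equilibrium steady state is attained they converge to the true
present-probabilities of the substrate and product.  Scoring those beliefs
against the model's conditional distributions given the enzyme state yields
two variational free-energy series that decrease as the beliefs converge —
with a transient increase permitted on the product side, whose 'data' (the
enzyme concentration) are actively changed by the substrate early in the
reaction.

The module computes these functionals only; nothing here claims chemical
species literally perceive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .master import Trajectory

__all__ = ["ImplicitBelief", "implicit_beliefs", "belief_free_energy"]


@dataclass
class ImplicitBelief:
    """Believed-present probability for one species, and the alpha2 it
    derives from."""

    species: str
    q_tilde: float
    alpha2: float


def implicit_beliefs(
    q_S: float, q_P: float, alpha2: float
) -> tuple[ImplicitBelief, ImplicitBelief]:
    """Beliefs implicitly encoded by the substrate and product marginals.

    ``q~_S = alpha2 - q_P`` and ``q~_P = alpha2 - q_S``, clipped to [0, 1]
    with a warning when the linear relations transiently exit the unit
    interval (possible under mean-field error).
    """
    if not 0.0 < alpha2 < 1.0:
        raise ValueError("alpha2 must lie strictly in (0, 1)")
    for nm, q in (("q_S", q_S), ("q_P", q_P)):
        if not -1e-12 <= q <= 1 + 1e-12:
            raise ValueError(f"{nm} must lie in [0, 1]")
    raw_S = alpha2 - q_P
    raw_P = alpha2 - q_S
    if not (0.0 <= raw_S <= 1.0 and 0.0 <= raw_P <= 1.0):
        warnings.warn("implicit belief clipped to [0, 1]", stacklevel=2)
    return (
        ImplicitBelief("S", float(np.clip(raw_S, 0.0, 1.0)), alpha2),
        ImplicitBelief("P", float(np.clip(raw_P, 0.0, 1.0)), alpha2),
    )


def _binary_kl(b: float, p: float) -> float:
    """KL([b,1-b] || [p,1-p]) with the 0 ln 0 convention."""
    total = 0.0
    for x, y in ((b, p), (1.0 - b, 1.0 - p)):
        if x > 0.0:
            if y <= 0.0:
                return float("inf")
            total += x * np.log(x / y)
    return total


def belief_free_energy(
    trajectory: Trajectory, alpha2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Free-energy series of the substrate-side and product-side beliefs.

    The trajectory must cover the four enzymatic species labelled
    S, E, C, P (probability units: present-marginals, i.e. concentrations at
    N = V = 1).  For each time point the implicit belief is conditioned on
    the free-enzyme state (the belief divided by the enzyme marginal, which
    converges to the model conditional P(species | enzyme) at steady state)
    and scored as

        F_side(t) = q_E(t) * KL( belief_side(t) || P(side | E present) )

    — a KL divergence against the conditional steady state given the
    enzyme, averaged with the enzyme's own weight.  The complex-conditioned
    term vanishes identically (given the complex, both substrate and
    product are surely absent, which is also what the conditioned beliefs
    assert), so only the enzyme term contributes.  See docs/methods.md for
    the convention and what is treated as testable (the qualitative shapes).

    Returns (substrate_series, product_series).
    """
    if trajectory.labels is None:
        raise ValueError("trajectory must carry species labels")
    try:
        cols = {s: trajectory.labels.index(s) for s in ("S", "E", "C", "P")}
    except ValueError as exc:
        raise ValueError("trajectory must cover species S, E, C, P") from exc
    qS = trajectory.states[:, cols["S"]]
    qE = trajectory.states[:, cols["E"]]
    qP = trajectory.states[:, cols["P"]]
    n = trajectory.times.size
    F_S = np.empty(n)
    F_P = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clip warnings handled per point
        for t in range(n):
            bS, bP = implicit_beliefs(
                float(np.clip(qS[t], 0, 1)), float(np.clip(qP[t], 0, 1)), alpha2
            )
            e = max(qE[t], 1e-300)
            cond_S = float(np.clip(bS.q_tilde / e, 0.0, 1.0))
            cond_P = float(np.clip(bP.q_tilde / e, 0.0, 1.0))
            F_S[t] = qE[t] * _binary_kl(cond_S, alpha2)
            F_P[t] = qE[t] * _binary_kl(cond_P, 1.0 - alpha2)
    return F_S, F_P
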