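"""Generative models, Markov blankets and mean-field operators."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from catkinetics import generative as G
from catkinetics.generative import _bits_of


class TestJointSteadyState:
    def test_reaction_model_support(self, reaction_model):
        j = G.joint_steady_state(reaction_model)
        mass = dict(zip(j.labels, j.probs))
        assert mass["ppaa"] == pytest.approx(0.25)
        assert mass["aapp"] == pytest.approx(0.75)
        assert sum(v for k, v in mass.items() if k not in ("ppaa", "aapp")) == 0.0

    def test_single_unconditioned_factor_is_its_table(self):
        f = G.ConditionalFactor(children=["A", "B"], table=np.array([0.1, 0.2, 0.3, 0.4]))
        m = G.GenerativeModel(species=["A", "B"], factors=[f])
        np.testing.assert_allclose(
            G.joint_steady_state(m).probs, [0.1, 0.2, 0.3, 0.4], atol=1e-14
        )

    def test_enzyme_model_excludes_complex_and_enzyme_copresence(self):
        for a1, a2 in [(0.3, 0.6), (0.8, 0.8), (0.5, 0.2)]:
            em = G.enzymatic_model(a1, a2)
            j = G.joint_steady_state(em)
            n = em.n
            iC, iE = em.index("C"), em.index("E")
            both = sum(
                p
                for k, p in enumerate(j.probs)
                if _bits_of(k, n)[iC] == 0 and _bits_of(k, n)[iE] == 0
            )
            assert both == 0.0

    def test_enzyme_model_marginals(self):
        em = G.enzymatic_model(0.8, 0.8)
        marg = G.marginals_of_joint(G.joint_steady_state(em).probs, em)
        assert marg["S"][0] == pytest.approx(0.64)
        assert marg["E"][0] == pytest.approx(0.8)
        assert marg["C"][0] == pytest.approx(0.2)
        assert marg["P"][0] == pytest.approx(0.16)

    def test_cyclic_factor_graph_rejected(self):
        fA = G.ConditionalFactor(
            children=["A"], parents=["B"], table=np.array([[0.5, 0.5], [0.5, 0.5]])
        )
        fB = G.ConditionalFactor(
            children=["B"], parents=["A"], table=np.array([[0.5, 0.5], [0.5, 0.5]])
        )
        with pytest.raises(G.ModelStructureError):
            G.GenerativeModel(species=["A", "B"], factors=[fA, fB])


def _is_blanket(model, species, candidate):
    """Brute-force conditional-independence oracle on the joint table.

    True iff P(x_i | x_candidate, x_rest) does not depend on x_rest wherever
    defined.
    """
    joint = G.joint_steady_state(model).probs
    n = model.n
    i = model.index(species)
    cand = sorted(model.index(s) for s in candidate)
    rest = [k for k in range(n) if k != i and k not in cand]
    for cfg_c in itertools.product([0, 1], repeat=len(cand)):
        conds = []
        for cfg_r in itertools.product([0, 1], repeat=len(rest)):
            num = den = 0.0
            for j, pj in enumerate(joint):
                bits = _bits_of(j, n)
                if all(bits[k] == v for k, v in zip(cand, cfg_c)) and all(
                    bits[k] == v for k, v in zip(rest, cfg_r)
                ):
                    den += pj
                    if bits[i] == 0:
                        num += pj
            if den > 1e-12:
                conds.append(num / den)
        if conds and max(conds) - min(conds) > 1e-10:
            return False
    return True


class TestMarkovBlanket:
    def test_enzyme_substrate_blanket_is_complex_and_enzyme(self, enzyme_model):
        assert G.markov_blanket(enzyme_model, "S") == {"C", "E"}

    def test_one_factor_model_blanket_is_everything_else(self):
        f = G.ConditionalFactor(
            children=["A", "B", "C"], table=np.full(8, 1 / 8)
        )
        m = G.GenerativeModel(species=["A", "B", "C"], factors=[f])
        assert G.markov_blanket(m, "B") == {"A", "C"}

    def test_chain_blanket_against_bruteforce_oracle(self, chain):
        blanket = G.markov_blanket(chain, "B")
        assert blanket == {"A", "C"}
        assert _is_blanket(chain, "B", blanket)
        # the blanket is minimal: dropping either member breaks it
        for drop in blanket:
            assert not _is_blanket(chain, "B", blanket - {drop})

    def test_unknown_species_rejected(self, chain):
        with pytest.raises(G.ModelStructureError):
            G.markov_blanket(chain, "Z")


class TestCorrectedBeta:
    def test_two_substrates_two_products(self):
        assert G.corrected_beta(0.25, 2, 2) == pytest.approx(1 / 9)

    def test_symmetric_alpha_half_is_one(self):
        for k in (1, 2, 3):
            assert G.corrected_beta(0.5, k, k) == pytest.approx(1.0)

    def test_single_species_reduces_to_odds_ratio(self):
        a = 0.3
        assert G.corrected_beta(a, 1, 1) == pytest.approx(a / (1 - a))

    def test_boundary_alpha_rejected(self):
        for a in (0.0, 1.0):
            with pytest.raises(ValueError):
                G.corrected_beta(a, 2, 2)


class TestBuildOperator:
    def test_reaction_operator_matches_closed_form(self, reaction_model, rng):
        """Substrate dynamics are lambda (beta q3 q4 - q1 q2) with corrected
        beta."""
        op = G.build_operator(reaction_model, "S1")
        beta = G.corrected_beta(0.25, 2, 2)
        for _ in range(10):
            q = {s: float(rng.uniform(0, 1)) for s in reaction_model.species}
            expected = beta * q["S3"] * q["S4"] - q["S1"] * q["S2"]
            assert op.rate(q) == pytest.approx(expected, abs=1e-14)

    def test_product_operator_is_opposite_flux(self, reaction_model, rng):
        op1 = G.build_operator(reaction_model, "S1")
        op3 = G.build_operator(reaction_model, "S3")
        q = {s: float(rng.uniform(0, 1)) for s in reaction_model.species}
        assert op3.rate(q) == pytest.approx(-op1.rate(q), abs=1e-14)

    def test_zero_rate_at_model_marginals(self, reaction_model):
        marg = G.marginals_of_joint(
            G.joint_steady_state(reaction_model).probs, reaction_model
        )
        q = {s: float(marg[s][0]) for s in reaction_model.species}
        for s in reaction_model.species:
            assert G.build_operator(reaction_model, s).rate(q) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_orthogonality_exact_mode_random_chains(self, rng):
        for _ in range(10):
            m = G.chain_model(
                a=float(rng.uniform(0.1, 0.9)),
                b=(float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9))),
                c=(float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9))),
            )
            for s in m.species:
                op = G.build_operator(m, s, correction="exact")
                assert op.orthogonality_residual() <= 1e-12

    def test_blanket_restriction_zeroes_outside_terms(self, enzyme_model):
        op = G.build_operator(enzyme_model, "S")
        allowed = G.markov_blanket(enzyme_model, "S") | {"S"}
        for subset in op.terms:
            assert set(subset) <= allowed

    def test_nonequilibrium_constant_is_stored_and_breaks_rate(self, reaction_model):
        op0 = G.build_operator(reaction_model, "S1")
        opc = G.build_operator(reaction_model, "S1", nonequilibrium_const=0.3)
        q = {s: 0.5 for s in reaction_model.species}
        assert opc.rate(q) == pytest.approx(op0.rate(q) + 0.3, abs=1e-14)
        # orthogonality of the reaction part is unaffected
        assert opc.orthogonality_residual() == pytest.approx(
            op0.orthogonality_residual(), abs=1e-14
        )


class TestMeanFieldSimulate:
    def test_constant_at_steady_state(self, reaction_model):
        marg = G.marginals_of_joint(
            G.joint_steady_state(reaction_model).probs, reaction_model
        )
        ops = [G.build_operator(reaction_model, s) for s in reaction_model.species]
        traj = G.meanfield_simulate(ops, marg, np.linspace(0, 50, 26))
        assert np.max(np.abs(traj.states - traj.states[0])) <= 1e-9

    def test_substrates_settle_at_quarter_concentration(self, reaction_model):
        ops = [G.build_operator(reaction_model, s) for s in reaction_model.species]
        q0 = {
            s: np.array([1.0, 0.0]) if s in ("S1", "S2") else np.array([0.0, 1.0])
            for s in reaction_model.species
        }
        traj = G.meanfield_simulate(ops, q0, np.linspace(0, 100, 201))
        final = dict(zip(traj.labels, traj.states[-1]))
        assert final["S1"] == pytest.approx(0.25, abs=1e-6)
        assert final["S3"] == pytest.approx(0.75, abs=1e-6)

    def test_summed_presence_probability_conserved(self, reaction_model):
        ops = [G.build_operator(reaction_model, s) for s in reaction_model.species]
        q0 = {
            "S1": np.array([0.9, 0.1]),
            "S2": np.array([0.9, 0.1]),
            "S3": np.array([0.1, 0.9]),
            "S4": np.array([0.1, 0.9]),
        }
        traj = G.meanfield_simulate(ops, q0, np.linspace(0, 50, 101))
        mass = traj.states[:, 0] + traj.states[:, 2]  # q1 + q3
        assert np.max(np.abs(mass - mass[0])) <= 1e-8

    def test_independent_model_matches_exact_master_equations(self):
        """Product-form oracle: independent species evolve as two decoupled
        exact two-state master equations."""
        fA = G.ConditionalFactor(children=["A"], table=np.array([0.3, 0.7]))
        fB = G.ConditionalFactor(children=["B"], table=np.array([0.6, 0.4]))
        m = G.GenerativeModel(species=["A", "B"], factors=[fA, fB])
        ops = [G.build_operator(m, s, correction="exact") for s in m.species]
        q0 = {"A": np.array([0.9, 0.1]), "B": np.array([0.1, 0.9])}
        times = np.linspace(0, 10, 41)
        traj = G.meanfield_simulate(ops, q0, times)

        def relax(qbar):
            return np.array([[qbar - 1.0, qbar], [1.0 - qbar, -qbar]])

        for k, (name, qbar) in enumerate([("A", 0.3), ("B", 0.6)]):
            exact = np.array(
                [(expm(relax(qbar) * t) @ q0[name])[0] for t in times]
            )
            assert np.max(np.abs(traj.states[:, k] - exact)) <= 1e-6

    def test_chain_marginals_attain_model_marginals(self, chain):
        ops = [G.build_operator(chain, s) for s in chain.species]
        q0 = {s: np.array([0.5, 0.5]) for s in chain.species}
        traj = G.meanfield_simulate(ops, q0, np.linspace(0, 300, 61))
        marg = G.marginals_of_joint(G.joint_steady_state(chain).probs, chain)
        for k, s in enumerate(chain.species):
            assert traj.states[-1, k] == pytest.approx(marg[s][0], abs=1e-4)

    def test_meanfield_free_energy_decreases_to_zero(self, reaction_model):
        ops = [G.build_operator(reaction_model, s) for s in reaction_model.species]
        q0 = {
            s: np.array([1.0, 0.0]) if s in ("S1", "S2") else np.array([0.0, 1.0])
            for s in reaction_model.species
        }
        traj = G.meanfield_simulate(ops, q0, np.linspace(0, 100, 201))
        fe = G.meanfield_free_energy(traj, reaction_model)
        assert np.max(np.diff(fe)) <= 1e-6
        assert fe[-1] == pytest.approx(0.0, abs=1e-6)
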