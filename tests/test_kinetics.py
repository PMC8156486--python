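"""Concentration mapping, mass action, model-derived constants, enzymes."""

import warnings

import numpy as np
import pytest

from catkinetics import generative as G, kinetics as K


class TestConcentrationMap:
    def test_unit_scale_identity(self):
        scale = K.ScaleParams(N=1, V=1)
        assert K.to_concentration([1.0], scale)[0] == pytest.approx(1.0)

    def test_formula_evaluation(self):
        scale = K.ScaleParams(N=2, V=0.5)
        assert K.to_concentration([0.25], scale)[0] == pytest.approx(1.0)

    def test_round_trip_is_exact(self, rng):
        # bitwise exact when N/V is a power of two; within one ulp otherwise
        q = rng.uniform(0, 1, size=6)
        scale2 = K.ScaleParams(N=4.0, V=0.5)
        np.testing.assert_array_equal(
            K.to_marginal(K.to_concentration(q, scale2), scale2), q
        )
        scale = K.ScaleParams(N=3.7, V=1.9)
        np.testing.assert_allclose(
            K.to_marginal(K.to_concentration(q, scale), scale), q, rtol=1e-15
        )

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            K.ScaleParams(N=0)


class TestMassAction:
    SPECIES = ["S1", "S3", "S4"]

    def test_zero_constants_give_zero_flux(self):
        rxn = K.MassActionReaction({"S1": 2}, {"S3": 1, "S4": 1}, kf=0.0, kr=0.0)
        du = K.mass_action_rhs(np.array([2.0, 1.0, 1.0]), [rxn], self.SPECIES)
        np.testing.assert_array_equal(du, np.zeros(3))

    def test_autocatalytic_stoichiometry_factor(self):
        """2 S1 <-> S3 + S4: the substrate derivative carries the factor 2."""
        rxn = K.MassActionReaction({"S1": 2}, {"S3": 1, "S4": 1}, kf=1.0, kr=1.0)
        du = K.mass_action_rhs(np.array([2.0, 0.0, 0.0]), [rxn], self.SPECIES)
        np.testing.assert_allclose(du, [-8.0, 4.0, 4.0])

    def test_zero_at_detailed_balance(self):
        rxn = K.MassActionReaction({"S1": 2}, {"S3": 1, "S4": 1}, kf=1.0, kr=4.0)
        # kf * u1^2 = kr * u3 u4 at u = (2, 1, 1)
        du = K.mass_action_rhs(np.array([2.0, 1.0, 1.0]), [rxn], self.SPECIES)
        np.testing.assert_allclose(du, np.zeros(3), atol=1e-14)

    def test_catalyst_enters_rate_but_not_net(self):
        rxn = K.MassActionReaction({"A": 1, "E": 1}, {"B": 1, "E": 1}, kf=2.0)
        du = K.mass_action_rhs(np.array([1.0, 0.5, 0.0]), [rxn], ["A", "E", "B"])
        np.testing.assert_allclose(du, [-1.0, 0.0, 1.0])

    def test_negative_concentrations_rejected(self):
        rxn = K.MassActionReaction({"S1": 1}, {"S3": 1}, kf=1.0)
        with pytest.raises(ValueError):
            K.mass_action_rhs(np.array([-1.0, 0.0, 0.0]), [rxn], self.SPECIES)


class TestTableConstants:
    def test_table1_derived_example(self):
        k1, k2, k3, k4 = K.table1_constants(0.2, 0.5, 0.5)
        assert k1 == pytest.approx(7.5)
        assert k2 == pytest.approx(0.5)
        assert k3 == pytest.approx(0.5)
        assert k4 == pytest.approx(7.5)

    def test_table1_degenerate_alphas(self):
        k1, _, _, k4 = K.table1_constants(0.3, 0.3, 0.6)
        assert k1 == 0.0 and k4 == 0.0
        with pytest.raises(ValueError):
            K.table1_constants(0.5, 0.3, 0.5)  # alpha2 < alpha1

    def test_table2_derived_example(self):
        sys0 = K.EnzymaticSystem(0.5, 0.5, 0.5, 0.0)
        k1, k2, k3, k4 = K.table2_constants(sys0)
        assert (k1, k2, k3, k4) == pytest.approx((2.0, 0.5, 0.5, 2.0))

    def test_table2_boundary_throughput_zeroes_kappa4(self):
        z, a1 = 0.6, 0.3
        sysb = K.EnzymaticSystem(a1, 0.5, z, (1 - z) * (1 - a1))
        assert sysb.kappas[3] == pytest.approx(0.0, abs=1e-15)

    def test_table2_nonnegative_over_parameter_sweep(self):
        for a1 in (0.1, 0.5, 0.9):
            for a2 in (0.2, 0.8):
                for z in (0.3, 0.7, 0.95):
                    for frac in (0.0, 0.5, 1.0):
                        c = frac * (1 - z) * (1 - a1)
                        kappas = K.EnzymaticSystem(a1, a2, z, c).kappas
                        assert min(kappas) >= -1e-15

    def test_throughput_bound_enforced(self):
        with pytest.raises(ValueError):
            K.EnzymaticSystem(0.5, 0.5, 0.9, 0.2)


class TestEnzymaticSystem:
    def test_source_only_when_empty(self):
        du = K.enzymatic_rhs(np.zeros(4), (1.0, 1.0, 1.0, 1.0), c=0.3)
        np.testing.assert_allclose(du, [0.3, 0.0, 0.0, 0.0])

    def test_closed_system_equilibrium_is_fixed_point(self):
        sys0 = K.EnzymaticSystem(0.8, 0.6, 0.7, 0.0)
        u = sys0.steady_concentrations()
        du = K.enzymatic_rhs(u, sys0.kappas, c=0.0)
        np.testing.assert_allclose(du, np.zeros(4), atol=1e-12)

    def test_open_system_marginals_are_fixed_point(self):
        # the smooth sink ramp (scale 1e-9) leaves a sub-1e-10 residual
        sysc = K.EnzymaticSystem(0.8, 0.8, 0.9, 0.01)
        du = K.enzymatic_rhs(sysc.steady_concentrations(), sysc.kappas, sysc.c)
        np.testing.assert_allclose(du, np.zeros(4), atol=1e-10)

    def test_enzyme_moiety_conserved_along_trajectory(self):
        """u_E + u_C is a left null vector of the enzymatic stoichiometry."""
        moiety = np.array([0.0, 1.0, 1.0, 0.0])
        np.testing.assert_allclose(moiety @ K.ENZYME_STOICH, np.zeros(4))
        sysc = K.EnzymaticSystem(0.8, 0.8, 0.9, 0.01)
        traj = K.simulate_enzymatic(sysc, [0.5, 1.0, 0.0, 0.5], np.linspace(0, 400, 201))
        vals = traj.states @ moiety
        assert np.max(np.abs(vals - vals[0])) <= 1e-8

    def test_trajectory_attains_model_marginals(self):
        sysc = K.EnzymaticSystem(0.8, 0.8, 0.9, 0.01)
        traj = K.simulate_enzymatic(sysc, [0.5, 1.0, 0.0, 0.5], np.linspace(0, 400, 201))
        np.testing.assert_allclose(
            traj.states[-1], sysc.steady_concentrations(), atol=1e-6
        )

    def test_concentrations_stay_nonnegative(self):
        sysc = K.EnzymaticSystem(0.8, 0.8, 0.9, 0.01)
        traj = K.simulate_enzymatic(sysc, [1.0, 1.0, 0.0, 0.0], np.linspace(0, 400, 201))
        assert traj.states.min() >= -1e-10


class TestMeanfieldMassActionConsistency:
    def test_probabilistic_and_kinetic_routes_agree(self, reaction_model):
        """The mean-field marginal dynamics and the mass-action system with
        model-derived constants are the same flow at N = V = lambda = 1."""
        ops = [G.build_operator(reaction_model, s) for s in reaction_model.species]
        times = np.linspace(0, 60, 121)
        q0 = {
            s: np.array([1.0, 0.0]) if s in ("S1", "S2") else np.array([0.0, 1.0])
            for s in reaction_model.species
        }
        mf = G.meanfield_simulate(ops, q0, times)
        beta = G.corrected_beta(0.25, 2, 2)
        rxn = K.MassActionReaction(
            {"S1": 1, "S2": 1}, {"S3": 1, "S4": 1}, kf=1.0, kr=beta
        )
        ma = K.simulate_mass_action(
            [rxn], ["S1", "S2", "S3", "S4"], [1, 1, 0, 0], times
        )
        assert np.max(np.abs(mf.states - ma.states)) <= 1e-6

    def test_equilibrium_flux_ratio(self, reaction_model):
        beta = G.corrected_beta(0.25, 2, 2)
        rxn = K.MassActionReaction(
            {"S1": 1, "S2": 1}, {"S3": 1, "S4": 1}, kf=1.0, kr=beta
        )
        traj = K.simulate_mass_action(
            [rxn], ["S1", "S2", "S3", "S4"], [1, 1, 0, 0], np.linspace(0, 200, 101)
        )
        u = traj.states[-1]
        assert abs(1.0 * u[0] * u[1] - beta * u[2] * u[3]) <= 1e-8

    def test_probabilistic_image_descends_free_energy(self, reaction_model):
        beta = G.corrected_beta(0.25, 2, 2)
        rxn = K.MassActionReaction(
            {"S1": 1, "S2": 1}, {"S3": 1, "S4": 1}, kf=1.0, kr=beta
        )
        traj = K.simulate_mass_action(
            [rxn], ["S1", "S2", "S3", "S4"], [1, 1, 0, 0], np.linspace(0, 100, 201)
        )
        fe = G.meanfield_free_energy(traj, reaction_model)
        assert np.max(np.diff(fe)) <= 1e-6


class TestMichaelisMenten:
    def test_half_saturation_identity(self):
        rxn = K.MichaelisMentenReaction("S", "P", v_max=2.0, k_m=0.7)
        assert rxn.rate(0.7) == pytest.approx(1.0)

    def test_zero_substrate_zero_rate(self):
        rxn = K.MichaelisMentenReaction("S", "P", v_max=2.0, k_m=0.7)
        assert rxn.rate(0.0) == 0.0

    def test_saturation_limit(self):
        rxn = K.MichaelisMentenReaction("S", "P", v_max=2.0, k_m=0.7)
        assert rxn.rate(700.0) == pytest.approx(2.0, rel=1e-3)

    def test_reduction_constants(self):
        sysz = K.EnzymaticSystem(0.99, 0.5, 0.99, 9.9e-5)
        k1, k2, k3, _ = sysz.kappas
        red = K.mm_reduce(sysz, enzyme_total=1.0)
        assert red.k_m == pytest.approx(k2 / k1)
        assert red.v_max == pytest.approx(k3 * 1.0)

    def test_weak_separation_warns(self):
        syslo = K.EnzymaticSystem(0.8, 0.5, 0.5, 0.001)
        with pytest.warns(UserWarning, match="quasi-equilibrium"):
            K.mm_reduce(syslo, enzyme_total=1.0)

    @staticmethod
    def _relative_error(z):
        sysz = K.EnzymaticSystem(0.99, 0.5, z, 9.9e-5)
        t = np.linspace(0, 30000, 301)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = K.simulate_enzymatic(sysz, [0.9, 1.0, 0.0, 0.1], t)
            red = K.mm_reduce(sysz, enzyme_total=1.0)
            reduced = K.simulate_mm_open(red, sysz.c, 0.9, 0.1, t)
        uPf = full.states[:, 3]
        return np.max(np.abs(reduced.states[:, 1] - uPf)) / uPf.max()

    def test_reduction_error_small_at_strong_separation(self):
        assert self._relative_error(0.99) <= 0.05

    def test_reduction_error_decreases_monotonically_in_z(self):
        errs = [self._relative_error(z) for z in (0.5, 0.7, 0.9, 0.99)]
        assert all(np.diff(errs) < 0)
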