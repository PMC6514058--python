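"""Reaction-network evaluation, steady states and simulation invariants."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from nfkbdyn import WT, build_system, rhs, simulate, steady_state
from nfkbdyn.exceptions import ConfigurationError
from nfkbdyn.ikk import DEFAULT_BASAL, constant_profile, make_tnfp_profile
from nfkbdyn.network import CompiledNetwork, Reaction


class TestRhs:
    def test_zero_state_gives_constitutive_terms_only(self, wt_system,
                                                      ref_params):
        dx = rhs(wt_system, np.zeros(wt_system.n_species), 0.0, DEFAULT_BASAL)
        expected = {
            "RelA": ref_params["syn_rela"],
            "p50": ref_params["syn_p50"],
            "IkBb": ref_params["syn_ikbb"],
            "tIkBa": ref_params["txn_ikba_const"],
            "tIkBe": ref_params["txn_ikbe_const"],
            "tNfkb2": ref_params["txn_nfkb2_const"],
            "tRelb": ref_params["txn_relb_const"],
        }
        for name, value in zip(wt_system.species_names, dx):
            assert value == pytest.approx(expected.get(name, 0.0), abs=1e-12)

    def test_one_species_toy_matches_closed_form(self):
        net = CompiledNetwork(
            ["X"],
            [Reaction("syn", "k", (), (("X", 1.0),)),
             Reaction("deg", "d", ("X",), (("X", -1.0),))],
            ["k", "d"])
        p = np.array([3.0, 0.5])
        for x in (0.0, 1.0, 10.0):
            assert net.rhs(p, np.array([x]), 0.0)[0] == pytest.approx(
                3.0 - 0.5 * x)

    def test_doubling_ikk_doubles_only_ikk_fluxes(self, wt_system, wt_steady):
        net = wt_system.network
        p = wt_system.param_vector()
        f1 = net.fluxes(p, wt_steady, 1.0)
        f2 = net.fluxes(p, wt_steady, 2.0)
        nonzero = f1 > 0
        ratio = f2[nonzero] / f1[nonzero]
        assert np.allclose(ratio[net.ikk_flag[nonzero]], 2.0)
        assert np.allclose(ratio[~net.ikk_flag[nonzero]], 1.0)

    def test_analytic_jacobian_matches_finite_differences(self, wt_system,
                                                          wt_steady):
        net = wt_system.network
        p = wt_system.param_vector()
        x = wt_steady + 0.1
        J = net.jac(p, x, 0.7)
        eps = 1e-6
        for j in (0, 5, 17, 30):
            xp = x.copy()
            xp[j] += eps
            fd = (net.rhs(p, xp, 0.7) - net.rhs(p, x, 0.7)) / eps
            assert np.allclose(J[:, j], fd, rtol=1e-4, atol=1e-6)


class TestSteadyState:
    def test_dead_system_has_zero_steady_state(self, ref_params):
        zeroed = {name: 0.0 for name in ref_params.values
                  if name.startswith(("syn_", "txn_"))}
        system = build_system(WT, ref_params.with_updates(zeroed))
        ss = steady_state(system, DEFAULT_BASAL)
        assert np.all(ss < 1e-10)

    def test_residual_below_tolerance(self, wt_system, wt_steady):
        res = rhs(wt_system, wt_steady, 0.0, DEFAULT_BASAL)
        assert np.max(np.abs(res)) < 1e-8

    def test_binding_toy_matches_root_finder(self):
        """A + B <-> AB with synthesis and degradation, against fsolve on the
        three-species algebraic system."""
        net = CompiledNetwork(
            ["A", "B", "AB"],
            [Reaction("syn A", "sa", (), (("A", 1.0),)),
             Reaction("syn B", "sb", (), (("B", 1.0),)),
             Reaction("bind", "kf", ("A", "B"),
                      (("A", -1.0), ("B", -1.0), ("AB", 1.0))),
             Reaction("unbind", "kr", ("AB",),
                      (("AB", -1.0), ("A", 1.0), ("B", 1.0))),
             Reaction("deg A", "da", ("A",), (("A", -1.0),)),
             Reaction("deg B", "db", ("B",), (("B", -1.0),)),
             Reaction("deg AB", "dab", ("AB",), (("AB", -1.0),))],
            ["sa", "sb", "kf", "kr", "da", "db", "dab"])
        p = np.array([2.0, 3.0, 1.5, 0.3, 0.4, 0.5, 0.2])

        def f(x):
            return net.rhs(p, x, 0.0)

        oracle = fsolve(f, np.ones(3), full_output=False)
        # the same fixed point through the package's integrate-and-polish path
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, x: f(x), (0, 200), np.zeros(3),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], oracle, rtol=1e-6)

    def test_nfkb2_null_elevates_basal_nuclear_b50(self, wt_system, wt_steady,
                                                   ko_system, ko_steady):
        i = wt_system.species_index("nB50")
        assert ko_steady[ko_system.species_index("nB50")] > wt_steady[i]

    def test_negative_basal_rejected(self, wt_system):
        with pytest.raises(ConfigurationError):
            steady_state(wt_system, -1.0)


class TestSimulate:
    def test_equilibrium_invariance_under_constant_basal(self, wt_system,
                                                         wt_steady):
        traj = simulate(wt_system, constant_profile(DEFAULT_BASAL), 16.0,
                        initial=wt_steady)
        nfkbn = traj.nfkbn
        assert np.max(np.abs(nfkbn - nfkbn[0])) / nfkbn[0] < 1e-6

    def test_tolerance_refinement_stable(self, wt_system, wt_steady):
        """Halving integrator tolerances moves NF-kBn by < 0.1% everywhere."""
        profile = make_tnfp_profile()
        a = simulate(wt_system, profile, 8.0, initial=wt_steady)
        b = simulate(wt_system, profile, 8.0, initial=wt_steady,
                     rtol=5e-9, atol=5e-11)
        scale = np.max(a.nfkbn)
        assert np.max(np.abs(a.nfkbn - b.nfkbn)) / scale < 1e-3

    def test_nonnegative_concentrations(self, wt_tnfp):
        assert np.all(wt_tnfp.states >= -1e-9)

    def test_monomer_conservation_without_turnover(self, ref_params,
                                                   wt_steady):
        """With synthesis, degradation and processing off, volume-weighted
        Rel-family totals are conserved through a stimulated time course."""
        zeroed = {name: 0.0 for name in ref_params.values
                  if name.startswith(("syn_", "txn_", "tl_"))
                  or name in ("deg_rela", "deg_relb", "deg_p50", "deg_p100",
                              "deg_p52", "deg_a50", "deg_a52", "deg_b50",
                              "deg_b52", "proc_p100")}
        system = build_system(WT, ref_params.with_updates(zeroed))
        traj = simulate(system, make_tnfp_profile(), 8.0, initial=wt_steady)
        for monomer in ("RelA", "RelB", "p50", "p52"):
            total = traj.rel_totals(monomer)
            assert np.max(np.abs(total - total[0])) <= max(
                1e-6 * total[0], 1e-9), monomer

    def test_genotype_null_species_stay_zero(self, ko_tnfp):
        for name in ("p100", "p52", "A52", "nA52", "B52", "nB52",
                     "p100:A50", "p100:B50", "p100:B52"):
            assert np.max(ko_tnfp.concentration(name)) < 1e-9, name

    def test_rela_null_has_no_rela_species(self, ref_params):
        from nfkbdyn.genotypes import RELA_NULL
        from nfkbdyn.experiments import run_timecourse
        traj = run_timecourse(RELA_NULL, make_tnfp_profile(), ref_params, 8.0)
        for name in ("RelA", "A50", "nA50", "A52", "nA52", "IkBa:A50"):
            assert np.max(traj.concentration(name)) < 1e-9, name

    def test_derived_curves_are_sums_of_nuclear_dimers(self, wt_tnfp):
        total = sum(wt_tnfp.concentration(n)
                    for n in ("nA50", "nA52", "nB50", "nB52"))
        assert np.allclose(wt_tnfp.nfkbn, total)
        assert np.allclose(wt_tnfp.nrela + wt_tnfp.nrelb, total)

    def test_horizon_must_be_positive(self, wt_system, wt_steady):
        with pytest.raises(ConfigurationError):
            simulate(wt_system, make_tnfp_profile(), -1.0, initial=wt_steady)

    def test_short_horizon_warns(self, wt_system, wt_steady):
        from nfkbdyn.ikk import make_tnfc_profile
        with pytest.warns(UserWarning, match="shorter than input support"):
            simulate(wt_system, make_tnfc_profile(), 2.0, initial=wt_steady)
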