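"""Equilibria, Jacobians, Routh–Hurwitz, and the pairing scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinreg.crn import Reaction, ReactionNetwork, Species, ode_rhs
from twinreg.motifs import RegulatorSpec, close_loop, make_plant, plant_steady_state
from twinreg.scenarios import PLANT_PARAMS, SCENARIOS, get_scenario
from twinreg.simulate import run
from twinreg.stability import (
    EquilibriumNotFound,
    assess,
    characteristic_polynomial,
    find_equilibrium,
    jacobian,
    pairing_scan,
    pr_balance_check,
    routh_hurwitz,
)


class TestRouthHurwitz:
    def test_first_order_stable(self):
        assert routh_hurwitz([1.0, 1.0]) == "stable"

    def test_sign_change_unstable(self):
        assert routh_hurwitz([1.0, 0.5, -1.0]) == "unstable"

    def test_imaginary_pair_is_marginal(self):
        # s² + 1: purely imaginary roots
        assert routh_hurwitz([1.0, 0.0, 1.0]) == "marginal"

    def test_symmetric_real_pair_is_unstable(self):
        # s² − 1: roots ±1, resolved through the auxiliary polynomial
        assert routh_hurwitz([1.0, 0.0, -1.0]) == "unstable"

    def test_integrator_chain_is_marginal(self):
        # s·(s+1): a root exactly at the origin
        assert routh_hurwitz([1.0, 1.0, 0.0]) == "marginal"

    def test_plant_characteristic_polynomial(self):
        # s² + (d1+d2)s + (d1d2 − α1α2) with the standard rates: 1 > 0.04
        p = PLANT_PARAMS
        coeffs = [1.0, p["d1"] + p["d2"],
                  p["d1"] * p["d2"] - p["alpha1"] * p["alpha2"]]
        assert routh_hurwitz(coeffs) == "stable"

    def test_negative_leading_coefficient_normalized(self):
        assert routh_hurwitz([-1.0, -2.0, -1.0]) == "stable"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            routh_hurwitz([])

    def test_agrees_with_root_construction_oracle(self):
        """Verdict ≡ sign pattern of root real parts, on 1000 polynomials
        built from randomly chosen (well-separated) roots."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            n_real = int(rng.integers(0, 4))
            n_pairs = int(rng.integers(0, 3))
            if n_real + n_pairs == 0:
                continue
            reals = rng.uniform(0.05, 3.0, n_real) * rng.choice([-1, 1], n_real)
            roots = list(reals)
            for _ in range(n_pairs):
                re = rng.uniform(0.05, 3.0) * rng.choice([-1, 1])
                im = rng.uniform(0.1, 3.0)
                roots += [complex(re, im), complex(re, -im)]
            coeffs = np.real(np.poly(roots))
            expected = ("stable" if max(np.real(roots)) < 0 else "unstable")
            assert routh_hurwitz(coeffs) == expected, roots
            checked += 1

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        reals=st.lists(
            st.floats(0.05, 3.0).flatmap(
                lambda m: st.sampled_from([-m, m])),
            min_size=1, max_size=5,
        ),
        pair=st.one_of(
            st.none(),
            st.tuples(st.floats(0.05, 3.0), st.floats(0.1, 3.0),
                      st.booleans()),
        ),
    )
    def test_verdict_property_on_constructed_roots(self, reals, pair):
        """For any polynomial built from well-separated roots, the verdict
        equals the sign pattern of the root real parts."""
        roots = [complex(r, 0) for r in reals]
        if pair is not None:
            mag, im, neg = pair
            re = -mag if neg else mag
            roots += [complex(re, im), complex(re, -im)]
        coeffs = np.real(np.poly(roots))
        expected = "stable" if max(z.real for z in roots) < 0 else "unstable"
        assert routh_hurwitz(coeffs) == expected


class TestJacobian:
    def test_plant_jacobian_constant(self):
        net = make_plant(**PLANT_PARAMS)
        expected = [[-1.0, 0.1], [0.4, -1.0]]
        for state in ([0.0, 0.0], [3.0, 7.0]):
            np.testing.assert_allclose(jacobian(net, state), expected)

    def test_ratio_loop_z1_row(self):
        """dŻ1/d(Y1,Y2,Z1,Z2) = [k1, 0, −η·Z2, −η·Z1]."""
        scen = get_scenario("fig4a")
        net = scen.network()
        state = np.array([2.0, 1.0, 0.3, 0.4])
        J = jacobian(net, state)
        i = net.species_index("Z1")
        np.testing.assert_allclose(
            J[i], [0.5, 0.0, -10 * 0.4, -10 * 0.3]
        )

    @pytest.mark.parametrize("scenario_id", sorted(SCENARIOS))
    def test_matches_central_finite_differences(self, scenario_id):
        net = SCENARIOS[scenario_id].network()
        rhs = ode_rhs(net)
        rng = np.random.default_rng(17)
        h = 1e-6
        for _ in range(5):
            x = rng.uniform(0.5, 5.0, len(net.species))
            J = jacobian(net, x)
            for m in range(len(x)):
                xp, xm = x.copy(), x.copy()
                xp[m] += h
                xm[m] -= h
                col = (rhs(xp) - rhs(xm)) / (2 * h)
                np.testing.assert_allclose(
                    J[:, m], col, rtol=1e-6, atol=1e-6
                )


class TestFindEquilibrium:
    def test_plant_matches_closed_form(self):
        net = make_plant(**PLANT_PARAMS)
        eq = find_equilibrium(net)
        np.testing.assert_allclose(eq, plant_steady_state(**PLANT_PARAMS),
                                   rtol=1e-10)

    def test_centralised_loop_outputs(self):
        net = get_scenario("fig5c").network()
        eq = find_equilibrium(net)
        assert eq[net.species_index("Y1")] == pytest.approx(16.0, rel=1e-9)
        assert eq[net.species_index("Y2")] == pytest.approx(4.0, rel=1e-9)

    def test_pure_decay_network_has_origin_equilibrium(self):
        net = ReactionNetwork(
            species=[Species("A"), Species("B")],
            reactions=[
                Reaction((("A", 1),), (("B", 1),), "k"),
                Reaction((("B", 1),), (), "d"),
            ],
            parameters={"k": 1.0, "d": 0.5},
        )
        eq = find_equilibrium(net, seed_state=np.zeros(2))
        np.testing.assert_allclose(eq, [0.0, 0.0], atol=1e-12)

    def test_bad_seed_rejected(self):
        net = make_plant(**PLANT_PARAMS)
        with pytest.raises(ValueError):
            find_equilibrium(net, seed_state=np.array([np.inf, 0.0]))


class TestAssess:
    @pytest.mark.parametrize("scenario_id",
                             ["fig3b", "fig4a", "fig4b", "fig5a", "fig5b",
                              "fig5c"])
    def test_nominal_scenarios_are_stable(self, scenario_id):
        report = assess(get_scenario(scenario_id).network())
        assert report.verdict == "stable"
        assert report.routh_verdict == "stable"

    def test_mispaired_loop_is_unstable(self):
        report = assess(get_scenario("fig6").network())
        assert report.verdict == "unstable"
        assert report.routh_verdict == "unstable"

    def test_verdicts_cross_validate(self):
        for sid in ("fig4a", "fig5b", "fig6"):
            report = assess(get_scenario(sid).network())
            signs = report.jacobian_eigenvalues.real < 0
            assert report.routh_verdict == (
                "stable" if signs.all() else "unstable"
            )

    def test_simulation_and_root_solve_agree(self):
        """Two independent routes to the same point: a convergence run and
        the Newton-type root solve must land on the same equilibrium."""
        for sid in ("fig4a", "fig4b", "fig5a", "fig5b", "fig5c"):
            net = get_scenario(sid).network()
            result = run(net, t_end=500.0)
            eq = find_equilibrium(net)
            sim = np.array([result.steady_state[n] for n in net.species_names])
            np.testing.assert_allclose(sim, eq, rtol=1e-6, atol=1e-8)

    def test_equilibrium_residual_reported(self):
        report = assess(get_scenario("fig4a").network())
        assert report.residual < 1e-10


class TestPairingScan:
    def test_single_point_consistent_with_assess(self):
        table = pairing_scan(max_points=1)
        assert len(table) == 1
        row = table.iloc[0]
        params = {k: row[k] for k in
                  ("k1", "k2", "k3", "k4", "theta1", "theta2", "eta1", "eta2")}
        spec = RegulatorSpec("D2_MISPAIRED", params)
        net = close_loop(make_plant(**PLANT_PARAMS), spec)
        if row["verdict"] == "no_equilibrium":
            with pytest.raises(EquilibriumNotFound):
                find_equilibrium(net, seed_state=np.ones(6))
        else:
            report = assess(net)
            assert report.verdict == row["verdict"]

    def test_small_scan_finds_no_stable_mispairing(self):
        table = pairing_scan(max_points=300)
        assert (table["verdict"] == "stable").sum() == 0

    def test_correct_pairing_stable_at_reference_point(self):
        assert assess(get_scenario("fig5b").network()).verdict == "stable"

    def test_deterministic_enumeration(self):
        a = pairing_scan(max_points=50)
        b = pairing_scan(max_points=50)
        assert a.equals(b)


class TestPrBalance:
    def _symmetric_loop(self, k1, k2, k3, k4):
        plant = make_plant(b1=1.5, b2=1.5, d1=1.0, d2=1.0,
                           alpha1=0.2, alpha2=0.2)
        spec = RegulatorSpec(
            "R", {"k1": k1, "k2": k2, "k3": k3, "eta": 10.0, "k4": k4},
            extra_inhibition_on_Y1=True,
        )
        return close_loop(plant, spec)

    def test_symmetric_configuration_balances(self):
        # symmetric plant and k1=k2, k3=k4 force Z1*=Z2*, so the
        # positive-real balance k2·k4·Z1* = k1·k3·Z2* holds exactly
        net = self._symmetric_loop(1.0, 1.0, 2.0, 2.0)
        assert pr_balance_check(net) == pytest.approx(0.0, abs=1e-9)

    def test_residual_antisymmetric_under_role_swap(self):
        net_a = self._symmetric_loop(0.5, 1.0, 2.0, 3.0)
        net_b = self._symmetric_loop(1.0, 0.5, 3.0, 2.0)
        ra, rb = pr_balance_check(net_a), pr_balance_check(net_b)
        assert ra == pytest.approx(-rb, rel=1e-6)

    def test_reference_augmented_loop_reports_residual(self):
        spec = RegulatorSpec(
            "R", {"k1": 0.5, "k2": 1.0, "k3": 2.0, "eta": 10.0, "k4": 2.0},
            extra_inhibition_on_Y1=True,
        )
        net = close_loop(make_plant(**PLANT_PARAMS), spec)
        residual = pr_balance_check(net)
        assert np.isfinite(residual)

    def test_wrong_family_refused(self):
        net = get_scenario("fig5a").network()
        with pytest.raises(ValueError, match="R or LC"):
            pr_balance_check(net)

    def test_missing_augmentation_refused(self):
        net = get_scenario("fig4a").network()
        with pytest.raises(ValueError, match="extra inhibition"):
            pr_balance_check(net)


class TestCharacteristicPolynomial:
    def test_monic_and_matches_trace_det(self):
        J = np.array([[-1.0, 0.1], [0.4, -1.0]])
        coeffs = characteristic_polynomial(J)
        np.testing.assert_allclose(coeffs, [1.0, 2.0, 1.0 - 0.04])
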