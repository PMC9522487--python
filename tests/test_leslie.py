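"""Leslie-Gower model: flow, fitness layer, equilibrium and stability."""

import numpy as np
import pytest

from leukodyn import (
    GowerSingularityError,
    IntegratorConfig,
    LeslieParams,
    PopulationState,
    characteristic_coefficients,
    coexistence_equilibrium,
    integrate,
    jacobian_at_equilibrium,
    leslie_fitness,
    leslie_map_step,
    leslie_rhs,
    leslie_stability_report,
    leslie_vector_field,
    node_focus_criterion,
    reported_trace_quantity,
    truncate,
)
from tests.conftest import random_positive_params


class TestFlow:
    def test_equilibrium_residual_early(self, stage_params):
        eq = coexistence_equilibrium(stage_params["early"])
        rhs = leslie_rhs(stage_params["early"], PopulationState(*eq.as_tuple()))
        assert rhs == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_direct_substitution(self, stage_params):
        rhs = leslie_rhs(stage_params["early"], PopulationState(i=1.0, l=1.0))
        assert rhs[0] == pytest.approx(0.3999986, abs=1e-7)
        assert rhs[1] == pytest.approx(0.1, abs=1e-12)

    def test_predator_free_axis(self, stage_params):
        assert leslie_rhs(stage_params["early"], PopulationState(i=5.0, l=0.0))[1] == 0.0

    def test_gower_singularity_raises(self, stage_params):
        with pytest.raises(GowerSingularityError):
            leslie_rhs(stage_params["early"], PopulationState(i=0.0, l=1.0))

    def test_equilibrium_residual_random_params(self, rng):
        for params in random_positive_params(rng, 1000):
            eq = coexistence_equilibrium(params)
            rhs = leslie_rhs(params, PopulationState(*eq.as_tuple()))
            scale = max(1.0, eq.x_star, eq.y_star)
            assert abs(rhs[0]) / scale < 1e-10 and abs(rhs[1]) / scale < 1e-10


class TestFitnessAndMap:
    def test_prey_at_carrying_capacity(self):
        params = LeslieParams(r1=0.5, c1=0.0, b=0.1, r2=0.6, c2=0.5, k=100.0)
        H1, _ = leslie_fitness(params, PopulationState(i=100.0, l=0.0))
        assert H1 == pytest.approx(0.0)

    def test_predator_free_growth_is_r2(self):
        params = LeslieParams(r1=0.5, c1=0.0, b=0.1, r2=0.6, c2=0.5)
        _, H2 = leslie_fitness(params, PopulationState(i=7.0, l=0.0))
        assert H2 == pytest.approx(0.6)

    def test_fitness_hand_value(self):
        params = LeslieParams(r1=0.5, c1=0.0, b=0.1, r2=0.6, c2=0.5, k=100.0)
        H1, _ = leslie_fitness(params, PopulationState(i=50.0, l=1.0))
        assert H1 == pytest.approx(0.15)

    def test_map_step_hand_value(self):
        params = LeslieParams(r1=0.5, c1=0.0, b=0.1, r2=0.6, c2=0.5, k=100.0, c=1.0)
        nxt = leslie_map_step(params, PopulationState(i=50.0, l=1.0))
        assert nxt.i == pytest.approx(57.5)
        assert nxt.t == pytest.approx(1.0)

    def test_extinction_is_absorbing(self, stage_params):
        nxt = leslie_map_step(stage_params["early"], PopulationState(0.0, 0.0))
        assert (nxt.i, nxt.l) == (0.0, 0.0)

    def test_equilibrium_is_map_fixed_point_under_ode_form(self, stage_params):
        """With the flow's own per-capita growth, E is a fixed point of the map."""
        for params in stage_params.values():
            eq = coexistence_equilibrium(params)
            nxt = leslie_map_step(
                params, PopulationState(*eq.as_tuple()), per_capita="ode"
            )
            assert (nxt.i, nxt.l) == pytest.approx(eq.as_tuple(), abs=1e-12)


class TestEquilibrium:
    def test_early_truncates_to_reported_values(self, stage_params):
        eq = coexistence_equilibrium(stage_params["early"])
        assert (truncate(eq.x_star), truncate(eq.y_star)) == (4.99, 5.99)

    def test_chronic_equilibrium(self, stage_params):
        eq = coexistence_equilibrium(stage_params["chronic"])
        assert eq.as_tuple() == pytest.approx((0.5, 0.5))

    def test_acute_equilibrium(self, stage_params):
        eq = coexistence_equilibrium(stage_params["acute"])
        assert eq.as_tuple() == pytest.approx((0.448, 0.84))

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            LeslieParams(r1=0.5, c1=0.0, b=0.0, r2=0.6, c2=0.5)


class TestJacobian:
    def test_early_closed_form_entries(self, stage_params):
        J = jacobian_at_equilibrium(stage_params["early"])
        assert J[0, 0] == pytest.approx(-0.4999914801, abs=1e-9)
        assert J[0, 1] == pytest.approx(-7.0999e-6, rel=1e-4)
        assert J[1, 0] == pytest.approx(0.72)
        assert J[1, 1] == pytest.approx(-0.6)

    def test_determinant_identity_random_params(self, rng):
        """det J(E) = r1*r2 exactly, for random positive parameter sets."""
        for params in random_positive_params(rng, 1000):
            det = np.linalg.det(jacobian_at_equilibrium(params))
            assert det == pytest.approx(params.r1 * params.r2, rel=1e-10)

    def test_characteristic_roots_are_eigenvalues(self, rng):
        """Eigenvalues solve lambda^2 + p*lambda + q from the printed coefficients."""
        for params in random_positive_params(rng, 200):
            p, q = characteristic_coefficients(params)
            roots = np.sort_complex(np.roots([1.0, p, q]))
            eig = np.sort_complex(np.linalg.eigvals(jacobian_at_equilibrium(params)))
            np.testing.assert_allclose(roots, eig, atol=1e-9)

    def test_characteristic_coefficients_early(self, stage_params):
        p, q = characteristic_coefficients(stage_params["early"])
        assert p == pytest.approx(1.09999, abs=1e-4)
        assert q == pytest.approx(0.3)


class TestStabilitySummaries:
    def test_early_node_criterion(self, stage_params):
        lhs, rhs, label = node_focus_criterion(stage_params["early"])
        assert lhs == pytest.approx(4.5548e-3, rel=1e-3)
        assert rhs == pytest.approx(8.519876e-6, rel=1e-3)
        assert label == "node"

    def test_acute_focus_criterion(self, stage_params):
        lhs, rhs, label = node_focus_criterion(stage_params["acute"])
        assert lhs == pytest.approx(8.623253e-4, rel=1e-3)
        assert rhs == pytest.approx(0.588)
        assert label == "focus"

    def test_equal_growth_rates_give_focus(self):
        params = LeslieParams(r1=0.6, c1=0.3, b=0.2, r2=0.6, c2=0.5)
        lhs, rhs, label = node_focus_criterion(params)
        assert lhs == 0.0 and label == "focus"

    @pytest.mark.parametrize(
        "stage, expected", [("acute", 0.638), ("chronic", 0.3), ("early", 0.100008)]
    )
    def test_reported_trace_quantity(self, stage_params, stage, expected):
        assert reported_trace_quantity(stage_params[stage]) == pytest.approx(
            expected, rel=1e-4
        )

    def test_report_bundles_criterion_fields(self, stage_params):
        report = leslie_stability_report(stage_params["chronic"]).to_dict()
        assert report["det"] == pytest.approx(0.36)
        assert report["label"] == "stable focus"  # tau=-0.9, disc=-0.63
        assert "criterion_lhs" in report and "reported_trace_quantity" in report


class TestGlobalAttraction:
    def test_grid_of_initial_conditions_reaches_equilibrium(self, stage_params):
        """Early-stage trajectories from a 10x10 grid all converge to E."""
        params = stage_params["early"]
        eq = np.array(coexistence_equilibrium(params).as_tuple())
        rhs = leslie_vector_field(params)
        for i0 in np.linspace(0.6, 10.0, 10):
            for l0 in np.linspace(0.6, 10.0, 10):
                traj = integrate(
                    rhs, [i0, l0], IntegratorConfig(method="rk45", t_end=500.0)
                )
                assert np.linalg.norm(traj.final - eq) < 1e-3, (i0, l0)
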