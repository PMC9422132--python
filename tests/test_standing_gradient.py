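import dataclasses

import numpy as np
import pytest

import csfosmo as c
from csfosmo.standing_gradient import StandingGradientError


class TestBuildProblem:
    def test_flux_density_is_rate_over_total_wall_area(self, unit_geometry):
        p = c.build_problem(unit_geometry, 1.4e-5, 3.48e-5)
        expected = 3.48e-5 / unit_geometry.total_wall_area_cm2
        assert p.flux_density_mmol_s_cm2 == pytest.approx(expected, rel=1e-12)
        # hand division against the ~57 cm^2 true membrane area
        assert p.flux_density_mmol_s_cm2 == pytest.approx(6.1e-7, rel=0.03)

    def test_zero_rate_zero_flux(self, unit_geometry):
        assert c.build_problem(unit_geometry, 1.4e-5, 0.0).flux_density_mmol_s_cm2 == 0

    def test_doubling_wall_area_halves_flux(self, unit_geometry):
        p1 = c.build_problem(unit_geometry, 1.4e-5, 3.48e-5)
        bigger = dataclasses.replace(
            unit_geometry, wall_area_um2=2 * unit_geometry.wall_area_um2
        )
        p2 = c.build_problem(bigger, 1.4e-5, 3.48e-5)
        assert p2.flux_density_mmol_s_cm2 == pytest.approx(
            p1.flux_density_mmol_s_cm2 / 2, rel=1e-12
        )


class TestSolve:
    def test_no_pumping_no_flow(self, unit_geometry):
        p = c.build_problem(unit_geometry, 1.4e-5, 0.0)
        sol = c.solve(p)
        assert sol.q_unit_cm3_s == 0.0
        assert np.allclose(sol.concentration_mosm, 307.0)
        assert np.allclose(sol.velocity_cm_s, 0.0)

    def test_boundary_conditions(self, reference_solution):
        assert reference_solution.velocity_cm_s[0] == pytest.approx(0.0, abs=1e-15)
        assert reference_solution.concentration_mosm[-1] == pytest.approx(
            307.0, rel=1e-9
        )

    def test_concentration_never_below_bath(self, reference_solution):
        assert np.all(reference_solution.concentration_mosm >= 307.0 - 1e-9)

    def test_reference_excess_is_fraction_of_a_mosm(self, reference_solution):
        assert 0.01 < reference_solution.max_excess_mosm < 1.0

    def test_solute_conservation(self, reference_solution):
        out = reference_solution.solute_flux_mouth_osmol_s()
        inp = reference_solution.solute_input_osmol_s()
        assert out == pytest.approx(inp, rel=1e-6)

    def test_water_conservation(self, reference_solution):
        q = reference_solution.q_unit_cm3_s
        integral = reference_solution.water_influx_integral_cm3_s()
        assert integral == pytest.approx(q, rel=1e-6)

    def test_mesh_doubling_changes_q_by_less_than_0p1_percent(
        self, reference_problem, reference_solution
    ):
        fine = c.solve(reference_problem, n_nodes=201)
        assert fine.q_unit_cm3_s == pytest.approx(
            reference_solution.q_unit_cm3_s, rel=1e-3
        )

    def test_diffusion_x100_shrinks_excess_x100(self, reference_problem):
        base = c.solve(reference_problem)
        fast = c.solve(
            dataclasses.replace(
                reference_problem,
                diffusion_cm2_s=100 * reference_problem.diffusion_cm2_s,
            )
        )
        ratio = base.max_excess_mosm / fast.max_excess_mosm
        assert ratio == pytest.approx(100.0, rel=0.01)

    def test_emergent_osmolarity_at_least_bath(self, reference_solution):
        assert reference_solution.emergent_osm_mosm >= 307.0

    @pytest.mark.parametrize("factor", [2.0, 5.0])
    def test_q_monotone_in_lp_and_flux(self, reference_problem, factor):
        base = c.solve(reference_problem).q_unit_cm3_s
        more_lp = dataclasses.replace(
            reference_problem,
            lp_wall_cm_s_osm=factor * reference_problem.lp_wall_cm_s_osm,
        )
        more_phi = dataclasses.replace(
            reference_problem,
            flux_density_mmol_s_cm2=factor * reference_problem.flux_density_mmol_s_cm2,
        )
        assert c.solve(more_lp).q_unit_cm3_s > base
        assert c.solve(more_phi).q_unit_cm3_s > base

    def test_q_monotone_in_channel_length(self, morphometry, reference_problem):
        longer_geom = c.derive_unit_geometry(
            morphometry, 4.6, channel_length="microvillus"
        )
        longer = dataclasses.replace(reference_problem, geometry=longer_geom)
        assert c.solve(longer).q_unit_cm3_s > c.solve(reference_problem).q_unit_cm3_s

    def test_invalid_problem_rejected(self, unit_geometry):
        with pytest.raises(StandingGradientError):
            c.StandingGradientProblem(
                geometry=unit_geometry,
                lp_wall_cm_s_osm=-1.0,
                diffusion_cm2_s=1.5e-5,
                bath_osm_mosm=307.0,
                flux_density_mmol_s_cm2=1e-7,
            )
        with pytest.raises(StandingGradientError):
            c.build_problem(unit_geometry, 1.4e-5, -1.0)


class TestLinearizedOracle:
    def test_agrees_with_full_bvp_in_small_perturbation_regime(
        self, reference_problem, reference_solution
    ):
        lin = c.analytic_linearized(reference_problem)
        assert reference_solution.max_excess_mosm / 307.0 < 0.01
        assert lin.q_unit_cm3_s == pytest.approx(
            reference_solution.q_unit_cm3_s, rel=0.05
        )

    def test_zero_flux_zero_everywhere(self, unit_geometry):
        p = c.build_problem(unit_geometry, 1.4e-5, 0.0)
        lin = c.analytic_linearized(p)
        assert lin.q_unit_cm3_s == 0.0
        assert np.allclose(lin.velocity_cm_s, 0.0)

    def test_linear_in_lp(self, reference_problem):
        full = c.analytic_linearized(reference_problem).q_unit_cm3_s
        half = c.analytic_linearized(
            dataclasses.replace(
                reference_problem,
                lp_wall_cm_s_osm=reference_problem.lp_wall_cm_s_osm / 2,
            )
        ).q_unit_cm3_s
        assert half == pytest.approx(full / 2, rel=1e-12)


class TestPredictedSecretion:
    def test_reference_fraction_below_0p1_percent(self, reference_solution):
        pred = c.predicted_secretion(reference_solution, observed_vp_ul_min=6.8)
        assert pred.fraction_percent < 0.1
        assert pred.q_total_ul_min < 0.01

    def test_zero_flow_zero_fraction(self, unit_geometry):
        sol = c.solve(c.build_problem(unit_geometry, 1.4e-5, 0.0))
        pred = c.predicted_secretion(sol, observed_vp_ul_min=6.8)
        assert pred.fraction_percent == 0.0

    def test_direct_method_scale_still_below_0p1_percent(self, unit_geometry):
        # lower 'direct-method' secretion rate, solute rate rescaled with it
        vp_alt = 1.9
        rate_alt = 3.48e-5 * vp_alt / 6.8
        sol = c.solve(c.build_problem(unit_geometry, 1.4e-5, rate_alt))
        pred = c.predicted_secretion(sol, observed_vp_ul_min=vp_alt)
        assert pred.fraction_percent < 0.1
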