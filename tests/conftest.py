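import pytest

import csfosmo as c


@pytest.fixture(scope="session")
def morphometry() -> c.MicrovillusMorphometry:
    return c.MicrovillusMorphometry()


@pytest.fixture(scope="session")
def unit_geometry(morphometry) -> c.FunctionalUnitGeometry:
    return c.derive_unit_geometry(morphometry, 4.6)


@pytest.fixture(scope="session")
def reference_problem(unit_geometry) -> c.StandingGradientProblem:
    """The measured-parameter standing-gradient problem."""
    return c.build_problem(
        unit_geometry,
        lp_luminal_true_cm_s_osm=1.4e-5,
        total_solute_rate_mmol_s=3.48e-5,
        bath_osm_mosm=307.0,
    )


@pytest.fixture(scope="session")
def reference_solution(reference_problem) -> c.StandingGradientSolution:
    return c.solve(reference_problem)
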