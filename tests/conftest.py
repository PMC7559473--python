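import logging

import numpy as np
import pytest

from thermalsteps.covariates import StandardizationRecord, annotate, standardize
from thermalsteps.raster import CovariateStack, RasterLayer
from thermalsteps.steps import ParametricKernel, aggregate_fixes, build_steps, build_strata
from thermalsteps.synthetic import (LandscapeConfig, SimulationConfig,
                                    generate_landscape, simulate_population)

logging.getLogger("thermalsteps").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def landscape() -> CovariateStack:
    """A mid-sized synthetic world shared across tests."""
    return generate_landscape(LandscapeConfig(n_rows=200, n_cols=200, seed=7))


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_animals=6, n_steps_per_animal=100, seed=3)


@pytest.fixture(scope="session")
def annotated_table(landscape, sim_config):
    """A standardized covariate table from one simulated herd, on the
    generator's coefficient scale, with the true model attached in attrs."""
    track, model = simulate_population(landscape, sim_config)
    steps = build_steps(aggregate_fixes(track))
    kernels = {a: ParametricKernel(a, sim_config.step_shape, sim_config.step_scale,
                                   sim_config.turn_concentration)
               for a in steps["animal_id"].unique()}
    strata = build_strata(steps, kernels, M=10, seed=5)
    table = annotate(strata, landscape)
    table, _ = standardize(table, record=StandardizationRecord.from_divisors(model.divisors))
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
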