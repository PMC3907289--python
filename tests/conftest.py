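"""Shared fixtures.

Expensive artefacts (reference trajectory, population run, response
coefficients, the recovery fit) are session-scoped so that module tests and
the acceptance tests reuse one computation.
"""

import numpy as np
import pytest

from nerkinetics.control import response_coefficients
from nerkinetics.datasets import NoiseSpec, generate_bulk_dataset
from nerkinetics.inference import fit_model
from nerkinetics.model import reference_parameters, simulate
from nerkinetics.population import PopulationSpec, simulate_population


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_traj(ref_params):
    times = np.linspace(0.0, 480.0, 161)
    return simulate(ref_params, times)


@pytest.fixture(scope="session")
def ref_response(ref_params):
    return response_coefficients(ref_params, target="repair_rate", t_eval=30.0)


@pytest.fixture(scope="session")
def population_run(ref_params):
    spec = PopulationSpec(n_cells=500, times=(30.0, 240.0), seed=11)
    return spec, simulate_population(ref_params, spec)


@pytest.fixture(scope="session")
def recovery_fit(ref_params):
    """Noise-free bulk dataset and the multi-start fit recovering two K_Ds."""
    data = generate_bulk_dataset(
        ref_params,
        NoiseSpec(sd=0.0),
        acc_times=np.arange(0.0, 241.0, 20.0),
        include_flip=False,
    )
    free = ("kd:XPC:DAMAGED", "kd:XPA:UNWOUND")
    fit = fit_model(data, ref_params, free, n_starts=10, seed=7, spread=3.0)
    return data, fit
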