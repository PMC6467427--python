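import numpy as np
import pytest

from glvfit import (
    CVaRSpec,
    GridSpec,
    NoiseModel,
    PriorSpec,
    build_design,
    draw_parameters,
    generate_dataset,
    transcribe,
)
from glvfit.solve import SolverOptions, solve


def population_prior_mean(n_species, model_form="glv"):
    """Prior mean at the generating-population means (mu=0.3, alpha_ss=-1)."""
    from glvfit.models import n_parameters

    mean = np.zeros(n_parameters(n_species, model_form))
    for s in range(n_species):
        mean[s * (n_species + 1)] = 0.3
        mean[s * (n_species + 1) + 1 + s] = -1.0
    if model_form == "saturable":
        mean[n_species * (n_species + 1):] = 1.0
    return mean


# A coarse grid for machinery tests where discretization accuracy is not the
# point; scientific accuracy tests use the defaults.
COARSE = GridSpec(mono_substeps=1, pairwise_n_intervals=120)


@pytest.fixture(scope="session")
def community2():
    params = draw_parameters(2, seed=21)
    design = build_design(2)
    data = generate_dataset(params, design, seed=22)
    return params, design, data


@pytest.fixture(scope="session")
def logistic_problem():
    """1-species community: mono logistic growth, 48 samples, 5% noise."""
    params = draw_parameters(1, seed=3)
    design = build_design(1)
    data = generate_dataset(params, design, seed=5)
    return params, design, data


@pytest.fixture(scope="session")
def logistic_map_solution(logistic_problem):
    params, design, data = logistic_problem
    nlp = transcribe(
        "glv", design, data, prior=PriorSpec(form="l2", mean=population_prior_mean(1), std=1 / 50)
    )
    result = solve(nlp)
    assert result.is_optimal
    return nlp, result


@pytest.fixture(scope="session")
def logistic_noprior_solution(logistic_problem):
    params, design, data = logistic_problem
    nlp = transcribe("glv", design, data, prior=PriorSpec(form="none"))
    result = solve(nlp)
    assert result.is_optimal
    return nlp, result
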