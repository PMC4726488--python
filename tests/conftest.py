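import numpy as np
import pandas as pd
import pytest

from dopametab import (
    MetaboliteMatrix,
    Scale,
    SimulationConfig,
    preprocess_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic study (1272 controls, 82 PD, 95 RLS, 456
    metabolites) with its preprocessed matrices; shared across recovery
    tests to amortize the simulation."""
    config = SimulationConfig(seed=11)
    matrix, annotation, genotypes, truth = simulate_cohort(config)
    standardized, log_complete, report = preprocess_pipeline(matrix, seed=11)
    return {
        "config": config,
        "matrix": matrix,
        "annotation": annotation,
        "genotypes": genotypes,
        "truth": truth,
        "standardized": standardized,
        "log": log_complete,
        "report": report,
    }


@pytest.fixture(scope="session")
def uncensored_cohort():
    """Default-size cohort without intensity-dependent censoring (random
    dropout only): isolates the pipeline's estimation behaviour from the
    irreducible truncation bias of left-censored data."""
    config = SimulationConfig(censor_quantile=0.0, seed=29)
    matrix, annotation, genotypes, truth = simulate_cohort(config)
    standardized, log_complete, report = preprocess_pipeline(matrix, seed=29)
    return {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "standardized": standardized,
        "log": log_complete,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (50 metabolites, default sample arms) for network
    recovery checks."""
    config = SimulationConfig(n_metabolites=50, seed=7)
    matrix, annotation, genotypes, truth = simulate_cohort(config)
    standardized, log_complete, report = preprocess_pipeline(matrix, seed=7)
    return {
        "config": config,
        "matrix": matrix,
        "annotation": annotation,
        "genotypes": genotypes,
        "truth": truth,
        "standardized": standardized,
        "log": log_complete,
    }


def toy_matrix(values, run_day=None, scale=Scale.RAW, metabolites=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"s{i}" for i in range(n)]
    metabolites = metabolites or [f"m{j}" for j in range(p)]
    if run_day is None:
        run_day = ["d0"] * n
    return MetaboliteMatrix(
        data=pd.DataFrame(values, index=samples, columns=metabolites),
        run_day=pd.Series(run_day, index=samples),
        scale=scale,
    )
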