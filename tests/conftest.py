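import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from icpnet import (  # noqa: E402
    CohortDesign,
    ExpressionMatrix,
    make_standard_effects,
    pool_samples,
    simulate_flags,
    simulate_individuals,
)


@pytest.fixture(scope="session")
def design():
    return CohortDesign(n_genes=500)


@pytest.fixture(scope="session")
def effects(design):
    return make_standard_effects(
        design, seed=11, n_de_mild=20, n_de_severe=25, module_size=10
    )


@pytest.fixture(scope="session")
def cohort_matrix(design, effects):
    individuals = simulate_individuals(design, effects)
    matrix = pool_samples(
        individuals, design, measurement_sd=effects.measurement_sd, seed=effects.seed
    )
    matrix.flags = simulate_flags(matrix, seed=effects.seed)
    return matrix


def toy_matrix(values, groups=None, flags=None):
    """Small ExpressionMatrix helper: values is a dict gene -> list."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    arrays = [f"a{j + 1}" for j in range(df.shape[1])]
    df.columns = arrays
    design = None
    if groups is not None:
        design = pd.DataFrame(
            {"array": arrays, "group": groups, "subgroup": groups}
        ).set_index("array")
    flags_df = None
    if flags is not None:
        flags_df = pd.DataFrame.from_dict(flags, orient="index").astype(bool)
        flags_df.columns = arrays
    return ExpressionMatrix(values=df, flags=flags_df, design=design)


@pytest.fixture
def three_group_matrix():
    return toy_matrix(
        {
            "gA": [1, 1, 2, 2, 3, 3],
            "gB": [0, 2, 1, 1, 1, 1],
            "gC": [5, 4, 3, 2, 1, 0],
        },
        groups=["healthy", "healthy", "mild", "mild", "severe", "severe"],
    )
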