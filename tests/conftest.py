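import numpy as np
import pytest

from lcsem import (
    CovarianceSummary,
    CovEdge,
    Edge,
    Fixed,
    Free,
    ModelSpec,
    default_params,
    simulate,
)


@pytest.fixture(scope="session")
def male_params():
    return default_params("male")


@pytest.fixture(scope="session")
def female_params():
    return default_params("female")


@pytest.fixture(scope="session")
def male_cohort(male_params):
    """A default-size synthetic male cohort (n = 201)."""
    return simulate(male_params, seed=42)


@pytest.fixture(scope="session")
def both_sexes_cohort(male_params, female_params):
    import pandas as pd

    from lcsem import RecordTable

    m = simulate(male_params, seed=11).frame
    f = simulate(female_params, seed=12).frame
    return RecordTable(frame=pd.concat([m, f], ignore_index=True))


@pytest.fixture
def toy_factor_spec():
    """One latent, two indicators, loadings (1, 2), unit variances."""
    return ModelSpec(
        variables=["x1", "x2", "f"],
        latents={"f"},
        edges=[Edge("f", "x1", Fixed(1.0)), Edge("f", "x2", Fixed(2.0))],
        covs=[
            CovEdge("x1", "x1", Fixed(1.0)),
            CovEdge("x2", "x2", Fixed(1.0)),
            CovEdge("f", "f", Fixed(1.0)),
        ],
    )


@pytest.fixture(scope="session")
def free_factor_spec():
    """Same toy model with free parameters, for fitting."""
    return ModelSpec(
        variables=["x1", "x2", "x3", "x4", "f"],
        latents={"f"},
        edges=[
            Edge("f", "x1", Fixed(1.0)),
            Edge("f", "x2", Free("l2")),
            Edge("f", "x3", Free("l3")),
            Edge("f", "x4", Free("l4")),
        ],
        covs=[
            CovEdge("x1", "x1", Free("e1")),
            CovEdge("x2", "x2", Free("e2")),
            CovEdge("x3", "x3", Free("e3")),
            CovEdge("x4", "x4", Free("e4")),
            CovEdge("f", "f", Free("psi")),
        ],
    )


def make_cov(labels, S, n) -> CovarianceSummary:
    return CovarianceSummary(labels=list(labels), S=np.asarray(S, dtype=float), n=n)
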