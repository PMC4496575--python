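import pytest

from icvnorm import (
    CohortSpec,
    StructureModel,
    fit_all_structures,
    generate_cohort,
    hunt_default_spec,
)


@pytest.fixture(scope="session")
def hunt_spec():
    return hunt_default_spec()


@pytest.fixture(scope="session")
def cohort(hunt_spec):
    """Default calibrated cohort, seed 1, shared across tests."""
    return generate_cohort(hunt_spec, seed=1)


@pytest.fixture(scope="session")
def fits(cohort):
    return fit_all_structures(cohort, grouping="sex")


@pytest.fixture()
def tiny_spec():
    """Three-structure spec for fast, targeted tests."""
    return CohortSpec(
        n_male=60,
        n_female=70,
        icv={"M": (1666.8, 122.9), "F": (1453.6, 113.5)},
        age={"M": (58.7, 4.1), "F": (58.2, 4.3)},
        height={"M": (178.1, 6.0), "F": (165.1, 5.6)},
        dbp={"M": (80.0, 10.0), "F": (73.2, 10.4)},
        structures=(
            StructureModel("gm_like", slope=0.003, intercept=3.0, noise_sd=0.5),
            StructureModel("wm_like", slope=0.32, intercept=-60.0, noise_sd=30.0),
            StructureModel("prop_like", slope=0.005, intercept=0.0, noise_sd=0.8),
        ),
        seed=0,
    )
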