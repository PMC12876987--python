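import numpy as np
import pytest

from itcmed.cohort import CohortSpec, sample_cohort
from itcmed.design import build_design_grid
from itcmed.estimation import estimate_participants, indifference_k

NO_DEGENERATES = {
    "bvftd": {"all_ss": 0.0, "all_ll": 0.0, "inconsistent": 0.0},
    "control": {"all_ss": 0.0, "all_ll": 0.0, "inconsistent": 0.0},
}


@pytest.fixture(scope="session")
def design():
    return build_design_grid()


@pytest.fixture(scope="session")
def indifference_ks(design):
    return np.array([indifference_k(t) for t in design])


@pytest.fixture(scope="session")
def clean_cohort200():
    """100+100 participants, no degenerate responders, fixed seed."""
    spec = CohortSpec(n_bvftd=100, n_control=100, fractions=NO_DEGENERATES,
                      seed=11)
    choices, clinical, truth = sample_cohort(spec)
    return spec, choices, clinical, truth


@pytest.fixture(scope="session")
def clean_estimates200(clean_cohort200):
    _, choices, _, _ = clean_cohort200
    return estimate_participants(choices)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (22 bvFTD / 17 controls) with default responder
    fractions."""
    spec = CohortSpec(seed=7)
    choices, clinical, truth = sample_cohort(spec)
    return spec, choices, clinical, truth
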