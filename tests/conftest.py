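import pytest

import mostscreen as ms
from mostscreen import published as pub


@pytest.fixture(scope="session")
def design():
    """The worked example's 2^5 leaflet design."""
    return pub.leaflet_design()


@pytest.fixture(scope="session")
def full_table(design):
    return pub.full_model_table(design)


@pytest.fixture(scope="session")
def pars_table(design):
    return pub.parsimonious_table(design)


@pytest.fixture(scope="session")
def tiny_design():
    """A 3-factor design for exhaustive checks."""
    return ms.enumerate_conditions(
        [
            ms.FactorDef("a", "Off", "On", "A"),
            ms.FactorDef("b", "Basic", "Enhanced", "B"),
            ms.FactorDef("c", "Off", "On", "C"),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort(design):
    """One scored synthetic cohort under the default truth model."""
    cohort = ms.generate_cohort(
        design, pub.default_truth_model(design), pub.default_cohort_config(1604, seed=42)
    )
    return ms.score_cohort(cohort)
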