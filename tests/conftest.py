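import pytest

import delaykit as dk


@pytest.fixture(scope="session")
def time_bank():
    return dk.time_selection_bank()


@pytest.fixture(scope="session")
def monetary_bank():
    return dk.monetary_selection_bank()


@pytest.fixture(scope="session")
def mcq_bank():
    return dk.mcq_bank()


@pytest.fixture(scope="session")
def default_study():
    """One default (uncontaminated) simulated cohort, scored."""
    study = dk.simulate_study(dk.clean_config(), seed=0)
    item_k, scores = dk.score_study(study.responses, study.config.banks())
    return study, item_k, scores


@pytest.fixture(scope="session")
def contaminated_study():
    """Cohort with 2+1 planted straightliners and 5 planted score outliers."""
    study = dk.simulate_study(dk.contaminated_config(), seed=0)
    item_k, scores = dk.score_study(study.responses, study.config.banks())
    return study, item_k, scores
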