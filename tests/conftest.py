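import numpy as np
import pytest

import shortform as sf
from shortform import ecr


@pytest.fixture(scope="session")
def bank():
    return ecr.build_ecr_bank()


@pytest.fixture(scope="session")
def ecr_model():
    return ecr.default_population_model()


@pytest.fixture(scope="session")
def study788(ecr_model):
    """One simulated development-sized study (n=788) from the ECR fixture."""
    return sf.simulate_study(ecr_model, 788, seed=3)


@pytest.fixture(scope="session")
def short_model():
    return ecr.short_form_population_model()


@pytest.fixture(scope="session")
def short_study_5000(short_model):
    return sf.simulate_study(short_model, 5000, seed=7)


@pytest.fixture(scope="session")
def planted_study():
    from shortform import planted

    return sf.simulate_study(planted.planted_model(), 500, seed=42)


@pytest.fixture(scope="session")
def planted_evaluator(planted_study):
    from shortform import planted

    return sf.SubsetEvaluator(
        planted_study.responses, planted.planted_bank(), "avoidance"
    )


@pytest.fixture(scope="session")
def short_recoded_5000(short_study_5000):
    """Short-form responses recoded back to the construct-aligned scale."""
    data = short_study_5000.responses.copy()
    for pos in (1, 3, 7, 9):
        data[pos] = 8 - data[pos]
    return data
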