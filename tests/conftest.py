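import numpy as np
import pytest

from voicetest import simulate


@pytest.fixture(scope="session")
def fixture_bundle():
    """End-to-end synthetic bundle for the full 72-trial design."""
    return simulate.make_fixture("item-selection", seed=11)


@pytest.fixture(scope="session")
def validation_bundle():
    return simulate.make_fixture("validation", seed=11)


@pytest.fixture(scope="session")
def rasch_responses():
    """Clean Rasch responses: 8 items, 300 persons, b spread over [-1.5, 1.5]."""
    b = np.linspace(-1.5, 1.5, 8)
    model = simulate.RespondentModel(difficulty=b)
    return b, simulate.simulate_responses(model, 300, seed=42)
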