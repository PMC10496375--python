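import numpy as np
import pytest

import virago


@pytest.fixture(scope="session")
def survey_table():
    """The bundled isolate survey table."""
    return virago.read_survey(virago.bundled_survey_path())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230912)
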