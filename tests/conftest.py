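import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_grid_warnings():
    """Silence the informational unknown-age/laterality warnings; tests
    that assert on warnings re-enable them explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def synth_records():
    """A moderately sized, diagnosis-dense synthetic population shared by
    the oracle-equivalence suites (generated once per session)."""
    from hboc_triage.synthpop import generate_population

    from helpers import dense_synth_config

    return generate_population(dense_synth_config(1000, seed=20120101))
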