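import pytest

from cycleopt import reference_initial_state, reference_parameters


@pytest.fixture(scope="session")
def reference():
    """Packaged reference parameter set and its cycle-start state."""
    return reference_parameters(), reference_initial_state()
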