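import warnings

import pytest

from coasim.pipeline import RunConfig, run_group


@pytest.fixture(scope="session")
def control_bundle():
    """Full control-group pipeline run (4 tuned time points), shared."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_group("control", seed=1, config=RunConfig())
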