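import warnings

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(autouse=True)
def _quiet_drive_warnings():
    """Negative-diagonal-drive warnings are expected at realistic scales."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*diagonal drive.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*floored negative covariance.*")
        yield
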