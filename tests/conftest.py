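import numpy as np
import pytest

from phagofit import NegativeControlStats, ParamPoint

LN10 = np.log(10)


@pytest.fixture(scope="session")
def fig_params() -> ParamPoint:
    """The reference fitted parameter set used in worked examples."""
    return ParamPoint(m=2.17, p=0.739, alpha=2.53)


@pytest.fixture(scope="session")
def reference_neg() -> NegativeControlStats:
    """Typical DIO negative control: log10 mean 4.57, log10 SD 0.29."""
    return NegativeControlStats(
        log_mean=4.57 * LN10, log_sd=0.29 * LN10, n_events=100_000
    )
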