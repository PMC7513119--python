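import numpy as np
import pytest

from vfshock.entropy_core import prepare_series
from vfshock.signal_io import extract_preshock_window
from vfshock.synthetic_vf import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180591)


@pytest.fixture(scope="session")
def small_cohort():
    """30 + 30 synthetic shocks with outcome-linked waveforms."""
    return generate_cohort(CohortSpec(n_success=30, n_failure=30, seed=11))


@pytest.fixture(scope="session")
def small_cohort_windows(small_cohort):
    """(x60, labels) pairs: 5 s pre-shock windows at the 60 Hz working rate."""
    out = []
    for record, labels in small_cohort:
        window = extract_preshock_window(record, record.shocks[0], 5.0)
        out.append((prepare_series(window.samples, window.fs), labels))
    return out
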