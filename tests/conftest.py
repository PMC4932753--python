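import numpy as np
import pytest

from pupilpath import SyntheticConfig, simulate_study
from pupilpath.preprocess import CleanRecording


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by integration-level tests."""
    cfg = SyntheticConfig(
        n_participants=4,
        cases_per_participant=4,
        trial_duration_s=(12.0, 20.0),
        rng_seed=42,
    )
    return simulate_study(cfg)


def make_clean(d, null_mask=None, rate=60.0, pid="P", cid="C"):
    """Assemble a CleanRecording directly from a diameter vector."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    null = np.zeros(n, bool) if null_mask is None else \
        np.asarray(null_mask, bool)
    return CleanRecording(
        participant_id=pid,
        case_id=cid,
        t=np.arange(n) * 1000.0 / rate,
        x=np.zeros(n),
        y=np.zeros(n),
        d=d.copy(),
        d_raw=d.copy(),
        interpolated_mask=null,
        null_fraction=float(null.mean()),
        nominal_rate=rate,
    )


@pytest.fixture
def clean_factory():
    return make_clean
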