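import numpy as np
import pandas as pd
import pytest

from errmon.io_formats import TRIAL_COLUMNS, load_default_montage
from errmon.preprocessing import EpochSet, reject_artifacts


@pytest.fixture(scope="session")
def montage():
    return load_default_montage()


def make_trials(rows):
    """Trial table from (kind, rt1, rt2) tuples; onsets 3 s apart, one block."""
    recs = []
    for i, (kind, rt1, rt2) in enumerate(rows):
        color = 0 if kind == "nogo" else 1
        recs.append((i, 0, kind, color, 1000.0 + 3000.0 * i,
                     np.nan if rt1 is None else float(rt1),
                     np.nan if rt2 is None else float(rt2), ""))
    return pd.DataFrame(recs, columns=TRIAL_COLUMNS)


def make_epochs(data, sampling_rate=500.0, t_min=-100.0, labels=None,
                channel_labels=None, lock="response", checked=True):
    """EpochSet straight from an array (epochs x channels x samples)."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, n_s = data.shape
    times = t_min + (1000.0 / sampling_rate) * np.arange(n_s)
    labels = labels or ["correct_go"] * n_ep
    channel_labels = channel_labels or [f"ch{i}" for i in range(n_ch)]
    ep = EpochSet(data, times, lock, list(labels), ["kept"] * n_ep,
                  list(channel_labels), ["scalp"] * n_ch, sampling_rate)
    return reject_artifacts(ep, threshold=np.inf) if checked else ep


@pytest.fixture
def trials_factory():
    return make_trials


@pytest.fixture
def epochs_factory():
    return make_epochs
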