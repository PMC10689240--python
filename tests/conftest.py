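import numpy as np
import pandas as pd
import pytest

from socialphot.behavior import BoutTable
from socialphot.photometry import FzTrace, PhotometryTrace


@pytest.fixture
def make_fz():
    """Build an FzTrace directly from sample values (fs default 25 Hz)."""

    def _make(values, fs=25.0, zero_level=0.0):
        values = np.asarray(values, dtype=float)
        return FzTrace(np.arange(values.size) / fs, values, fs, zero_level=zero_level)

    return _make


@pytest.fixture
def make_trace():
    def _make(values, fs=25.0):
        return PhotometryTrace.from_samples(np.asarray(values, dtype=float), fs)

    return _make


@pytest.fixture
def make_bouts():
    """BoutTable from (stimulus, behavior, onset, offset) tuples."""

    def _make(rows, session="s1"):
        return BoutTable(
            pd.DataFrame(
                [(session, *r) for r in rows],
                columns=["session", "stimulus", "behavior", "onset_s", "offset_s"],
            )
        )

    return _make
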