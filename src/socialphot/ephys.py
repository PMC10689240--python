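"""Optogenetically evoked postsynaptic current detection and classification.

Voltage-clamp sweep sets are recorded while brief light pulses activate
opsin-expressing axons.  At -70 mV holding, evoked currents are inward
(negative, oEPSC); at 0 mV they are outward (positive, oIPSC).  A cell is
responsive when the across-sweep mean current deflects in the expected
direction beyond 1.5x the baseline standard deviation; the latency is the
first such crossing relative to light onset.  Sequential pharmacology
(ACSF -> TTX -> TTX + 4-AP) distinguishes monosynaptic connections
(abolished by TTX, recovered by 4-AP) from polysynaptic ones (not
recovered).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = ["PSCSweepSet", "PSCEvent", "detect_psc", "classify_connection", "CONDITIONS"]

CONDITIONS = ("ACSF", "TTX", "TTX+4AP")


@dataclass(frozen=True)
class PSCSweepSet:
    """A set of repeated voltage-clamp sweeps around one light pulse.

    sweeps : (n_samples, n_sweeps) current in pA.
    light_onset_ms : light pulse onset relative to sweep start.
    holding_mv : -70 (oEPSC, inward/negative) or 0 (oIPSC, outward/positive).
    """

    time_ms: np.ndarray
    sweeps: np.ndarray
    fs: float
    light_onset_ms: float
    holding_mv: float
    condition: str = "ACSF"
    pulse_width_ms: float = 1.0

    def __post_init__(self):
        time_ms = np.asarray(self.time_ms, dtype=float)
        sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if sweeps.ndim != 2 or sweeps.shape[0] != time_ms.size:
            raise ValueError("sweeps must be (n_samples, n_sweeps)")
        object.__setattr__(self, "time_ms", time_ms)
        object.__setattr__(self, "sweeps", sweeps)
        if not (time_ms[0] <= self.light_onset_ms <= time_ms[-1]):
            raise ValueError("light onset must lie within the sweep")
        if self.holding_mv not in (-70.0, 0.0, -70, 0):
            raise ValueError("holding potential must be -70 or 0 mV")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def expected_sign(self) -> int:
        """Expected PSC polarity: -1 (inward) at -70 mV, +1 (outward) at 0 mV."""
        return -1 if self.holding_mv == -70 else +1


@dataclass(frozen=True)
class PSCEvent:
    responsive: bool
    amplitude_pa: float
    latency_ms: Optional[float]
    kind: str  # 'oEPSC' or 'oIPSC'


def detect_psc(
    sweeps: PSCSweepSet,
    baseline_window_ms: float = 50.0,
    search_window_ms: float = 50.0,
    threshold_folds: float = 1.5,
    min_duration_ms: float = 0.3,
) -> PSCEvent:
    """Detect an evoked PSC on the across-sweep mean current.

    Baseline mean/SD come from the ``baseline_window_ms`` ending at light
    onset.  The cell is responsive iff, within ``search_window_ms`` after
    light onset, the mean current deflects in the expected direction
    strictly beyond ``threshold_folds`` x baseline SD and stays beyond it
    for at least ``min_duration_ms`` (a single noisy sample above threshold
    is not a synaptic current; a real PSC outlasts its rise time).  Latency
    is the start of the first sustained crossing minus light onset;
    amplitude is the baseline-subtracted extremum of the mean sweep within
    the search window (sign-rectified).
    """
    t = sweeps.time_ms
    mean = sweeps.sweeps.mean(axis=1)
    sign = sweeps.expected_sign
    kind = "oEPSC" if sign < 0 else "oIPSC"

    b_lo = sweeps.light_onset_ms - baseline_window_ms
    if b_lo < t[0]:
        raise ValueError("baseline window extends before the sweep start")
    base = mean[(t >= b_lo) & (t < sweeps.light_onset_ms)]
    if base.size < 2:
        raise ValueError("baseline window contains fewer than two samples")
    b_mean = float(base.mean())
    b_sd = float(base.std(ddof=1))

    win = (t >= sweeps.light_onset_ms) & (t <= sweeps.light_onset_ms + search_window_ms)
    deflect = sign * (mean[win] - b_mean)  # positive in the expected direction
    crossing = deflect > threshold_folds * b_sd  # strict exceedance
    amplitude = float(np.max(deflect, initial=0.0))
    need = max(int(round(min_duration_ms * sweeps.fs / 1000.0)), 1)

    # first run of >= `need` consecutive supra-threshold samples
    first = None
    run = 0
    for i, c in enumerate(crossing):
        run = run + 1 if c else 0
        if run >= need:
            first = i - need + 1
            break
    if first is None:
        return PSCEvent(False, amplitude, None, kind)
    latency = float(t[win][first] - sweeps.light_onset_ms)
    return PSCEvent(True, amplitude, latency, kind)


def classify_connection(events: Mapping[str, PSCEvent]) -> str:
    """Classify a connection from per-condition detection results.

    ACSF non-responsive -> 'none'.  ACSF responsive, abolished by TTX and
    recovered under TTX + 4-AP -> 'monosynaptic'; not recovered ->
    'polysynaptic'.  A response that survives TTX is physiologically
    'inconsistent'; missing pharmacology makes the cell 'unclassifiable'.
    """
    if "ACSF" not in events:
        raise ValueError("ACSF condition is required")
    if not events["ACSF"].responsive:
        return "none"
    if "TTX" not in events or "TTX+4AP" not in events:
        return "unclassifiable"
    if events["TTX"].responsive:
        return "inconsistent"
    return "monosynaptic" if events["TTX+4AP"].responsive else "polysynaptic"
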