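"""Raw fluorescence -> baseline-corrected dF/F -> whole-trace z-score (Fz).

Bulk fiber-photometry traces combine slow photobleaching drift with fast
calcium transients.  The baseline estimator tracks the drift with a sliding
low-quantile so that transients (which are one-sided, upward deflections) do
not pull the baseline up.  dF/F is the fractional change relative to that
baseline, and Fz is the whole-trace z-score of dF/F, the unit in which all
downstream response metrics are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "PhotometryTrace",
    "BaselineConfig",
    "DffTrace",
    "FzTrace",
    "estimate_baseline",
    "compute_dff",
    "zscore_trace",
    "preprocess",
]

_GRID_TOL = 1e-6


@dataclass(frozen=True)
class PhotometryTrace:
    """Uniformly sampled raw fluorescence.

    Parameters
    ----------
    time : array of sample times in seconds, strictly increasing on a
        uniform grid with spacing 1/fs.
    raw : raw fluorescence, arbitrary detector units.
    fs : sampling rate in Hz.
    """

    time: np.ndarray
    raw: np.ndarray
    fs: float

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "raw", raw)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if time.ndim != 1 or raw.shape != time.shape:
            raise ValueError("time and raw must be 1-D arrays of equal length")
        if time.size < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(time)
        if np.any(np.abs(dt - 1.0 / self.fs) > _GRID_TOL):
            raise ValueError("time grid is not uniform at the stated sampling rate")
        if not np.all(np.isfinite(raw)):
            raise ValueError("raw fluorescence contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0] + 1.0 / self.fs

    @classmethod
    def from_samples(cls, raw: np.ndarray, fs: float) -> "PhotometryTrace":
        raw = np.asarray(raw, dtype=float)
        return cls(np.arange(raw.size) / fs, raw, fs)


@dataclass(frozen=True)
class BaselineConfig:
    """Sliding-window low-quantile baseline estimation.

    window_fraction : window length as a fraction of the total recording
        (0.25 = a moving window of 25% of the recording).
    stride_fraction : anchor stride as a fraction of the window (0.2 places
        five anchors per window length).
    quantile : the within-window quantile taken as the baseline anchor.  A
        low quantile (0.10) is robust to upward transients.
    interpolation : 'spline' (cubic) or 'linear' interpolation of anchors
        onto the full sample grid.
    """

    window_fraction: float = 0.25
    stride_fraction: float = 0.2
    quantile: float = 0.10
    band: float = 0.05
    interpolation: str = "spline"

    def __post_init__(self):
        if not (0 < self.window_fraction <= 1):
            raise ValueError("window_fraction must be in (0, 1]")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")
        if not (0 < self.band < 1 - self.quantile):
            raise ValueError("band must be in (0, 1 - quantile)")
        if self.stride_fraction <= 0:
            raise ValueError("stride_fraction must be positive")
        if self.interpolation not in ("spline", "linear"):
            raise ValueError("interpolation must be 'spline' or 'linear'")


@dataclass(frozen=True)
class DffTrace:
    """Baseline-corrected fractional fluorescence (dimensionless)."""

    time: np.ndarray
    dff: np.ndarray
    fs: float


@dataclass(frozen=True)
class FzTrace:
    """Whole-trace z-score of dF/F.

    ``zero_level`` is the Fz value that corresponds to dF/F = 0, i.e. the
    quiescent floor of the trace after z-scoring (z-scoring centres the
    whole trace at 0, so periods without transients sit below 0).  It is
    carried along so decay metrics can reference the true floor.
    """

    time: np.ndarray
    fz: np.ndarray
    fs: float
    zero_level: Optional[float] = None


def estimate_baseline(trace: PhotometryTrace, cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Estimate the slow instantaneous baseline of a raw trace.

    A window of ``window_fraction`` of the recording slides along the trace
    at a stride of ``stride_fraction`` of the window.  In each window the
    samples lying between the ``quantile`` and ``quantile + band``
    within-window quantiles form a low-amplitude band; their mean value
    *and mean time* give one anchor.  On transient-free signals these
    anchors lie on the drift curve (a low band excludes upward calcium
    transients, and averaging the band suppresses sample noise), and the
    anchors are interpolated back onto the full sample grid.  Edge windows
    are truncated rather than padded.
    """
    raw = trace.raw
    n = raw.size
    w = int(round(cfg.window_fraction * n))
    if w > n:
        raise ValueError("baseline window is longer than the trace")
    w = max(w, 2)
    stride = max(int(round(cfg.stride_fraction * w)), 1)

    centers = list(range(0, n, stride))
    if centers[-1] != n - 1:
        centers.append(n - 1)

    anchor_pos: list[float] = []
    anchor_val: list[float] = []
    half = w // 2
    for c in centers:
        lo = max(0, c - half)
        hi = min(n, c + (w - half))  # truncated at the edges, no padding
        seg = raw[lo:hi]
        k0 = int(round(cfg.quantile * (seg.size - 1)))
        k1 = max(int(round((cfg.quantile + cfg.band) * (seg.size - 1))), k0 + 1)
        band = np.argpartition(seg, [k0, k1])[k0 : k1 + 1]
        anchor_pos.append(lo + float(np.mean(band)))
        anchor_val.append(float(np.mean(seg[band])))

    anchor_pos = np.asarray(anchor_pos)
    anchor_val = np.asarray(anchor_val)
    order = np.argsort(anchor_pos, kind="stable")
    anchor_pos, anchor_val = anchor_pos[order], anchor_val[order]

    # merge anchors closer than half a stride: near-coincident anchors with
    # slightly different values would make the spline oscillate
    merged_pos, merged_val = [anchor_pos[0]], [anchor_val[0]]
    counts = [1]
    for p, v in zip(anchor_pos[1:], anchor_val[1:]):
        if p - merged_pos[-1] < stride / 2:
            c = counts[-1]
            merged_pos[-1] = (merged_pos[-1] * c + p) / (c + 1)
            merged_val[-1] = (merged_val[-1] * c + v) / (c + 1)
            counts[-1] = c + 1
        else:
            merged_pos.append(p)
            merged_val.append(v)
            counts.append(1)
    anchor_pos = np.asarray(merged_pos)
    anchor_val = np.asarray(merged_val)

    x = np.arange(n, dtype=float)
    if anchor_pos.size == 1:
        return np.full(n, anchor_val[0])
    if cfg.interpolation == "spline" and anchor_pos.size >= 4:
        spline = CubicSpline(anchor_pos, anchor_val)
        out = spline(np.clip(x, anchor_pos[0], anchor_pos[-1]))
        # linear extension beyond the anchor range (cubic extrapolation of
        # noisy anchors diverges)
        left = x < anchor_pos[0]
        right = x > anchor_pos[-1]
        if left.any():
            slope = float(spline(anchor_pos[0], 1))
            out[left] = anchor_val[0] + slope * (x[left] - anchor_pos[0])
        if right.any():
            slope = float(spline(anchor_pos[-1], 1))
            out[right] = anchor_val[-1] + slope * (x[right] - anchor_pos[-1])
        return out
    return np.interp(x, anchor_pos, anchor_val)


def compute_dff(trace: PhotometryTrace, baseline: np.ndarray) -> DffTrace:
    """(F_raw - F_baseline) / F_baseline, elementwise."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != trace.raw.shape:
        raise ValueError("baseline must be on the same grid as the trace")
    bad = np.nonzero(baseline <= 0)[0]
    if bad.size:
        raise ValueError(
            f"baseline must be strictly positive; first offending sample index {bad[0]}"
        )
    dff = (trace.raw - baseline) / baseline
    return DffTrace(trace.time, dff, trace.fs)


def zscore_trace(dff: DffTrace) -> FzTrace:
    """Whole-trace z-score of dF/F with the sample-SD (n-1) convention."""
    x = np.asarray(dff.dff, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("dF/F has zero variance; z-score is undefined")
    fz = (x - mean) / sd
    return FzTrace(dff.time, fz, dff.fs, zero_level=(0.0 - mean) / sd)


def preprocess(
    trace: PhotometryTrace, cfg: BaselineConfig = BaselineConfig()
) -> tuple[np.ndarray, DffTrace, FzTrace]:
    """Full normalization chain: baseline -> dF/F -> Fz."""
    baseline = estimate_baseline(trace, cfg)
    dff = compute_dff(trace, baseline)
    return baseline, dff, zscore_trace(dff)
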