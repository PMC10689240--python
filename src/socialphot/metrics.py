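"""Event-aligned response metrics on z-scored photometry traces.

All quantities are in Fz units (whole-trace z-score of dF/F).  The
peri-event time histogram (PETH) averages trial snippets aligned to bout
onsets or offsets, hierarchically: trials -> per-animal mean -> grand mean
+- s.e.m. across animals.  Pointwise significance is a per-bin one-sample
t-test against Fz = 0 with Benjamini-Hochberg FDR control across bins,
flagging only significantly *increased* bins.  Per-trial response
detection normalizes each trial by its value at time 0 and asks whether it
reaches Z >= 1 (threshold configurable), yielding the percent of
responsive trials and the latency to respond.  The preference index (PI)
contrasts one stimulus's response against the mean of the other two,
bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import BoutTable
from .photometry import FzTrace

__all__ = [
    "PETHResult",
    "StatsConfig",
    "TrialResponseSet",
    "PreferenceIndex",
    "compute_peth",
    "decay_time",
    "introduction_peak",
    "presentation_peak",
    "behavior_mean_fz",
    "session_mean_fz",
    "trial_responses",
    "percent_responsive",
    "preference_index",
    "pointwise_onesample_fdr",
    "bh_fdr",
]


@dataclass(frozen=True)
class StatsConfig:
    """Pointwise-test configuration: one-sample t vs 0 at FDR level q."""

    q: float = 0.05

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")


@dataclass
class PETHResult:
    """Trial-aligned average response.

    time : bin centers, seconds relative to the alignment event
        (negative = before).
    trials : list (one entry per animal) of (n_trials, n_bins) matrices.
    animal_means : (n_animals, n_bins).
    mean, sem : grand mean and s.e.m. across animals.
    sig_mask : optional per-bin significance (filled by
        :func:`pointwise_onesample_fdr`).
    """

    time: np.ndarray
    trials: list
    animal_means: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    align: str
    sig_mask: Optional[np.ndarray] = None

    @property
    def empty(self) -> bool:
        return self.animal_means.size == 0

    @property
    def n_animals(self) -> int:
        return self.animal_means.shape[0] if self.animal_means.size else 0

    @property
    def n_trials(self) -> int:
        return sum(m.shape[0] for m in self.trials)


def _bin_trials(
    fz: FzTrace, events: np.ndarray, window_pre: float, window_post: float, bin_width: float
) -> np.ndarray:
    """Bin-average Fz snippets around each event onto a common grid."""
    n_bins = int(round((window_pre + window_post) / bin_width))
    out = np.full((events.size, n_bins), np.nan)
    t = fz.time
    for k, ev in enumerate(events):
        rel = t - ev
        sel = (rel >= -window_pre) & (rel < window_post)
        if not sel.any():
            continue
        idx = np.floor((rel[sel] + window_pre) / bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        sums = np.bincount(idx, weights=fz.fz[sel], minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            out[k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def compute_peth(
    sessions,
    behavior: Optional[str] = "investigation",
    stimulus: Optional[str] = None,
    align: str = "onset",
    window_pre: float = 10.0,
    window_post: float = 20.0,
    bin_width: float = 0.2,
) -> PETHResult:
    """PETH of Fz aligned to bout onsets or offsets.

    ``sessions`` is one ``(FzTrace, BoutTable)`` pair or a list of pairs
    (one per animal).  Trials keep their raw Fz values (no per-trial
    renormalization); the hierarchy is trials -> animal mean -> grand
    mean/sem across animals.  A request matching no bouts yields an
    empty-flagged result, not an exception.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    if isinstance(sessions, tuple) and len(sessions) == 2 and isinstance(sessions[0], FzTrace):
        sessions = [sessions]

    n_bins = int(round((window_pre + window_post) / bin_width))
    centers = -window_pre + (np.arange(n_bins) + 0.5) * bin_width

    per_animal_trials, animal_means = [], []
    for fz, bouts in sessions:
        sel = bouts.select(stimulus=stimulus, behavior=behavior)
        col = "onset_s" if align == "onset" else "offset_s"
        events = sel.df[col].to_numpy()
        if events.size == 0:
            continue
        mat = _bin_trials(fz, events, window_pre, window_post, bin_width)
        per_animal_trials.append(mat)
        with np.errstate(invalid="ignore"):
            animal_means.append(np.nanmean(mat, axis=0))

    if not animal_means:
        return PETHResult(centers, [], np.empty((0, n_bins)), np.full(n_bins, np.nan),
                          np.full(n_bins, np.nan), align)

    am = np.vstack(animal_means)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(am, axis=0)
        n_valid = np.sum(~np.isnan(am), axis=0)
        sd = np.nanstd(am, axis=0, ddof=1) if am.shape[0] > 1 else np.zeros(n_bins)
    sem = np.where(n_valid > 0, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return PETHResult(centers, per_animal_trials, am, mean, sem, align)


def decay_time(
    peth: PETHResult, fraction: float = 0.1, asymptote: float = 0.0
) -> float:
    """Time after the alignment event for the grand-mean PETH to fall below
    ``fraction`` of its value at time 0, both measured relative to
    ``asymptote`` (the quiescent Fz floor; pass ``FzTrace.zero_level`` when
    the trace's floor is below 0 after whole-trace z-scoring).

    Returns NaN when the curve never reaches the target inside the window.
    Linear interpolation between bins gives sub-bin resolution.
    """
    post = peth.time >= 0
    t = peth.time[post]
    y = peth.mean[post]
    if t.size == 0 or np.isnan(y[0]):
        return float("nan")
    v0 = y[0] - asymptote
    target = asymptote + fraction * v0
    below = np.nonzero(y <= target)[0]
    below = below[below > 0]
    if below.size == 0:
        return float("nan")
    i = below[0]
    # linear interpolation of the crossing between bins i-1 and i
    y0, y1 = y[i - 1], y[i]
    frac = 0.0 if y1 == y0 else (y0 - target) / (y0 - y1)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def introduction_peak(fz: FzTrace, intro_time: float, window: float = 100.0) -> float:
    """Maximum Fz during the first ``window`` seconds after stimulus
    introduction (truncated at the end of the trace)."""
    if not (fz.time[0] <= intro_time <= fz.time[-1]):
        raise ValueError("intro_time lies outside the trace")
    sel = (fz.time >= intro_time) & (fz.time < intro_time + window)
    return float(np.max(fz.fz[sel]))


def presentation_peak(fz: FzTrace, presentations: BoutTable) -> float:
    """Mean over presentations of the maximum Fz within each presentation."""
    if len(presentations) == 0:
        raise ValueError("no presentation bouts")
    peaks = []
    for row in presentations.df.itertuples(index=False):
        sel = (fz.time >= row.onset_s) & (fz.time < row.offset_s)
        if not sel.any():
            raise ValueError(f"presentation at {row.onset_s} s has no samples")
        peaks.append(np.max(fz.fz[sel]))
    return float(np.mean(peaks))


def behavior_mean_fz(
    fz: FzTrace, bouts: BoutTable, behavior: str = "investigation",
    stimulus: Optional[str] = None,
) -> float:
    """Bout-weighted mean Fz during a behavior: per-bout mean first, then
    the mean across bouts (each bout counts equally regardless of length)."""
    sel = bouts.select(stimulus=stimulus, behavior=behavior)
    if len(sel) == 0:
        raise ValueError(f"no {behavior!r} bouts" + (f" toward {stimulus!r}" if stimulus else ""))
    means = []
    for row in sel.df.itertuples(index=False):
        mask = (fz.time >= row.onset_s) & (fz.time < row.offset_s)
        if mask.any():
            means.append(np.mean(fz.fz[mask]))
    if not means:
        raise ValueError("no samples within any bout")
    return float(np.mean(means))


def session_mean_fz(fz: FzTrace, window: tuple[float, float]) -> float:
    """Mean Fz over the whole intruder-presence window [t0, t1)."""
    t0, t1 = window
    mask = (fz.time >= t0) & (fz.time < t1)
    if not mask.any():
        raise ValueError("session window contains no samples")
    return float(np.mean(fz.fz[mask]))


@dataclass(frozen=True)
class TrialResponseSet:
    """Per-trial normalized responses and session summaries.

    ``trials`` has one row per bout: onset_s, offset_s, peak (max of the
    time-0-normalized trace), responded, latency_s (NaN when not
    responded).  ``traces`` holds the normalized per-trial traces
    (rel_time, n) for heat-map display.
    """

    trials: pd.DataFrame
    traces: list
    percent_responsive: float
    mean_latency_s: float
    mean_bout_duration_s: float
    n_trials: int
    n_skipped: int
    threshold: float


def trial_responses(
    fz: FzTrace,
    bouts: BoutTable,
    behavior: str = "investigation",
    stimulus: Optional[str] = None,
    threshold: float = 1.0,
) -> TrialResponseSet:
    """Detect per-trial responses: Z >= threshold of the normalized trace.

    Each trial's trace is normalized by subtracting the Fz at time 0 (the
    mean of the two samples straddling the bout onset) and evaluated from
    onset to bout offset.  Responded iff the normalized trace reaches the
    threshold; latency is the first crossing time minus onset.
    """
    sel = bouts.select(stimulus=stimulus, behavior=behavior)
    dt = 1.0 / fz.fs
    rows, traces, skipped = [], [], 0
    for row in sel.df.itertuples(index=False):
        mask = (fz.time >= row.onset_s) & (fz.time < row.offset_s)
        if not mask.any():
            skipped += 1
            continue
        pos = (row.onset_s - fz.time[0]) * fz.fs
        i0 = int(np.clip(np.floor(pos), 0, fz.fz.size - 1))
        i1 = min(i0 + 1, fz.fz.size - 1)
        f0 = 0.5 * (fz.fz[i0] + fz.fz[i1])
        n_trace = fz.fz[mask] - f0
        rel = fz.time[mask] - row.onset_s
        crossing = np.nonzero(n_trace >= threshold)[0]
        responded = crossing.size > 0
        latency = float(rel[crossing[0]]) if responded else float("nan")
        rows.append(
            dict(onset_s=row.onset_s, offset_s=row.offset_s,
                 peak=float(np.max(n_trace)), responded=responded, latency_s=latency)
        )
        traces.append((rel, n_trace))
    trials = pd.DataFrame(rows, columns=["onset_s", "offset_s", "peak", "responded", "latency_s"])
    n = len(trials)
    pct = 100.0 * trials["responded"].sum() / n if n else float("nan")
    lat = float(trials.loc[trials["responded"], "latency_s"].mean()) if n else float("nan")
    dur = float((trials["offset_s"] - trials["onset_s"]).mean()) if n else float("nan")
    return TrialResponseSet(trials, traces, pct, lat, dur, n, skipped, threshold)


def percent_responsive(sets: Sequence[TrialResponseSet], mode: str = "pooled") -> float:
    """Percent of responsive trials across sessions.

    'pooled' counts all trials together (default); 'per_animal' averages
    each session's own percentage.
    """
    if mode == "pooled":
        n = sum(s.n_trials for s in sets)
        hits = sum(int(s.trials["responded"].sum()) for s in sets)
        return 100.0 * hits / n if n else float("nan")
    if mode == "per_animal":
        return float(np.mean([s.percent_responsive for s in sets]))
    raise ValueError("mode must be 'pooled' or 'per_animal'")


@dataclass(frozen=True)
class PreferenceIndex:
    """Contrast of one stimulus's response against the mean of the other two,
    in [-1, 1]; undefined (pi is NaN) when the denominator vanishes."""

    target: str
    pi: float
    defined: bool


def preference_index(summary: Mapping[str, float], target: str) -> PreferenceIndex:
    """PI_target = (Z_t - 0.5*(Z_a + Z_b)) / (|Z_t| + 0.5*|Z_a + Z_b|)
    where a, b are the two non-target social stimuli."""
    needed = {"male", "female", "pup"}
    missing = needed - set(summary)
    if missing:
        raise ValueError(f"summary is missing stimuli: {sorted(missing)}")
    if target not in needed:
        raise ValueError(f"target must be one of {sorted(needed)}")
    others = sorted(needed - {target})
    z_t = summary[target]
    z_o = summary[others[0]] + summary[others[1]]
    den = abs(z_t) + 0.5 * abs(z_o)
    if den == 0:
        return PreferenceIndex(target, float("nan"), False)
    return PreferenceIndex(target, (z_t - 0.5 * z_o) / den, True)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns the rejected indices.

    Rejects all hypotheses with rank <= k* on the sorted p-values, where
    k* = max{k : p_(k) <= k*q/m}.  Equal p-values share the same fate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return np.nonzero(reject)[0]


def pointwise_onesample_fdr(
    animal_means: np.ndarray, cfg: StatsConfig = StatsConfig()
) -> np.ndarray:
    """Per-bin one-sample t-test vs Fz = 0, BH-corrected across bins.

    ``animal_means`` is (n_animals, n_bins).  Returns a boolean mask, True
    where q < cfg.q *and* the group mean is positive (only significantly
    increased responses are flagged).  Bins with zero variance get p = 1
    when the mean is 0 (no evidence) and p = 0 when it is nonzero.
    """
    x = np.asarray(animal_means, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two animals")
    n = np.sum(~np.isnan(x), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
    p = np.ones(x.shape[1])
    ok = (n >= 2) & (sd > 0)
    tvals = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    p[ok] = 2.0 * stats.t.sf(np.abs(tvals), df=n[ok] - 1)
    degenerate = (n >= 2) & (sd == 0) & (mean != 0)
    p[degenerate] = 0.0
    rejected = bh_fdr(p, cfg.q)
    mask = np.zeros(x.shape[1], dtype=bool)
    mask[rejected] = True
    return mask & (mean > 0)
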