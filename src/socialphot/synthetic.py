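"""Synthetic sessions with known ground truth for every pipeline stage.

The generator emulates the two recording paradigms of the study design it
models: a head-fixed paradigm in which each stimulus (male, female, pup,
object) is presented five times for 10 s with a 40-s interval and at least
5 min between stimuli, and a freely-moving resident-intruder paradigm in
which each stimulus is present for minutes and the subject investigates it
in bouts.  Calcium transients follow a saturating-rise / exponential-decay
kernel whose offset time constant distinguishes the two cell classes being
emulated: a male-tuned, slow-offset class (tau_off = 12 s, so activity
returns to 10% of its plateau only after tau_off*ln(10) ~ 28 s) and a
broadly social, fast-offset class (tau_off = 1.2 s, 10%-return in under
3 s).  Raw fluorescence is multiplicative bleaching drift times
(1 + transient) plus i.i.d. Gaussian noise.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .behavior import BoutTable
from .circuit import RegionQuantTable
from .ephys import CONDITIONS, PSCSweepSet
from .photometry import PhotometryTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_photometry_session",
    "simulate_count_table",
    "simulate_psc_sweeps",
]

_DEFAULT_AMPLITUDE = {"male": 0.10, "female": 0.0, "pup": 0.0, "object": 0.0}
_DEFAULT_PROB = {"male": 0.9, "female": 0.9, "pup": 0.9, "object": 0.9}
_DEFAULT_PRESENCE = {"male": 600.0, "female": 600.0, "pup": 300.0, "object": 300.0}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated photometry session.

    Amplitudes ``amplitude[s]`` are transient plateau heights in dF/F
    units; ``response_prob[s]`` is the per-bout probability that a bout of
    stimulus ``s`` evokes a transient.  ``tau_r``/``tau_off`` are the rise
    and offset-decay time constants of the kernel in seconds.  Bleaching is
    multiplicative: drift(t) = 1 - A*(1 - exp(-t/tau_bleach)).
    """

    seed: int = 0
    fs: float = 25.0
    paradigm: str = "head_fixed"
    stimuli: tuple = ("male", "female", "pup", "object")
    amplitude: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE))
    response_prob: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PROB))
    tau_r: float = 0.2
    tau_off: float = 12.0
    bleach_amplitude: float = 0.2
    bleach_tau: Optional[float] = None  # defaults to the session length
    noise_sd: float = 0.5  # raw units; f0 = 100 -> ~0.5% dF/F noise
    f0: float = 100.0
    session_length: Optional[float] = None  # computed from the schedule if None
    # head-fixed schedule ("presented five times for 10 s with a 40-s interval")
    n_presentations: int = 5
    presentation_s: float = 10.0
    interval_s: float = 40.0
    block_gap_s: float = 300.0
    lead_in_s: float = 60.0
    tail_s: float = 40.0
    # freely-moving bout structure
    presence_s: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PRESENCE))
    stimulus_gap_s: float = 300.0
    mean_bout_s: float = 4.0
    mean_gap_bout_s: float = 6.0
    min_bout_s: float = 0.5
    max_bout_s: float = 30.0
    attack_prob: float = 0.0  # P(attack follows a male investigation bout)
    attack_gap_s: float = 0.3
    session_id: str = "sim"

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.tau_r <= 0 or self.tau_off <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.paradigm not in ("head_fixed", "freely_moving"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        for s in self.stimuli:
            p = self.response_prob.get(s, 0.0)
            if not (0 <= p <= 1):
                raise ValueError(f"response_prob[{s!r}] must be in [0, 1]")
        if not (0 <= self.attack_prob <= 1):
            raise ValueError("attack_prob must be in [0, 1]")

    @classmethod
    def foxp2_like(cls, paradigm: str = "head_fixed", **overrides) -> "SimConfig":
        """Male-tuned, slow-offset profile (10%-return time > 10 s)."""
        base = dict(
            paradigm=paradigm,
            amplitude={"male": 0.10, "female": 0.0, "pup": 0.0, "object": 0.0},
            tau_off=12.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def dbx1_like(cls, paradigm: str = "head_fixed", **overrides) -> "SimConfig":
        """Broadly social, fast-offset profile (10%-return time < 3 s)."""
        base = dict(
            paradigm=paradigm,
            amplitude={"male": 0.08, "female": 0.10, "pup": 0.08, "object": 0.0},
            tau_off=1.2,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, paradigm: str = "freely_moving", **overrides) -> "SimConfig":
        """Zero-amplitude control: drift and noise only."""
        base = dict(
            paradigm=paradigm,
            amplitude={"male": 0.0, "female": 0.0, "pup": 0.0, "object": 0.0},
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class GroundTruth:
    """Latents behind one simulated session.

    ``responded`` is aligned row-for-row with the bout table: True where a
    transient was actually injected for that bout.  ``baseline`` is the
    true drift in raw units; ``transient`` the latent dF/F transient trace.
    """

    baseline: np.ndarray
    transient: np.ndarray
    responded: np.ndarray
    intro_times: dict
    config: SimConfig


def _head_fixed_schedule(cfg: SimConfig) -> list[tuple]:
    rows, t = [], cfg.lead_in_s
    for stim in cfg.stimuli:
        for _ in range(cfg.n_presentations):
            rows.append((cfg.session_id, stim, "introduction", t, t + cfg.presentation_s))
            t += cfg.presentation_s + cfg.interval_s
        t += cfg.block_gap_s - cfg.interval_s  # >= 5 min between stimuli
    return rows


def _freely_moving_schedule(cfg: SimConfig, rng: np.random.Generator) -> list[tuple]:
    rows, t = [], cfg.lead_in_s
    for stim in cfg.stimuli:
        presence = cfg.presence_s.get(stim, 300.0)
        end = t + presence
        rows.append((cfg.session_id, stim, "introduction", t, end))
        cursor = t + 1.0 + rng.exponential(1.0)  # first approach shortly after intro
        while True:
            dur = float(np.clip(rng.exponential(cfg.mean_bout_s), cfg.min_bout_s, cfg.max_bout_s))
            if cursor + dur > end:
                break
            rows.append((cfg.session_id, stim, "investigation", cursor, cursor + dur))
            bout_end = cursor + dur
            if stim == "male" and rng.random() < cfg.attack_prob:
                atk_on = bout_end + cfg.attack_gap_s
                atk_dur = float(np.clip(rng.exponential(2.0), 0.5, 5.0))
                if atk_on + atk_dur <= end:
                    rows.append((cfg.session_id, stim, "attack", atk_on, atk_on + atk_dur))
                    bout_end = atk_on + atk_dur
            cursor = bout_end + cfg.mean_gap_bout_s / 4 + rng.exponential(cfg.mean_gap_bout_s)
        t = end + cfg.stimulus_gap_s
    return rows


def _add_transient(
    transient: np.ndarray, fs: float, onset: float, offset: float, amp: float,
    tau_r: float, tau_off: float,
) -> None:
    """Saturating rise during the bout, exponential decay after its offset."""
    n = transient.size
    i0 = int(np.ceil(onset * fs))
    i1 = min(int(np.ceil(offset * fs)), n)
    if i1 > i0:
        t = np.arange(i0, i1) / fs
        transient[i0:i1] += amp * (1.0 - np.exp(-(t - onset) / tau_r))
    plateau = amp * (1.0 - np.exp(-max(offset - onset, 0.0) / tau_r))
    i2 = min(int(np.ceil((offset + 10.0 * tau_off) * fs)), n)
    if i2 > i1:
        t = np.arange(i1, i2) / fs
        transient[i1:i2] += plateau * np.exp(-(t - offset) / tau_off)


def simulate_photometry_session(
    config: SimConfig,
) -> tuple[PhotometryTrace, BoutTable, GroundTruth]:
    """Generate one session: raw trace, bout table and ground truth.

    Raw fluorescence is ``f0 * drift(t) * (1 + transient(t)) + noise``.
    Transients are injected per bout with probability ``response_prob`` of
    the bout's stimulus; ``introduction`` rows in the freely-moving
    paradigm mark stimulus presence windows and do not themselves drive
    transients (the first investigation bout carries the introduction
    response).
    """
    rng = np.random.default_rng(config.seed)
    if config.paradigm == "head_fixed":
        rows = _head_fixed_schedule(config)
    else:
        rows = _freely_moving_schedule(config, rng)

    last_off = max(r[4] for r in rows)
    needed = last_off + config.tail_s
    if config.session_length is None:
        length = needed
    else:
        if config.session_length < needed:
            raise ValueError(
                f"schedule ends at {needed:.1f} s but session_length is "
                f"{config.session_length:.1f} s"
            )
        length = config.session_length

    n = int(round(length * config.fs))
    t = np.arange(n) / config.fs

    bouts = BoutTable(pd.DataFrame(
        rows, columns=["session", "stimulus", "behavior", "onset_s", "offset_s"]
    ))

    driving = (
        (bouts.df["behavior"] != "introduction")
        if config.paradigm == "freely_moving"
        else pd.Series(True, index=bouts.df.index)
    )
    transient = np.zeros(n)
    responded = np.zeros(len(bouts), dtype=bool)
    for i, row in enumerate(bouts.df.itertuples(index=False)):
        if not driving.iloc[i]:
            continue
        amp = config.amplitude.get(row.stimulus, 0.0)
        hit = rng.random() < config.response_prob.get(row.stimulus, 0.0)
        responded[i] = hit and amp > 0
        if responded[i]:
            _add_transient(
                transient, config.fs, row.onset_s, row.offset_s, amp,
                config.tau_r, config.tau_off,
            )

    tau_b = config.bleach_tau if config.bleach_tau is not None else length
    drift = 1.0 - config.bleach_amplitude * (1.0 - np.exp(-t / tau_b))
    baseline = config.f0 * drift
    raw = baseline * (1.0 + transient) + config.noise_sd * rng.standard_normal(n)

    intro = {
        stim: float(bouts.df.loc[bouts.df["stimulus"] == stim, "onset_s"].min())
        for stim in config.stimuli
    }
    trace = PhotometryTrace(t, raw, config.fs)
    truth = GroundTruth(baseline, transient, responded, intro, config)
    return trace, bouts, truth


def simulate_count_table(
    fractions: Mapping[str, float],
    n_cells: int,
    starter_in: int = 80,
    starter_out: int = 20,
    tracer: str = "rabies",
    animal_id: str = "sim",
    seed: int = 0,
) -> tuple[RegionQuantTable, dict]:
    """Multinomial draw of ``n_cells`` input cells over regions.

    ``fractions`` are the true per-region input probabilities and must sum
    to 1 (within 1e-9).
    """
    probs = np.array(list(fractions.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {probs.sum()!r}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, probs)
    df = pd.DataFrame({"region": list(fractions.keys()), "count": counts})
    table = RegionQuantTable(
        df, animal_id=animal_id, tracer=tracer,
        starter_in=starter_in, starter_out=starter_out,
    )
    return table, {"fractions": dict(fractions), "n_cells": n_cells}


def simulate_psc_sweeps(
    latency_ms: float,
    amplitude_pa: float,
    holding_mv: float = -70,
    connection: str = "monosynaptic",
    fs: float = 20_000.0,
    sweep_ms: float = 200.0,
    light_onset_ms: float = 60.0,
    n_sweeps: int = 10,
    noise_sd_pa: float = 2.0,
    tau_ms: float = 2.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Simulate one cell's sweep sets across the pharmacology sequence.

    Each sweep is baseline noise plus an alpha-shaped PSC starting at
    ``light_onset + latency``; the PSC is inward (negative) at -70 mV and
    outward (positive) at 0 mV.  Condition scaling encodes the connection
    class: monosynaptic responses are abolished by TTX and recovered under
    TTX + 4-AP; polysynaptic responses are not recovered; 'none' cells have
    no response in any condition.
    """
    if latency_ms <= 0:
        raise ValueError("true latency must be positive")
    if connection not in ("monosynaptic", "polysynaptic", "none"):
        raise ValueError(f"unknown connection class {connection!r}")
    scale = {
        "monosynaptic": {"ACSF": 1.0, "TTX": 0.0, "TTX+4AP": 0.8},
        "polysynaptic": {"ACSF": 1.0, "TTX": 0.0, "TTX+4AP": 0.0},
        "none": {"ACSF": 0.0, "TTX": 0.0, "TTX+4AP": 0.0},
    }[connection]

    rng = np.random.default_rng(seed)
    n = int(round(sweep_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    sign = -1.0 if holding_mv == -70 else 1.0
    onset = light_onset_ms + latency_ms
    rel = t - onset
    alpha = np.where(rel >= 0, (rel / tau_ms) * np.exp(1.0 - rel / tau_ms), 0.0)

    out = {}
    for cond in CONDITIONS:
        psc = sign * amplitude_pa * scale[cond] * alpha
        sweeps = psc[:, None] + noise_sd_pa * rng.standard_normal((n, n_sweeps))
        out[cond] = PSCSweepSet(
            t, sweeps, fs, light_onset_ms, float(holding_mv), condition=cond
        )
    truth = {
        "latency_ms": latency_ms,
        "amplitude_pa": amplitude_pa,
        "connection": connection,
    }
    return out, truth
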