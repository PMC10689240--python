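"""Behavior bout tables, label merge rules, and body-tracking velocity.

Bouts are manually annotated behavior episodes (investigation, attack,
mount, ...) toward a stimulus animal, stored as half-open intervals
``[onset_s, offset_s)`` in seconds from session start.  For photometry
analysis, grooming of the stimulus is folded into investigation, and the
male-directed investigation bouts can be partitioned by whether an attack
follows within a short gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STIMULI",
    "BEHAVIORS",
    "BoutTable",
    "TrackSeries",
    "load_bouts",
    "merge_labels",
    "split_investigations_by_attack",
    "compute_velocity",
]

STIMULI = frozenset({"male", "female", "pup", "object"})
BEHAVIORS = frozenset(
    {
        "investigation",
        "groom",
        "attack",
        "mount",
        "intromission",
        "ejaculation",
        "infanticide",
        "introduction",
    }
)

REQUIRED_COLUMNS = ["session", "stimulus", "behavior", "onset_s", "offset_s"]

#: same-label bouts separated by less than one 25-Hz annotation frame are
#: treated as one bout (frame-quantization artifact of manual scoring)
COALESCE_TOL_S = 1.0 / 25.0


@dataclass(frozen=True)
class BoutTable:
    """Validated table of behavior bouts for one or more sessions."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        object.__setattr__(self, "df", df)
        _validate(df)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, stimulus: str | None = None, behavior: str | None = None) -> "BoutTable":
        df = self.df
        if stimulus is not None:
            df = df[df["stimulus"] == stimulus]
        if behavior is not None:
            df = df[df["behavior"] == behavior]
        return BoutTable(df.reset_index(drop=True))

    def durations(self) -> np.ndarray:
        return (self.df["offset_s"] - self.df["onset_s"]).to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records) -> "BoutTable":
        return cls(pd.DataFrame(records, columns=REQUIRED_COLUMNS))


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bout table is missing required columns: {missing}")
    bad_stim = df.loc[~df["stimulus"].isin(STIMULI)]
    if len(bad_stim):
        row = bad_stim.index[0]
        raise ValueError(
            f"unknown stimulus {bad_stim['stimulus'].iloc[0]!r} at row {row}"
        )
    bad_lab = df.loc[~df["behavior"].isin(BEHAVIORS)]
    if len(bad_lab):
        row = bad_lab.index[0]
        raise ValueError(
            f"unknown behavior label {bad_lab['behavior'].iloc[0]!r} at row {row}"
        )
    bad_dur = df.loc[df["offset_s"] <= df["onset_s"]]
    if len(bad_dur):
        row = bad_dur.index[0]
        raise ValueError(f"bout with offset <= onset at row {row}")
    # same-label bouts must be non-overlapping within a session
    for (sess, stim, lab), grp in df.groupby(["session", "stimulus", "behavior"]):
        grp = grp.sort_values("onset_s")
        overlap = grp["onset_s"].to_numpy()[1:] < grp["offset_s"].to_numpy()[:-1]
        if overlap.any():
            row = grp.index[1:][overlap][0]
            raise ValueError(
                f"overlapping {lab!r} bouts in session {sess!r} ({stim}) at row {row}"
            )


def load_bouts(path) -> BoutTable:
    """Read and validate a bout CSV (session, stimulus, behavior, onset_s, offset_s)."""
    df = pd.read_csv(path)
    return BoutTable(df)


def merge_labels(bouts: BoutTable, tol: float = COALESCE_TOL_S) -> BoutTable:
    """Fold groom into investigation and coalesce abutting same-label bouts.

    Grooming of any stimulus is relabeled ``investigation`` (per stimulus,
    so pup groom becomes pup investigation).  After relabeling, same-label
    bouts that overlap or abut within ``tol`` seconds are merged into one
    bout spanning min onset to max offset.
    """
    df = bouts.df.copy()
    df.loc[df["behavior"] == "groom", "behavior"] = "investigation"
    out = []
    for _, grp in df.groupby(["session", "stimulus", "behavior"], sort=False):
        grp = grp.sort_values("onset_s")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = row._asdict()
            elif row.onset_s <= cur["offset_s"] + tol:
                cur["offset_s"] = max(cur["offset_s"], row.offset_s)
            else:
                out.append(cur)
                cur = row._asdict()
        if cur is not None:
            out.append(cur)
    merged = pd.DataFrame(out, columns=df.columns).sort_values(
        ["session", "onset_s"], kind="stable"
    )
    return BoutTable(merged.reset_index(drop=True))


def split_investigations_by_attack(bouts: BoutTable, gap_max: float = 1.0) -> pd.DataFrame:
    """Partition investigation bouts by whether an attack follows.

    An investigation bout is *followed by attack* iff some attack bout
    onset lies in ``(offset, offset + gap_max]`` within the same session.
    Returns the investigation rows with a boolean ``followed_by_attack``
    column; the partition is exhaustive and disjoint.
    """
    if gap_max < 0:
        raise ValueError("gap_max must be non-negative")
    df = bouts.df
    inv = df[df["behavior"] == "investigation"].copy()
    atk = df[df["behavior"] == "attack"]
    flags = []
    for row in inv.itertuples(index=False):
        onsets = atk.loc[atk["session"] == row.session, "onset_s"].to_numpy()
        flags.append(
            bool(np.any((onsets > row.offset_s) & (onsets <= row.offset_s + gap_max)))
        )
    inv["followed_by_attack"] = flags
    return inv.reset_index(drop=True)


@dataclass(frozen=True)
class TrackSeries:
    """Top-view body position track (frame index, x, y in pixels)."""

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = 25.0

    def __post_init__(self):
        frame = np.asarray(self.frame, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("frame", frame), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (frame.shape == x.shape == y.shape):
            raise ValueError("frame, x and y must have equal length")
        if frame.size and np.any(np.diff(frame) != 1):
            raise ValueError("frames must be consecutive")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_csv(cls, path, fps: float = 25.0) -> "TrackSeries":
        df = pd.read_csv(path)
        return cls(df["frame"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), fps)


def compute_velocity(track: TrackSeries, window: float = 300.0) -> float:
    """Mean per-frame Euclidean displacement (pixels/frame) over the first
    ``window`` seconds of the track (default: the 5-min pre-stimulus period)."""
    n = int(round(window * track.fps))
    if n > track.frame.size:
        raise ValueError("window exceeds track duration")
    dx = np.diff(track.x[:n])
    dy = np.diff(track.y[:n])
    if dx.size == 0:
        return 0.0
    return float(np.mean(np.hypot(dx, dy)))
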