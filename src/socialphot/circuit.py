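"""Anatomical circuit quantification.

Covers the count/intensity arithmetic of monosynaptic rabies input mapping
(starter-cell QC, per-region input fractions with region exclusions and a
reporting floor), anterograde projection mapping (background-subtracted
intensity normalized to the brightest region, and region-group intensity
ratios), double-label overlap percentages, and point-to-line distances used
for cell-distribution analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RegionQuantTable",
    "QCRule",
    "RABIES_RULE",
    "ANTEROGRADE_RULE",
    "starter_qc",
    "input_fractions",
    "projection_intensity",
    "projection_ratio",
    "overlap_fractions",
    "point_to_line_distances",
]


@dataclass(frozen=True)
class RegionQuantTable:
    """Per-region counts (rabies) or intensities (anterograde) for one brain.

    ``df`` has a ``region`` column plus either ``count`` or
    ``i_raw``/``i_background``.  Starter-cell totals inside/outside the
    target region live in the metadata fields.
    """

    df: pd.DataFrame
    animal_id: str = "sim"
    tracer: str = "rabies"
    starter_in: int = 0
    starter_out: int = 0

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        object.__setattr__(self, "df", df)
        if "region" not in df.columns:
            raise ValueError("table must have a 'region' column")
        if df["region"].duplicated().any():
            dup = df.loc[df["region"].duplicated(), "region"].iloc[0]
            raise ValueError(f"duplicate region {dup!r}")
        for col in ("count", "i_raw", "i_background"):
            if col in df.columns and (df[col] < 0).any():
                raise ValueError(f"negative values in column {col!r}")
        if self.tracer not in ("rabies", "anterograde"):
            raise ValueError(f"unknown tracer type {self.tracer!r}")


@dataclass(frozen=True)
class QCRule:
    """Inclusion rules for a tracing experiment.

    starter_threshold : minimum fraction of starter cells inside the target
        region; strict inequality ("more than").
    excluded_regions : regions dropped before normalization (too close to
        the injection site to be trusted).
    report_floor : minimum input fraction / normalized intensity for a
        region to appear in the reported subset.
    always_report : regions reported regardless of the floor.
    """

    starter_threshold: float = 0.70
    excluded_regions: frozenset = frozenset()
    report_floor: float = 0.02
    always_report: frozenset = frozenset()

    def __post_init__(self):
        if not (0 < self.starter_threshold <= 1):
            raise ValueError("starter_threshold must be in (0, 1]")


RABIES_RULE = QCRule(
    starter_threshold=0.70,
    excluded_regions=frozenset({"LH", "anterior MeA", "AAA"}),
    report_floor=0.02,
)

ANTEROGRADE_RULE = QCRule(
    starter_threshold=0.65,
    excluded_regions=frozenset({"LH", "anterior MeA"}),
    report_floor=0.2,
    always_report=frozenset({"VMHvl"}),
)


def starter_qc(table: RegionQuantTable, rule: QCRule) -> tuple[bool, float]:
    """Starter-cell quality control: pass iff in/(in+out) > threshold."""
    total = table.starter_in + table.starter_out
    if total == 0:
        raise ValueError("no starter cells counted")
    frac = table.starter_in / total
    return frac > rule.starter_threshold, frac


def input_fractions(table: RegionQuantTable, rule: QCRule = RABIES_RULE) -> pd.DataFrame:
    """Per-region fraction of retrogradely labeled input cells.

    Excluded regions are dropped *before* normalization; the remaining
    fractions sum to 1.  The reported subset is fractions above the
    reporting floor (strict).
    """
    df = table.df[~table.df["region"].isin(rule.excluded_regions)].copy()
    if "count" not in df.columns:
        raise ValueError("input_fractions requires a 'count' column")
    total = df["count"].sum()
    if total == 0:
        raise ValueError("all input counts are zero after exclusions")
    df["fraction"] = df["count"] / total
    df["reported"] = df["fraction"] > rule.report_floor
    return df.reset_index(drop=True)


def projection_intensity(
    table: RegionQuantTable, rule: QCRule = ANTEROGRADE_RULE
) -> pd.DataFrame:
    """Background-subtracted projection intensity, normalized to the
    brightest region.

    I_signal = max(I_raw - I_background, 0); I_norm = I_signal / max(I_signal).
    The reported subset is I_norm >= floor plus the always-report set.
    """
    df = table.df[~table.df["region"].isin(rule.excluded_regions)].copy()
    for col in ("i_raw", "i_background"):
        if col not in df.columns:
            raise ValueError(f"projection_intensity requires an {col!r} column")
    df["i_signal"] = np.maximum(df["i_raw"] - df["i_background"], 0.0)
    peak = df["i_signal"].max()
    if peak == 0:
        raise ValueError("all background-subtracted intensities are zero")
    df["i_norm"] = df["i_signal"] / peak
    df["reported"] = (df["i_norm"] >= rule.report_floor) | df["region"].isin(
        rule.always_report
    )
    return df.reset_index(drop=True)


def projection_ratio(
    i_norm: Mapping[str, float],
    numerator: Iterable[str],
    denominator: Iterable[str],
) -> Optional[float]:
    """Summed I_norm over one region group divided by another.

    Returns None (undefined) when the denominator sum is zero.
    """
    num = sum(i_norm[r] for r in numerator)
    den = sum(i_norm[r] for r in denominator)
    if den == 0:
        return None
    return num / den


def overlap_fractions(only_a: int, only_b: int, both: int) -> dict:
    """Double-label overlap percentages from exclusive/shared counts.

    Returns percentages: ``a_in_b`` = share of A+ cells that are also B+,
    ``b_in_a`` symmetric, ``double`` = double-positive share of all labeled
    cells.  Undefined entries (zero denominator) are None.
    """
    if min(only_a, only_b, both) < 0:
        raise ValueError("counts must be non-negative")
    total = only_a + only_b + both
    if total == 0:
        raise ValueError("no labeled cells")

    def pct(n, d):
        return None if d == 0 else 100.0 * n / d

    return {
        "a_in_b": pct(both, only_a + both),
        "b_in_a": pct(both, only_b + both),
        "double": pct(both, total),
    }


def point_to_line_distances(points: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to an infinite line.

    ``points`` is (n, 2); ``line`` is (2, 2): two distinct points defining
    the line (e.g. the optic tract, or the dorsal edge of the MeApd).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p0, p1 = np.asarray(line, dtype=float)
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("line endpoints are coincident")
    # cross product magnitude / |d|
    rel = points - p0
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / norm
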