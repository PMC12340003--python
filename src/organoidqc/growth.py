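"""Longitudinal size monitoring: area time-series and growth profiles.

Organoid size is the projected 2-D area measured from brightfield images at
irregular culture timepoints.  The growth profile is an ordinary
least-squares line (area ~ day); reference sizes are read off at days 10, 30
and 60 from the nearest observation within a matching window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .stats import FriedmanResult, friedman

__all__ = ["GrowthSeries", "GrowthProfile", "fit_growth", "compare_growth"]

#: Default reference days at which sizes are reported.
REFERENCE_DAYS = (10, 30, 60)

#: Nearest-observation matching window around a reference day, in days.
MATCH_WINDOW = 3


@dataclass(frozen=True)
class GrowthSeries:
    """One organoid's (day, area) observations, days strictly increasing."""

    organoid_id: str
    days: tuple[int, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.areas):
            raise ValueError("days and areas differ in length")
        d = np.asarray(self.days)
        if d.size and (np.diff(d) <= 0).any():
            raise ValueError("days must be strictly increasing")
        if d.size and d.min() < 0:
            raise ValueError("days must be >= 0")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be >= 0 um^2")

    def __len__(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class GrowthProfile:
    """Least-squares growth line and reference sizes for one organoid."""

    organoid_id: str
    slope: float  # um^2 / day
    intercept: float  # um^2
    size_at: dict[int, float | None]  # reference day -> area (None if unmatched)


def fit_growth(
    series: GrowthSeries,
    reference_days: Sequence[int] = REFERENCE_DAYS,
    window: int = MATCH_WINDOW,
) -> GrowthProfile:
    """Fit area ~ day by ordinary least squares and extract reference sizes.

    A reference size is the area at the observed day nearest to the reference
    day, provided it lies within ``window`` days; otherwise it is ``None``.
    Requires at least two observations on distinct days.
    """
    if len(series) < 2:
        raise ValueError(f"{series.organoid_id}: need >= 2 observations to fit a slope")
    days = np.asarray(series.days, dtype=float)
    areas = np.asarray(series.areas, dtype=float)
    if np.unique(days).size < 2:
        raise ValueError(f"{series.organoid_id}: all observations on the same day")
    fit = sps.linregress(days, areas)
    size_at: dict[int, float | None] = {}
    for ref in reference_days:
        offsets = np.abs(days - ref)
        i = int(offsets.argmin())
        size_at[int(ref)] = float(areas[i]) if offsets[i] <= window else None
    return GrowthProfile(series.organoid_id, float(fit.slope), float(fit.intercept), size_at)


def compare_growth(*series: GrowthSeries) -> FriedmanResult:
    """Compare growth curves of two or more organoids with a Friedman test.

    Shared observation days act as blocks and organoids as treatments; the
    series must be observed on an identical day grid.
    """
    if len(series) < 2:
        raise ValueError("need at least two series to compare")
    grids = [s.days for s in series]
    common = set(grids[0]).intersection(*map(set, grids[1:]))
    for s in series:
        missing = sorted(set().union(*map(set, grids)) - set(s.days))
        if missing:
            raise ValueError(
                f"{s.organoid_id}: day grid mismatch, missing blocks {missing}"
            )
    days = sorted(common)
    table = np.column_stack(
        [[s.areas[s.days.index(d)] for d in days] for s in series]
    )
    return friedman(table)
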