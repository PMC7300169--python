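"""Candidate measurement times and sampling-schedule enumeration.

The candidate grid holds the clinically feasible imaging times (hours post
injection, p.i.) from which sampling schedules are drawn.  Three schedule
families are enumerated:

* planar schedules — 2 to 4 planar whole-body images picked from the grid;
  4-point schedules must place exactly one or two points within the first
  4 h p.i. (the early uptake phase),
* hybrid schedules — a planar schedule plus one quantitative SPECT/CT
  acquired a fixed 0.5 h after one of the planar images,
* single-time-point schedules — one SPECT/CT only.

Enumeration is exhaustive and deterministic (lexicographic in the planar
times, then in the SPECT anchor), so schedule indices are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence, Union

__all__ = [
    "DEFAULT_GRID_TIMES",
    "SPECT_OFFSET_H",
    "EARLY_CUTOFF_H",
    "TimeGrid",
    "PlanarSchedule",
    "HybridSchedule",
    "SingleTPSchedule",
    "default_grid",
    "enumerate_planar_schedules",
    "attach_spect",
    "enumerate_hybrid_schedules",
    "enumerate_single_tp_schedules",
    "filter_by_last_tp",
]

#: Default candidate times for planar imaging, hours p.i. (24 entries,
#: restricted to working hours over an 8-day span).
DEFAULT_GRID_TIMES: tuple[float, ...] = (
    1, 2, 3, 4, 20, 22, 24, 26, 28, 44, 48, 52, 68, 72, 76, 92, 96, 100,
    116, 120, 124, 144, 168, 192,
)

#: Fixed delay of the SPECT/CT acquisition after its anchoring planar image.
SPECT_OFFSET_H: float = 0.5

#: Upper edge of the "early" window used by the 4-point constraint.
EARLY_CUTOFF_H: float = 4.0


@dataclass(frozen=True)
class TimeGrid:
    """Ordered set of candidate measurement times in hours p.i."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if not times:
            raise ValueError("grid must contain at least one time")
        if times[0] <= 0:
            raise ValueError("grid times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("grid times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[float]:
        return iter(self.times)

    def __contains__(self, t: float) -> bool:
        return float(t) in self.times


@dataclass(frozen=True)
class PlanarSchedule:
    """Subset of grid times at which planar images are acquired."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n_tp(self) -> int:
        return len(self.times)

    @property
    def t_last(self) -> float:
        return self.times[-1]


@dataclass(frozen=True)
class HybridSchedule:
    """Planar schedule plus one SPECT/CT anchored to a planar image.

    The SPECT/CT is acquired ``spect_offset`` hours after the planar image at
    index ``spect_anchor_index``.
    """

    planar: PlanarSchedule
    spect_anchor_index: int
    spect_offset: float = SPECT_OFFSET_H

    def __post_init__(self) -> None:
        if not 0 <= self.spect_anchor_index < self.planar.n_tp:
            raise ValueError(
                f"anchor index {self.spect_anchor_index} out of range for "
                f"{self.planar.n_tp}-point schedule"
            )

    @property
    def t_spect(self) -> float:
        return self.planar.times[self.spect_anchor_index] + self.spect_offset

    @property
    def t_last(self) -> float:
        """Latest planar time (the SPECT offset does not count)."""
        return self.planar.t_last


@dataclass(frozen=True)
class SingleTPSchedule:
    """A single quantitative SPECT/CT measurement at ``t_ref`` hours p.i."""

    t_ref: float

    def __post_init__(self) -> None:
        if self.t_ref <= 0:
            raise ValueError("t_ref must be positive")
        object.__setattr__(self, "t_ref", float(self.t_ref))

    @property
    def t_last(self) -> float:
        return self.t_ref


Schedule = Union[PlanarSchedule, HybridSchedule, SingleTPSchedule]


def default_grid() -> TimeGrid:
    """Return the default 24-point candidate grid (1 … 192 h p.i.)."""
    return TimeGrid(DEFAULT_GRID_TIMES)


def enumerate_planar_schedules(grid: TimeGrid, n_tp: int) -> list[PlanarSchedule]:
    """Enumerate all admissible planar schedules with ``n_tp`` time points.

    For ``n_tp`` in {2, 3} every size-``n_tp`` subset of the grid is admissible.
    For ``n_tp`` = 4 the early-phase constraint applies: exactly one or two of
    the four times must lie at or below 4 h p.i.  Output is in lexicographic
    order of the time tuples.
    """
    if n_tp not in (2, 3, 4):
        raise ValueError(f"n_tp must be 2, 3 or 4, got {n_tp!r}")
    subsets = combinations(grid.times, n_tp)
    if n_tp == 4:
        subsets = (
            s for s in subsets
            if 1 <= sum(1 for t in s if t <= EARLY_CUTOFF_H) <= 2
        )
    return [PlanarSchedule(s) for s in subsets]


def attach_spect(schedule: PlanarSchedule) -> list[HybridSchedule]:
    """Expand a planar schedule into hybrid schedules, one per SPECT anchor."""
    return [
        HybridSchedule(planar=schedule, spect_anchor_index=i)
        for i in range(schedule.n_tp)
    ]


def enumerate_hybrid_schedules(grid: TimeGrid, n_tp: int) -> list[HybridSchedule]:
    """All hybrid schedules with ``n_tp`` planar points (n_tp × planar count)."""
    return [
        h for s in enumerate_planar_schedules(grid, n_tp) for h in attach_spect(s)
    ]


def enumerate_single_tp_schedules(grid: TimeGrid) -> list[SingleTPSchedule]:
    """One single-time-point schedule per grid time."""
    return [SingleTPSchedule(t) for t in grid.times]


def filter_by_last_tp(schedules: Sequence[Schedule], t_last_max: float) -> list[Schedule]:
    """Retain schedules whose latest planar (or reference) time is ≤ the limit.

    For hybrid schedules the limit applies to the planar times; the +0.5 h
    SPECT offset may exceed it, matching how shortened protocols are counted
    clinically (the SPECT follows the final planar visit).
    """
    if t_last_max <= 0:
        raise ValueError("t_last_max must be positive")
    return [s for s in schedules if s.t_last <= t_last_max]
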