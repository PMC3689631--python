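"""Body-water deuterium enrichment: dosing simulation and measured-saliva curves.

The labeling protocol administers 50 mL of 70% 2H2O twice daily, Monday
through Friday, for 16-38 days.  Body-water enrichment is either measured
directly in saliva on tape-strip days (the preferred mode, mirroring the
study design) or forward-simulated with a one-compartment pharmacokinetic
stand-in: each dose instantaneously raises enrichment by
(dose volume x purity) / body-water volume, and enrichment decays
first-order with the water turnover rate between doses.  The quantity the
fractional-synthesis ratio needs is the *time-averaged* enrichment from the
start of labeling to each tape-strip day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, InvalidInputError
from .isotopomers import MAX_PRECURSOR_ENRICHMENT

__all__ = [
    "DoseEvent",
    "DosingSchedule",
    "BodyWaterParams",
    "EnrichmentCurve",
    "build_protocol_schedule",
    "simulate_body_water",
    "interpolate_measured",
    "time_averaged_enrichment",
]

#: Default dose times within a day: 08:00 and 20:00 as day fractions.
DEFAULT_DOSE_TIMES = (1.0 / 3.0, 5.0 / 6.0)
#: Monday-Friday as weekday indices (Monday = 0).
WEEKDAYS_MON_FRI = (0, 1, 2, 3, 4)
#: Grid spacing (days) for simulated curves.
SIMULATION_GRID_STEP = 0.05


@dataclass(frozen=True)
class DoseEvent:
    """One oral 2H2O dose: time (days from study start), volume, isotopic purity."""

    day: float
    volume_ml: float
    purity: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise InvalidInputError("dose volume must be positive")
        if not 0.0 < self.purity <= 1.0:
            raise InvalidInputError("dose purity must lie in (0, 1]")


@dataclass(frozen=True)
class DosingSchedule:
    """Chronologically ordered list of dose events."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.day))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def days(self) -> np.ndarray:
        return np.array([e.day for e in self.events])


@dataclass(frozen=True)
class BodyWaterParams:
    """One-compartment stand-in for body-water kinetics.

    Defaults are textbook adult values: 42 L total body water and a water
    turnover rate of 0.10/day (half-life about a week).
    """

    volume_l: float = 42.0
    turnover_per_day: float = 0.10

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise InvalidInputError("body-water volume must be positive")
        if self.turnover_per_day < 0:
            raise InvalidInputError("water turnover rate must be >= 0")


@dataclass(frozen=True)
class EnrichmentCurve:
    """Body-water 2H enrichment (mole-fraction excess) on a time grid."""

    days: np.ndarray
    values: np.ndarray
    provenance: str = "simulated"  # "simulated" | "measured-interpolated"

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if days.ndim != 1 or days.shape != values.shape or days.size == 0:
            raise InvalidInputError("days and values must be matching 1-D arrays")
        if np.any(np.diff(days) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")
        if np.any(values < -1e-15) or np.any(values > MAX_PRECURSOR_ENRICHMENT):
            raise InvalidInputError(
                f"enrichments must lie in [0, {MAX_PRECURSOR_ENRICHMENT}]"
            )
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", np.clip(values, 0.0, None))

    def value_at(self, t):
        """Enrichment at time ``t`` (linear interpolation, flat extension)."""
        return np.interp(t, self.days, self.values)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])


def build_protocol_schedule(
    duration_days: int,
    dose_volume_ml: float = 50.0,
    purity: float = 0.70,
    doses_per_day: int = 2,
    weekday_pattern: Sequence[int] = WEEKDAYS_MON_FRI,
    start_day: float = 0.0,
    start_weekday: int = 0,
    dose_times: Sequence[float] | None = None,
) -> DosingSchedule:
    """Expand a weekly dosing pattern into explicit dose events.

    ``weekday_pattern`` lists the dosing weekdays (Monday = 0);
    ``start_weekday`` is the weekday of day 0.  Twice-daily doses default to
    08:00 and 20:00; other ``doses_per_day`` values are spaced evenly.
    """
    if not 1 <= duration_days <= 365:
        raise InvalidInputError("duration_days must lie in [1, 365]")
    if dose_volume_ml <= 0:
        raise InvalidInputError("dose_volume_ml must be positive")
    if doses_per_day < 1:
        raise InvalidInputError("doses_per_day must be >= 1")
    pattern = sorted(set(int(w) for w in weekday_pattern))
    if not pattern:
        raise InvalidInputError("weekday_pattern must not be empty")
    if any(w < 0 or w > 6 for w in pattern):
        raise InvalidInputError("weekday indices must lie in [0, 6]")
    if dose_times is None:
        if doses_per_day == 2:
            times = DEFAULT_DOSE_TIMES
        else:
            times = tuple((i + 0.5) / doses_per_day for i in range(doses_per_day))
    else:
        times = tuple(float(t) for t in dose_times)
        if len(times) != doses_per_day:
            raise InvalidInputError("dose_times must have doses_per_day entries")

    events = []
    for d in range(int(duration_days)):
        if (start_weekday + d) % 7 in pattern:
            for t in times:
                events.append(DoseEvent(start_day + d + t, dose_volume_ml, purity))
    return DosingSchedule(tuple(events))


def simulate_body_water(
    schedule: DosingSchedule,
    params: BodyWaterParams,
    grid: np.ndarray | None = None,
) -> EnrichmentCurve:
    """One-compartment impulse-dose enrichment curve.

    Closed-form superposition: each dose contributes a step of
    ``volume x purity / body-water volume`` that decays exponentially at the
    water turnover rate.  The default grid runs from day 0 to two days past
    the last dose in 0.05-day steps.
    """
    if grid is None:
        end = (schedule.days[-1] + 2.0) if len(schedule) else 1.0
        grid = np.arange(0.0, end + SIMULATION_GRID_STEP / 2, SIMULATION_GRID_STEP)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be a strictly increasing 1-D array")
    values = np.zeros_like(grid)
    if len(schedule):
        dose_days = schedule.days
        deltas = np.array(
            [e.volume_ml * e.purity / (params.volume_l * 1000.0) for e in schedule.events]
        )
        dt = grid[None, :] - dose_days[:, None]
        contrib = np.where(dt >= 0, np.exp(-params.turnover_per_day * np.maximum(dt, 0.0)), 0.0)
        values = deltas @ contrib
    return EnrichmentCurve(grid, values, provenance="simulated")


def interpolate_measured(
    saliva_points: Iterable[tuple[float, float]],
) -> EnrichmentCurve:
    """Piecewise-linear enrichment curve through measured saliva points.

    Held flat before the first and after the last point; a (0, 0) point is
    prepended when no measurement exists at or before day 0, since labeling
    starts unenriched.
    """
    points = sorted((float(d), float(v)) for d, v in saliva_points)
    if len(points) < 2:
        raise InsufficientDataError("need at least 2 saliva points")
    days = [p[0] for p in points]
    if len(set(days)) != len(days):
        raise InvalidInputError("saliva measurement days must be distinct")
    if days[0] > 0:
        points.insert(0, (0.0, 0.0))
    days = np.array([p[0] for p in points])
    values = np.array([p[1] for p in points])
    return EnrichmentCurve(days, values, provenance="measured-interpolated")


def time_averaged_enrichment(curve: EnrichmentCurve, t: float) -> float:
    """Time-averaged enrichment from day 0 to day ``t``.

    (1/t) times the trapezoidal integral of the curve on its native grid.
    Beyond the curve span the last value is carried forward (with a warning).
    """
    t = float(t)
    if t <= 0:
        raise DomainError("time-averaged enrichment requires t > 0")
    if t > curve.days[-1] + 1e-12:
        warnings.warn(
            f"t={t} exceeds the enrichment curve span; extrapolating flat",
            stacklevel=2,
        )
    interior = curve.days[(curve.days > 0) & (curve.days < t)]
    xs = np.concatenate(([0.0], interior, [t]))
    ys = curve.value_at(xs)
    return float(np.trapezoid(ys, xs) / t)
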