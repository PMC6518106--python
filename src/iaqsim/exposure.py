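"""Personal exposure assembly and annual summary statistics.

The occupant's time-activity pattern maps each hour of day to one (or a
time-weighted mix) of the microenvironments: the apartment zones or the
outdoors.  Personal exposure at hour *h* is the concentration of the occupied
microenvironment — the ambient series when outdoors.  The annual summary is
the mean of the 365 daily means with a normal-approximation 95% confidence
interval, ``mean ± 1.96·sd(daily means)/√365``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iaq_sim import ConcentrationField
from .synth_env import AmbientSeries, DAYS_PER_YEAR

OUTDOOR = "outdoor"

__all__ = [
    "OUTDOOR",
    "Occupancy",
    "ExposureSeries",
    "AnnualSummary",
    "default_occupancy",
    "personal_exposure",
    "annual_summary",
    "percent_reduction",
]


@dataclass(frozen=True)
class Occupancy:
    """Hour-of-day → microenvironment fractions.

    ``fractions[h]`` maps location labels (zone names or ``"outdoor"``) to the
    share of hour ``h`` spent there; each hour's shares must sum to 1.
    """

    fractions: tuple[dict[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != 24:
            raise ValueError("occupancy needs 24 hourly entries")
        for h, entry in enumerate(self.fractions):
            total = sum(entry.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"hour {h}: location fractions sum to {total}, not 1")
            if any(v < 0 for v in entry.values()):
                raise ValueError("location fractions must be non-negative")

    def dominant_zone(self, hour_of_day: int) -> str:
        """Indoor zone with the largest share that hour (outdoors excluded)."""
        entry = {k: v for k, v in self.fractions[hour_of_day].items() if k != OUTDOOR}
        if not entry:
            return OUTDOOR
        return max(entry, key=entry.get)

    def with_outdoor_hours(self, hours) -> "Occupancy":
        """Variant spending the given hours of day entirely outdoors."""
        new = list(self.fractions)
        for h in hours:
            new[h] = {OUTDOOR: 1.0}
        return Occupancy(fractions=tuple(new))


def default_occupancy() -> Occupancy:
    """The single occupant's base-case day, indoors 24 h.

    Bedroom 22:00–06:00, bathroom 06:00–07:00, kitchen while cooking
    (half-hours 7:00–7:30 and 12:00–12:30 shared with the living room,
    17:00–18:00 fully), living room otherwise.
    """
    entries: list[dict[str, float]] = []
    for h in range(24):
        if h >= 22 or h < 6:
            entries.append({"bedroom": 1.0})
        elif h == 6:
            entries.append({"bathroom": 1.0})
        elif h in (7, 12):
            entries.append({"kitchen": 0.5, "living_room": 0.5})
        elif h == 17:
            entries.append({"kitchen": 1.0})
        else:
            entries.append({"living_room": 1.0})
    return Occupancy(fractions=tuple(entries))


@dataclass(frozen=True)
class ExposureSeries:
    """Hourly personal PM2.5 exposure (µg/m³) plus the occupied-location label."""

    values: np.ndarray
    locations: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.locations):
            raise ValueError("values and locations must align")
        if not np.all(np.isfinite(values)):
            raise ValueError("exposure values must be finite")

    def daily_means(self) -> np.ndarray:
        if len(self.values) % 24 != 0:
            raise ValueError("series must cover whole days")
        return self.values.reshape(-1, 24).mean(axis=1)


@dataclass(frozen=True)
class AnnualSummary:
    """Annual mean of daily means with its normal-approximation 95% CI."""

    mean: float
    ci95: tuple[float, float]
    daily_means: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.mean <= hi:
            raise ValueError("CI must bracket the mean")


def personal_exposure(
    field: ConcentrationField,
    ambient: AmbientSeries,
    occupancy: Occupancy | None = None,
) -> ExposureSeries:
    """Weight zone concentrations by the occupant's location each hour.

    With a single-zone field every indoor label resolves to that zone.  An
    hour split between two rooms yields the time-weighted concentration mix.
    """
    occ = occupancy if occupancy is not None else default_occupancy()
    H = field.values.shape[0]
    names = field.zone_names
    single = field.n_zones == 1

    values = np.empty(H)
    labels: list[str] = []
    for h in range(H):
        entry = occ.fractions[h % 24]
        total = 0.0
        for loc, frac in entry.items():
            if loc == OUTDOOR:
                total += frac * float(ambient.pm25[h])
            elif single:
                total += frac * float(field.values[h, 0])
            else:
                if loc not in names:
                    raise ValueError(f"occupancy references unknown zone {loc!r}")
                total += frac * float(field.values[h, names.index(loc)])
        values[h] = total
        labels.append(max(entry, key=entry.get))
    return ExposureSeries(values=values, locations=tuple(labels))


def annual_summary(exposure: ExposureSeries) -> AnnualSummary:
    """Mean of the 365 daily means and its 95% CI across days."""
    daily = exposure.daily_means()
    if len(daily) != DAYS_PER_YEAR:
        raise ValueError(f"annual summary needs {DAYS_PER_YEAR} full days, got {len(daily)}")
    mean = float(daily.mean())
    sd = float(daily.std(ddof=1))
    half = 1.96 * sd / np.sqrt(DAYS_PER_YEAR)
    return AnnualSummary(mean=mean, ci95=(mean - half, mean + half), daily_means=daily)


def summary_from_daily_means(daily_means: np.ndarray) -> AnnualSummary:
    """Annual summary straight from 365 daily means (same CI machinery)."""
    daily = np.asarray(daily_means, dtype=float)
    if len(daily) != DAYS_PER_YEAR:
        raise ValueError(f"expected {DAYS_PER_YEAR} daily means")
    mean = float(daily.mean())
    half = 1.96 * float(daily.std(ddof=1)) / np.sqrt(DAYS_PER_YEAR)
    return AnnualSummary(mean=mean, ci95=(mean - half, mean + half), daily_means=daily)


def percent_reduction(baseline: AnnualSummary, scenario: AnnualSummary) -> float:
    """Percent reduction of the annual mean relative to the baseline."""
    if baseline.mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (baseline.mean - scenario.mean) / baseline.mean
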