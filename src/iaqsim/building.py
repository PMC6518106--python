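"""Apartment template, schedules, emission sources and the scenario factorial.

The dwelling is the 30 m² naturally ventilated urban-Delhi apartment used
throughout the analysis: bedroom, living room, kitchen and bathroom, windows
open 7:00–18:00, a bathroom exhaust fan (120 m³/h, 6:00–7:00), a kitchen
exhaust fan (170 m³/h, running with the LPG stove), PM2.5 deposition at
0.19/h, and optionally an indoor smoker and a portable air filter with
CADR 200 cfm and single-pass efficiency 0.30 / 0.65 / 0.99.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "CFM_TO_M3_PER_MIN",
    "DEFAULT_CADR_M3H",
    "FILTER_EFFICIENCIES",
    "FILTER_USE_HOURS",
    "Zone",
    "Schedule",
    "EmissionSource",
    "FanSpec",
    "FilterSpec",
    "ApartmentModel",
    "Scenario",
    "cfm_to_m3h",
    "default_apartment",
    "cooking_source",
    "smoking_source",
    "filter_schedule",
    "scenario_factorial",
    "apartment_to_dict",
    "apartment_from_dict",
    "apartment_to_yaml",
    "apartment_from_yaml",
]

#: exact unit conversion, 1 cfm = 0.0283168 m³/min
CFM_TO_M3_PER_MIN = 0.0283168

#: device CADR on the printed basis: 200 cfm ≈ 5.66 m³/min = 339.6 m³/h
DEFAULT_CADR_M3H = 5.66 * 60.0

#: single-pass PM2.5 removal efficiency by filter grade (MERV 8 / MERV 12 / HEPA)
FILTER_EFFICIENCIES = {"low": 0.30, "mid": 0.65, "hepa": 0.99}

#: daily on-hours for the three use schedules: all day, evening+night, sleep
FILTER_USE_HOURS = {
    "24h": tuple(range(24)),
    "15h": tuple(range(17, 24)) + tuple(range(0, 8)),
    "8h": (22, 23, 0, 1, 2, 3, 4, 5),
}


def cfm_to_m3h(cfm: float) -> float:
    """Convert cubic feet per minute to m³/h."""
    return cfm * CFM_TO_M3_PER_MIN * 60.0


# --------------------------------------------------------------------------- #
# elementary types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Zone:
    """A well-mixed room: name, floor area (m²) and volume (m³)."""

    name: str
    floor_area: float
    volume: float

    def __post_init__(self) -> None:
        if self.floor_area <= 0 or self.volume <= 0:
            raise ValueError("zone area and volume must be positive")


@dataclass(frozen=True)
class Schedule:
    """Active fraction per hour of day, 24 slots in [0, 1].

    Half-hour events are expressed as fractional values (cooking 7:00–7:30 is
    0.5 in slot 7); the simulator treats the fraction as the within-hour duty
    cycle of a piecewise-constant hourly coefficient.
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != 24:
            raise ValueError("a Schedule needs exactly 24 hourly fractions")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("schedule fractions must lie in [0, 1]")
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))

    @classmethod
    def always_off(cls) -> "Schedule":
        return cls(fractions=(0.0,) * 24)

    @classmethod
    def always_on(cls) -> "Schedule":
        return cls(fractions=(1.0,) * 24)

    @classmethod
    def from_windows(cls, windows: list[tuple[float, float]]) -> "Schedule":
        """Build from [(start_hour, end_hour), ...] with half-hour resolution.

        ``(7.0, 7.5)`` puts 0.5 in slot 7; ``(17, 18)`` puts 1.0 in slot 17.
        Windows may not wrap midnight (split them instead).
        """
        frac = np.zeros(24)
        for start, end in windows:
            if not 0 <= start < end <= 24:
                raise ValueError(f"invalid window ({start}, {end})")
            for h in range(int(np.floor(start)), int(np.ceil(end))):
                lo, hi = max(start, h), min(end, h + 1)
                frac[h] += max(0.0, hi - lo)
        return cls(fractions=tuple(np.clip(frac, 0.0, 1.0)))

    @classmethod
    def from_hours(cls, hours) -> "Schedule":
        frac = [1.0 if h in set(hours) else 0.0 for h in range(24)]
        return cls(fractions=tuple(frac))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def hours_per_day(self) -> float:
        return float(sum(self.fractions))


@dataclass(frozen=True)
class EmissionSource:
    """Indoor PM2.5 source: zone, emission rate while active (mg/min), schedule."""

    zone: str
    rate_mg_per_min: float
    schedule: Schedule
    label: str = ""

    def __post_init__(self) -> None:
        if self.rate_mg_per_min < 0:
            raise ValueError("emission rate must be non-negative")

    def daily_mass_mg(self) -> float:
        """Emitted PM2.5 mass per day (mg)."""
        return self.rate_mg_per_min * 60.0 * self.schedule.hours_per_day()


@dataclass(frozen=True)
class FanSpec:
    """Exhaust fan: zone, volumetric flow while on (m³/h), schedule."""

    zone: str
    flow_m3h: float
    schedule: Schedule

    def __post_init__(self) -> None:
        if self.flow_m3h < 0:
            raise ValueError("fan flow must be non-negative")


@dataclass(frozen=True)
class FilterSpec:
    """Portable air filter: CADR basis flow, single-pass efficiency, schedule.

    ``zone_policy`` is either the literal ``"follow_occupant"`` (the device is
    moved with the occupant — bedroom at night, living room by day) or a fixed
    zone name.
    """

    cadr_m3h: float = DEFAULT_CADR_M3H
    efficiency: float = FILTER_EFFICIENCIES["hepa"]
    schedule: Schedule = field(default_factory=Schedule.always_on)
    zone_policy: str = "follow_occupant"

    def __post_init__(self) -> None:
        if self.cadr_m3h < 0:
            raise ValueError("CADR must be non-negative")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")

    @property
    def clean_air_flow_m3h(self) -> float:
        """Effective clean-air delivery: efficiency × device flow (m³/h)."""
        return self.efficiency * self.cadr_m3h


# --------------------------------------------------------------------------- #
# the apartment
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ApartmentModel:
    """Zones, doorway topology, sinks, sources and (optionally) a filter.

    ``doorways`` lists unordered zone-name pairs connected by an open doorway;
    each carries a symmetric mixing flow of ``interzonal_flow_m3h`` in both
    directions.  ``penetration`` is the fraction of outdoor PM2.5 surviving
    envelope entry (1.0: infiltrating air carries full ambient concentration).
    """

    zones: tuple[Zone, ...]
    doorways: tuple[tuple[str, str], ...]
    interzonal_flow_m3h: float = 150.0
    penetration: float = 1.0
    deposition_rate_per_h: float = 0.19
    sources: tuple[EmissionSource, ...] = ()
    fans: tuple[FanSpec, ...] = ()
    filter: FilterSpec | None = None

    def __post_init__(self) -> None:
        if self.deposition_rate_per_h < 0:
            raise ValueError("deposition rate must be non-negative")
        if not 0 < self.penetration <= 1:
            raise ValueError("penetration must lie in (0, 1]")
        if self.interzonal_flow_m3h < 0:
            raise ValueError("interzonal flow must be non-negative")
        names = [z.name for z in self.zones]
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique")
        name_set = set(names)
        for a, b in self.doorways:
            if a not in name_set or b not in name_set:
                raise ValueError(f"doorway ({a}, {b}) references unknown zone")
        for item in list(self.sources) + list(self.fans):
            if item.zone not in name_set:
                raise ValueError(f"{item} references unknown zone {item.zone!r}")
        if len(self.zones) > 1 and not self._connected():
            raise ValueError("doorway graph must connect all zones")

    def _connected(self) -> bool:
        names = {z.name for z in self.zones}
        adj: dict[str, set[str]] = {n: set() for n in names}
        for a, b in self.doorways:
            adj[a].add(b)
            adj[b].add(a)
        seen = {next(iter(names))}
        stack = list(seen)
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen == names

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(z.name for z in self.zones)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([z.volume for z in self.zones])

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def single_zone(self) -> "ApartmentModel":
        """Collapse to one well-mixed zone of the total volume.

        Sources, fans and the filter keep their schedules but act in the
        single merged zone.  This is the mode used for runs that target the
        whole-dwelling summary numbers.
        """
        merged = Zone(
            name="home",
            floor_area=sum(z.floor_area for z in self.zones),
            volume=self.total_volume,
        )
        sources = tuple(replace(s, zone="home") for s in self.sources)
        fans = tuple(replace(f, zone="home") for f in self.fans)
        filt = replace(self.filter, zone_policy="home") if self.filter else None
        return ApartmentModel(
            zones=(merged,),
            doorways=(),
            interzonal_flow_m3h=self.interzonal_flow_m3h,
            penetration=self.penetration,
            deposition_rate_per_h=self.deposition_rate_per_h,
            sources=sources,
            fans=fans,
            filter=filt,
        )


# default floor-area split (m²); only the 30 m² total is fixed by the template
_DEFAULT_AREAS = {"bedroom": 9.0, "living_room": 12.0, "kitchen": 6.0, "bathroom": 3.0}

#: LPG-stove windows: 7:00–7:30, 12:00–12:30, 17:00–18:00 (2 h/day total)
COOKING_WINDOWS = [(7.0, 7.5), (12.0, 12.5), (17.0, 18.0)]


def cooking_source(rate_mg_per_min: float = 0.14) -> EmissionSource:
    """LPG cooking source in the kitchen, 2 h/day on the stove windows."""
    return EmissionSource(
        zone="kitchen",
        rate_mg_per_min=rate_mg_per_min,
        schedule=Schedule.from_windows(COOKING_WINDOWS),
        label="cooking",
    )


def smoking_source(
    n_cigarettes: int = 8,
    minutes_per_cigarette: float = 10.0,
    rate_mg_per_min: float = 0.33,
    start_hour: int = 9,
    zone: str = "living_room",
) -> EmissionSource:
    """Indoor smoker: one cigarette per hour starting 9:00, living room.

    Each cigarette burns for ``minutes_per_cigarette`` at ``rate_mg_per_min``;
    with the defaults the daily emitted mass is 8 × 10 × 0.33 = 26.4 mg.  If
    the cigarette count exceeds the daytime slots the events simply continue
    hourly into the evening.
    """
    if n_cigarettes < 0:
        raise ValueError("cigarette count must be non-negative")
    if minutes_per_cigarette <= 0 or minutes_per_cigarette > 60:
        raise ValueError("minutes_per_cigarette must lie in (0, 60]")
    if start_hour + n_cigarettes > 24:
        raise ValueError("cigarette events would run past midnight")
    frac = [0.0] * 24
    for k in range(n_cigarettes):
        frac[start_hour + k] = minutes_per_cigarette / 60.0
    return EmissionSource(
        zone=zone,
        rate_mg_per_min=rate_mg_per_min,
        schedule=Schedule(fractions=tuple(frac)),
        label="smoking",
    )


def default_apartment(ceiling_height_m: float = 2.5) -> ApartmentModel:
    """The 30 m² four-room Delhi apartment with its fans and cooking source.

    Zones share doorways with the living room (star topology).  No smoker and
    no filter; scenario composition adds those.
    """
    if not 2.2 <= ceiling_height_m <= 3.5:
        raise ValueError("ceiling height outside the sanity range [2.2, 3.5] m")
    zones = tuple(
        Zone(name=n, floor_area=a, volume=a * ceiling_height_m)
        for n, a in _DEFAULT_AREAS.items()
    )
    doorways = (
        ("bedroom", "living_room"),
        ("kitchen", "living_room"),
        ("bathroom", "living_room"),
    )
    fans = (
        FanSpec(zone="bathroom", flow_m3h=120.0, schedule=Schedule.from_windows([(6, 7)])),
        FanSpec(zone="kitchen", flow_m3h=170.0, schedule=Schedule.from_windows(COOKING_WINDOWS)),
    )
    return ApartmentModel(
        zones=zones,
        doorways=doorways,
        sources=(cooking_source(),),
        fans=fans,
    )


def filter_schedule(use_schedule: str) -> Schedule:
    """Daily on-hours of a named filter use schedule (``8h``/``15h``/``24h``)."""
    if use_schedule not in FILTER_USE_HOURS:
        raise ValueError(f"unknown filter use schedule {use_schedule!r}")
    return Schedule.from_hours(FILTER_USE_HOURS[use_schedule])


# --------------------------------------------------------------------------- #
# scenarios
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Scenario:
    """One cell of the intervention factorial."""

    id: str
    filter_type: str  # none | low | mid | hepa
    use_schedule: str  # none | 8h | 15h | 24h
    smoker: bool

    def __post_init__(self) -> None:
        if (self.filter_type == "none") != (self.use_schedule == "none"):
            raise ValueError("filter_type is 'none' iff use_schedule is 'none'")
        if self.filter_type not in ("none", *FILTER_EFFICIENCIES):
            raise ValueError(f"unknown filter type {self.filter_type!r}")
        if self.use_schedule not in ("none", *FILTER_USE_HOURS):
            raise ValueError(f"unknown use schedule {self.use_schedule!r}")

    @property
    def has_filter(self) -> bool:
        return self.filter_type != "none"


def scenario_factorial() -> list[Scenario]:
    """The 20-run factorial: {3 filters × 3 schedules × 2 smoking} + 2 baselines.

    Deterministic order: baselines first, then sorted by (use schedule,
    filter grade, smoker).
    """
    scenarios = [
        Scenario(id=f"none-none-{'smoker' if s else 'nosmoker'}",
                 filter_type="none", use_schedule="none", smoker=s)
        for s in (False, True)
    ]
    for sched, ftype, smoker in itertools.product(
        ("8h", "15h", "24h"), ("low", "mid", "hepa"), (False, True)
    ):
        scenarios.append(
            Scenario(
                id=f"{sched}-{ftype}-{'smoker' if smoker else 'nosmoker'}",
                filter_type=ftype,
                use_schedule=sched,
                smoker=smoker,
            )
        )
    return scenarios


# --------------------------------------------------------------------------- #
# config (de)serialization
# --------------------------------------------------------------------------- #

def apartment_to_dict(apartment: ApartmentModel) -> dict:
    return {
        "zones": [
            {"name": z.name, "floor_area": z.floor_area, "volume": z.volume}
            for z in apartment.zones
        ],
        "doorways": [list(d) for d in apartment.doorways],
        "interzonal_flow_m3h": apartment.interzonal_flow_m3h,
        "penetration": apartment.penetration,
        "deposition_rate_per_h": apartment.deposition_rate_per_h,
        "sources": [
            {
                "zone": s.zone,
                "rate_mg_per_min": s.rate_mg_per_min,
                "schedule": list(s.schedule.fractions),
                "label": s.label,
            }
            for s in apartment.sources
        ],
        "fans": [
            {"zone": f.zone, "flow_m3h": f.flow_m3h, "schedule": list(f.schedule.fractions)}
            for f in apartment.fans
        ],
        "filter": None
        if apartment.filter is None
        else {
            "cadr_m3h": apartment.filter.cadr_m3h,
            "efficiency": apartment.filter.efficiency,
            "schedule": list(apartment.filter.schedule.fractions),
            "zone_policy": apartment.filter.zone_policy,
        },
    }


def apartment_from_dict(data: dict) -> ApartmentModel:
    filt = data.get("filter")
    return ApartmentModel(
        zones=tuple(Zone(**z) for z in data["zones"]),
        doorways=tuple(tuple(d) for d in data["doorways"]),
        interzonal_flow_m3h=data.get("interzonal_flow_m3h", 150.0),
        penetration=data.get("penetration", 1.0),
        deposition_rate_per_h=data.get("deposition_rate_per_h", 0.19),
        sources=tuple(
            EmissionSource(
                zone=s["zone"],
                rate_mg_per_min=s["rate_mg_per_min"],
                schedule=Schedule(fractions=tuple(s["schedule"])),
                label=s.get("label", ""),
            )
            for s in data.get("sources", [])
        ),
        fans=tuple(
            FanSpec(
                zone=f["zone"],
                flow_m3h=f["flow_m3h"],
                schedule=Schedule(fractions=tuple(f["schedule"])),
            )
            for f in data.get("fans", [])
        ),
        filter=None
        if filt is None
        else FilterSpec(
            cadr_m3h=filt["cadr_m3h"],
            efficiency=filt["efficiency"],
            schedule=Schedule(fractions=tuple(filt["schedule"])),
            zone_policy=filt["zone_policy"],
        ),
    )


def apartment_to_yaml(apartment: ApartmentModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(apartment_to_dict(apartment), fh, sort_keys=False)


def apartment_from_yaml(path) -> ApartmentModel:
    with open(path) as fh:
        return apartment_from_dict(yaml.safe_load(fh))
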