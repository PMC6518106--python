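"""Multi-zone well-mixed PM2.5 mass balance over one year.

Each zone *i* (volume ``V_i``, m³) obeys, with concentrations in µg/m³ and
flows in m³/h::

    V_i dC_i/dt = P·Q_inf,i·C_out + Σ_j Q_ji·C_j
                  − (Q_exf,i + Q_fan,i + Σ_j Q_ij)·C_i
                  + S_i(t) − k_dep·V_i·C_i − η·CADR·C_i·[filter in i, on]

Airflows are prescribed rather than solved from a pressure network: at hour
*t* the whole-dwelling envelope exchange is ``a(t)·V_total`` apportioned to
zones by volume, and every exhaust fan induces matching make-up infiltration
through the non-fan zones.  Doorways carry a symmetric mixing flow plus the
directed transfer needed to route fan make-up air to the fan zones, so air
mass is conserved in every zone at every hour.

All forcing (ambient, AER, schedules) is constant within an hour, so the
hourly step is advanced with the exact solution of the constant-coefficient
linear system — a scalar exponential in single-zone mode, a Van Loan matrix
exponential otherwise.  Hourly outputs are true within-hour time averages;
concentrations are therefore non-negative by construction and the mass budget
closes to floating-point precision.

Unit constant: 1 mg/min = 6.0·10⁴ µg/h.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .building import ApartmentModel
from .synth_env import AERSeries, AmbientSeries, HOURS_PER_YEAR

MG_PER_MIN_TO_UG_PER_H = 6.0e4

__all__ = [
    "MG_PER_MIN_TO_UG_PER_H",
    "ConcentrationField",
    "FlowState",
    "build_flows",
    "simulate",
    "steady_state",
    "mass_budget",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ConcentrationField:
    """Per-zone hourly mean PM2.5 (µg/m³), shape (n_hours, n_zones)."""

    values: np.ndarray
    zone_names: tuple[str, ...]
    dt_minutes: float
    state_initial: np.ndarray
    state_final: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(self.zone_names):
            raise ValueError("values must be (n_hours, n_zones)")
        if not np.all(np.isfinite(values)) or np.any(values < -1e-9):
            raise ValueError("concentrations must be finite and non-negative")

    @property
    def n_zones(self) -> int:
        return len(self.zone_names)

    def zone(self, name: str) -> np.ndarray:
        return self.values[:, self.zone_names.index(name)]

    def volume_weighted_mean(self, volumes: np.ndarray) -> np.ndarray:
        return self.values @ (volumes / volumes.sum())

    def to_csv(self, path: str | Path) -> None:
        """Long-format writer: ``hour_index,zone,pm25_ugm3``."""
        n_hours = self.values.shape[0]
        df = pd.DataFrame(
            {
                "hour_index": np.repeat(np.arange(n_hours), self.n_zones),
                "zone": list(self.zone_names) * n_hours,
                "pm25_ugm3": self.values.ravel(),
            }
        )
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class FlowState:
    """Hourly airflow bookkeeping (all m³/h).

    ``q_iz[h, i, j]`` is the directed flow from zone *i* to zone *j* during
    hour *h* (symmetric doorway mixing plus make-up transfer routing).
    """

    q_inf: np.ndarray  # (H, n) envelope infiltration incl. fan make-up
    q_exf: np.ndarray  # (H, n) envelope exfiltration
    q_fan: np.ndarray  # (H, n) fan exhaust
    q_iz: np.ndarray  # (H, n, n)
    zone_names: tuple[str, ...]

    def balance_residual(self) -> np.ndarray:
        """Per-zone, per-hour (inflow − outflow); ~0 by construction."""
        inflow = self.q_inf + self.q_iz.sum(axis=1)
        outflow = self.q_exf + self.q_fan + self.q_iz.sum(axis=2)
        return inflow - outflow


# --------------------------------------------------------------------------- #
# prescribed airflows
# --------------------------------------------------------------------------- #

def _fan_flows_by_hod(apartment: ApartmentModel) -> np.ndarray:
    """(24, n) average exhaust flow per zone per hour of day."""
    n = len(apartment.zones)
    names = apartment.zone_names
    out = np.zeros((24, n))
    for fan in apartment.fans:
        out[:, names.index(fan.zone)] += fan.flow_m3h * fan.schedule.as_array()
    return out


def _makeup_shares(apartment: ApartmentModel, fan_hod: np.ndarray) -> np.ndarray:
    """(24, n) make-up infiltration per zone: total fan flow routed into
    the non-fan zones proportionally to volume (all zones if every zone
    exhausts that hour)."""
    volumes = apartment.volumes
    out = np.zeros_like(fan_hod)
    for h in range(24):
        total = fan_hod[h].sum()
        if total <= 0:
            continue
        mask = fan_hod[h] == 0
        if not mask.any():
            mask[:] = True
        w = volumes * mask
        out[h] = total * w / w.sum()
    return out


def _transfer_matrices(apartment: ApartmentModel, supply_hod: np.ndarray) -> np.ndarray:
    """(24, n, n) directed doorway transfers balancing per-zone net supply.

    ``supply_hod[h, i]`` is make-up inflow minus fan exhaust for zone *i*
    (sums to zero over zones); the transfer field with that divergence is
    obtained from a potential on the doorway graph (graph Laplacian solve).
    """
    n = len(apartment.zones)
    names = apartment.zone_names
    T = np.zeros((24, n, n))
    if n == 1 or not apartment.doorways:
        return T
    lap = np.zeros((n, n))
    edges = []
    for a, b in apartment.doorways:
        i, j = names.index(a), names.index(b)
        edges.append((i, j))
        lap[i, i] += 1
        lap[j, j] += 1
        lap[i, j] -= 1
        lap[j, i] -= 1
    for h in range(24):
        s = supply_hod[h]
        if not np.any(s):
            continue
        phi = np.linalg.lstsq(lap, s, rcond=None)[0]
        for i, j in edges:
            flow = phi[i] - phi[j]
            if flow >= 0:
                T[h, i, j] += flow
            else:
                T[h, j, i] -= flow
    return T


def build_flows(apartment: ApartmentModel, aer: AERSeries | np.ndarray) -> FlowState:
    """Prescribed hourly airflow field for the dwelling.

    Envelope infiltration at hour *t* is ``a(t)·V_total`` (apportioned to
    zones by volume) plus the make-up matching all active fan exhaust; the
    inflow/outflow balance holds per zone and hour.
    """
    a = aer.aer if isinstance(aer, AERSeries) else np.asarray(aer, dtype=float)
    if np.any(a < 0):
        raise ValueError("AER values must be non-negative")
    H = len(a)
    hod = np.arange(H) % 24
    volumes = apartment.volumes
    n = len(volumes)

    fan_hod = _fan_flows_by_hod(apartment)
    makeup_hod = _makeup_shares(apartment, fan_hod)
    T_hod = _transfer_matrices(apartment, makeup_hod - fan_hod)

    mix = np.zeros((n, n))
    names = apartment.zone_names
    for za, zb in apartment.doorways:
        i, j = names.index(za), names.index(zb)
        mix[i, j] += apartment.interzonal_flow_m3h
        mix[j, i] += apartment.interzonal_flow_m3h

    q_exf = a[:, None] * volumes[None, :]
    q_inf = q_exf + makeup_hod[hod]
    q_fan = fan_hod[hod]
    q_iz = mix[None, :, :] + T_hod[hod]
    return FlowState(q_inf=q_inf, q_exf=q_exf, q_fan=q_fan, q_iz=q_iz,
                     zone_names=names)


# --------------------------------------------------------------------------- #
# coefficient assembly
# --------------------------------------------------------------------------- #

def _source_rates_by_hod(apartment: ApartmentModel) -> np.ndarray:
    """(24, n) hourly-average emission rate per zone, µg/h."""
    n = len(apartment.zones)
    names = apartment.zone_names
    out = np.zeros((24, n))
    for src in apartment.sources:
        out[:, names.index(src.zone)] += (
            src.rate_mg_per_min * MG_PER_MIN_TO_UG_PER_H * src.schedule.as_array()
        )
    return out


def _default_filter_zone(apartment: ApartmentModel, hour_of_day: int) -> str:
    names = apartment.zone_names
    if len(names) == 1:
        return names[0]
    night = hour_of_day >= 22 or hour_of_day < 6
    if night and "bedroom" in names:
        return "bedroom"
    if "living_room" in names:
        return "living_room"
    return names[0]


def _filter_removal_by_hod(apartment: ApartmentModel, occupancy=None) -> np.ndarray:
    """(24, n) clean-air removal flow η·CADR per zone, m³/h (schedule-weighted).

    ``occupancy`` may provide ``dominant_zone(hour_of_day)`` to place a
    follow-occupant device; otherwise the default rule is bedroom at night
    (22:00–06:00) and living room by day.
    """
    n = len(apartment.zones)
    out = np.zeros((24, n))
    filt = apartment.filter
    if filt is None or filt.clean_air_flow_m3h == 0:
        return out
    names = apartment.zone_names
    for h in range(24):
        frac = filt.schedule.fractions[h]
        if frac == 0:
            continue
        if filt.zone_policy == "follow_occupant":
            zone = None
            if occupancy is not None and hasattr(occupancy, "dominant_zone"):
                zone = occupancy.dominant_zone(h)
            if zone not in names:
                zone = _default_filter_zone(apartment, h)
        else:
            zone = filt.zone_policy
            if zone not in names:
                raise ValueError(f"filter zone {zone!r} not in apartment")
        out[h, names.index(zone)] = filt.clean_air_flow_m3h * frac
    return out


def _system_matrices(
    apartment: ApartmentModel,
    q_inf: np.ndarray,
    q_exf: np.ndarray,
    q_fan: np.ndarray,
    q_iz: np.ndarray,
    filter_flow: np.ndarray,
    source_ugh: np.ndarray,
    c_out: float,
) -> tuple[np.ndarray, np.ndarray]:
    """A (n×n) and b (n) of dC/dt = A·C + b for one set of constant coefficients."""
    V = apartment.volumes
    k = apartment.deposition_rate_per_h
    outflow = q_exf + q_fan + q_iz.sum(axis=1)
    A = (q_iz.T / V[:, None]).copy()  # A[i, j] = q_ji / V_i
    np.fill_diagonal(A, -(outflow + filter_flow) / V - k)
    b = (apartment.penetration * q_inf * c_out + source_ugh) / V
    return A, b


# --------------------------------------------------------------------------- #
# steady-state oracle
# --------------------------------------------------------------------------- #

def steady_state(
    apartment: ApartmentModel,
    c_out: float,
    aer: float,
    *,
    sources_on: bool = False,
    fans_on: bool = False,
    filter_on: bool = False,
    filter_zone: str | None = None,
) -> np.ndarray:
    """Exact steady state of the linear system under constant forcing.

    Sources and fans, when on, run at their full rated values (schedules are
    ignored — this is the verification oracle, not the transient model).  For
    a single zone the result is the closed form
    ``(a·P·c_out + S/V) / (a + k_dep + η·CADR/V)``.
    """
    n = len(apartment.zones)
    names = apartment.zone_names
    V = apartment.volumes

    fan = np.zeros(n)
    if fans_on:
        for f in apartment.fans:
            fan[names.index(f.zone)] += f.flow_m3h
    makeup = np.zeros(n)
    if fan.sum() > 0:
        mask = fan == 0
        if not mask.any():
            mask[:] = True
        w = V * mask
        makeup = fan.sum() * w / w.sum()

    mix = np.zeros((n, n))
    for za, zb in apartment.doorways:
        i, j = names.index(za), names.index(zb)
        mix[i, j] += apartment.interzonal_flow_m3h
        mix[j, i] += apartment.interzonal_flow_m3h
    T = _transfer_matrices(apartment, np.tile(makeup - fan, (24, 1)))[0]
    q_iz = mix + T

    q_exf = aer * V
    q_inf = q_exf + makeup

    source = np.zeros(n)
    if sources_on:
        for s in apartment.sources:
            source[names.index(s.zone)] += s.rate_mg_per_min * MG_PER_MIN_TO_UG_PER_H

    filter_flow = np.zeros(n)
    if filter_on and apartment.filter is not None:
        zone = filter_zone or (
            apartment.filter.zone_policy
            if apartment.filter.zone_policy in names
            else _default_filter_zone(apartment, 12)
        )
        filter_flow[names.index(zone)] = apartment.filter.clean_air_flow_m3h

    A, b = _system_matrices(apartment, q_inf, q_exf, fan, q_iz, filter_flow, source, c_out)
    try:
        return np.linalg.solve(-A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular steady state: no removal pathway balances the sources") from err


# --------------------------------------------------------------------------- #
# transient simulation
# --------------------------------------------------------------------------- #

def _advance_hour_multizone(A: np.ndarray, b: np.ndarray, c0: np.ndarray):
    """Exact one-hour step: returns (end state, within-hour mean).

    Van Loan augmentation: with z = [c, 1, u] and u' = c, the matrix
    exponential of the block system delivers both the end state and the
    integral of c over the hour in one call.
    """
    n = len(c0)
    M = np.zeros((2 * n + 1, 2 * n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    M[n + 1:, :n] = np.eye(n)
    Phi = expm(M)  # Δt = 1 h
    z0 = np.concatenate([c0, [1.0], np.zeros(n)])
    z1 = Phi @ z0
    return z1[:n], z1[n + 1:]


def simulate(
    apartment: ApartmentModel,
    ambient: AmbientSeries,
    aer: AERSeries,
    *,
    dt_minutes: float = 1.0,
    occupancy=None,
    n_hours: int | None = None,
) -> ConcentrationField:
    """Integrate the mass balance over the year (or ``n_hours``).

    Coefficients are constant within each hour, so every step uses the exact
    solution of the hourly linear system; ``dt_minutes`` is validated for
    interface compatibility but does not affect the result.  The initial
    condition is the steady state of hour 0.  Returned values are within-hour
    time averages.
    """
    if 60.0 % dt_minutes != 0:
        raise ValueError("dt_minutes must divide 60")
    if np.any(~np.isfinite(ambient.pm25)) or np.any(~np.isfinite(aer.aer)):
        raise ValueError("non-finite values in forcing series")
    H = HOURS_PER_YEAR if n_hours is None else int(n_hours)
    if not 1 <= H <= HOURS_PER_YEAR:
        raise ValueError("n_hours must lie in [1, 8760]")

    flows = build_flows(apartment, aer.aer[:H])
    source_hod = _source_rates_by_hod(apartment)
    filter_hod = _filter_removal_by_hod(apartment, occupancy)
    hod = np.arange(H) % 24
    n = len(apartment.zones)
    single = n == 1
    V = apartment.volumes

    values = np.empty((H, n))
    c = None
    for h in range(H):
        A, b = _system_matrices(
            apartment,
            flows.q_inf[h],
            flows.q_exf[h],
            flows.q_fan[h],
            flows.q_iz[h],
            filter_hod[hod[h]],
            source_hod[hod[h]],
            float(ambient.pm25[h]),
        )
        if c is None:
            c = np.linalg.solve(-A, b)  # spin-up: steady state of hour 0
            c_init = c.copy()
        if single:
            lam = -A[0, 0]
            f = b[0]
            e = np.exp(-lam)
            cs = f / lam
            c_end = cs + (c[0] - cs) * e
            mean = cs + (c[0] - cs) * (1.0 - e) / lam
            values[h, 0] = mean
            c = np.array([c_end])
        else:
            c, mean = _advance_hour_multizone(A, b, c)
            values[h] = mean
    # exact solutions of a positive system can only dip below zero by rounding
    np.clip(values, 0.0, None, out=values)
    return ConcentrationField(
        values=values,
        zone_names=apartment.zone_names,
        dt_minutes=dt_minutes,
        state_initial=c_init,
        state_final=c,
    )


# --------------------------------------------------------------------------- #
# mass accounting
# --------------------------------------------------------------------------- #

def mass_budget(
    field: ConcentrationField,
    apartment: ApartmentModel,
    ambient: AmbientSeries,
    aer: AERSeries,
    occupancy=None,
) -> dict[str, float]:
    """Integrated PM2.5 mass budget (µg) over the simulated window.

    Because hourly outputs are exact within-hour averages of the linear
    system, emitted + infiltrated mass equals deposited + exfiltrated +
    filtered mass plus the airborne storage change, to floating point.
    """
    H = field.values.shape[0]
    flows = build_flows(apartment, aer.aer[:H])
    hod = np.arange(H) % 24
    source_hod = _source_rates_by_hod(apartment)
    filter_hod = _filter_removal_by_hod(apartment, occupancy)
    V = apartment.volumes
    C = field.values

    emitted = float(source_hod[hod].sum())
    infiltrated = float(
        (apartment.penetration * flows.q_inf * ambient.pm25[:H, None]).sum()
    )
    deposited = float((apartment.deposition_rate_per_h * V[None, :] * C).sum())
    exfiltrated = float(((flows.q_exf + flows.q_fan) * C).sum())
    filtered = float((filter_hod[hod] * C).sum())
    storage = float((V * (field.state_final - field.state_initial)).sum())
    inputs = emitted + infiltrated
    outputs = deposited + exfiltrated + filtered + storage
    return {
        "emitted_ug": emitted,
        "infiltrated_ug": infiltrated,
        "deposited_ug": deposited,
        "exfiltrated_ug": exfiltrated,
        "filtered_ug": filtered,
        "storage_change_ug": storage,
        "relative_imbalance": (inputs - outputs) / max(inputs, 1e-12),
    }
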