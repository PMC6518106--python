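"""Synthetic yearlong environment for the Delhi indoor-air simulations.

Two generators drive the whole pipeline:

* :func:`generate_ambient` — hourly outdoor PM2.5 for a 365-day year, built as
  a lognormal process: an annual cosine on the log scale (winter elevation,
  peak in early January), a two-bump diurnal cycle (morning and late-night
  peaks, mid-afternoon trough, the canonical shape of Delhi surface PM2.5),
  and AR(1) hourly log-residuals.  After exponentiation the series is rescaled
  so the annual mean of daily means hits the target (123 µg/m³ by default)
  exactly, independent of seed.

* :func:`generate_aer` — an hourly whole-dwelling air-exchange-rate schedule:
  a deterministic windows-open (7:00–18:00) / windows-closed step profile,
  modulated by an annual cosine and lognormal day-to-day jitter, rescaled so
  the annual mean of daily means equals the deterministic baseline mean
  (1.5/h under defaults) exactly.

Optional readers ingest real CPCB station exports (wide CSV, stations
averaged) and EnergyPlus EPW weather files (dry-bulb temperature only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HOURS_PER_YEAR = 8760
DAYS_PER_YEAR = 365

#: day-of-year index (0-based) at which the annual cosine peaks (≈ 5 January)
SEASONAL_PEAK_DOY = 4

__all__ = [
    "HOURS_PER_YEAR",
    "DAYS_PER_YEAR",
    "AmbientSeries",
    "AmbientGenParams",
    "AERSeries",
    "AERGenParams",
    "generate_ambient",
    "generate_aer",
    "read_cpcb_csv",
    "read_epw",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

def _hour_axes() -> tuple[np.ndarray, np.ndarray]:
    """(day-of-year, hour-of-day) integer arrays for hour indices 0..8759."""
    idx = np.arange(HOURS_PER_YEAR)
    return idx // 24, idx % 24


@dataclass(frozen=True)
class AmbientSeries:
    """Hourly outdoor PM2.5 (µg/m³) for one non-leap year, local time.

    ``pm25[h]`` is the mean concentration over the left-closed hourly interval
    starting at hour index ``h`` (0..8759).  ``temperature`` (°C) is optional.
    """

    pm25: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        pm25 = np.asarray(self.pm25, dtype=float)
        object.__setattr__(self, "pm25", pm25)
        if pm25.shape != (HOURS_PER_YEAR,):
            raise ValueError(f"pm25 must have shape ({HOURS_PER_YEAR},), got {pm25.shape}")
        if not np.all(np.isfinite(pm25)):
            raise ValueError("pm25 contains non-finite values")
        if np.any(pm25 <= 0):
            raise ValueError("pm25 values must be strictly positive")
        if self.temperature is not None:
            temp = np.asarray(self.temperature, dtype=float)
            if temp.shape != (HOURS_PER_YEAR,):
                raise ValueError("temperature must have 8760 hourly values")
            object.__setattr__(self, "temperature", temp)

    def daily_means(self) -> np.ndarray:
        """365 daily mean concentrations (µg/m³)."""
        return self.pm25.reshape(DAYS_PER_YEAR, 24).mean(axis=1)

    def annual_mean(self) -> float:
        """Annual mean of daily means (µg/m³)."""
        return float(self.daily_means().mean())

    def to_csv(self, path: str | Path) -> None:
        """Write the two-column ``hour_index,pm25_ugm3`` interchange format."""
        pd.DataFrame(
            {"hour_index": np.arange(HOURS_PER_YEAR), "pm25_ugm3": self.pm25}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AmbientSeries":
        df = pd.read_csv(path)
        if not {"hour_index", "pm25_ugm3"} <= set(df.columns):
            raise ValueError("expected columns hour_index,pm25_ugm3")
        df = df.sort_values("hour_index")
        return cls(pm25=df["pm25_ugm3"].to_numpy(dtype=float))


@dataclass(frozen=True)
class AERSeries:
    """Hourly whole-dwelling air exchange rate (air changes per hour)."""

    aer: np.ndarray

    def __post_init__(self) -> None:
        aer = np.asarray(self.aer, dtype=float)
        object.__setattr__(self, "aer", aer)
        if aer.shape != (HOURS_PER_YEAR,):
            raise ValueError(f"aer must have shape ({HOURS_PER_YEAR},), got {aer.shape}")
        if np.any(~np.isfinite(aer)) or np.any(aer <= 0):
            raise ValueError("aer values must be finite and strictly positive")
        daily = self.daily_means()
        if daily.min() < 0.1 or daily.max() > 12.0:
            raise ValueError("daily mean AER outside the sanity envelope [0.1, 12] 1/h")

    def daily_means(self) -> np.ndarray:
        return self.aer.reshape(DAYS_PER_YEAR, 24).mean(axis=1)

    def annual_mean(self) -> float:
        return float(self.daily_means().mean())


# --------------------------------------------------------------------------- #
# ambient generator
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AmbientGenParams:
    """Parameters of the lognormal ambient PM2.5 generator.

    target_annual_mean
        Annual mean of daily means, µg/m³ (Delhi 2017 station average: 123).
    seasonal_amplitude
        Log-scale amplitude of the annual cosine peaking ≈ 5 January.
    diurnal_amplitudes
        Log-scale amplitudes ``(morning, late_night)`` of two circular
        Gaussian bumps centred at 07:30 (width 2 h) and 22:30 (width 4 h);
        the diurnal profile is mean-centred so it does not shift the annual
        level.
    diurnal_seasonality
        Seasonal modulation of the diurnal amplitude: the profile is scaled by
        ``1 + diurnal_seasonality·cos(annual phase)``, peaking in winter, when
        the shallow nocturnal boundary layer amplifies the day/night contrast.
    ar1_rho
        Lag-1 autocorrelation of the hourly log-residual AR(1) process.
    resid_sd
        Stationary standard deviation of the log residuals.
    """

    target_annual_mean: float = 123.0
    seasonal_amplitude: float = 0.82
    diurnal_amplitudes: tuple[float, float] = (0.55, 0.90)
    diurnal_seasonality: float = 0.6
    ar1_rho: float = 0.95
    resid_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_annual_mean <= 0:
            raise ValueError("target_annual_mean must be positive")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")
        if not 0.0 <= self.diurnal_seasonality < 1.0:
            raise ValueError("diurnal_seasonality must lie in [0, 1)")


def _circular_bump(hod: np.ndarray, center: float, width: float) -> np.ndarray:
    dist = np.abs(hod - center)
    dist = np.minimum(dist, 24.0 - dist)
    return np.exp(-0.5 * (dist / width) ** 2)


def diurnal_profile(amplitudes: tuple[float, float]) -> np.ndarray:
    """Mean-centred 24-value log-scale diurnal profile (morning + late night)."""
    hod = np.arange(24, dtype=float)
    a_morning, a_night = amplitudes
    prof = a_morning * _circular_bump(hod, 7.5, 2.0) + a_night * _circular_bump(hod, 22.5, 4.0)
    return prof - prof.mean()


def generate_ambient(params: AmbientGenParams | None = None) -> AmbientSeries:
    """Generate one year of hourly ambient PM2.5.

    The log-concentration is ``season + diurnal + AR(1) residual``; the
    exponentiated series is rescaled multiplicatively so the annual mean of
    daily means equals ``target_annual_mean`` exactly (up to floating point),
    for any seed.  Positivity is guaranteed by construction.
    """
    p = params if params is not None else AmbientGenParams()
    rng = np.random.default_rng(p.seed)
    doy, hod = _hour_axes()

    phase = np.cos(2.0 * np.pi * (doy - SEASONAL_PEAK_DOY) / DAYS_PER_YEAR)
    season = p.seasonal_amplitude * phase
    diurnal = diurnal_profile(p.diurnal_amplitudes)[hod] * (
        1.0 + p.diurnal_seasonality * phase
    )

    resid = np.zeros(HOURS_PER_YEAR)
    if p.resid_sd > 0:
        innov_sd = p.resid_sd * np.sqrt(1.0 - p.ar1_rho**2)
        eps = rng.normal(0.0, innov_sd, HOURS_PER_YEAR)
        resid[0] = rng.normal(0.0, p.resid_sd)
        for t in range(1, HOURS_PER_YEAR):
            resid[t] = p.ar1_rho * resid[t - 1] + eps[t]

    pm25 = np.exp(season + diurnal + resid)
    series = AmbientSeries(pm25=pm25)
    scale = p.target_annual_mean / series.annual_mean()
    return AmbientSeries(pm25=pm25 * scale)


# --------------------------------------------------------------------------- #
# AER generator
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AERGenParams:
    """Parameters of the prescribed air-exchange-rate schedule generator.

    The deterministic skeleton is a two-level step profile: ``aer_windows_open``
    during ``window_open_hours`` and ``aer_windows_closed`` otherwise.  Day-to-day
    variability enters as a daily multiplier — an annual cosine of amplitude
    ``seasonal_modulation`` (peak mid-June: windows work harder in the hot
    season) times mean-one lognormal jitter with log-sd ``noise_sd``.  The
    final series is rescaled so its annual mean of daily means equals the
    skeleton's daily mean exactly.

    Defaults are calibrated to the study dwelling: daily mean 1.5/h with the
    bulk of daily values inside 0.3–4.5/h.
    """

    aer_windows_open: float = 29.5 / 11.0  # => (11*open + 13*closed)/24 == 1.5
    aer_windows_closed: float = 0.5
    seasonal_modulation: float = 0.25
    noise_sd: float = 0.45
    window_open_hours: frozenset[int] = field(default_factory=lambda: frozenset(range(7, 18)))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aer_windows_open <= 0 or self.aer_windows_closed <= 0:
            raise ValueError("AER baselines must be strictly positive")
        if self.aer_windows_open < self.aer_windows_closed:
            raise ValueError("aer_windows_open must be >= aer_windows_closed")
        if not 0.0 <= self.seasonal_modulation < 1.0:
            raise ValueError("seasonal_modulation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        hours = frozenset(int(h) for h in self.window_open_hours)
        if any(h < 0 or h > 23 for h in hours):
            raise ValueError("window_open_hours must be hours of day 0..23")
        object.__setattr__(self, "window_open_hours", hours)

    @property
    def baseline_daily_mean(self) -> float:
        n_open = len(self.window_open_hours)
        return (
            n_open * self.aer_windows_open + (24 - n_open) * self.aer_windows_closed
        ) / 24.0


def generate_aer(params: AERGenParams | None = None) -> AERSeries:
    """Generate one year of hourly air exchange rates.

    Every day keeps the open-hours > closed-hours contrast (the daily
    multiplier is common to all hours of a day, and the final rescale is
    global), so window-driven diurnal structure survives the noise.
    """
    p = params if params is not None else AERGenParams()
    rng = np.random.default_rng(p.seed)
    doy, hod = _hour_axes()

    base = np.where(
        np.isin(hod, list(p.window_open_hours)), p.aer_windows_open, p.aer_windows_closed
    )
    # mid-June peak: day-of-year 166
    seasonal = 1.0 + p.seasonal_modulation * np.cos(2.0 * np.pi * (doy - 166) / DAYS_PER_YEAR)
    if p.noise_sd > 0:
        jitter_daily = np.exp(
            rng.normal(-0.5 * p.noise_sd**2, p.noise_sd, DAYS_PER_YEAR)
        )
    else:
        jitter_daily = np.ones(DAYS_PER_YEAR)
    aer = base * seasonal * jitter_daily[doy]

    series = AERSeries(aer=aer)
    scale = p.baseline_daily_mean / series.annual_mean()
    return AERSeries(aer=aer * scale)


# --------------------------------------------------------------------------- #
# optional readers for real inputs
# --------------------------------------------------------------------------- #

def read_cpcb_csv(
    path: str | Path, *, max_gap_hours: int = 6, max_missing_fraction: float = 0.2
) -> AmbientSeries:
    """Read a wide CPCB-style station export into an :class:`AmbientSeries`.

    Expected layout: one timestamp column (first column, parseable datetimes,
    hourly cadence, one full non-leap year) plus one numeric column per
    monitoring station.  Station columns are averaged per hour; gaps in the
    station-average are linearly interpolated up to ``max_gap_hours``
    consecutive hours.  Longer gaps, or more than ``max_missing_fraction`` of
    hours missing before interpolation, are errors.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("CPCB export needs a timestamp column plus station columns")
    ts = pd.to_datetime(df.iloc[:, 0], errors="raise")
    stations = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    avg = stations.mean(axis=1, skipna=True)
    avg.index = ts
    avg = avg.sort_index()
    if len(avg) != HOURS_PER_YEAR:
        raise ValueError(f"expected {HOURS_PER_YEAR} hourly rows, got {len(avg)}")

    missing = avg.isna()
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{missing.mean():.0%} of hours missing exceeds the "
            f"{max_missing_fraction:.0%} limit"
        )
    if missing.any():
        run = missing.groupby((~missing).cumsum()).cumsum()
        if run.max() > max_gap_hours:
            raise ValueError(
                f"gap of {int(run.max())} h exceeds max_gap_hours={max_gap_hours}"
            )
        avg = avg.interpolate(method="linear", limit_direction="both")
    return AmbientSeries(pm25=avg.to_numpy(dtype=float))


def read_epw(path: str | Path) -> pd.Series:
    """Read dry-bulb temperature (°C) from an EnergyPlus EPW weather file.

    EPW files carry 8 header lines followed by 8760 hourly CSV records; the
    dry-bulb temperature is field 7 (0-based column 6).  Returns a pandas
    Series indexed by hour index 0..8759.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = lines[8:]
    if len(data_lines) < HOURS_PER_YEAR:
        raise ValueError(
            f"EPW file has {len(data_lines)} data rows, expected {HOURS_PER_YEAR}"
        )
    for line in data_lines[:HOURS_PER_YEAR]:
        parts = line.split(",")
        if len(parts) < 7:
            raise ValueError("malformed EPW data row")
        rows.append(float(parts[6]))
    return pd.Series(rows, index=pd.RangeIndex(HOURS_PER_YEAR, name="hour_index"), name="temperature_c")
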