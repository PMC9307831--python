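"""Synthetic half-hourly meteorological forcing.

Generates seeded, reproducible weather series with the statistical structure
of mid/high-latitude flux-tower records: seasonal and diurnal temperature
cycles with AR(1) anomalies, clear-sky shortwave modulated by persistent
cloudiness, bulk-emissivity longwave, and a two-state wet/dry precipitation
occurrence chain with exponential daily amounts partitioned into rain or
snow by air temperature.

Four climate archetypes ship as defaults: ``subalpine``, ``alpine``,
``sub_arctic`` and ``arctic``. Their numbers are plausible site conditions
(a subalpine spruce-fir forest around 3000 m, an alpine fellfield above it,
and a taiga-tundra pair near 68 N), not measurements.

All years are 365-day non-leap years; timestamps are nominal UTC labels at
1800 s spacing and the ``doy``/``hour`` columns carry the model calendar.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClimateArchetype",
    "ARCHETYPES",
    "solar_elevation",
    "clear_sky_shortwave",
    "partition_precip",
    "generate_forcing",
    "write_forcing",
    "read_forcing",
    "load_archetype",
]

STEPS_PER_DAY = 48
DAYS_PER_YEAR = 365
STEP_SECONDS = 1800.0
SOLAR_CONSTANT = 1361.0  # W/m2
BULK_TRANSMISSIVITY = 0.75  # clear-sky atmospheric transmissivity

FORCING_COLUMNS = [
    "timestamp",
    "SW_in",
    "LW_in",
    "T_air",
    "precip",
    "phase",
    "wind",
    "RH",
    "pressure",
]


@dataclass(frozen=True)
class ClimateArchetype:
    """Climate statistics that parameterize the weather generator.

    Temperatures in K, precipitation in mm water-equivalent per year,
    elevation in m. ``seasonal_amplitude`` and ``diurnal_amplitude`` are
    semi-amplitudes of the respective sinusoids.
    """

    name: str
    latitude: float
    elevation: float
    mean_annual_temp: float
    seasonal_amplitude: float
    diurnal_amplitude: float
    annual_precip: float
    wet_day_fraction: float
    cloud_persistence: float
    mean_wind: float = 3.0
    snow_threshold_temp: float = 274.15

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.seasonal_amplitude <= 0:
            raise ValueError("seasonal_amplitude must be > 0")
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal_amplitude must be >= 0")
        if self.annual_precip <= 0:
            raise ValueError("annual_precip must be > 0")
        if not 0.0 < self.wet_day_fraction < 1.0:
            raise ValueError("wet_day_fraction must be in (0, 1)")
        if not 0.0 <= self.cloud_persistence < 1.0:
            raise ValueError("cloud_persistence must be in [0, 1)")


#: Default archetypes. Values are realistic site conditions for the four
#: climate types, chosen once; they are generator inputs, not observations.
ARCHETYPES: dict[str, ClimateArchetype] = {
    "subalpine": ClimateArchetype(
        name="subalpine", latitude=40.03, elevation=3050.0,
        mean_annual_temp=274.65, seasonal_amplitude=10.0,
        diurnal_amplitude=5.0, annual_precip=800.0, wet_day_fraction=0.35,
        cloud_persistence=0.7,
    ),
    "alpine": ClimateArchetype(
        name="alpine", latitude=40.05, elevation=3480.0,
        mean_annual_temp=271.65, seasonal_amplitude=10.0,
        diurnal_amplitude=5.0, annual_precip=950.0, wet_day_fraction=0.40,
        cloud_persistence=0.7, mean_wind=5.5,
    ),
    # heavy-snow alpine variant: colder and snowier, emulating sites or
    # periods with late-lying snow where the counterfactual forest's
    # shading pushes melt-out into mid-summer
    "alpine_late_snow": ClimateArchetype(
        name="alpine_late_snow", latitude=40.05, elevation=3480.0,
        mean_annual_temp=270.65, seasonal_amplitude=10.0,
        diurnal_amplitude=5.0, annual_precip=1400.0, wet_day_fraction=0.40,
        cloud_persistence=0.7, mean_wind=5.5,
    ),
    "sub_arctic": ClimateArchetype(
        name="sub_arctic", latitude=68.32, elevation=80.0,
        mean_annual_temp=265.15, seasonal_amplitude=17.0,
        diurnal_amplitude=3.0, annual_precip=350.0, wet_day_fraction=0.30,
        cloud_persistence=0.75, mean_wind=2.5,
    ),
    "arctic": ClimateArchetype(
        name="arctic", latitude=68.75, elevation=85.0,
        mean_annual_temp=264.15, seasonal_amplitude=17.5,
        diurnal_amplitude=3.0, annual_precip=350.0, wet_day_fraction=0.30,
        cloud_persistence=0.75, mean_wind=4.5,
    ),
}


def solar_elevation(latitude: float, doy, hour):
    """Solar elevation angle (radians) from declination/hour-angle geometry.

    ``hour`` is local solar time in hours; broadcasting over arrays is
    supported. Longitude is folded into solar time, so noon means solar noon.
    """
    if np.any(np.asarray(latitude) < -90) or np.any(np.asarray(latitude) > 90):
        raise ValueError("latitude outside [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    hour = np.asarray(hour, dtype=float)
    lat = math.radians(latitude)
    # Cooper-style declination, max +23.44 deg at the June solstice
    decl = np.radians(-23.44) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)
    hour_angle = np.radians(15.0 * (hour - 12.0))
    sin_el = (np.sin(lat) * np.sin(decl)
              + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    return np.arcsin(np.clip(sin_el, -1.0, 1.0))


def clear_sky_shortwave(elevation):
    """Clear-sky global shortwave (W/m2): TOA x fixed bulk transmissivity."""
    sin_el = np.sin(np.asarray(elevation, dtype=float))
    return SOLAR_CONSTANT * BULK_TRANSMISSIVITY * np.clip(sin_el, 0.0, None)


def partition_precip(T_air, threshold: float):
    """Phase of falling precipitation: snow strictly below threshold.

    The boundary ``T_air == threshold`` is assigned to rain by convention.
    """
    return np.where(np.asarray(T_air, dtype=float) < threshold, "snow", "rain")


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) series with lag-1 autocorrelation rho and std sigma."""
    from scipy.signal import lfilter

    eps = rng.standard_normal(n)
    innov = math.sqrt(1.0 - rho * rho)
    driven = innov * eps
    driven[0] = eps[0]  # stationary start
    out = lfilter([1.0], [1.0, -rho], driven)
    return sigma * out


def _saturation_vapor_pressure(T):
    """Saturation vapor pressure over water (Pa), Magnus form."""
    Tc = np.asarray(T, dtype=float) - 273.15
    return 610.94 * np.exp(17.625 * Tc / (Tc + 243.04))


def generate_forcing(
    archetype: ClimateArchetype,
    n_years: int,
    seed: int,
    start_year: int = 2001,
) -> pd.DataFrame:
    """Generate a half-hourly forcing table for ``n_years`` 365-day years.

    Columns: timestamp (nominal UTC labels), SW_in, LW_in, T_air, precip,
    phase, wind, RH, pressure, plus calendar helpers year/doy/hour. Identical
    ``(archetype, n_years, seed)`` give bit-identical output; per-variable
    substreams are spawned from the master seed so each variable's stream is
    independent.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    n = n_years * DAYS_PER_YEAR * STEPS_PER_DAY
    n_days = n_years * DAYS_PER_YEAR

    master = np.random.SeedSequence(seed)
    streams = [np.random.Generator(np.random.PCG64(s)) for s in master.spawn(5)]
    rng_temp, rng_cloud, rng_occ, rng_amt, rng_misc = streams

    year_index = np.repeat(np.arange(n_years), DAYS_PER_YEAR * STEPS_PER_DAY)
    doy = np.tile(np.repeat(np.arange(1, DAYS_PER_YEAR + 1), STEPS_PER_DAY), n_years)
    hour = np.tile(np.arange(STEPS_PER_DAY) * 0.5, n_days)

    # --- air temperature: mean + seasonal + diurnal + AR(1) anomaly
    seasonal = -archetype.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 15.0) / DAYS_PER_YEAR)
    diurnal = archetype.diurnal_amplitude * np.cos(
        2.0 * np.pi * (hour - 14.0) / 24.0)
    # synoptic anomalies persist for days: rho per half-hour step
    rho_temp = math.exp(-STEP_SECONDS / (2.5 * 86400.0))
    anomaly = _ar1(rng_temp, n, rho_temp, 4.5)
    T_air = archetype.mean_annual_temp + seasonal + diurnal + anomaly

    # --- cloudiness: probit transform of an AR(1) latent Gaussian
    g = _ar1(rng_cloud, n, archetype.cloud_persistence, 1.0)
    from scipy.special import ndtr

    cloud = ndtr(g)  # in (0, 1)
    cloud_factor = 1.0 - 0.7 * cloud

    elev = solar_elevation(archetype.latitude, doy, hour)
    SW_in = clear_sky_shortwave(elev) * cloud_factor
    SW_in[elev <= 0.0] = 0.0

    # --- longwave: bulk effective emissivity increasing with cloudiness
    e_clear = np.clip(1.24 * ((_saturation_vapor_pressure(T_air) * 0.7 / 100.0)
                              / T_air) ** (1.0 / 7.0), 0.4, 1.0)
    emiss = np.clip(e_clear * (1.0 + 0.22 * cloud**2), 0.0, 1.0)
    LW_in = emiss * 5.670374419e-8 * T_air**4

    # --- precipitation: daily two-state occurrence chain, exponential amounts
    pi_wet = archetype.wet_day_fraction
    r = 0.5  # occurrence persistence p_ww - p_wd
    p_wd = pi_wet * (1.0 - r)
    p_ww = p_wd + r
    u = rng_occ.random(n_days)
    wet = np.empty(n_days, dtype=bool)
    wet[0] = u[0] < pi_wet
    for d in range(1, n_days):
        wet[d] = u[d] < (p_ww if wet[d - 1] else p_wd)
    mean_daily = archetype.annual_precip / (DAYS_PER_YEAR * pi_wet)
    amounts = np.where(wet, rng_amt.exponential(mean_daily, n_days), 0.0)
    precip = np.repeat(amounts / STEPS_PER_DAY, STEPS_PER_DAY)
    phase = partition_precip(T_air, archetype.snow_threshold_temp)

    # --- wind, humidity, pressure
    wind = np.maximum(0.1, archetype.mean_wind
                      + _ar1(rng_misc, n, 0.9, 0.5 * archetype.mean_wind))
    RH = np.clip(55.0 + 35.0 * cloud + 5.0 * rng_misc.standard_normal(n), 5.0, 100.0)
    pressure = 101.325 * math.exp(-archetype.elevation / 8434.0)  # kPa

    timestamps = (np.datetime64(f"{start_year}-01-01T00:00")
                  + (np.arange(n) * 1800).astype("timedelta64[s]"))

    return pd.DataFrame({
        "timestamp": timestamps,
        "SW_in": SW_in,
        "LW_in": LW_in,
        "T_air": T_air,
        "precip": precip,
        "phase": phase,
        "wind": wind,
        "RH": RH,
        "pressure": np.full(n, pressure),
        "year": year_index,
        "doy": doy,
        "hour": hour,
        "cloud": cloud,
    })


def write_forcing(forcing: pd.DataFrame, path) -> None:
    """Write the forcing table as delimited text with ISO-8601 timestamps."""
    out = forcing.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.10g")


def read_forcing(path) -> pd.DataFrame:
    """Read a forcing table written by :func:`write_forcing`."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"].str.rstrip("Z"))
    return df


def load_archetype(source) -> ClimateArchetype:
    """Load a :class:`ClimateArchetype` from a YAML key: value file or stream."""
    if isinstance(source, (str,)) and "\n" not in source:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase):
        data = yaml.safe_load(source)
    else:
        data = yaml.safe_load(source)
    return ClimateArchetype(**data)


def archetype_to_yaml(archetype: ClimateArchetype) -> str:
    """Serialize an archetype to the plain-text config format."""
    return yaml.safe_dump(dataclasses.asdict(archetype), sort_keys=False)
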