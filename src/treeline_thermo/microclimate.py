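"""One-dimensional canopy-snow-soil energy balance.

The physics core steps a column with 20 above-ground canopy layers, one
ground-surface layer and 12 soil layers at a half-hourly cadence:

* shortwave is attenuated through the canopy with a Beer-Lambert law on
  cumulative leaf area (single extinction coefficient);
* each leaf layer solves a big-leaf energy balance
  ``absorbed = H + LE + net longwave`` for its leaf temperature by
  safeguarded bracketed root-finding;
* the ground/snow surface solves its own balance, partitioning available
  energy into sensible and latent heat, soil heat flux ``G`` and, when a
  snowpack is present, melt ``M`` — with the surface temperature capped at
  273.15 K while melt occurs (the mechanism that sustains snowmelt
  temperature inversions);
* the snowpack carries mass (SWE), an ageing albedo and a bulk density;
* the soil column conducts heat explicitly with a zero-flux bottom
  boundary, so the control volume loses no heat through its base.

Within-canopy air is a massless node offset above the ambient air by the
flux-gradient relation (canopy sensible heat through the canopy-top
resistance); the vertical air profile interpolates between the ground
cover and that node — a deliberately simple stand-in for a turbulence
closure that still gives each layer the local climate it experiences.
Energy closure holds at every step to well under 1 W/m2 by construction
(the only slack is solver residual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .vegetation import (
    N_CANOPY_LAYERS,
    N_SOIL_LAYERS,
    CanopyGrid,
    VegetationScenario,
    phenology_fraction,
)

__all__ = [
    "PhysicsParams",
    "SnowState",
    "SoilState",
    "FluxRecord",
    "SolverError",
    "attenuate_shortwave",
    "aerodynamic_resistance",
    "leaf_energy_balance",
    "saturation_vapor_pressure",
    "step_snowpack",
    "step_soil_heat",
    "simulate",
    "SimulationOutput",
]

SIGMA = 5.670374419e-8  # W/m2/K4
CP_AIR = 1004.0  # J/kg/K
R_DRY = 287.05  # J/kg/K
GAMMA_PSY = 66.0  # psychrometric constant, Pa/K
VON_KARMAN = 0.4
T_FREEZE = 273.15


class SolverError(RuntimeError):
    """A leaf or surface energy-balance root could not be bracketed."""


@dataclass
class PhysicsParams:
    """Config-exposed physical parameters of the simplified column."""

    dt: float = 1800.0  # s
    extinction_k: float = 0.35  # effective shortwave extinction (incl. clumping)
    extinction_k_lw: float = 0.8  # longwave canopy extinction per unit LAI
    leaf_emissivity: float = 0.97
    leaf_reflectance: float = 0.1
    ground_albedo: float = 0.2
    # stomatal resistance, s/m per unit LAI
    stomatal_open: float = 200.0
    stomatal_closed: float = 5000.0
    soil_surface_resistance: float = 500.0  # s/m, bare-soil evaporation
    snow_surface_resistance: float = 0.0  # s/m; snow is a saturated surface
    under_canopy_resistance_per_lai: float = 25.0  # s/m per unit LAI
    leaf_boundary_resistance: float = 25.0  # s/m per unit leaf area
    litter_resistance: float = 0.3  # m2 K/W, litter/moss/organic layer
    wind_floor: float = 0.5  # m/s
    # snow
    snow_density: float = 250.0  # kg/m3 bulk
    snow_albedo_fresh: float = 0.85
    snow_albedo_old: float = 0.60
    snow_age_efold_days: float = 10.0
    albedo_reset_snowfall: float = 2.0  # mm w.e. in one step to refresh albedo
    latent_heat_fusion: float = 0.334e6  # J/kg
    snow_conductivity: float = 0.18  # W/m/K
    snow_temp_relax_hours: float = 6.0
    # blowing-snow scour at sites without a sheltering overstory: wind
    # events remove pack above the vegetation trapping height
    scour_wind_threshold: float = 6.0  # m/s
    scour_efold_hours: float = 12.0
    scour_trap_margin: float = 0.02  # m on top of the trapping height
    scour_trap_herbaceous: float = 0.03  # m; collapsed graminoid mat
    shelter_min_height: float = 2.0  # m; overstory this tall stops scour
    shelter_min_lai: float = 0.25
    # soil
    soil_conductivity: float = 1.0  # W/m/K
    soil_heat_capacity: float = 2.5e6  # J/m3/K
    soil_thickness: np.ndarray = field(default_factory=lambda: np.array(
        [0.05, 0.05, 0.10, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50, 0.80, 1.00]))
    # solver
    leaf_residual_tol: float = 1e-3  # W/m2
    leaf_bracket: float = 80.0  # K around local air temperature
    surface_bracket: float = 70.0  # K around air temperature
    # dormancy / phenology coupling
    stability_damping: bool = True  # bulk-Richardson damping, stable surface
    dormancy_temp: float = T_FREEZE + 5.0  # 5-day mean canopy-air threshold
    burial_snow_depth_min: float = 0.01  # m; snow-free definition
    earliest_greenup_doy: int = 105

    def __post_init__(self) -> None:
        self.soil_thickness = np.asarray(self.soil_thickness, dtype=float)
        if self.soil_thickness.size != N_SOIL_LAYERS:
            raise ValueError(f"need {N_SOIL_LAYERS} soil layers")


@dataclass
class SnowState:
    """Snowpack mass/energy state. SWE in mm water-equivalent."""

    swe: float = 0.0
    surface_temp: float = T_FREEZE
    age_seconds: float = 0.0
    albedo: float = 0.85

    def depth(self, params: PhysicsParams) -> float:
        """Snow depth in m from SWE and the fixed bulk density."""
        return self.swe / 1000.0 * (1000.0 / params.snow_density)


@dataclass
class SoilState:
    """12-layer soil column; temperatures in K, zero-flux bottom boundary."""

    layer_temps: np.ndarray
    thickness: np.ndarray
    conductivity: float
    heat_capacity: float

    @classmethod
    def uniform(cls, temp: float, params: PhysicsParams) -> "SoilState":
        return cls(
            layer_temps=np.full(N_SOIL_LAYERS, float(temp)),
            thickness=params.soil_thickness.copy(),
            conductivity=params.soil_conductivity,
            heat_capacity=params.soil_heat_capacity,
        )

    def energy(self) -> float:
        """Column heat content (J/m2) relative to 0 K."""
        return float(np.sum(self.layer_temps * self.thickness) * self.heat_capacity)


@dataclass
class FluxRecord:
    """Canopy-top and surface fluxes for one step; positive upward/out."""

    LE: float
    H: float
    Rn_abs: float
    G: float
    M: float
    sw_absorbed_layers: np.ndarray


def saturation_vapor_pressure(T):
    """Saturation vapor pressure over water (Pa), Magnus form."""
    Tc = np.asarray(T, dtype=float) - T_FREEZE
    return 610.94 * np.exp(17.625 * Tc / (Tc + 243.04))


def _svp_slope(T):
    Tc = np.asarray(T, dtype=float) - T_FREEZE
    es = 610.94 * np.exp(17.625 * Tc / (Tc + 243.04))
    return es * 17.625 * 243.04 / (Tc + 243.04) ** 2


def attenuate_shortwave(SW_in: float, lad_profile: np.ndarray,
                        extinction_k: float, ground_albedo: float,
                        leaf_reflectance: float = 0.1):
    """Beer-Lambert shortwave attenuation through the layered canopy.

    ``lad_profile`` is per-layer leaf area, index 0 at the bottom.
    Irradiance below cumulative (from the top) leaf area L is
    ``SW_in * exp(-k L)``; a layer absorbs the irradiance difference across
    it times (1 - leaf_reflectance), the rest of the intercepted beam is
    reflected out. Returns ``(absorbed_per_layer, ground_absorbed,
    ground_incident)``; absorbed + reflected + ground terms close to SW_in.
    """
    if SW_in < 0:
        raise ValueError("SW_in must be >= 0")
    if extinction_k <= 0:
        raise ValueError("extinction_k must be > 0")
    lad = np.asarray(lad_profile, dtype=float)
    # cumulative leaf area above the top and bottom of each layer
    cum_above = np.concatenate(([0.0], np.cumsum(lad[::-1])))  # top-down
    irr = SW_in * np.exp(-extinction_k * cum_above)
    intercepted_topdown = irr[:-1] - irr[1:]
    intercepted = intercepted_topdown[::-1]
    absorbed = intercepted * (1.0 - leaf_reflectance)
    ground_incident = float(irr[-1])
    ground_absorbed = ground_incident * (1.0 - ground_albedo)
    return absorbed, ground_absorbed, ground_incident


def aerodynamic_resistance(wind: float, measurement_height: float,
                           h_canopy: float, wind_floor: float = 0.5) -> float:
    """Bulk neutral log-profile aerodynamic resistance (s/m).

    Roughness length 0.1 h and displacement 0.67 h; wind speed is floored
    to bound the resistance in calm conditions.
    """
    if wind < 0:
        raise ValueError("wind must be >= 0")
    h = max(h_canopy, 0.1)
    d = 0.67 * h
    z0 = 0.1 * h
    if measurement_height <= d + z0:
        raise ValueError(
            f"measurement height {measurement_height} m not above "
            f"displacement {d:.2f} m + roughness {z0:.2f} m")
    u = max(wind, wind_floor)
    return math.log((measurement_height - d) / z0) ** 2 / (VON_KARMAN**2 * u)


def _leaf_residual(T, absorbed, T_air_local, e_air, a_coef, b_coef, emis):
    es = saturation_vapor_pressure(T)
    H = a_coef * (T - T_air_local)
    LE = b_coef * (es - e_air)
    LW = emis * SIGMA * (T**4 - T_air_local**4)
    return absorbed - H - LE - LW, H, LE


def _solve_leaf_vec(absorbed, T_air_local, e_air, a_coef, b_coef, emis,
                    bracket, tol, max_iter=80):
    """Vectorized safeguarded Newton for the leaf energy balance.

    The residual is strictly decreasing in leaf temperature, so the root in
    ``[T_air_local - bracket, T_air_local + bracket]`` is unique when the
    residual changes sign across it.
    """
    absorbed = np.asarray(absorbed, dtype=float)
    lo = T_air_local - bracket
    hi = T_air_local + bracket
    f_lo, _, _ = _leaf_residual(lo, absorbed, T_air_local, e_air, a_coef,
                                b_coef, emis)
    f_hi, _, _ = _leaf_residual(hi, absorbed, T_air_local, e_air, a_coef,
                                b_coef, emis)
    if np.any(f_lo < 0) or np.any(f_hi > 0):
        bad = np.where((f_lo < 0) | (f_hi > 0))[0]
        raise SolverError(
            f"no sign change in leaf energy-balance bracket at indices "
            f"{bad.tolist()}: absorbed={absorbed[bad]}, "
            f"T_air_local={np.asarray(T_air_local)[bad] if np.ndim(T_air_local) else T_air_local}")
    T = np.array(T_air_local + np.zeros_like(absorbed), dtype=float)
    lo = np.array(lo + np.zeros_like(absorbed), dtype=float)
    hi = np.array(hi + np.zeros_like(absorbed), dtype=float)
    for _ in range(max_iter):
        f, H, LE = _leaf_residual(T, absorbed, T_air_local, e_air, a_coef,
                                  b_coef, emis)
        if np.all(np.abs(f) <= tol):
            break
        hi = np.where(f < 0, T, hi)
        lo = np.where(f > 0, T, lo)
        fprime = -(a_coef + b_coef * _svp_slope(T)
                   + 4.0 * emis * SIGMA * T**3)
        T_new = T - f / fprime
        outside = (T_new <= lo) | (T_new >= hi)
        T = np.where(outside, 0.5 * (lo + hi), T_new)
    else:
        raise SolverError("leaf energy-balance solver did not converge")
    f, H, LE = _leaf_residual(T, absorbed, T_air_local, e_air, a_coef,
                              b_coef, emis)
    return T, H, LE


def leaf_energy_balance(absorbed: float, T_air_local: float, RH: float,
                        r_a: float, stomata_open: bool,
                        params: PhysicsParams | None = None,
                        pressure_kpa: float = 101.325,
                        lai: float = 1.0):
    """Solve one big-leaf layer balance; returns (T_leaf, LE, H).

    ``absorbed`` is absorbed radiation (W/m2 ground), ``lai`` the layer
    leaf area it applies to (stomatal conductance scales with it). Sensible
    heat is rho cp (T_leaf - T_air)/r_a; latent heat follows the vapor
    pressure deficit at the leaf through stomatal + aerodynamic resistance
    (cuticular-level conductance when stomata are closed). Solved to
    |residual| <= params.leaf_residual_tol by bracketed root-finding.
    """
    params = params or PhysicsParams()
    rho_air = pressure_kpa * 1000.0 / (R_DRY * T_air_local)
    a_coef = rho_air * CP_AIR / r_a
    r_s_unit = params.stomatal_open if stomata_open else params.stomatal_closed
    r_s = r_s_unit / max(lai, 1e-9)
    b_coef = rho_air * CP_AIR / (GAMMA_PSY * (r_a + r_s))
    e_air = RH / 100.0 * float(saturation_vapor_pressure(T_air_local))
    T, H, LE = _solve_leaf_vec(
        np.array([absorbed]), T_air_local, e_air, a_coef, b_coef,
        params.leaf_emissivity, params.leaf_bracket, params.leaf_residual_tol)
    return float(T[0]), float(LE[0]), float(H[0])


def step_snowpack(snow: SnowState, snowfall_mm: float,
                  available_energy: float, dt: float,
                  params: PhysicsParams | None = None,
                  T_air: float | None = None,
                  surface_temp: float | None = None):
    """Advance the snowpack one step; returns (new_state, melt_energy_used).

    SWE gains the snowfall; if snow is present and energy is available,
    melt removes ``min(swe, E dt / lambda_f)`` mm and the energy actually
    used is returned (surplus stays with the caller's surface balance).
    Albedo decays from the fresh to the old value with an e-folding snow
    age, resetting on fresh snowfall. Unless an explicit ``surface_temp``
    is supplied, the surface relaxes toward air temperature but never
    exceeds 273.15 K while snow is present; it is pinned at 273.15 K while
    melt occurs.
    """
    params = params or PhysicsParams()
    if snowfall_mm < 0:
        raise ValueError("snowfall must be >= 0")
    swe = snow.swe + snowfall_mm
    age = 0.0 if snowfall_mm > params.albedo_reset_snowfall else snow.age_seconds + dt
    albedo = params.snow_albedo_old + (
        params.snow_albedo_fresh - params.snow_albedo_old
    ) * math.exp(-age / (params.snow_age_efold_days * 86400.0))

    melt_mm = 0.0
    melt_energy_used = 0.0
    if swe > 0.0 and available_energy > 0.0:
        melt_cap = available_energy * dt / params.latent_heat_fusion  # kg/m2 = mm
        melt_mm = min(swe, melt_cap)
        melt_energy_used = melt_mm * params.latent_heat_fusion / dt
        swe -= melt_mm

    if surface_temp is not None:
        ts = surface_temp
    elif melt_mm > 0.0:
        ts = T_FREEZE
    else:
        ts = snow.surface_temp
        if T_air is not None:
            tau = params.snow_temp_relax_hours * 3600.0
            ts += (T_air - ts) * (1.0 - math.exp(-dt / tau))
    if swe > 0.0:
        ts = min(ts, T_FREEZE)

    return SnowState(swe=swe, surface_temp=ts, age_seconds=age,
                     albedo=albedo), melt_energy_used


def step_soil_heat(soil: SoilState, G_surface: float, dt: float) -> SoilState:
    """Explicit conduction update of the soil column.

    Top boundary receives ``G_surface`` (W/m2, positive downward into the
    soil); the bottom boundary is zero-flux. Raises if the explicit scheme
    would be unstable at this dt.
    """
    dz = soil.thickness
    dt_max = 0.5 * float(np.min(dz)) ** 2 * soil.heat_capacity / soil.conductivity
    if dt > dt_max:
        raise ValueError(
            f"explicit soil step unstable: dt={dt} s exceeds {dt_max:.0f} s")
    T = soil.layer_temps
    # conductive flux between layer i and i+1 (positive downward)
    dz_between = 0.5 * (dz[:-1] + dz[1:])
    flux = soil.conductivity * (T[:-1] - T[1:]) / dz_between
    flux_in = np.concatenate(([G_surface], flux))
    flux_out = np.concatenate((flux, [0.0]))
    T_new = T + dt * (flux_in - flux_out) / (soil.heat_capacity * dz)
    return replace(soil, layer_temps=T_new)


def _solve_surface(f, lo: float, hi: float, tol: float = 1e-3,
                   max_iter: int = 80) -> float:
    """Scalar safeguarded bisection/Newton-free root finder for a
    monotonically decreasing residual."""
    f_lo = f(lo)
    f_hi = f(hi)
    if f_lo < 0 or f_hi > 0:
        raise SolverError(
            f"surface balance not bracketed: f({lo:.1f})={f_lo:.2f}, "
            f"f({hi:.1f})={f_hi:.2f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol or (hi - lo) < 1e-7:
            return mid
        if fm > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# full column simulation

_STATE_COLUMNS = [
    "timestamp", "year", "doy", "hour", "T_air", "SW_in", "LW_in", "precip",
    "wind", "RH",
    "T_surf", "T_snow_surf", "swe", "snow_depth", "snow_albedo", "snowfall",
    "melt_mm", "scour_mm",
    "lai_total", "sw_abs_canopy", "sw_abs_ground", "LE", "H", "Rn_abs",
    "G", "M", "lw_net_canopy", "closure_residual", "soil_T1",
    "A", "R_a", "co2_net", "stomata_open_frac",
]


@dataclass
class SimulationOutput:
    """Per-step column states and fluxes for one scenario run.

    ``table`` is a half-hourly DataFrame (see ``_STATE_COLUMNS``);
    ``layer_temps`` holds canopy leaf temperatures, shape (n_steps, 20)
    (NaN where a layer holds no leaf area).
    """

    scenario: VegetationScenario
    params: PhysicsParams
    table: pd.DataFrame
    layer_temps: np.ndarray
    greenup_days: dict[int, int]

    def write_table(self, path) -> None:
        out = self.table.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False, float_format="%.10g")


def simulate(forcing: pd.DataFrame, scenario: VegetationScenario,
             params: PhysicsParams | None = None,
             initial_temp: float | None = None) -> SimulationOutput:
    """Run the column model over a half-hourly forcing table.

    Deterministic given inputs. Raises :class:`SolverError` with the
    timestamp if any step's energy-balance root cannot be bracketed.
    """
    from . import carbon

    params = params or PhysicsParams()
    grid = CanopyGrid(scenario.h_e)
    n = len(forcing)
    dt = params.dt

    T_air = forcing["T_air"].to_numpy(float)
    SW_in = forcing["SW_in"].to_numpy(float)
    LW_in = forcing["LW_in"].to_numpy(float)
    precip = forcing["precip"].to_numpy(float)
    phase = forcing["phase"].to_numpy()
    wind = forcing["wind"].to_numpy(float)
    RH = forcing["RH"].to_numpy(float)
    pressure = forcing["pressure"].to_numpy(float)
    doy = forcing["doy"].to_numpy(int)
    year = forcing["year"].to_numpy(int)

    # 5-day running mean air temperature for the dormancy switch
    T5 = pd.Series(T_air).rolling(240, min_periods=1).mean().to_numpy()

    if initial_temp is None:
        initial_temp = float(np.mean(T_air))

    groups = scenario.groups
    n_groups = len(groups)
    weights = np.stack([
        _group_weights(grid, g) for g in groups])  # (n_groups, 20)
    tops = np.array([g.canopy_top for g in groups])
    evergreen = np.array([g.evergreen for g in groups])
    max_lai = np.array([g.max_LAI for g in groups])
    sai = np.array([g.stem_area_index for g in groups])
    capacity = np.array([g.photosynthetic_capacity for g in groups])
    resp_base = np.array([g.respiration_base for g in groups])
    refl = params.leaf_reflectance

    h_canopy = scenario.canopy_height
    z_meas = max(10.0, 1.5 * scenario.h_e)
    # wind scour applies only where no overstory shelters the pack; woody
    # stems trap snow to their height, collapsed graminoid mats barely do
    sheltered = any(g.canopy_top >= params.shelter_min_height
                    and g.max_LAI >= params.shelter_min_lai for g in groups)
    trap_depth = max(
        (g.canopy_top if g.name != "grass_or_sedge"
         else params.scour_trap_herbaceous) for g in groups
    ) + params.scour_trap_margin
    trap_swe = trap_depth * params.snow_density  # mm w.e. per m depth
    z_frac = np.clip(grid.midpoints / scenario.h_e, 0.0, 1.0)

    soil = SoilState.uniform(initial_temp, params)
    snow = SnowState(swe=0.0, surface_temp=min(initial_temp, T_FREEZE))
    ts_boundary = initial_temp  # snow surface or bare-ground skin
    t_ca_prev = initial_temp  # within-canopy air from the previous step

    # per-year green-up day (first snow-free day, floored)
    greenup: dict[int, int] = {}
    current_year = -1

    # running mean (5-day EMA) of the canopy air each group experiences
    z_mid_frac = np.clip(
        np.array([0.5 * (g.canopy_top + g.canopy_bottom) for g in groups])
        / scenario.h_e, 0.0, 1.0)
    t5_local = np.full(n_groups, initial_temp)
    ema_alpha = dt / (5.0 * 86400.0)

    cols = {c: np.zeros(n) for c in _STATE_COLUMNS
            if c not in ("timestamp", "year", "doy", "hour")}
    layer_temps = np.full((n, N_CANOPY_LAYERS), np.nan)

    emis = params.leaf_emissivity
    k_sw = params.extinction_k
    k_lw = params.extinction_k_lw
    tol = params.leaf_residual_tol

    for i in range(n):
        ta = T_air[i]
        d = int(doy[i])
        if year[i] != current_year:
            current_year = int(year[i])
        snow_depth = snow.depth(params)

        # green-up: first warm snow-free day in spring, photoperiod-floored
        if (current_year not in greenup and d >= 60
                and snow_depth < params.burial_snow_depth_min
                and T5[i] > params.dormancy_temp):
            greenup[current_year] = max(d, params.earliest_greenup_doy)
        gday = greenup.get(current_year, 10_000)

        # --- effective leaf area per group (phenology + burial)
        pheno = np.array([
            1.0 if evergreen[g] else phenology_fraction(d, gday)
            for g in range(n_groups)])
        buried = snow_depth >= tops
        lai_g = np.where(buried, 0.0, max_lai * pheno)
        lad_groups = lai_g[:, None] * weights  # (n_groups, 20)
        lad = lad_groups.sum(axis=0)
        lai_total = float(lad.sum())
        # woody stems stand year-round (unless buried) and intercept
        # radiation without transpiring or photosynthesizing
        sai_g = np.where(buried, 0.0, sai)
        rad_area = lad + (sai_g[:, None] * weights).sum(axis=0)
        rad_total = float(rad_area.sum())

        # --- shortwave attenuation on leaf + stem area
        albedo_ground = snow.albedo if snow.swe > 0 else params.ground_albedo
        sw_abs, sw_abs_ground, _ = attenuate_shortwave(
            SW_in[i], rad_area, k_sw, albedo_ground, refl)

        # --- aerodynamic resistances
        r_a = aerodynamic_resistance(wind[i], z_meas, h_canopy,
                                     params.wind_floor)
        r_ag = r_a + params.under_canopy_resistance_per_lai * rad_total

        # --- stomatal state per group (dormancy switch on the running
        # mean of the within-canopy air each group experiences)
        t_inst = ts_boundary + (t_ca_prev - ts_boundary) * z_mid_frac
        t5_local += ema_alpha * (t_inst - t5_local)
        open_g = np.array([
            carbon.dormancy_switch(
                t5_local[g], snow_depth, tops[g], evergreen[g], pheno[g],
                params)
            for g in range(n_groups)])

        # --- leaf energy balances on occupied layers
        rho_air = pressure[i] * 1000.0 / (R_DRY * ta)
        e_air = RH[i] / 100.0 * float(saturation_vapor_pressure(ta))
        mask = rad_area > 1e-9
        # sky-view factor per layer: leaves deep in the canopy exchange
        # longwave with neighbouring foliage at similar temperature, so
        # only the sky-exposed fraction loses net longwave
        cum_above = np.concatenate((np.cumsum(rad_area[::-1])[::-1][1:], [0.0]))
        sky_view = np.exp(-k_lw * cum_above)
        LE_layers = np.zeros(N_CANOPY_LAYERS)
        H_layers = np.zeros(N_CANOPY_LAYERS)
        LW_net_layers = np.zeros(N_CANOPY_LAYERS)
        T_leaf = np.full(N_CANOPY_LAYERS, np.nan)
        if mask.any():
            # canopy air (previous step) is the upper anchor: mid/lower
            # canopy layers feel it rather than the free air above
            ta_local = ts_boundary + (t_ca_prev - ts_boundary) * z_frac[mask]
            # stomatal conductances of the groups add in parallel
            g_s = np.zeros(N_CANOPY_LAYERS)
            for g in range(n_groups):
                r_unit = (params.stomatal_open if open_g[g]
                          else params.stomatal_closed)
                g_s += lad_groups[g] / r_unit
            r_s = 1.0 / np.maximum(g_s[mask], 1e-12)
            # leaf-to-canopy-air boundary resistance scales inversely with
            # the layer's leaf area; in series with the bulk resistance
            r_h = r_a + params.leaf_boundary_resistance / rad_area[mask]
            a_coef = rho_air * CP_AIR / r_h
            b_coef = rho_air * CP_AIR / (GAMMA_PSY * (r_h + r_s))
            emis_eff = emis * sky_view[mask]
            try:
                Tl, Hl, LEl = _solve_leaf_vec(
                    sw_abs[mask], ta_local, e_air, a_coef, b_coef, emis_eff,
                    params.leaf_bracket, tol)
            except SolverError as err:
                raise SolverError(
                    f"step {i} ({forcing['timestamp'].iloc[i]}): {err}"
                ) from err
            T_leaf[mask] = Tl
            H_layers[mask] = Hl
            LE_layers[mask] = LEl
            LW_net_layers[mask] = emis_eff * SIGMA * (Tl**4 - ta_local**4)

        # --- ground / snow surface balance
        snowfall = precip[i] if phase[i] == "snow" else 0.0
        swe_incoming = snow.swe + snowfall
        if mask.any():
            # the ground sees mostly the lowest canopy layers: weight the
            # effective radiating temperature by the ground-view factor
            cum_below = np.concatenate(([0.0], np.cumsum(rad_area)[:-1]))
            w_ground = rad_area[mask] * np.exp(-k_lw * cum_below[mask])
            t_canopy = float(np.average(T_leaf[mask], weights=w_ground))
        else:
            t_canopy = ta
        tau_lw = math.exp(-k_lw * rad_total)
        lw_down_ground = tau_lw * LW_in[i] + (1.0 - tau_lw) * SIGMA * t_canopy**4

        T1 = soil.layer_temps[0]
        dz1 = soil.thickness[0]
        if swe_incoming > 0:
            d_snow = swe_incoming / 1000.0 * 1000.0 / params.snow_density
            g_cond = 1.0 / (d_snow / params.snow_conductivity
                            + params.litter_resistance
                            + 0.5 * dz1 / soil.conductivity)
            r_surf = params.snow_surface_resistance
        else:
            g_cond = 1.0 / (params.litter_resistance
                            + 0.5 * dz1 / soil.conductivity)
            r_surf = params.soil_surface_resistance

        # the ground exchanges with within-canopy air, which sits above the
        # ambient temperature by the flux-gradient offset of the canopy
        # sensible heat passing through the canopy-top resistance
        H_can = float(H_layers.sum())
        t_ca = ta + H_can * r_a / (rho_air * CP_AIR)
        t_ca_prev = t_ca

        # stable stratification collapses turbulent exchange with the
        # surface; bulk-Richardson damping of the neutral conductance
        stab = 1.0
        if params.stability_damping and ts_boundary < t_ca:
            u_eff = max(wind[i], params.wind_floor)
            ri = 9.81 * z_meas * (t_ca - ts_boundary) / (ta * u_eff**2)
            stab = max(0.10, (1.0 - 5.0 * min(ri, 0.19)) ** 2)
        a_g = stab * rho_air * CP_AIR / r_ag
        b_g = stab * rho_air * CP_AIR / (GAMMA_PSY * (r_ag + r_surf))

        def surf_residual(ts):
            return (sw_abs_ground + lw_down_ground - SIGMA * ts**4
                    - a_g * (ts - t_ca)
                    - b_g * (saturation_vapor_pressure(ts) - e_air)
                    - g_cond * (ts - T1))

        lo = min(ta, t_ca) - params.surface_bracket
        hi = max(ta, t_ca) + params.surface_bracket
        melt_energy_avail = 0.0
        try:
            ts_balance = _solve_surface(surf_residual, lo, hi)
        except SolverError as err:
            raise SolverError(
                f"step {i} ({forcing['timestamp'].iloc[i]}): {err}") from err

        if swe_incoming > 0 and ts_balance > T_FREEZE:
            ts = T_FREEZE
            melt_energy_avail = float(surf_residual(T_FREEZE))
        else:
            ts = ts_balance

        snow, melt_used = step_snowpack(
            snow, snowfall, melt_energy_avail, dt, params, T_air=ta,
            surface_temp=ts if swe_incoming > 0 else None)
        melt_mm = melt_used * dt / params.latent_heat_fusion
        surplus = melt_energy_avail - melt_used  # pack exhausted mid-step
        scour_mm = 0.0
        if (not sheltered and snow.swe > trap_swe
                and wind[i] > params.scour_wind_threshold):
            decay = 1.0 - math.exp(-dt / (params.scour_efold_hours * 3600.0))
            scour_mm = (snow.swe - trap_swe) * decay
            snow = replace(snow, swe=snow.swe - scour_mm)
        H_g = a_g * (ts - t_ca)
        LE_g = b_g * (float(saturation_vapor_pressure(ts)) - e_air)
        G_base = g_cond * (ts - T1)
        G = G_base + surplus

        soil = step_soil_heat(soil, G, dt)
        # Thermodynamic surface temperature (the soil surface of the
        # gradient definition): under snow it is the snow-soil interface,
        # pinned at the melting point while melt occurs; bare ground uses
        # the skin temperature directly.
        if swe_incoming > 0:
            if melt_mm > 0 or surplus > 0:
                T_surf = T_FREEZE
            else:
                r_snow = d_snow / params.snow_conductivity
                r_tot = (r_snow + params.litter_resistance
                         + 0.5 * dz1 / soil.conductivity)
                T_surf = min(ts + (T1 - ts) * r_snow / r_tot, T_FREEZE)
        else:
            T_surf = ts
        ts_boundary = snow.surface_temp if snow.swe > 0 else ts

        # --- carbon exchange
        A_step, R_step = carbon.canopy_carbon_step(
            sw_abs, lad_groups, T_leaf, open_g, buried, pheno, max_lai,
            capacity, resp_base, lai_g, rad_area=rad_area)

        LE_total = float(LE_layers.sum()) + LE_g
        H_total = float(H_layers.sum()) + H_g
        lw_net_canopy = float(LW_net_layers.sum())
        sw_abs_canopy = float(sw_abs.sum())
        rn_abs = (sw_abs_canopy + sw_abs_ground + lw_down_ground
                  - SIGMA * ts**4 - lw_net_canopy)
        closure = rn_abs - (LE_total + H_total + (G - surplus) + surplus
                            + melt_used)

        layer_temps[i] = T_leaf
        c = cols
        c["T_air"][i] = ta
        c["SW_in"][i] = SW_in[i]
        c["LW_in"][i] = LW_in[i]
        c["precip"][i] = precip[i]
        c["wind"][i] = wind[i]
        c["RH"][i] = RH[i]
        c["T_surf"][i] = T_surf
        c["swe"][i] = snow.swe
        c["snow_depth"][i] = snow.depth(params)
        c["snow_albedo"][i] = snow.albedo
        c["snowfall"][i] = snowfall
        c["melt_mm"][i] = melt_mm
        c["scour_mm"][i] = scour_mm
        c["T_snow_surf"][i] = ts_boundary
        c["lai_total"][i] = lai_total
        c["sw_abs_canopy"][i] = sw_abs_canopy
        c["sw_abs_ground"][i] = sw_abs_ground
        c["LE"][i] = LE_total
        c["H"][i] = H_total
        c["Rn_abs"][i] = rn_abs
        c["G"][i] = G
        c["M"][i] = melt_used
        c["lw_net_canopy"][i] = lw_net_canopy
        c["closure_residual"][i] = closure
        c["soil_T1"][i] = soil.layer_temps[0]
        c["A"][i] = A_step
        c["R_a"][i] = R_step
        c["co2_net"][i] = A_step - R_step
        c["stomata_open_frac"][i] = float(np.mean(open_g))

    table = pd.DataFrame({
        "timestamp": forcing["timestamp"].to_numpy(),
        "year": year, "doy": doy, "hour": forcing["hour"].to_numpy(float),
        **cols,
    })
    return SimulationOutput(scenario=scenario, params=params, table=table,
                            layer_temps=layer_temps, greenup_days=greenup)


def _group_weights(grid: CanopyGrid, group) -> np.ndarray:
    from .vegetation import _overlap_weights

    return _overlap_weights(grid, group.canopy_bottom, group.canopy_top)
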