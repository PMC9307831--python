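"""Leaf CO2 exchange with a winter/snow dormancy switch.

Photosynthesis follows a rectangular-hyperbola light response on absorbed
photosynthetically active radiation (PAR, taken as a fixed fraction of
absorbed shortwave) scaled by a symmetric temperature response peaking at
20 C and vanishing below 0 C and above 40 C. It is gated by a dormancy
switch: stomata open only when the layer is not snow-buried, the 5-day
running mean air temperature exceeds +5 C, the ground snowpack has
essentially cleared, and the group is inside its phenology window.

Above-ground autotrophic respiration is a Q10 = 2 law on leaf temperature
and never switches off while leaf area exists: buried leaf area keeps
respiring at a reduced subnivean rate. This asymmetry — respiration
persists while photosynthesis is blocked by late-lying snow — is what
turns an extended snow season into an annual net CO2 loss.

Fluxes are umol CO2 m-2 ground s-1; annual integrals are mol m-2 yr-1
with positive = net leaf uptake.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dormancy_switch",
    "leaf_photosynthesis",
    "autotrophic_respiration",
    "canopy_carbon_step",
    "annual_net_co2",
]

PAR_FRACTION = 0.45  # absorbed shortwave -> PAR, W/m2
HALF_SATURATION_PAR = 100.0  # W/m2
Q10 = 2.0
T_REF_RESP = 283.15  # K
T_OPT_PHOTO = 293.15  # K; response zero at 273.15 and 313.15
BURIED_RESPIRATION_FACTOR = 0.1
SNOW_PACK_TEMP = 273.15  # assumed subnivean leaf temperature
STEPS_PER_YEAR = 365 * 48
STEP_SECONDS = 1800.0


def dormancy_switch(T_local_5day: float, snow_depth: float, canopy_top: float,
                    evergreen: bool, phenology_fraction: float,
                    params=None) -> bool:
    """True (stomata open) iff photosynthesis is enabled.

    Conditions: (a) the group is not snow-buried, (b) the running 5-day
    mean of the air temperature the group experiences (within-canopy air
    at its height) exceeds the dormancy threshold (+5 C), and (c) the
    group is inside its phenology window (always, for evergreens). A
    melt-pinned cold surface keeps canopy air below the threshold, so
    late-lying snow delays the photosynthetic season mechanistically.
    """
    temp_thresh = params.dormancy_temp if params is not None else 278.15
    if snow_depth >= canopy_top:
        return False
    if T_local_5day <= temp_thresh:
        return False
    return bool(evergreen or phenology_fraction > 0.0)


def _temperature_response(T_leaf):
    """Symmetric photosynthesis temperature factor in [0, 1]."""
    return np.clip(1.0 - ((np.asarray(T_leaf, dtype=float) - T_OPT_PHOTO)
                          / 20.0) ** 2, 0.0, 1.0)


def leaf_photosynthesis(absorbed_PAR, T_leaf, capacity: float,
                        stomata_open: bool):
    """Photosynthetic uptake per unit leaf area (umol CO2 m-2 leaf s-1).

    Rectangular hyperbola in absorbed PAR (W/m2 leaf) with half-saturation
    at 100 W/m2, asymptote ``capacity``, times the temperature response;
    identically zero when the dormancy switch is closed.
    """
    par = np.asarray(absorbed_PAR, dtype=float)
    if np.any(par < 0):
        raise ValueError("absorbed_PAR must be >= 0")
    if not stomata_open:
        return np.zeros_like(par) if par.ndim else 0.0
    A = capacity * par / (par + HALF_SATURATION_PAR) * _temperature_response(T_leaf)
    return A if par.ndim else float(A)


def autotrophic_respiration(T_leaf, base: float, LAI_layer):
    """Above-ground autotrophic respiration, umol CO2 m-2 ground s-1.

    Q10 = 2 law referenced to 10 C, scaling with the layer leaf area.
    """
    lai = np.asarray(LAI_layer, dtype=float)
    R = base * lai * Q10 ** ((np.asarray(T_leaf, dtype=float) - T_REF_RESP) / 10.0)
    return R if lai.ndim else float(R)


def canopy_carbon_step(sw_abs, lad_groups, T_leaf, open_g, buried, pheno,
                       max_lai, capacity, resp_base, lai_g, rad_area=None):
    """Whole-canopy A and R_a for one timestep (umol CO2 m-2 ground s-1).

    ``sw_abs`` and ``T_leaf`` are per-layer; ``lad_groups`` is
    (n_groups, n_layers). Absorbed PAR divides among co-located absorbing
    area (``rad_area``, leaf + stem; defaults to leaf area) in proportion,
    so only the leaf share drives uptake. Buried groups respire at the
    reduced subnivean rate on their phenology-potential leaf area.
    """
    lad_total = lad_groups.sum(axis=0)
    if rad_area is None:
        rad_area = lad_total
    occupied = lad_total > 1e-9
    A_total = 0.0
    R_total = 0.0
    if occupied.any():
        par_per_leaf = np.zeros_like(lad_total)
        par_per_leaf[occupied] = (PAR_FRACTION * np.asarray(sw_abs)[occupied]
                                  / np.asarray(rad_area)[occupied])
        ft = _temperature_response(T_leaf)
        light = par_per_leaf / (par_per_leaf + HALF_SATURATION_PAR)
        q10 = Q10 ** ((np.asarray(T_leaf, dtype=float) - T_REF_RESP) / 10.0)
        for g in range(lad_groups.shape[0]):
            lg = lad_groups[g][occupied]
            if open_g[g]:
                A_total += float(np.sum(
                    lg * capacity[g] * light[occupied] * ft[occupied]))
            R_total += float(np.sum(lg * resp_base[g] * q10[occupied]))
    # buried leaf area: reduced respiration at the snowpack temperature
    q10_snow = Q10 ** ((SNOW_PACK_TEMP - T_REF_RESP) / 10.0)
    for g in range(lad_groups.shape[0]):
        if buried[g]:
            potential = max_lai[g] * pheno[g]
            R_total += BURIED_RESPIRATION_FACTOR * resp_base[g] * potential * q10_snow
    return A_total, R_total


def annual_net_co2(series: pd.DataFrame, year: int | None = None) -> float:
    """Annual net leaf CO2 flux, mol CO2 m-2 yr-1 (positive = net uptake).

    ``series`` needs half-hourly ``A`` and ``R_a`` columns (umol m-2 s-1)
    and, unless pre-filtered, a ``year`` column to select from. The year
    must be complete (365 days x 48 steps).
    """
    df = series if year is None else series[series["year"] == year]
    if len(df) != STEPS_PER_YEAR:
        raise ValueError(
            f"incomplete year: {len(df)} steps, expected {STEPS_PER_YEAR}")
    net = (df["A"].to_numpy(float) - df["R_a"].to_numpy(float))
    return float(net.sum() * STEP_SECONDS * 1e-6)
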