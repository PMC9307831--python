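"""Ecosystem thermodynamic diagnostics.

The resultant temperature gradient of the column is

    dT/dz = (T_air - T_surf) / h_e

with T_air the air above the canopy, T_surf the ground/snow surface and
h_e the ecosystem height of the site pair. Work performed by the
ecosystem is measured through the net heat leaving the canopy top:

    Work = (LE + H) * -sign(dT)

so work is positive exactly when net heat moves from high to low
temperature, and negative when the net heat transport opposes the
gradient. Four cases follow from the signs:

1. dT < 0, net heat loss (LE+H > 0): daytime dissipation, positive work;
2. dT < 0, net heat gain: heat enters against the gradient, negative work;
3. dT > 0 (inversion), net heat gain: heat flows downhill into the
   ecosystem, positive work;
4. dT > 0 (inversion), net heat loss: snowmelt-type inversion with heat
   escaping uphill, negative work — the infeasibility signature.

When dT = 0 the sign is 0, work is 0 and no case applies ("neutral");
LE+H = 0 with nonzero dT is likewise excluded from case counts
("neutral-flux").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "temperature_gradient",
    "work_flux",
    "classify_work_case",
    "compute_thermo",
    "daily_mean_work",
    "inversion_episodes",
    "negative_work_persistence",
    "work_gradient_summary",
    "assess_feasibility",
    "InversionEpisode",
    "FeasibilityReport",
]

STEP_HOURS = 0.5
DEFAULT_THRESHOLD_DAYS = 14


def temperature_gradient(T_air, T_surf, h_e: float):
    """Resultant temperature gradient (K/m): (T_air - T_surf) / h_e."""
    if h_e <= 0:
        raise ValueError("h_e must be > 0")
    return (np.asarray(T_air, dtype=float) - np.asarray(T_surf, dtype=float)) / h_e


def work_flux(LE, H, delta_T):
    """Signed ecosystem work (W/m2): (LE + H) * -sign(delta_T)."""
    total = np.asarray(LE, dtype=float) + np.asarray(H, dtype=float)
    out = total * -np.sign(np.asarray(delta_T, dtype=float))
    return out if out.ndim else float(out)


def classify_work_case(net_heat, delta_T):
    """Work case 1-4 for each record; 0 where no case applies.

    Case 1: dT<0, net loss; 2: dT<0, net gain; 3: dT>0, net gain;
    4: dT>0, net loss. dT=0 ("neutral") and net_heat=0 ("neutral-flux")
    are coded 0 and excluded from case counts.
    """
    nh = np.asarray(net_heat, dtype=float)
    dt = np.asarray(delta_T, dtype=float)
    case = np.zeros(np.broadcast(nh, dt).shape, dtype=int)
    case = np.where((dt < 0) & (nh > 0), 1, case)
    case = np.where((dt < 0) & (nh < 0), 2, case)
    case = np.where((dt > 0) & (nh < 0), 3, case)
    case = np.where((dt > 0) & (nh > 0), 4, case)
    return case if case.ndim else int(case)


def compute_thermo(table: pd.DataFrame, h_e: float) -> pd.DataFrame:
    """Half-hourly thermodynamic record from a simulation state table.

    Requires columns T_air, T_surf, LE, H (and carries timestamp/year/doy
    and snow presence through when available).
    """
    delta_T = table["T_air"].to_numpy(float) - table["T_surf"].to_numpy(float)
    net_heat = table["LE"].to_numpy(float) + table["H"].to_numpy(float)
    out = pd.DataFrame({
        "delta_T": delta_T,
        "gradient": delta_T / h_e,
        "work": work_flux(table["LE"], table["H"], delta_T),
        "case": classify_work_case(net_heat, delta_T),
    })
    for col in ("timestamp", "year", "doy", "hour"):
        if col in table:
            out[col] = table[col].to_numpy()
    if "swe" in table:
        out["snow_present"] = table["swe"].to_numpy(float) > 0
    return out


def daily_mean_work(thermo: pd.DataFrame) -> pd.DataFrame:
    """Mean work per calendar day; partial days are dropped with a warning.

    Returns columns year, doy, work (mean of the 48 half-hourly values).
    """
    import warnings

    grouped = thermo.groupby(["year", "doy"], sort=True)
    counts = grouped.size()
    partial = counts[counts != 48]
    if len(partial):
        warnings.warn(f"excluding {len(partial)} partial day(s)", stacklevel=2)
    daily = grouped["work"].mean().reset_index()
    complete = counts[counts == 48].index
    daily = daily.set_index(["year", "doy"]).loc[complete].reset_index()
    return daily


@dataclass(frozen=True)
class InversionEpisode:
    """One maximal run of consecutive timesteps with positive gradient."""

    start: object
    end: object
    n_steps: int
    duration_hours: float
    mean_work: float
    snow_present: bool


def inversion_episodes(thermo: pd.DataFrame) -> list[InversionEpisode]:
    """Maximal consecutive runs with gradient > 0, in chronological order.

    Each episode carries its duration, mean work over the episode, and
    whether snow was present at any step of it.
    """
    grad = thermo["gradient"].to_numpy(float)
    pos = grad > 0
    if not pos.any():
        return []
    edges = np.diff(pos.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(len(pos))
    work = thermo["work"].to_numpy(float)
    snow = (thermo["snow_present"].to_numpy(bool)
            if "snow_present" in thermo else np.zeros(len(pos), dtype=bool))
    ts = (thermo["timestamp"].to_numpy()
          if "timestamp" in thermo else np.arange(len(pos)))
    episodes = []
    for s, e in zip(starts, ends):
        episodes.append(InversionEpisode(
            start=ts[s], end=ts[e - 1], n_steps=e - s,
            duration_hours=(e - s) * STEP_HOURS,
            mean_work=float(work[s:e].mean()),
            snow_present=bool(snow[s:e].any())))
    return episodes


def negative_work_persistence(daily_work: pd.DataFrame,
                              threshold_days: int = DEFAULT_THRESHOLD_DAYS):
    """Longest run of consecutive days with negative daily-mean work.

    Returns ``(longest_run_days, flagged)`` with ``flagged`` true iff the
    longest run reaches ``threshold_days``.
    """
    if threshold_days < 1:
        raise ValueError("threshold_days must be >= 1")
    w = daily_work["work"].to_numpy(float) if isinstance(
        daily_work, pd.DataFrame) else np.asarray(daily_work, dtype=float)
    neg = w < 0
    longest = run = 0
    for flag in neg:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return longest, longest >= threshold_days


def work_gradient_summary(thermo: pd.DataFrame,
                          lai_series: np.ndarray | pd.Series,
                          gradient_bins: np.ndarray | None = None,
                          lai_bins: np.ndarray | None = None) -> pd.DataFrame:
    """Binned mean work versus -gradient versus total LAI.

    Follows the plotting convention that the *negative* of the resultant
    gradient is on the x axis, so positive x means a negative gradient
    (surface warmer than air) and negative x an inversion. Returns one row
    per occupied (neg_gradient_bin x lai_bin) cell with count and mean
    work.
    """
    lai = np.asarray(lai_series, dtype=float)
    if len(lai) != len(thermo):
        raise ValueError("lai_series and thermo series are misaligned")
    x = -thermo["gradient"].to_numpy(float)
    if gradient_bins is None:
        span = max(np.abs(x).max(), 1e-9)
        gradient_bins = np.linspace(-span, span, 41)
    if lai_bins is None:
        lai_bins = np.linspace(0.0, max(lai.max(), 1e-9) + 1e-9, 6)
    if (np.any(np.diff(gradient_bins) <= 0)
            or np.any(np.diff(lai_bins) <= 0)):
        raise ValueError("bin edges must be strictly increasing")
    gi = np.clip(np.digitize(x, gradient_bins) - 1, 0, len(gradient_bins) - 2)
    li = np.clip(np.digitize(lai, lai_bins) - 1, 0, len(lai_bins) - 2)
    work = thermo["work"].to_numpy(float)
    df = pd.DataFrame({
        "neg_gradient_bin": gi, "lai_bin": li, "work": work})
    summary = df.groupby(["neg_gradient_bin", "lai_bin"]).agg(
        count=("work", "size"), mean_work=("work", "mean")).reset_index()
    summary["neg_gradient_mid"] = 0.5 * (
        gradient_bins[summary["neg_gradient_bin"]]
        + gradient_bins[summary["neg_gradient_bin"] + 1])
    summary["lai_mid"] = 0.5 * (lai_bins[summary["lai_bin"]]
                                + lai_bins[summary["lai_bin"] + 1])
    return summary


@dataclass
class FeasibilityReport:
    """Thermodynamic feasibility verdicts for one scenario.

    ``overall`` is "infeasible" if either verdict fires, "disadvantaged"
    if the scenario is feasible but gains less CO2 than its paired
    existing-vegetation scenario, else "feasible".
    """

    scenario: str
    longest_negative_work_run: int
    negative_work_days_total: int
    annual_net_co2: list = field(default_factory=list)
    mean_annual_net_co2: float = float("nan")
    verdict_negative_work: bool = False
    verdict_co2: bool = False
    paired_mean_annual_net_co2: float | None = None
    overall: str = "feasible"

    def summary_lines(self) -> list[str]:
        rep = [
            f"scenario: {self.scenario}",
            f"longest_negative_work_run_days: {self.longest_negative_work_run}",
            f"negative_work_days_total: {self.negative_work_days_total}",
            f"mean_annual_net_co2_mol_m2_yr: {self.mean_annual_net_co2:.4f}",
            f"verdict_negative_work: {self.verdict_negative_work}",
            f"verdict_co2: {self.verdict_co2}",
            f"overall: {self.overall}",
        ]
        if self.paired_mean_annual_net_co2 is not None:
            rep.insert(-1, "paired_mean_annual_net_co2_mol_m2_yr: "
                           f"{self.paired_mean_annual_net_co2:.4f}")
        return rep


def assess_feasibility(daily_work: pd.DataFrame,
                       annual_net_co2_by_year: dict | list,
                       scenario_label: str,
                       paired_annual_net_co2: dict | list | None = None,
                       threshold_days: int = DEFAULT_THRESHOLD_DAYS,
                       ) -> FeasibilityReport:
    """Combine the negative-work and CO2-balance criteria into verdicts.

    ``annual_net_co2_by_year`` holds the post-spin-up annual net leaf CO2
    fluxes (mol m-2 yr-1). Infeasible iff the longest negative-work run
    reaches ``threshold_days`` or the mean annual net CO2 is negative;
    disadvantaged iff feasible but below the paired existing scenario.
    """
    values = (list(annual_net_co2_by_year.values())
              if isinstance(annual_net_co2_by_year, dict)
              else list(annual_net_co2_by_year))
    longest, flagged = negative_work_persistence(daily_work, threshold_days)
    neg_total = int((daily_work["work"].to_numpy(float) < 0).sum())
    mean_co2 = float(np.mean(values)) if values else float("nan")
    verdict_co2 = bool(mean_co2 < 0)
    report = FeasibilityReport(
        scenario=scenario_label,
        longest_negative_work_run=longest,
        negative_work_days_total=neg_total,
        annual_net_co2=values,
        mean_annual_net_co2=mean_co2,
        verdict_negative_work=bool(flagged),
        verdict_co2=verdict_co2,
    )
    if paired_annual_net_co2 is not None:
        pv = (list(paired_annual_net_co2.values())
              if isinstance(paired_annual_net_co2, dict)
              else list(paired_annual_net_co2))
        report.paired_mean_annual_net_co2 = float(np.mean(pv))
    if report.verdict_negative_work or report.verdict_co2:
        report.overall = "infeasible"
    elif (report.paired_mean_annual_net_co2 is not None
          and mean_co2 >= 0
          and mean_co2 < report.paired_mean_annual_net_co2):
        report.overall = "disadvantaged"
    else:
        report.overall = "feasible"
    return report
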