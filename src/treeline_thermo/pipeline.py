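"""Scenario orchestration: build a site pair, run it, compare outcomes.

For one treeline site pair this runs the four vegetation scenarios —
existing forest (X-For) and its understory-only counterfactual (X-Un)
under the below-treeline forcing, existing alpine/Arctic vegetation
(X-Alp/X-Arc) and the trees-added counterfactual (X-Tr) under the
above-treeline forcing — on bit-identical shared forcing within each
site, discards spin-up years, and produces the thermodynamic and CO2
feasibility comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import carbon, thermo
from .forcing import ARCHETYPES, ClimateArchetype, generate_forcing
from .microclimate import PhysicsParams, SimulationOutput, simulate
from .vegetation import VegetationScenario, build_table1_scenarios

__all__ = [
    "RunConfig",
    "ScenarioResult",
    "SitePairResult",
    "run_scenario",
    "run_site_pair",
    "compare_scenarios",
    "matched_bin_work",
]

#: study-period lengths (post-spin-up years) emulating the three site pairs
DEFAULT_STUDY_YEARS = {"IT": 2, "US": 6, "CA": 3}

#: which forcing archetype drives each side of each pair
PAIR_ARCHETYPES = {
    "IT": {"below": "subalpine", "above": "alpine"},
    "US": {"below": "subalpine", "above": "alpine"},
    "CA": {"below": "sub_arctic", "above": "arctic"},
}

@dataclass
class RunConfig:
    """Configuration for one site-pair experiment."""

    site_pair: str = "US"
    n_years: int = 3  # total simulated years including spin-up
    spinup_years: int = 1
    seed: int = 0
    threshold_days: int = thermo.DEFAULT_THRESHOLD_DAYS
    archetype_below: ClimateArchetype | str | None = None
    archetype_above: ClimateArchetype | str | None = None
    params: PhysicsParams = field(default_factory=PhysicsParams)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.site_pair not in PAIR_ARCHETYPES:
            raise ValueError(f"unknown site pair {self.site_pair!r}")
        if self.n_years < 2 or self.n_years <= self.spinup_years:
            raise ValueError(
                "n_years must be >= 2 with at least one post-spin-up year")
        for side in ("below", "above"):
            val = getattr(self, f"archetype_{side}")
            if val is None:
                val = PAIR_ARCHETYPES[self.site_pair][side]
            if isinstance(val, str):
                val = ARCHETYPES[val]
            setattr(self, f"archetype_{side}", val)

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, str) and "\n" not in source:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        params = data.pop("params", None)
        cfg = cls(**data)
        if params:
            cfg.params = PhysicsParams(**params)
        return cfg


def forcing_hash(forcing: pd.DataFrame) -> str:
    """Deterministic digest of the numeric forcing content."""
    h = hashlib.sha256()
    for col in ("SW_in", "LW_in", "T_air", "precip", "wind", "RH", "pressure"):
        h.update(forcing[col].to_numpy(float).tobytes())
    h.update("".join(forcing["phase"].astype(str)).encode())
    return h.hexdigest()


@dataclass
class ScenarioResult:
    """One scenario's simulation plus derived diagnostics (post-spin-up)."""

    label: str
    sim: SimulationOutput
    thermo_table: pd.DataFrame
    daily_work: pd.DataFrame
    annual_co2: dict[int, float]
    forcing_digest: str
    feasibility: thermo.FeasibilityReport | None = None

    @property
    def melt_out_doy(self) -> float:
        """Mean start day of the snow-free season, per post-spin-up year.

        The snow-free season is the longest run of consecutive days with
        snow depth of at most 5 cm (summer dustings and a scoured residual
        pack do not interrupt it); its first day marks when the ground
        came functionally clear. Robust to both deep continuous packs and
        intermittent wind-scoured cover.
        """
        t = self.sim.table
        post = t[t["year"].isin(self.annual_co2.keys())]
        days = []
        for _, yr in post.groupby("year"):
            bare = (yr.groupby("doy")["snow_depth"].max() <= 0.05)
            run = best = 0
            start = cur_start = 1
            for doy, flag in bare.items():
                if flag:
                    if run == 0:
                        cur_start = doy
                    run += 1
                    if run > best:
                        best, start = run, cur_start
                else:
                    run = 0
            days.append(float(start))
        return float(np.mean(days)) if days else float("nan")


def run_scenario(forcing: pd.DataFrame, scenario: VegetationScenario,
                 config: RunConfig) -> ScenarioResult:
    """Simulate one scenario and derive its post-spin-up diagnostics."""
    sim = simulate(forcing, scenario, config.params)
    post = sim.table[sim.table["year"] >= config.spinup_years]
    th = thermo.compute_thermo(post.reset_index(drop=True), scenario.h_e)
    daily = thermo.daily_mean_work(th)
    annual = {int(y): carbon.annual_net_co2(post, y)
              for y in sorted(post["year"].unique())}
    return ScenarioResult(
        label=scenario.label, sim=sim, thermo_table=th, daily_work=daily,
        annual_co2=annual, forcing_digest=forcing_hash(forcing))


@dataclass
class SitePairResult:
    """All four scenario results of one site pair plus the comparison."""

    config: RunConfig
    results: dict[str, ScenarioResult]
    comparison: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, res in self.results.items():
            res.sim.write_table(outdir / f"{label}_states.csv")
            th = res.thermo_table.copy()
            if "timestamp" in th:
                th["timestamp"] = pd.to_datetime(th["timestamp"]).dt.strftime(
                    "%Y-%m-%dT%H:%M:%SZ")
            th.to_csv(outdir / f"{label}_thermo.csv", index=False,
                      float_format="%.10g")
            res.daily_work.to_csv(outdir / f"{label}_daily_work.csv",
                                  index=False, float_format="%.10g")
            if res.feasibility is not None:
                (outdir / f"{label}_feasibility.txt").write_text(
                    "\n".join(res.feasibility.summary_lines()) + "\n")
        self.comparison.to_csv(outdir / "comparison.csv", index=False,
                               float_format="%.10g")
        summary = {
            label: {
                "overall": res.feasibility.overall,
                "verdict_negative_work": res.feasibility.verdict_negative_work,
                "verdict_co2": res.feasibility.verdict_co2,
                "mean_annual_net_co2": res.feasibility.mean_annual_net_co2,
            }
            for label, res in self.results.items()
            if res.feasibility is not None
        }
        (outdir / "feasibility.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")


def run_site_pair(config: RunConfig) -> SitePairResult:
    """Run the four scenarios of one site pair on shared forcing.

    The counterfactual and its real counterpart share forcing
    bit-for-bit; both forcings derive from the master seed through
    independent substreams. Spin-up years are excluded from all derived
    statistics.
    """
    pair = config.site_pair
    scenarios = build_table1_scenarios(pair)
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    forcing_below = generate_forcing(config.archetype_below, config.n_years,
                                     int(seeds[0]))
    forcing_above = generate_forcing(config.archetype_above, config.n_years,
                                     int(seeds[1]))
    above_label = f"{pair}-Alp" if pair in ("IT", "US") else f"{pair}-Arc"
    driver = {
        f"{pair}-For": forcing_below,
        f"{pair}-Un": forcing_below,
        above_label: forcing_above,
        f"{pair}-Tr": forcing_above,
    }
    results: dict[str, ScenarioResult] = {}
    for label, scen in scenarios.items():
        results[label] = run_scenario(driver[label], scen, config)

    # feasibility: counterfactuals are judged against their real counterpart
    paired_existing = {
        f"{pair}-Tr": above_label,
        f"{pair}-Un": f"{pair}-For",
        f"{pair}-For": None,
        above_label: None,
    }
    for label, res in results.items():
        partner = paired_existing.get(label)
        res.feasibility = thermo.assess_feasibility(
            res.daily_work, res.annual_co2, label,
            paired_annual_net_co2=(results[partner].annual_co2
                                   if partner else None),
            threshold_days=config.threshold_days)

    comparison = compare_scenarios(list(results.values()))
    out = SitePairResult(config=config, results=results, comparison=comparison)
    if config.output_dir:
        out.write(config.output_dir)
    return out


def compare_scenarios(results: list[ScenarioResult]) -> pd.DataFrame:
    """Stable-schema comparison table across scenarios of one site pair."""
    if len(results) < 2:
        raise ValueError("need at least two scenario results to compare")
    pairs = {r.label.split("-")[0] for r in results}
    if len(pairs) > 1:
        raise ValueError(f"mixed site pairs in comparison: {sorted(pairs)}")
    rows = []
    for r in results:
        th = r.thermo_table
        rows.append({
            "scenario": r.label,
            "mean_annual_net_co2": float(np.mean(list(r.annual_co2.values()))),
            "negative_work_days_total": int(
                (r.daily_work["work"].to_numpy(float) < 0).sum()),
            "longest_negative_work_run": thermo.negative_work_persistence(
                r.daily_work)[0],
            "negative_work_halfhours": int((th["work"].to_numpy(float) < 0).sum()),
            "melt_out_doy": r.melt_out_doy,
            "mean_work": float(th["work"].mean()),
            "mean_annual_lai": float(r.sim.table.loc[
                r.sim.table["year"].isin(r.annual_co2), "lai_total"].mean()),
            "verdict_negative_work": (r.feasibility.verdict_negative_work
                                      if r.feasibility else False),
            "verdict_co2": (r.feasibility.verdict_co2
                            if r.feasibility else False),
            "overall": r.feasibility.overall if r.feasibility else "",
            "forcing_digest": r.forcing_digest,
        })
    return pd.DataFrame(rows)


def matched_bin_work(th_a: pd.DataFrame, th_b: pd.DataFrame,
                     bins: np.ndarray | None = None,
                     min_frac: float = 0.0) -> pd.DataFrame:
    """Mean work per negative-gradient bin for bins occupied by both series.

    x is the negative of the gradient (positive x = surface warmer than
    air); only bins with at least 20 records in each series are kept, and
    with ``min_frac`` > 0 a bin must additionally hold that fraction of
    each series' records to count as occupied (at extreme gradients the
    two scenarios' residual records come from disjoint conditions —
    forest nights versus open-site middays — and their conditional means
    are not comparable).
    """
    if bins is None:
        lo = min(th_a["gradient"].min(), th_b["gradient"].min())
        hi = max(th_a["gradient"].max(), th_b["gradient"].max())
        span = max(abs(lo), abs(hi))
        bins = np.linspace(-span, span, 41)
    out = []
    for name, th in (("a", th_a), ("b", th_b)):
        x = -th["gradient"].to_numpy(float)
        gi = np.clip(np.digitize(x, bins) - 1, 0, len(bins) - 2)
        df = pd.DataFrame({"bin": gi, "work": th["work"].to_numpy(float)})
        agg = df.groupby("bin").agg(**{
            f"count_{name}": ("work", "size"),
            f"mean_work_{name}": ("work", "mean")})
        out.append(agg)
    merged = out[0].join(out[1], how="inner")
    min_a = max(20, int(min_frac * len(th_a)))
    min_b = max(20, int(min_frac * len(th_b)))
    merged = merged[(merged["count_a"] >= min_a) & (merged["count_b"] >= min_b)]
    merged["bin_mid"] = 0.5 * (bins[merged.index] + bins[merged.index + 1])
    return merged.reset_index()
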