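# Model description and methods

This note documents the science inside `treeline_thermo`: what each
component assumes, which parameters matter, what the synthetic forcing
does and does not emulate, and where the model's known limits are.

## The experiment

Each treeline site pair contributes four scenarios on a shared 20-layer
canopy grid spanning the pair's ecosystem height `h_e`:

| scenario | vegetation | forcing |
|---|---|---|
| X-For | existing forest (overstory + understory) | below-treeline |
| X-Un | that forest's understory alone (counterfactual) | below-treeline |
| X-Alp / X-Arc | existing meadow / tundra | above-treeline |
| X-Tr | the forest's vegetation transplanted upslope (counterfactual) | above-treeline |

A counterfactual and its real counterpart share forcing bit-for-bit
(asserted via content digests), so every difference in outcome is caused
by vegetation structure. The first simulated year is discarded as
spin-up; soil and canopy start at the forcing's mean temperature with no
snow.

## Synthetic forcing

The generator produces half-hourly series over 365-day years:
air temperature as mean + seasonal sinusoid + diurnal sinusoid + an AR(1)
anomaly (σ = 4.5 K, ~2.5-day decorrelation — continental synoptic
variability, which matters because warm spells interrupt snowpacks and
break negative-work runs); shortwave as clear-sky irradiance
(top-of-atmosphere × bulk transmissivity 0.75) modulated by a persistent
cloud process (probit-transformed AR(1), lag-1 autocorrelation set by the
archetype); longwave from a Brutsaert-style clear-sky emissivity
increased by cloudiness; precipitation from a daily two-state wet/dry
chain with exponential amounts, split into rain and snow at a fixed air
temperature threshold (boundary → rain); wind as an AR(1) around the
archetype mean; pressure barometric in elevation.

Five archetypes ship as defaults: `subalpine`, `alpine`,
`alpine_late_snow` (colder and snowier, for heavy-snow sequences),
`sub_arctic`, `arctic`. Their numbers are plausible site conditions
chosen once — a subalpine forest near 3000 m, a windy fellfield 400 m
higher, a taiga–tundra pair near 68° N — not fitted values. The
generator reproduces its own parameters (annual precipitation within
15%, long-run mean temperature within 0.5 K, cloud autocorrelation
within 0.1), which the test suite checks.

What it does **not** emulate: weather fronts with coherent
cross-variable structure, rain-on-snow energy, humidity–temperature
covariance beyond cloudiness, interannual climate modes, or real
topographic effects. Passing tests therefore demonstrate mechanism
reproduction under statistically realistic but idealized weather, not
site-level fidelity.

## Vegetation

Species are aggregated into functional groups (evergreen needleleaf
trees, suppressed deciduous trees, shrubs, grasses/sedges) with group
defaults: maximum LAI 4.0 for temperate conifer overstories, 0.5 at the
sparse sub-Arctic forest-tundra site, 1.0 for shrubs and the suppressed
deciduous layer, 1.5 for grasses/sedges. Only the sub-Arctic tree value
is anchored to the study system; the rest are plausible defaults exposed
in config. Leaf area distributes uniformly over the layers each group
spans. Trees and shrubs carry a stem-area index (0.5 / 0.3 / 0.15–0.3)
that intercepts radiation and exchanges heat year-round without
transpiring or photosynthesizing — essential for winter energy exchange
of leafless or sparse canopies.

Non-evergreen groups green up with a 30-day cosine ramp starting at the
first warm snow-free day of spring (floored at day 105 as a photoperiod
constraint) and senesce from day 250; a group whose canopy top is at or
below the snow surface is buried and holds no effective leaf area.
"Understory" means everything below the evergreen-needleleaf overstory,
so the Italian understory counterfactual is its suppressed deciduous
layer alone.

## Canopy–snow–soil physics

Shortwave follows Beer–Lambert on cumulative leaf+stem area with a
single effective extinction coefficient 0.35 (a flat-leaf 0.5 reduced by
needleleaf clumping; with unclumped extinction almost no direct light
reaches a forest floor and the floor–air temperature contrast that
drives the work–gradient relation collapses). Each occupied layer solves
`absorbed = H + LE + net longwave` for its big-leaf temperature by
safeguarded Newton/bisection within ±80 K of local air, to a residual
below 10⁻³ W m⁻²; stomatal resistance is two-state (200 / 5000 s m⁻¹ per
unit LAI) controlled by the dormancy switch. Longwave loss per layer is
scaled by a sky-view factor `exp(−0.8·L_above)`: foliage deep in a
canopy faces foliage at its own temperature, so only sky-exposed layers
lose net longwave.

Within-canopy air is modelled as a massless node at
`T_air + H_canopy·r_a/(ρ c_p)` — the flux-gradient offset of the canopy
sensible heat through the canopy-top aerodynamic resistance — and the
vertical air profile interpolates between the ground-cover surface and
that node. This is a deliberately simple stand-in for a turbulence
closure; it supplies the "climate plants experience" (warm mid-canopy,
cool shaded floor, heat trapping over melting snow) without resolving
turbulent transport, and is flagged as a limitation.

The ground/snow surface solves its own balance against within-canopy
air, with bulk aerodynamic resistance from a neutral log profile
(roughness 0.1·h, displacement 0.67·h, wind floored at 0.5 m s⁻¹), an
under-canopy resistance of 25 s m⁻¹ per unit plant area, and a
bulk-Richardson damping of the conductance under stable stratification
(floored at 0.10) — without which nighttime downward heat fluxes over
snow are grossly overestimated. An insulating litter/moss/organic layer
(0.3 m² K W⁻¹) sits between the skin and the 12-layer explicitly
conducted soil column (zero-flux base, stability-checked explicit
scheme), decoupling the skin so it can warm above the air on sunny days
and cool below it on clear nights.

Snow: fixed bulk density 250 kg m⁻³; albedo decays from 0.85 to 0.60
with a 10-day e-folding age, refreshed by snowfall of at least 2 mm per
half-hour (dustings do not whiten an ageing pack); melt consumes
0.334 MJ kg⁻¹ and is capped by available mass, with surplus energy
passed to the soil. While the pack melts, the thermodynamic surface
temperature — the *soil-surface/snow-interface* temperature used in the
gradient — is exactly 273.15 K; under a non-melting pack it follows the
conduction chain through snow, litter and the top soil layer, capped at
freezing. The snow *surface* temperature (which the canopy air feels) is
solved separately and recorded as `T_snow_surf`.

Blowing-snow scour removes pack above the vegetation trapping height
during wind events (> 6 m s⁻¹, 12-hour e-folding) at sites without a
sheltering overstory (≥ 2 m tall with LAI ≥ 0.25). Woody stems trap snow
to their canopy top; collapsed graminoid mats trap ~3 cm. This is what
separates a wind-scoured fellfield (thin, intermittent pack, warm sunlit
winter skin) from the same forcing under transplanted trees (deep
sheltered pack, late melt) — the snow-accumulation contrast at the heart
of the counterfactual. Scour is an explicit exported-mass term: the snow
budget `ΔSWE = snowfall − melt − scour` closes to 10⁻⁹ mm.

Energy closure `|Rn_abs − LE − H − G − M| ≤ 1 W m⁻²` holds at every step
by construction; the only slack is solver residual (observed worst
≈ 0.02 W m⁻²).

## Carbon exchange and dormancy

Photosynthesis is a rectangular hyperbola in absorbed PAR (45% of
absorbed shortwave, half-saturation 100 W m⁻²) capped at the group's
capacity and scaled by a symmetric temperature response peaking at 20 °C
and vanishing at 0 and 40 °C. Stomata open only when the group is
unburied, inside its phenology window, and the 5-day running mean of the
*within-canopy air at the group's height* exceeds +5 °C. The last rule
is the dormancy switch's key property: a melt-pinned snow surface keeps
canopy air cold, so late-lying snow mechanistically delays the
photosynthetic season of unburied evergreens — the pathway by which
shading-extended snow cover shortens the carbon season.

Above-ground autotrophic respiration is Q₁₀ = 2 on leaf temperature,
referenced to 10 °C, scaling with leaf area; buried leaf area respires
at 10% of its rate at the snowpack temperature, so respiration never
fully switches off — the asymmetry that converts a shortened uptake
season into annual net CO₂ loss. Respiration bases (0.35 µmol m⁻² s⁻¹
for woody groups, 0.3 for graminoids) put above-ground respiration near
40–50% of uptake for a healthy forest. Annual net leaf CO₂ flux is the
time integral of (A − R_a) over a complete 365-day year, positive for
net uptake; no soil heterotrophic respiration is included.

## Feasibility verdicts

A scenario is **infeasible** if its longest run of consecutive days with
negative daily-mean work reaches the threshold (default 14 days,
config-exposed; sensible values 7–28 all separate the feasible meadow
from the trees-added counterfactual in the alpine experiment), or if its
mean annual net leaf CO₂ flux is negative. A feasible scenario whose CO₂
gain falls below its paired existing-vegetation scenario is
**disadvantaged** — the Italian-Alps trees-added case. Daily work is the
arithmetic mean of the 48 half-hourly work values (work first, then
average).

For the matched-bin work comparison (forest versus understory), bins of
the negative gradient count as occupied only if they hold at least 5% of
each scenario's records: at more extreme gradients the forest's residual
records are nights while the open site's are sunny middays, and
conditional means there would compare disjoint conditions.

## Numerical choices

Half-hourly timestep throughout; 365-day non-leap calendar; per-variable
random substreams spawned from one master seed (bit-identical reruns);
leaf and surface solvers bracketed and monotone, aborting with a
timestamped error if a root cannot be bracketed; explicit soil
conduction validated against its stability bound; ΔT = 0 yields work 0
and no case ("neutral"), and zero net heat with nonzero ΔT is excluded
from case counts ("neutral-flux").

## Known limitations

- No soil-water freezing latent heat: winter soil under deep packs cools
  too smoothly and the snow–soil interface stays warm, so at the
  sub-Arctic pair the polar season produces multi-week runs of
  weakly negative work (heat gained against a downward gradient) for
  *all* scenarios, and the existing forest there can trip the
  negative-work threshold. The counterfactual contrast (trees-added runs
  are 2–4× longer) survives, but absolute verdicts at the CA pair should
  be read with this caveat.
- Single bulk sky longwave term; no within-canopy longwave transport
  beyond the sky-view scaling.
- No liquid soil moisture, root uptake or water stress; evaporation uses
  fixed surface resistances.
- The within-canopy air node is diagnostic, not a turbulence closure.
- Vegetation is static between years; no growth, mortality or
  disturbance.
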