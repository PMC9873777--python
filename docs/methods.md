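# Methods

This note documents the model equations, parameter defaults, the synthetic
data the package generates, and the design choices made where the design
was genuinely open. Everything stated here is computed by the code and
exercised by the test suite; no empirical claim below goes beyond what the
tests and the acceptance script themselves produce.

## Soil characterization

Field soil cores parameterize the water bucket through four equations:
gravimetric water % = ((wet − dry)/dry) × 100; bulk density BD = dry weight
/ core volume (g cm⁻³); and volumetric DUL or CLL = gravimetric % × BD.
Per-layer plant-available water is (DUL − CLL) × thickness, with depths in
cm and water in mm (factor 10); profile PAWC is the sum over layers, and
available soil water (ASW) is Σ max(0, θ − CLL) × thickness.

Bundled profiles transcribe the measured Melkassa (10 layers to 160 cm) and
Miesso (7 layers to 180 cm) tables verbatim. The Miesso sums reproduce the
published totals (504 mm PAWC; ASW at sowing 186 vs the printed 185 mm,
within the rounding of two-decimal table entries). The Melkassa table sums
to 219 mm PAWC and 205.5 mm ASW while the source text prints 244 and
232 mm; the tables are shipped as printed and the discrepancy is documented
rather than "corrected" — none of the packaged checks depend on the
irreconcilable Melkassa totals.

Values not present in any table and therefore decided here: the extraction
coefficient kl defaults to 0.08 in the top layer, declining 0.01 per layer
to a floor of 0.02 (a standard declining-with-depth profile); water content
is clamped to [0.5 × CLL, DUL + 0.05] (air-dry to saturation), bounds that
are inert for all bundled profiles.

## Phenology

Daily thermal time uses the mean of the temperature extremes through a
broken-linear response: zero at or below T_base, rising to T_opt − T_base
at T_opt; pre-anthesis it declines linearly to zero at T_max, post-anthesis
it plateaus. Daily means (not sub-daily interpolation) are a documented
simplification relative to the parent model family.

Stage targets (°Cd), Meko / Jigurti: emergence→PI 347 / 450 (derived as
(TLN − 4) × LIR with four seed leaf initials), flag→anthesis 207 / 222,
anthesis→maturity 819 / 801; LAR 63 / 58 °Cd per leaf, LIR 31.5 / 29
(≈ LAR/2; a >15 % departure warns). Two spans the sources leave open are
defaults here: sowing→emergence 40 °Cd and anthesis→start-of-grain-fill
100 °Cd (taken out of the anthesis→maturity total). The PI→flag span is
not an independent parameter: it equals TLN × LAR − TT(emergence→PI), so
leaf appearance and the stage clock stay mutually consistent. Stage
promotion carries surplus °Cd into the next stage, making the accumulated
total exact regardless of step size. Photoperiod response is omitted (none
was detected for these genotypes). Jigurti's phenology uses TLN 19.5 (which
back-solves the printed 450 °Cd), while its leaf-size profile uses the
observed 19 leaves — the two views are deliberately kept as published.

## Canopy

Individual fully expanded leaf area follows
Y = Y₀ exp(a(X−X₀)² + b(X−X₀)³). X₀ and Y₀ come from linear regressions on
total leaf number (Meko: X₀ = 0.83 TLN, Y₀ = 36.9 TLN − 95.2; Jigurti:
X₀ = 0.74 TLN, Y₀ = 13.2 TLN + 318 — the latter with famously poor fit,
used as published). The breadth and skew coefficients are not refitted from
sparse data but fixed to the TLN-dependent forms of the established maize
profile study: a = −0.0344 − 0.000186 TLN, b = 0.00175 − 0.0000449 TLN;
both are overridable and nothing in the packaged checks depends on their
precise values. Blade area from length × width uses shape factors 0.635
(flag leaf) and 0.71 (other leaves).

`fit_profile_regressions` reverses the parameterization: per plant, a
nonlinear least-squares fit with only Y₀ and X₀ free (a, b fixed), then OLS
of X₀ and Y₀ on TLN (X₀ through the origin by default, matching the
published form). Parameter recovery is tested exactly on noise-free
synthetic plants and within 5 % under 1 % area noise.

Leaves appear at one per LAR °Cd up to TLN; each contributes its profile
area × plant density × 10⁻⁴ to green LAI as it appears, scaled by the
day's supply/demand ratio — expansion forgone under stress is never
recovered, though later leaves still expand fully if stress lifts. No new
leaves appear after anthesis. Fractional X₀ is used as-is in the curve;
the "largest leaf" reported to users rounds half-up.

## Water balance

Daily order: (1) irrigation (if managed) and rain, partitioned by the USDA
curve-number relation (CN 80, S = 25400/CN − 254, runoff once rain exceeds
0.2 S), infiltrating top-down with spill past the bottom counted as
drainage; (2) cascading drainage of water above DUL at fraction swcon = 0.3
per day; (3) two-stage soil evaporation — potential = 0.75 × a
Hargreaves-form reference (0.0023 · radn · (T_mean + 17.8) · √(T_max −
T_min)) × (1 − cover), stage 1 up to U = 6 mm since last wetting, stage 2
declining as α(√t+1 − √t) with α = 3.5 mm d⁻⁰·⁵, floored at air-dry in the
top layer; (4) root-zone supply Σ kl (θ − CLL) Δz over rooted layers
(bottom layer pro-rated), demand = potential growth ÷ TE with TE = 9 Pa /
VPD and VPD = 0.75 (svp(T_max) − svp(T_min)) floored at 0.1 kPa;
(5) extraction proportional to kl-weighted availability, never below CLL.
Roots advance 0.1 cm per pre-anthesis °Cd from a 10 cm sowing depth until
flag leaf, capped at profile depth.

Water closure — Δstorage = infiltration + irrigation − drainage −
evaporation − transpiration — is asserted every simulated day at 10⁻⁶ mm
and doubles as the module's continuous self-test. The irrigated fixture
refills the top 60 cm to DUL every 5th day, the practical meaning of
"non-limiting water" without inventing applied depths.

## Growth and grain

Interception is Beer's law with k = 0.4; growth = radiation × interception
× RUE × supply/demand ratio, with RUE 1.25 / 1.65 g MJ⁻¹ (Meko / Jigurti)
applied to total incident shortwave radiation. Potential growth uses the
previous day's canopy. Vegetative growth splits with leaf fraction
f = 1/(1 + k_p N²) (k_p 0.0073 / 0.0106): the published coefficient is a
bare scalar, and this functional form — chosen here, flagged as not the
parent model's verbatim equation — makes the taller landrace's larger
coefficient yield a larger stem fraction, as its height requires. After
flag leaf all growth goes to stem or grain.

Grain number = (mean plant growth rate over PI→start-of-grain-fill, g
plant⁻¹ d⁻¹) ÷ grain number factor (0.00083 / 0.0014 g per grain) ×
density; under the rate interpretation the factors give the agronomically
plausible ~10³ grains per plant, and the landrace's larger factor yields
fewer grains per unit growth — the source of its sink limitation and lower
harvest index. Daily grain demand is number × max kernel mass × Δ°Cd /
fill-span, met from current growth first, then from stem up to a cumulative
20 % of stem mass at anthesis; surplus growth accrues to stem (the
"stem gain during fill" signature of a sink-limited tall landrace). Kernel
mass caps (0.028 / 0.032 g) are decided defaults — no packaged numeric
target depends on them. Carbon closure (pools sum = Σ daily growth at
10⁻⁶ g m⁻²) is asserted daily.

Senescence: after anthesis green LAI declines to 85 % of the anthesis peak
at mid-fill and 70 % at maturity (age component); drought senescence keys
off the profile's remaining fraction of plant-available water (FASW) —
below 0.25 of capacity, up to 20 % of green LAI dies per day, scaling with
depletion depth. FASW rather than the instantaneous supply/demand ratio
drives leaf death because the ratio is coupled to canopy size: a shrinking
canopy lowers demand, relaxes its own stress signal and stabilizes at a
small residual LAI, which contradicts the observed complete senescence of
the late landrace under terminal drought. Depletion of the water store is
also the causal account given for that observation. The whole profile (not
the rooted zone) supplies the signal so a seedling with a shallow root
front is not condemned by a dry topsoil. Leaf mass moves to dead leaf in
proportion to area lost; above-ground mass is conserved.

A crop whose supply/demand ratio is zero for 15 consecutive pre-anthesis
days is recorded as failed (complete crop failure being a normal feature of
these systems); failed seasons carry zero yield and biomass plus a flag.

## Synthetic weather

A WGEN-family generator driven by authored monthly normals: rainfall
occurrence is a two-state Markov chain with p₁₁ = min(0.8, 2 p₀₁) and p₀₁
solved so the stationary wet fraction matches the normal's wet days (each
month's first day draws from the stationary probability, keeping expected
wet days unbiased across month boundaries); wet-day amounts are Gamma
(shape 0.8, mean = monthly total / wet days); temperature = smoothly
interpolated monthly means + AR(1) anomaly (σ 1.5 °C, ρ 0.6), with wet-day
maxima 2 °C cooler, mean-compensated so long-run monthly means converge to
the normals; radiation follows the extraterrestrial seasonal envelope for
the latitude scaled to the monthly normal, −25 % on wet days, floored at
3 MJ m⁻². One seeded NumPy generator feeds every stream, so equal seeds
give identical series.

Four presets are bundled: a unimodal Tigray-like climate (single Jun–Sep
wet season holding ≥ 70 % of ~600 mm), a bimodal eastern-Oromia-like
climate (Mar–Apr and Jul–Sep peaks around a drier May–Jun, ~700 mm), and
two experimental-site analogues. The normals are authored structural
approximations for testing — not station records — and the long-term
generated statistics (monthly rain within 15 %, monthly temperature within
0.5 °C at 100 years, inter-annual rainfall CV ≈ 0.19) are verified by the
suite. What the generator does **not** emulate: multi-day synoptic storm
persistence beyond first-order, year-scale rainfall regimes (ENSO-like
clustering), temperature–radiation covariance beyond the wet-day rules, and
any specific historical year. Passing tests therefore demonstrate the
model's behaviour across a realistic envelope of seasons, not a
reproduction of the station records behind the original analysis.

The dryland validation fixture uses a deliberately below-average season
variant of the Miesso preset (main-season rains curtailed from September)
because the experiment it emulates was defined by terminal water
limitation; the long-term preset's average year is too wet to produce that
condition.

## Simulation and risk experiment

`run_season` executes the daily order (water, phenology, potential growth,
stress, actual growth and extraction, partitioning/grain fill, canopy and
senescence, root advance, closure assertions) from the start of the
weather; before sowing only the bare-soil water balance runs, so
pre-season rains wet the profile before a trigger is evaluated. Sowing is
an explicit date or the first day in a configured window whose trailing
rain rule is satisfied; the lookback never reaches before the window opens.
Defaults: early strategy — window Apr 1–May 20, ≥ 3 events of ≥ 5 mm and
≥ 25 mm total in 15 days (the traditional "after 3–4 rain showers"); late
strategy — window Jul 1–31, one rain of ≥ 15 mm in 5 days ("after a
planting rain"). At the unimodal site the early window extends to Jun 30,
since a single-wet-season climate delivers its "initial rains" with the
June onset; with an April-only window almost every unimodal year would
record no sowing opportunity, which matches neither practice nor the
regional result being tested.

The paired experiment gives both strategies the same weather realization
per year, resets the soil each season to 20 % of PAWC on 1 January (no
carryover by default; a carryover switch exists), and records failed
seasons as zeros with flags — risk is the point of the analysis. Season
quality for tercile classification is proxied by the early strategy's
total-biomass rank (configurable; annual rainfall is the natural
alternative). Trade-off statistics: OLS by explicit normal equations
(cross-checked against an independent least-squares route in tests) and
percentiles by linear interpolation between order statistics.

Long-term runs use 30 years (bimodal) and 50 years (unimodal) — enough for
stable tercile means at roughly a second of runtime per 30 seasons — on
generic 100 cm profiles holding 120 / 132 mm PAWC, the catalogued values
for the representative unimodal and bimodal stations.

## Known limitations

- The growth coefficient equations (partitioning form, grain-number rate
  interpretation, kernel caps) are documented stand-ins whose tested
  contract is directional behaviour, not magnitudes from the parent model.
- With the published thermal-time targets the two cultivars differ by only
  ~8 % in season-total °Cd, so the "late" landrace matures about two weeks
  after the "early" variety under any constant climate; traditional
  April-to-November landrace cycles are not reproducible from those
  targets, which compresses the early strategy's biomass advantage in the
  long-term experiment.
- At a 132 mm PAWC bimodal site, a full canopy's transpiration demand
  (~5 mm d⁻¹) across the ~45-day May–Jun gap exceeds any plausible store,
  so mid-season canopy loss in the early system is structural, not a
  parameter artifact.
- No nitrogen or phosphorus dynamics (experiments were fertilized to
  non-limiting), no tillering, lodging, pests, photoperiod, or replanting
  logic; biomass is above-ground only.
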