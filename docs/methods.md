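# Methods

This note documents the models, the synthetic data-generating processes,
the numerical choices, and the limits of what the test suite demonstrates.

## 1. The choice model

Landowner behavior is a two-level nested logit. Nests are the harvest
options {clearcut, partialcut, nocut}; sub-nests are the replant forest
types (for cuts) and the natural outcomes {grow, fire, insects, disease}
(for no cut). The inclusive value is the standard log-sum
I_k = log Σ_j exp(V_{j|k}/λ_k), computed max-shifted so utilities of
magnitude 10³ stay finite; λ_k ∈ (0, 1] is the dissimilarity coefficient
and λ = 1 collapses the model to a flat multinomial logit over (k, j)
composites (verified to 1e-10 in tests).

Utility specifications:

- **Harvest level.** V_clear = α_c0 + α_rev(p·v − τ_c),
  V_partial = α_p0 + α_rev(φ·p·v − τ_p),
  V_nocut = α_grow·[p·(V(a+10) − V(a)) + carbon accrual], with the no-cut
  intercept fixed at 0 for identification. p is the own-type timber price,
  v standing volume, τ the harvest carbon tax, φ the partial-cut removal
  fraction (default 0.4, configurable — no canonical value exists, so a
  moderate thinning intensity was chosen once). The linear-in-revenue form
  is the minimal specification consistent with a harvest value driven by
  current revenue and forgone revenue growth. Climate reaches the harvest
  level only through the inclusive values of the sub-nests.
- **Replant level.** V_j = β_j0 + β_rent·rent_j^eff + β_j·climate + β_je·elev
  over the plot's viable types, with the Douglas-fir intercept and slopes
  fixed at 0 (reference type). rent^eff is the carbon-augmented annual rent.
- **Disturbance level.** Multinomial logit in (1, volume, 4 climate
  normals, elevation) with "grow" as the zero-utility reference.

**Nest structure of the partial cut.** By default a partial cut keeps the
current forest type: its sub-nest is the degenerate {keep} outcome and its
λ, being structurally unidentified (the inclusive value is identically 0),
is fixed at 1 and excluded from estimation. A configuration switch
(`ChoiceConfig.partial_replant`) instead gives the partial cut the same
replant sub-nest as the clear cut; parameter-recovery exercises use this
switch so all three λ are identified. The landscape transition for a
partial cut removes a fraction φ of volume and never changes the type in
either mode; the switch alters only the utility structure.

## 2. Economics

Volume and stand carbon follow Chapman–Richards curves
V(a) = v_max(1 − e^(−ka))^θ. Timber profitability is annualized with the
Faustmann land expectation value; the optimal rotation is found by a coarse
600-point bracket over [0.5, 300] yr followed by bounded continuous
refinement, and is cross-checked in tests against an independent exhaustive
grid search (tolerance 1 %/1 yr). When no rotation yields a positive land
value the rent is 0 and the rotation flagged undefined. The default
discount rate is 5 %/yr with zero planting cost; regional rents equal the
per-type Faustmann rent of the ecoregion's (NPP-adjusted) curve, which is
what a "regional average" reduces to when curves are regional.

Carbon policy: a standing rent price × C(T*)/T* — the mean annual carbon
increment over the replanted type's timber-optimal rotation, keeping carbon
and timber on one rotation concept (if timber is unprofitable, the rotation
maximizing C(T)/T is used) — plus a harvest tax
price × release_fraction × C(age), applied fully to clear cuts and scaled
by φ for partial cuts. release_fraction defaults to 0.5 (half of stand
carbon released at harvest, half persisting in products), configurable. By
default the no-cut option also accrues the decade's carbon value on the
standing stand (`ChoiceConfig.carbon_on_standing`), so the policy pays
standing and replanted stands through one effective-rent mechanism; the
toggle exists because either design is defensible. Effective rent is the
sum of timber and carbon rents — a $1 carbon payment moves utilities
exactly as $1 of timber rent. Carbon prices follow right-continuous step
schedules; the three shipped schedules are $15/50/80, $15/30/50 and
$30/60/100 per tC starting in 2020/2050/2080.

Productivity change enters as per-decade NPP multipliers on the curve
asymptotes, by forest type × ecoregion: Douglas-fir declines linearly
through 2100 in proportion to ecoregion warmth (up to −15 % in the warmest
region), the other non-pine conifers at half that rate, and hardwoods and
pine stay at 1.0. Rents are re-annualized from the adjusted curves every
decade (a toggle-free design choice; freezing them at 2020 values is a
one-line change in `effective_rents`).

## 3. Synthetic data

The generators define the study conditions; all are pure functions of
settings and a seed.

- **Plots.** n plots (default scale ~6,800; most tests use 800–2,000)
  scattered on a 100×100 grid, partitioned into contiguous
  nearest-centroid ecoregions (default 12). Growing-season mean temperature
  rises west→east from 11 to 20 °C and growing-season precipitation falls
  from ~1150 to ~250 mm, each plus independent noise (1.3 °C, 110 mm);
  August maximum and December minimum are offset from the mean with
  truncated noise so aug_tmax ≥ gs_tmean ≥ dec_tmin always holds. Forest
  types are drawn from a climate-dependent softmax (cool/wet → Douglas-fir
  and hemlock/spruce; warm/dry → pine and hardwoods), giving a Douglas-fir
  dominant landscape (~40 %). Viable replant sets come from rectangular
  climatic envelopes in (gs_tmean, gs_precip), inflated by a tolerance
  (0.5 °C, 50 mm), with the current type always included and the
  nearest-envelope alternative added when needed so every plot has ≥ 2
  options. Stand ages are uniform on 5–90 yr and volumes follow the type's
  yield curve with lognormal noise. Plot area is a constant 100 ha
  (configurable); only relative area results are meaningful.
- **Climate trajectories.** Additive per-decade deltas, uniform across
  ecoregions: zero for the baseline; linear warming/drying otherwise,
  defaulting to +4 °C (all three temperature normals) and −80 mm by 2100 —
  a stylized high-emissions trajectory.
- **Species.** Default 8 amphibians, 12 birds, 15 mammals (35 candidates).
  Ranges are L2 balls of plots around a random centroid with broadly drawn
  sizes so some candidates fail the range-size criterion; binary
  associations are drawn from taxon templates (amphibians biased toward wet
  conifer types; birds closest to indifferent), and small probabilities of
  the old-growth-specialist (0.15) and non-forest-associated (0.1) flags
  give the filter work. The filter retains species that are forest
  associated, neither generalists (all-1) nor non-users (all-0), have
  strictly more than 500 in-range plots, and are not old-growth
  specialists; it is idempotent.
- **"True" parameters.** Drawn from documented ranges with the sign
  structure the analysis presupposes: positive rent slope; hardwood and
  pine temperature slopes positive (and precipitation slopes negative)
  against the Douglas-fir reference, so warmer/drier climates shift
  replanting away from Douglas-fir; λ ∈ [0.5, 0.9] ⊂ [0.3, 1.0]; fire odds
  increasing in August maximum temperature. Replant intercepts are anchored
  at a cool/wet reference climate (900 mm, 13 °C) so that each type sits a
  drawn amount below Douglas-fir there and the climate slopes act on
  departures from it; harvest intercepts are set so decadal clear-cut
  probabilities land in a realistic 15–25 % band. These levels were fixed
  once at design time.

## 4. Estimation

Full-information maximum likelihood over all ~59 coefficients.
Numerics: covariates are standardized internally — an exact linear
re-parameterisation of the likelihood (per-alternative intercepts absorb
the centering; the no-cut revenue-growth term is scaled but not centered
because that nest has no intercept) — and estimates and standard errors are
mapped back to the natural scale through a delta-method Jacobian. Each λ is
estimated through a logistic transform onto (0.05, 1.0), bounded away from
0 to avoid boundary pathologies, with box bounds on the transformed scale
so a λ pinned near 1 terminates cleanly rather than crawling; a pinned λ
can carry a near-zero natural-scale standard error (the transform's
derivative vanishes), which is reported as-is. The score is analytic
(validated against numeric differentiation to ~1e-7) and optimization is
L-BFGS-B; standard errors come from the inverse numerical Hessian of the
analytic score. A sequential fallback (within-nest multinomial logits, then
the nest level) provides starting values when the cold start stalls.
Recovery at 20,000 records places ≥ 95 % of coefficients within 3
estimated standard errors of truth across 20 replications.

## 5. Simulation and habitat accounting

Decisions are simulated at 2020…2090 with states recorded through 2100
(the post-2090 growth decade). Transitions: clear-cut → replanted type at
age 0; partial cut → volume × (1 − φ); no-cut + grow → age + 10 with
volume reset to the NPP-adjusted yield curve; disturbance → same-type
natural regeneration at age 0 (the post-disturbance fate is not otherwise
pinned down; same-type regeneration is the conservative choice and a
replant-choice variant would hang off the same transition table). One
decision per plot per decade; no land-use conversion out of forestry and no
spatial contagion of disturbance. Replicates use substreams
`default_rng([master_seed, r])` consuming one uniform per plot per decade
in fixed order, so ensembles across scenarios are coupled by common random
numbers and scenario differences are free of sampling noise at matched
replicates.

Habitat accounting counts in-range plots whose current type a species
uses, for the whole range and for each ecoregion with ≥ 50 in-range plots.
"Through 2100" is read as the end-state (2100) difference, not a time
average. Percent change versus baseline divides by the baseline 2100 mean
and is flagged undefined (NaN) when that mean is zero. Projection
intervals average a species metric over the n_tail replicates with the
greatest and least landscape-wide Douglas-fir plot-count loss (absolute
in-scope count, ties broken by replicate index). Significance of a change
("ns") is operationalized as the paired across-replicate 95 % interval of
the count difference covering zero — a definition chosen here, since no
standard one exists for this construct. Marginal decadal areas sum
per-species (scenario − baseline) area differences decade over decade; by
construction they telescope to the cumulative 2100 change (verified to
1e-9).

## 6. Problem sizes and what the tests show

Default test and acceptance sizes are 800–5,000 plots, 200-replicate
ensembles, and 20,000-record estimation samples — scaled-down study
conditions chosen so the full pipeline exercises every code path at
desk scale. The synthetic landscape reproduces the *structure* the analysis
assumes (a monotone climate gradient, climate-sorted forest types,
climate-sensitive preferences) but not the real region's geography,
spatial autocorrelation, FIA plot expansion factors, real species ranges,
or estimated coefficient magnitudes. Passing tests therefore demonstrate
correctness of the algebra, the estimator, the simulator and the
accounting, and the qualitative direction of the system's response
(warming and carbon pricing shift the landscape from Douglas-fir toward
hardwoods, with more species-ecoregion habitat losses than gains); they do
not validate any real-world magnitude.

## Known limitations

- Landowners are myopic per-period choosers; no forward-looking dynamic
  programming.
- Timber prices and productivity trajectories are exogenous; no market
  equilibrium feedback.
- Species ranges are static (no range-shift modeling), and habitat is
  "potential" — forest-type suitability, not occupancy.
- The ns rule and the carbon-accrual-on-standing-stands design are
  reasonable but non-unique choices; both are isolated behind switches or
  single functions.
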