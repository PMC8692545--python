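# Methods

## Model overview

`isoarctic` reduces the surface Arctic Ocean to eight well-mixed boxes of
100 m depth: three Pacific-influenced (Chukchi, Beaufort Gyre, Canadian
Archipelago), four Atlantic-sector (Barents, East Greenland, Labrador,
Irminger) and one interior (Siberian shelves). Each box carries salinity,
NO₃, PO₄ and particulate organic nitrogen (PON); NO₃ and PON are stored as
(total N, ¹⁵N) mass pairs, so conservative mixing is exact addition and both
mass budgets are auditable to machine precision. δ¹⁵N is a derived view,
`δ = (R/R_std − 1)·1000` with `R = ¹⁵N/¹⁴N` and `R_std = 0.0036765`
(atmospheric N₂; any constant cancels in round trips).

### Process order within a sub-step

Integration is forward Euler with monthly sub-steps; within each sub-step the
processes apply in a fixed order, each flux-limited to the mass available:

1. **Lateral exchange.** Each box relaxes toward Pacific and Atlantic
   endmember water at its scenario inflow rates, and exchanges pairwise with
   configured neighbour boxes (conservative volume swaps). The Atlantic
   endmember additionally carries an anthropogenic N_r anomaly (below).
2. **Vertical resupply.** Relaxation toward a per-box subsurface reservoir
   (nutrient-rich, with a fixed deep δ¹⁵N_NO₃); particles mix downward out of
   the box (deep PON ≈ 0).
3. **Assimilation.** Uptake `U = μ_max · NO₃/(NO₃+k_NO₃) · L · NO₃ · dt`,
   with light `L = I(month) · (1 − ice)^p`. `I(month)` is a polar-night
   insolation factor (zero November–February, peaking in June): without it,
   winter production erases the seasonal drawdown–enrichment cycle that the
   isotope dynamics ride on. Uptake transfers NO₃→PON with kinetic
   fractionation at the *expressed* ε = ε_assim·NO₃/(NO₃+k_ε), which
   reproduces the suppression of the ¹⁴N preference as nitrate is exhausted.
   PO₄ is drawn down at the Redfield ratio (16 N : 1 P).
4. **PON loss.** A fraction of PON (turnover `loss_rate`) is recycled to NO₃
   in-box without fractionation (the implicit closure standing in for
   ammonium, nitrification, zooplankton and DOM) and a fraction is exported.
5. **Benthic processing.** Exported PON remineralises at the seafloor;
   `sed_denit_frac` of it is removed by sedimentary denitrification with
   kinetic fractionation ε_sed (the removed flux is isotopically light); of
   the enriched residual, `benthic_return_frac` returns to the box NO₃ and
   the rest is buried. This is what lets denitrification enrich the nitrate
   the water column sees while remaining a net nitrogen sink.
6. **External inputs.** Riverine nitrate at δ = +2‰ and atmospheric N_r
   deposition at δ = −4‰ are added to NO₃.

The instantaneous-product convention (`R_flux = R_pool·(1 − ε/1000)`) makes
closed-system consumption converge to the Rayleigh form `δ = δ₀ − ε·ln f` as
sub-steps shrink; the residual ~0.006‰ offset at f = 0.5 between the exact
ratio-space ODE solution and the first-order Rayleigh formula is far inside
the 0.05‰ test tolerance.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ε_assim | 5 | ‰ | assimilation fractionation |
| ε_sed | 3 | ‰ | sedimentary-denitrification fractionation |
| k_NO₃ | 1.0 | mmol m⁻³ | uptake half-saturation |
| k_ε | 1.0 | mmol m⁻³ | fractionation-expression half-saturation |
| μ_max | 14 | yr⁻¹ | maximum specific production |
| p (`light_ice_exponent`) | 3 | – | ice shading non-linearity |
| loss_rate | 10 | yr⁻¹ | PON turnover |
| recycle / export | 0.7 / 0.3 | – | fate of PON loss |
| sed_denit_frac | 0.25 | – | exported N removed by denitrification |
| benthic_return_frac | 0.5 | – | post-denitrification residual returned to NO₃ |
| δ_river / δ_dep | +2 / −4 | ‰ | source signatures |

`k_ε = 1.0 mmol m⁻³` (rather than a smaller value) is what lets the expressed
fractionation collapse as late-century nitrate in the Beaufort Gyre falls
toward ~1 mmol m⁻³, producing the rise-then-fall of high-Arctic δ¹⁵N_NO₃
after mid-century; the suppression phenomenon is physically established but
its functional form is a modelling choice.

## Scenario forcings

All drivers are **deterministic**: trends plus sums of sinusoids with
driver-specific incommensurate periods and box-specific phases stand in for
inter-annual weather, so every run is bit-reproducible without seeds. The
spectral separation is deliberate — each statistical predictor (salinity,
N*, POM) receives an independent variance source (freshwater cycle, river
nitrogen pulses, ice/light variability), which is what keeps the per-box
variance inflation factors below the 3.0 screen while the shared
multi-decadal trends remain.

* **Deposition** follows the anchored global schedule (11 Tg N yr⁻¹ before
  1851; anchors 1850/2000/2030/2050/2100 = 11/39/41/43/44 Tg N yr⁻¹; 60% of
  the 1850→2000 rise after 1950, implemented as two linear sub-segments
  continuous at 1950). Regional fluxes are `weight × global total / area`,
  with weights placing ~7 mmol N m⁻² yr⁻¹ (≈ 0.1 g N m⁻² yr⁻¹) of modern
  increment in the Atlantic-sector seas.
* **Far-field N_r.** Deposition south of the domain accumulates in Atlantic
  inflow water as a nitrate anomaly at δ = −4‰, scaled to the deposition
  ramp (3.4 mmol m⁻³ at year-2000 deposition). This indirect pathway, not
  the direct local flux, carries most of the Atlantic-sector δ¹⁵N decline;
  it also raises N*, which is why N* attributes that decline.
* **Sea ice** declines linearly over 1970–2019 (reanalysis) or along a
  logistic trajectory to near-zero summer ice by 2081–2100 (emissions);
  annual-mean area-weighted loss in the emissions run is ~71% of the
  1986–2005 level.
* **Toggles**: `no_anthropogenic_deposition` pins deposition (and the
  far-field anomaly) at preindustrial values; `no_assimilation_fractionation`
  sets ε_assim = 0; `fixed_rivers` holds river fluxes at era-start values.

## Calibration

The calibrated quantities are the endmember δ¹⁵N contrast (2.9‰, inside the
observed 2–3‰ window), μ_max, the light exponent, per-box ice baselines and
losses, exchange rates and river fluxes, and the far-field N_r scale. They
were tuned once, by hand against the era metrics printed by
`scripts/calibrate.py` — baseline (1970–1990) sector δ¹⁵N_POM gradient ≈ 2‰,
modern (2009–2019) ≈ 4‰, all eight boxes passing the VIF screen with the
expected best predictors, ≥50% future ice loss and ≥400% high-Arctic POM
increase — and then frozen as package defaults. The Pacific-influenced boxes
are configured strongly ice-covered and stratified at era start, so
production there is light-limited and low; ice loss then drives a large
relative production increase, seasonal nitrate drawdown, and isotopic
enrichment of both nitrate and particles. The Atlantic-sector boxes are
vigorously flushed, so their δ¹⁵N is pinned near the (increasingly
N_r-contaminated) inflow signature.

## Statistical procedure

Per cell: predictors standardised to mean 0, sd 1 (denominator n−1);
VIF = 1/(1−R²) computed once on the full predictor set, any value > 3.0
excludes the cell; OLS by exact least squares with
`AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, `k = p + 2` (intercept and
residual variance counted), RSS floored at `1e−12·Σy²` on exact fits. If no
candidate model beats the intercept-only null, the cell is non-significant.
Otherwise the confidence set is the models below the null with ΔAICc < 4
from the best; the null itself joins the averaging when it falls inside the
window — its zero coefficients shrink weakly supported effects, and this is
what holds the false-positive rate at n = 50 under ~7% (versus ~14% when the
null is excluded) while leaving CI coverage at ~95%. Averaging is full-model
(absent predictors contribute 0) with Burnham–Anderson unconditional
standard errors `se_u = Σ wᵢ·sqrt(varᵢ + (βᵢ − β̄)²)` and normal-quantile
95% CIs (the t-correction is immaterial at n = 50). Significance is CI
excluding zero; the best predictor is the significant effect of largest
magnitude. Exclusions and skip reasons are always materialised in the
output table.

## Synthetic known-truth cells

`synthetic.generate` draws AR(1) predictor series (φ = 0.5 by default —
multi-decadal persistence, not white noise), standardises them, and forms
the response as Σβ·x + Gaussian noise, so the configured β are exact
standardised effects. A configurable fraction of cells receives a
near-duplicate predictor pair (sd 0.01 perturbation) to exercise the
collinearity screen. What these cells do **not** emulate: spatial covariance
between cells, non-Gaussian noise, predictor measurement error, and
autocorrelated residuals — so passing coverage/type-I tests demonstrates
the procedure's calibration under its own assumptions, not robustness to
violations of them.

## Numerical choices and degenerate inputs

* Forward Euler with per-process flux limiting (each sink capped at 90% of
  its source per sub-step) instead of a higher-order integrator:
  transparency and an exactly auditable budget matter more here than order
  of accuracy. Budgets (total N and ¹⁵N separately) close to ≤ 1e−6 relative
  error every simulated year, enforced at run time.
* δ values are reported only where the parent pool exceeds 1e−6 mmol m⁻³;
  below the floor they are masked (NaN), never extrapolated.
* Annual δ means are computed from annual-mean (total, heavy) masses, i.e.
  concentration-weighted, which keeps them consistent with mass budgets.
* Empty pools raise an explicit undefined-delta error rather than returning
  a sentinel; overdrawing a pool raises rather than clamping.
* Spin-up (default 50 years under first-year forcing) is discarded before
  the scenario era; the default run sizes — 8 boxes × 12 sub-steps × 50–300
  years — keep a full scenario under three seconds.

## Known limitations

* Eight boxes cannot resolve sub-regional structure (e.g. the northern vs
  southern Barents Sea) or the observed post-1990s Pacific-inflow increase,
  which is deliberately not represented.
* The NH₄/nitrification/DOM/zooplankton web is collapsed into a single
  non-fractionating recycling fraction; processes with their own
  fractionation (water-column denitrification, N₂ fixation, excretion) are
  absent.
* Sea ice is forcing, not state: no thermodynamic feedback, no under-ice
  blooms.
* The freshwater salinity tendency is a prescribed cycle, not a budget; and
  rivers deliver nitrogen only (no phosphorus), so long isolated-box runs
  can become phosphorus-starved — a configuration the scenario geographies
  avoid but idealised experiments must handle (see
  `experiments.source_signature_steady_state`).
* The attribution applies no spatial-autocorrelation or multiple-testing
  correction across cells; effects are per-cell statements.
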