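# isoarctic

A reduced, isotope-enabled nitrogen-cycle simulator for the changing Arctic
Ocean, together with the statistical machinery to attribute trends in its
nitrogen isoscape to their drivers.

## The problem

The nitrogen isotope ratio of particulate organic matter (δ¹⁵N_POM) at the
base of Arctic food webs — the *isoscape* — is shifting as the Arctic loses
sea ice, Atlantic water pushes north, and isotopically light anthropogenic
reactive nitrogen (N_r, δ¹⁵N ≈ −4‰) rains onto the subpolar seas. Anyone
using δ¹⁵N to place Arctic consumers in a food web needs to know how fast and
why the baseline itself is moving. This package provides:

* **A deterministic eight-box surface model** (Chukchi, Beaufort Gyre,
  Canadian Archipelago, Siberian shelves, Barents, East Greenland, Labrador,
  Irminger; 100 m deep) tracking salinity, NO₃, PO₄ and particulate organic
  nitrogen, with ¹⁵N carried through every flux. Boxes exchange with Pacific
  and Atlantic endmember waters (Pacific δ¹⁵N_NO₃ elevated by 2–3‰,
  N*-negative; Atlantic N*-positive), receive nitrate from below, from rivers
  (δ = +2‰) and from an anchored anthropogenic deposition schedule
  (11 Tg N yr⁻¹ preindustrially; anchors at 1850/2000/2030/2050/2100 with 60%
  of the 1850→2000 rise after 1950; δ = −4‰), and cycle nitrogen through
  assimilation, recycling, export, sedimentary denitrification and burial.
* **Isotope physics**: kinetic fractionation acts on the instantaneous
  product, `R_flux = R_pool (1 − ε/1000)`, with ε ≈ 5‰ for phytoplankton
  assimilation (suppressed as nitrate runs out, via
  ε·NO₃/(NO₃ + k_ε)) and ε ≈ 3‰ for sedimentary denitrification. Closed-box
  consumption therefore follows the Rayleigh relation δ = δ₀ − ε·ln f, which
  the test suite uses as an analytic oracle.
* **The attribution procedure**: per cell (grid cell or box), standardise the
  predictors salinity, N* (= NO₃ − 16·PO₄) and POM; drop cells with variance
  inflation factors above 3.0; fit all candidate OLS models (8 subsets
  historically, 4 in the future mode where salinity is collinear with N*);
  select against the intercept-only null by AICc; average coefficients over
  the ΔAICc < 4 confidence set with Akaike weights and Burnham–Anderson
  unconditional standard errors; flag effects whose 95% CI excludes zero.

Scenarios: `control` (preindustrial, flat drivers plus deterministic
multi-year oscillations), `reanalysis` (historical, 1970–2019) and
`emissions` (strong warming, 1850–2100), plus factorial toggles
(`no_anthropogenic_deposition`, `no_assimilation_fractionation`,
`fixed_rivers`). Everything is deterministic: no seeds are needed to
reproduce a simulation bit-for-bit.

## Worked example

```python
import isoarctic as ia
from isoarctic.diagnostics import sector_gradient
from isoarctic.attribution import attribute_cells, attribution_table
from isoarctic.io import cells_from_trajectory

forcing = ia.build_scenario("reanalysis")
traj = ia.run(forcing)                       # 1970-2019, monthly sub-steps

for period in [(1970, 1990), (2009, 2019)]:
    g = sector_gradient(traj, "d15n_pom", period)
    print(f"d15N_POM sector gradient {period[0]}-{period[1]}: {g:.2f} permil")

results = attribute_cells(cells_from_trajectory(traj.data), mode="reanalysis")
print(attribution_table(results, mode="reanalysis")[
    ["cell_id", "status", "best_predictor", "nstar_estimate", "pom_estimate"]
].round(3).to_string(index=False))
```

prints

```
d15N_POM sector gradient 1970-1990: 1.99 permil
d15N_POM sector gradient 2009-2019: 3.65 permil
             cell_id    status best_predictor  nstar_estimate  pom_estimate
             barents estimated          nstar          -0.262         0.131
       beaufort_gyre estimated            pom          -0.252         0.440
canadian_archipelago estimated            pom          -0.084         0.339
             chukchi estimated            pom          -0.143         0.416
      east_greenland estimated          nstar          -0.236         0.100
            irminger estimated          nstar          -0.252        -0.003
            labrador estimated          nstar          -0.258         0.060
    siberian_shelves estimated            pom          -0.067         0.212
```

The Pacific-minus-Atlantic δ¹⁵N_POM gradient roughly doubles from ~2‰ to
~4‰ over the historical era. The attribution reads the mechanism off the
time series: in the Pacific-influenced high Arctic the best predictor is POM
with a positive standardised effect (ice loss → more primary production →
isotopically enriched nitrate and particles), while in the Atlantic-sector
seas N* carries a significant negative effect (encroaching Atlantic water
loaded with isotopically light anthropogenic N_r raises N* while lowering
δ¹⁵N_POM).

The same tools are available from a shell:

```bash
isoarctic simulate --scenario reanalysis --out runs/hist
isoarctic attribute --input runs/hist/trajectory.csv --mode reanalysis --out runs/attr
isoarctic report --run-dir runs/hist
isoarctic generate-synthetic --n-cells 100 --beta 0 -0.8 0.8 --out runs/synth
```

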