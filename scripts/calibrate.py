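#!/usr/bin/env python
"""Calibration report for the current default configuration.

The box model is calibrated by hand against a small set of era metrics:
the control/baseline sector gradient (~2 permil), the modern gradient
(~4 permil), the per-box VIF screen (every default box should pass), the
sign structure of the attributed effects, and the future ice/POM changes.
This script recomputes those metrics so that any configuration change can
be checked at a glance; it performs no optimisation itself.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import isoarctic as ia
from isoarctic.attribution import attribute_cells
from isoarctic.boxmodel import nitrogen_budget
from isoarctic.diagnostics import decadal_mean, sector_gradient
from isoarctic.io import cells_from_trajectory


def main() -> int:
    hist = ia.run(ia.build_scenario("reanalysis"))
    nitrogen_budget(hist)
    print("historical (1970-2019)")
    for var in ("d15n_pom", "d15n_no3"):
        g0 = sector_gradient(hist, var, (1970, 1990))
        g1 = sector_gradient(hist, var, (2009, 2019))
        print(f"  {var} sector gradient: {g0:+.2f} -> {g1:+.2f} permil")

    print("  per-box attribution (VIF screen + best predictor):")
    for r in attribute_cells(cells_from_trajectory(hist.data), "reanalysis"):
        vif_max = max(r.vifs.values()) if r.vifs else float("nan")
        print(f"    {r.cell_id:22s} {r.status:18s} best={str(r.best_predictor):8s}"
              f" max VIF={vif_max:.1f}")

    fut = ia.run(ia.build_scenario("emissions"))
    nitrogen_budget(fut)
    pac = fut.boxes_in_sector("pacific_influenced")
    ice0 = decadal_mean(fut, "ice", (1986, 2005))
    ice1 = decadal_mean(fut, "ice", (2081, 2100))
    pon0 = decadal_mean(fut, "pon", (1986, 2005), pac)
    pon1 = decadal_mean(fut, "pon", (2081, 2100), pac)
    bg = fut.pivot("d15n_no3")["beaufort_gyre"]
    print("future (1850-2100, strong warming)")
    print(f"  annual-mean ice loss 1986-2005 -> 2081-2100: "
          f"{100 * (ice0 - ice1) / ice0:.1f}%")
    print(f"  high-Arctic PON change: +{100 * (pon1 / pon0 - 1):.0f}%")
    print(f"  Beaufort d15N_NO3: peak {bg.max():.2f} permil in {int(bg.idxmax())}, "
          f"{bg.loc[2100]:.2f} by 2100")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
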