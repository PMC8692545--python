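"""Reduced isotope-enabled nitrogen-cycle simulator.

Eight Arctic surface boxes (100 m deep by default) exchange laterally with
idealised Pacific and Atlantic endmember waters and with configured neighbour
boxes, receive nitrate from below (vertical mixing toward a subsurface
reservoir), from rivers (δ15N = +2‰) and from atmospheric deposition
(δ15N = −4‰), and cycle nitrogen through phytoplankton assimilation
(fractionating at ε ≈ 5‰, suppressed as nitrate is exhausted), recycling,
export, sedimentary denitrification (ε ≈ 3‰ on the benthic return path) and
burial.  State tracers are salinity, NO3, PO4 and particulate organic
nitrogen (PON); NO3 and PON carry heavy-isotope submasses.

Integration is forward Euler with monthly sub-steps and per-process flux
limiting; every flux is logged so the annual nitrogen budget (total N and
15N separately) closes to floating-point precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .isotope import (
    IsotopePair,
    R_STD_AIR,
    delta_of,
    fractionating_flux,
    pool_of,
)
from .forcing import ForcingSeries, RegionConfig, DEFAULT_REGIONS

__all__ = [
    "BoxGeometry",
    "BoxState",
    "ModelParams",
    "Trajectory",
    "IntegrationError",
    "BudgetViolationError",
    "DEFAULT_NEIGHBOR_LINKS",
    "geometry_from_regions",
    "initial_state",
    "step",
    "run",
    "nitrogen_budget",
]

SECTORS = ("pacific_influenced", "atlantic_sector", "interior")

#: below this concentration (mmol m-3) delta values are masked, not computed
DELTA_FLOOR = 1e-6


class IntegrationError(RuntimeError):
    """Tracer went non-finite or negative despite flux limiting."""


class BudgetViolationError(RuntimeError):
    """Annual nitrogen budget failed to close within tolerance."""


@dataclass(frozen=True)
class BoxGeometry:
    """Static geometry and subsurface-reservoir properties of one box."""

    name: str
    area: float
    depth: float = 100.0
    sector: str = "interior"
    sub_salinity: float = 33.5
    sub_no3: float = 12.0
    sub_po4: float = 1.0
    sub_d15n: float = 5.5

    def __post_init__(self) -> None:
        if self.area <= 0 or self.depth <= 0:
            raise ValueError(f"box {self.name}: area and depth must be positive")
        if self.sector not in SECTORS:
            raise ValueError(f"box {self.name}: unknown sector {self.sector!r}")

    @property
    def volume(self) -> float:
        return self.area * self.depth


def geometry_from_regions(
    regions: tuple[RegionConfig, ...] = DEFAULT_REGIONS,
) -> tuple[BoxGeometry, ...]:
    return tuple(
        BoxGeometry(r.name, r.area, r.depth, r.sector,
                    r.sub_salinity, r.sub_no3, r.sub_po4, r.sub_d15n)
        for r in regions
    )


@dataclass(frozen=True)
class BoxState:
    """Per-box tracer vector; concentrations in mmol m⁻³, salinity in psu."""

    salinity: float
    no3: IsotopePair
    po4: float
    pon: IsotopePair

    def __post_init__(self) -> None:
        if self.po4 < 0 or self.salinity < 0:
            raise IntegrationError(
                f"negative scalar tracer (S={self.salinity}, PO4={self.po4})"
            )


@dataclass(frozen=True)
class ModelParams:
    """Biogeochemical parameters with field-standard defaults.

    ``eps_assim`` and ``eps_sed`` are the per-mil fractionation magnitudes of
    phytoplankton assimilation and sedimentary denitrification.  The expressed
    assimilation fractionation saturates as ε·NO3/(NO3 + k_eps), reproducing
    the suppression of the ¹⁴N preference when nitrate runs low.
    """

    eps_assim: float = 5.0
    eps_sed: float = 3.0
    k_no3: float = 1.0            # uptake half-saturation, mmol m-3
    k_eps: float = 1.0            # fractionation-expression half-saturation
    mu_max: float = 14.0          # maximum specific production, yr-1
    light_ice_exponent: float = 3.0
    loss_rate: float = 10.0       # PON turnover, yr-1
    recycle_frac: float = 0.7
    export_frac: float = 0.3
    sed_denit_frac: float = 0.25  # of exported N, removed by denitrification
    benthic_return_frac: float = 0.5
    redfield_n_to_p: float = 16.0
    delta_river: float = 2.0
    r_std: float = R_STD_AIR

    def __post_init__(self) -> None:
        for name in ("recycle_frac", "export_frac", "sed_denit_frac",
                     "benthic_return_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.recycle_frac + self.export_frac > 1.0 + 1e-12:
            raise ValueError("recycle_frac + export_frac exceeds 1")
        if self.eps_assim < 0 or self.eps_sed < 0:
            raise ValueError("fractionation magnitudes must be >= 0")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


#: symmetric neighbour-exchange links (box_a, box_b, rate yr-1 of the smaller volume)
DEFAULT_NEIGHBOR_LINKS: tuple[tuple[str, str, float], ...] = (
    ("chukchi", "beaufort_gyre", 0.05),
    ("beaufort_gyre", "canadian_archipelago", 0.04),
    ("chukchi", "siberian_shelves", 0.08),
    ("canadian_archipelago", "labrador", 0.05),
    ("siberian_shelves", "barents", 0.05),
    ("barents", "east_greenland", 0.10),
    ("east_greenland", "irminger", 0.10),
    ("irminger", "labrador", 0.10),
)

def initial_state(geoms: tuple[BoxGeometry, ...]) -> dict[str, BoxState]:
    """Default initial condition: each box at its subsurface-reservoir values."""
    out = {}
    for g in geoms:
        out[g.name] = BoxState(
            salinity=g.sub_salinity,
            no3=pool_of(g.sub_no3, g.sub_d15n),
            po4=g.sub_po4,
            pon=pool_of(0.1, g.sub_d15n - 4.0),
        )
    return out


def _monthly_ice(annual: float, amp: float, month: int) -> float:
    """Seasonal cycle: maximum in late winter (Mar), minimum in Sep."""
    cyc = amp * math.cos(2.0 * math.pi * (month - 2.5) / 12.0)
    return min(1.0, max(0.0, annual + cyc))


def _insolation(month: int) -> float:
    """High-latitude insolation factor: zero through the polar night,
    peaking in June; production is confined to the sunlit season."""
    return max(0.0, math.sin(2.0 * math.pi * (month - 2.5) / 12.0))


def step(
    states: dict[str, BoxState],
    geoms: tuple[BoxGeometry, ...],
    forcing: ForcingSeries,
    params: ModelParams,
    year_idx: int,
    month: int,
    dt: float,
    neighbor_links: tuple[tuple[str, str, float], ...] = (),
    diag: dict[str, dict[str, float]] | None = None,
) -> dict[str, BoxState]:
    """Advance all boxes one sub-step of length ``dt`` (years, <= 1/12).

    Process order: lateral endmember/neighbour exchange, vertical resupply,
    assimilation, PON loss (recycling + export), benthic denitrification and
    return, external inputs.  If ``diag`` is given, fluxes are accumulated
    into it in mass units (mmol of N; keys suffixed ``_h`` for 15N).
    """
    if dt > 1.0 / 12.0 + 1e-12:
        raise ValueError("sub-step must be at most one month")
    gmap = {g.name: g for g in geoms}
    new: dict[str, BoxState] = {}

    def log(box: str, key: str, value: float) -> None:
        if diag is not None:
            diag[box][key] = diag[box].get(key, 0.0) + value

    # --- (1a) neighbour exchange, computed from the pre-step state ----------
    # mass moved a->b is w * conc_a and vice versa, so each link conserves
    # exactly; signed increments are accumulated as plain floats and applied
    # together with the endmember exchange below.
    nbr_salt = {g.name: 0.0 for g in geoms}
    nbr_po4 = {g.name: 0.0 for g in geoms}
    nbr_no3_t = {g.name: 0.0 for g in geoms}
    nbr_no3_h = {g.name: 0.0 for g in geoms}
    nbr_pon_t = {g.name: 0.0 for g in geoms}
    nbr_pon_h = {g.name: 0.0 for g in geoms}
    for a, b, rate in neighbor_links:
        ga, gb = gmap[a], gmap[b]
        w = rate * dt * min(ga.volume, gb.volume)  # exchanged volume, m3
        sa, sb = states[a], states[b]
        nbr_salt[a] += w * (sb.salinity - sa.salinity) / ga.volume
        nbr_salt[b] += w * (sa.salinity - sb.salinity) / gb.volume
        nbr_po4[a] += w * (sb.po4 - sa.po4) / ga.volume
        nbr_po4[b] += w * (sa.po4 - sb.po4) / gb.volume
        for acc_t, acc_h, attr in ((nbr_no3_t, nbr_no3_h, "no3"),
                                   (nbr_pon_t, nbr_pon_h, "pon")):
            pa: IsotopePair = getattr(sa, attr)
            pb: IsotopePair = getattr(sb, attr)
            acc_t[a] += w * (pb.total - pa.total) / ga.volume
            acc_h[a] += w * (pb.heavy - pa.heavy) / ga.volume
            acc_t[b] += w * (pa.total - pb.total) / gb.volume
            acc_h[b] += w * (pa.heavy - pb.heavy) / gb.volume

    for j, g in enumerate(geoms):
        s = states[g.name]
        V = g.volume
        ice = _monthly_ice(float(forcing.ice_fraction[year_idx, j]),
                           float(forcing.ice_seasonal_amp[j]), month)

        salinity = s.salinity
        no3 = s.no3
        po4 = s.po4
        pon = s.pon

        # --- (1) lateral exchange with endmembers --------------------------
        v_p = float(forcing.inflow_pacific[year_idx, j]) * dt
        v_a = float(forcing.inflow_atlantic[year_idx, j]) * dt
        v_out = min(v_p + v_a, 0.5)
        if v_out > 0:
            scale = v_out / (v_p + v_a)
            v_p, v_a = v_p * scale, v_a * scale
            pac, atl = forcing.pacific, forcing.atlantic
            salinity += v_p * (pac.salinity - salinity) + v_a * (atl.salinity - salinity)
            po4 += v_p * (pac.po4 - po4) + v_a * (atl.po4 - po4)
            no3_in = pool_of(v_p * pac.no3, pac.d15n_no3) + pool_of(v_a * atl.no3, atl.d15n_no3)
            nr = float(forcing.atl_nr_no3[year_idx])
            if nr > 0.0:  # far-field anthropogenic N_r carried by Atlantic water
                no3_in = no3_in + pool_of(v_a * nr, forcing.delta_dep)
            no3_out = no3.scaled(v_out)
            pon_in = pool_of(v_p * pac.pon, pac.d15n_pon) + pool_of(v_a * atl.pon, atl.d15n_pon)
            pon_out = pon.scaled(v_out)
            no3 = no3 + no3_in - no3_out
            pon = pon + pon_in - pon_out
            log(g.name, "lateral_net", (no3_in.total - no3_out.total
                                        + pon_in.total - pon_out.total) * V)
            log(g.name, "lateral_net_h", (no3_in.heavy - no3_out.heavy
                                          + pon_in.heavy - pon_out.heavy) * V)

        # freshwater-cycle salinity tendency (rivers, melt, precipitation)
        salinity = max(salinity + float(forcing.fw_salinity_tendency[year_idx, j]) * dt, 0.0)

        # neighbour increments (already conservative pairwise)
        salinity += nbr_salt[g.name]
        po4 = max(po4 + nbr_po4[g.name], 0.0)
        no3 = IsotopePair(max(no3.total + nbr_no3_t[g.name], 0.0),
                          max(no3.heavy + nbr_no3_h[g.name], 0.0))
        pon = IsotopePair(max(pon.total + nbr_pon_t[g.name], 0.0),
                          max(pon.heavy + nbr_pon_h[g.name], 0.0))
        log(g.name, "neighbor_net", (nbr_no3_t[g.name] + nbr_pon_t[g.name]) * V)
        log(g.name, "neighbor_net_h", (nbr_no3_h[g.name] + nbr_pon_h[g.name]) * V)

        # --- (2) vertical resupply toward the subsurface reservoir ---------
        v_m = float(forcing.mixing_supply[year_idx, j]) * dt
        if v_m > 0:
            v_m = min(v_m, 0.5)
            salinity += v_m * (g.sub_salinity - salinity)
            po4 += v_m * (g.sub_po4 - po4)
            no3_up = pool_of(v_m * g.sub_no3, g.sub_d15n)
            no3_dn = no3.scaled(v_m)
            pon_dn = pon.scaled(v_m)  # deep PON ~ 0: mixing sinks particles
            no3 = no3 + no3_up - no3_dn
            pon = pon - pon_dn
            log(g.name, "vertical_net", (no3_up.total - no3_dn.total - pon_dn.total) * V)
            log(g.name, "vertical_net_h", (no3_up.heavy - no3_dn.heavy - pon_dn.heavy) * V)

        # --- (3) assimilation ----------------------------------------------
        light = _insolation(month) * (1.0 - ice) ** params.light_ice_exponent
        u = params.mu_max * (no3.total / (no3.total + params.k_no3)) * light \
            * no3.total * dt
        u = min(u, 0.9 * no3.total, 0.9 * params.redfield_n_to_p * po4)
        if u > 0:
            eps_eff = 0.0 if forcing.eps_assim_zero else \
                params.eps_assim * no3.total / (no3.total + params.k_eps)
            uptake = fractionating_flux(no3, u, eps_eff)
            no3 = no3 - uptake
            pon = pon + uptake
            po4 -= u / params.redfield_n_to_p
            log(g.name, "production", u * V)

        # --- (4) PON loss: recycling + export -------------------------------
        loss = min(params.loss_rate * dt, 0.9) * pon.total
        if loss > 0:
            loss_pair = pon.scaled(loss / pon.total)
            recycle = loss_pair.scaled(params.recycle_frac)
            export = loss_pair.scaled(params.export_frac)
            pon = pon - recycle - export
            no3 = no3 + recycle  # remineralisation does not fractionate
            po4 += recycle.total / params.redfield_n_to_p
            log(g.name, "recycle", recycle.total * V)
            log(g.name, "export", export.total * V)

            # --- (5) benthic: denitrification, return, burial ---------------
            denit = fractionating_flux(export, params.sed_denit_frac * export.total,
                                       params.eps_sed)
            residual = export - denit
            benthic_return = residual.scaled(params.benthic_return_frac)
            burial = residual - benthic_return
            no3 = no3 + benthic_return
            po4 += export.total * params.benthic_return_frac / params.redfield_n_to_p
            log(g.name, "denitrification", denit.total * V)
            log(g.name, "denitrification_h", denit.heavy * V)
            log(g.name, "burial", burial.total * V)
            log(g.name, "burial_h", burial.heavy * V)

        # --- (6) external inputs --------------------------------------------
        dep_c = float(forcing.dep_flux[year_idx, j]) * dt / g.depth
        riv_c = float(forcing.river_flux[year_idx, j]) * dt / g.depth
        if dep_c > 0:
            no3 = no3 + pool_of(dep_c, forcing.delta_dep)
            log(g.name, "dep_in", dep_c * V)
            log(g.name, "dep_in_h", pool_of(dep_c, forcing.delta_dep).heavy * V)
        if riv_c > 0:
            no3 = no3 + pool_of(riv_c, forcing.delta_river)
            log(g.name, "river_in", riv_c * V)
            log(g.name, "river_in_h", pool_of(riv_c, forcing.delta_river).heavy * V)

        if not all(map(math.isfinite, (salinity, po4, no3.total, no3.heavy,
                                       pon.total, pon.heavy))):
            raise IntegrationError(
                f"non-finite tracer in box {g.name}, year index {year_idx}, "
                f"month {month}"
            )
        new[g.name] = BoxState(salinity=salinity, no3=no3, po4=max(po4, 0.0),
                               pon=pon)
    return new


STATE_VARS = ("salinity", "no3", "po4", "pon", "d15n_no3", "d15n_pom",
              "nstar", "ice")
DIAG_VARS = ("production", "recycle", "export", "denitrification", "burial",
             "river_in", "dep_in", "lateral_net", "vertical_net", "neighbor_net",
             "denitrification_h", "burial_h", "river_in_h", "dep_in_h",
             "lateral_net_h", "vertical_net_h", "neighbor_net_h",
             "inventory_n", "inventory_15n")


@dataclass
class Trajectory:
    """Annual-mean output of a simulation run, long format.

    ``data`` columns: year, box, variable, value.  Delta variables are NaN
    (masked) wherever the parent pool is below the concentration floor.
    """

    data: pd.DataFrame
    geometry: tuple[BoxGeometry, ...]
    params: ModelParams
    scenario: str = ""
    toggles: tuple[str, ...] = ()

    def pivot(self, variable: str) -> pd.DataFrame:
        """Wide (year x box) table of one variable."""
        sub = self.data[self.data["variable"] == variable]
        if sub.empty:
            raise KeyError(f"variable {variable!r} not in trajectory")
        return sub.pivot(index="year", columns="box", values="value")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def boxes_in_sector(self, sector: str) -> list[str]:
        return [g.name for g in self.geometry if g.sector == sector]

    def area_of(self, box: str) -> float:
        for g in self.geometry:
            if g.name == box:
                return g.area
        raise KeyError(box)


def run(
    scenario: ForcingSeries,
    params: ModelParams | None = None,
    initial: dict[str, BoxState] | None = None,
    regions: tuple[RegionConfig, ...] = DEFAULT_REGIONS,
    spinup_years: int = 50,
    neighbor_links: tuple[tuple[str, str, float], ...] = DEFAULT_NEIGHBOR_LINKS,
    substeps_per_year: int = 12,
) -> Trajectory:
    """Integrate the box model over a scenario and return annual means.

    A spin-up of ``spinup_years`` is run first under the scenario's first-year
    forcing and discarded; the simulator is fully deterministic, so repeated
    calls are bit-identical.
    """
    params = params or ModelParams()
    geoms = geometry_from_regions(regions)
    if tuple(g.name for g in geoms) != scenario.box_names:
        raise ValueError("forcing box names do not match the region geometry")
    states = initial or initial_state(geoms)
    dt = 1.0 / substeps_per_year

    links = tuple(
        (a, b, r) for a, b, r in neighbor_links
        if a in scenario.box_names and b in scenario.box_names
    )

    for _ in range(spinup_years):
        for m in range(substeps_per_year):
            states = step(states, geoms, scenario, params, 0, m, dt, links)

    rows: list[tuple[int, str, str, float]] = []
    for i, year in enumerate(scenario.years):
        diag = {g.name: {} for g in geoms}
        acc = {g.name: {v: 0.0 for v in
                        ("salinity", "no3", "po4", "pon", "no3_h", "pon_h", "ice")}
               for g in geoms}
        for m in range(substeps_per_year):
            states = step(states, geoms, scenario, params, i, m, dt, links, diag)
            for j, g in enumerate(geoms):
                s = states[g.name]
                a = acc[g.name]
                a["salinity"] += s.salinity
                a["no3"] += s.no3.total
                a["no3_h"] += s.no3.heavy
                a["po4"] += s.po4
                a["pon"] += s.pon.total
                a["pon_h"] += s.pon.heavy
                a["ice"] += _monthly_ice(float(scenario.ice_fraction[i, j]),
                                         float(scenario.ice_seasonal_amp[j]), m)
        for g in geoms:
            a = {k: v / substeps_per_year for k, v in acc[g.name].items()}
            d15_no3 = (delta_of(IsotopePair(a["no3"], a["no3_h"]), params.r_std)
                       if a["no3"] > DELTA_FLOOR else math.nan)
            d15_pom = (delta_of(IsotopePair(a["pon"], a["pon_h"]), params.r_std)
                       if a["pon"] > DELTA_FLOOR else math.nan)
            values = {
                "salinity": a["salinity"], "no3": a["no3"], "po4": a["po4"],
                "pon": a["pon"], "d15n_no3": d15_no3, "d15n_pom": d15_pom,
                "nstar": a["no3"] - 16.0 * a["po4"], "ice": a["ice"],
            }
            s = states[g.name]
            V = [gg for gg in geoms if gg.name == g.name][0].volume
            values["inventory_n"] = (s.no3.total + s.pon.total) * V
            values["inventory_15n"] = (s.no3.heavy + s.pon.heavy) * V
            for k in DIAG_VARS:
                if k not in ("inventory_n", "inventory_15n"):
                    values[k] = diag[g.name].get(k, 0.0)
            for k, v in values.items():
                rows.append((int(year), g.name, k, float(v)))

    data = pd.DataFrame(rows, columns=["year", "box", "variable", "value"])
    return Trajectory(data=data, geometry=geoms, params=params,
                      scenario=scenario.scenario, toggles=scenario.toggles)


def nitrogen_budget(traj: Trajectory, tol: float = 1e-6,
                    raise_on_violation: bool = True) -> pd.DataFrame:
    """Audit the annual nitrogen budget of a trajectory.

    For each simulated year after the first, checks that the change of the
    (NO3 + PON) inventory equals sources (rivers, deposition, net endmember
    inflow, net vertical supply, net neighbour exchange) minus sinks (burial,
    denitrification), for total N and for 15N separately, to within ``tol``
    of the gross flux.
    """
    wide = {v: traj.pivot(v) for v in DIAG_VARS}
    years = wide["inventory_n"].index.to_numpy()
    out = []
    for total, suffix in (("n", ""), ("15n", "_h")):
        inv = wide[f"inventory_{total}"].sum(axis=1).to_numpy()
        if suffix == "":
            src = (wide["river_in"] + wide["dep_in"] + wide["lateral_net"]
                   + wide["vertical_net"] + wide["neighbor_net"]).sum(axis=1).to_numpy()
            snk = (wide["burial"] + wide["denitrification"]).sum(axis=1).to_numpy()
            gross = (wide["river_in"] + wide["dep_in"]
                     + wide["lateral_net"].abs() + wide["vertical_net"].abs()
                     + wide["burial"] + wide["denitrification"]
                     + wide["production"]).sum(axis=1).to_numpy()
        else:
            src = (wide["river_in_h"] + wide["dep_in_h"] + wide["lateral_net_h"]
                   + wide["vertical_net_h"] + wide["neighbor_net_h"]).sum(axis=1).to_numpy()
            snk = (wide["burial_h"] + wide["denitrification_h"]).sum(axis=1).to_numpy()
            gross = (wide["river_in_h"] + wide["dep_in_h"]
                     + wide["lateral_net_h"].abs() + wide["vertical_net_h"].abs()
                     + wide["burial_h"] + wide["denitrification_h"]).sum(axis=1).to_numpy()
        for k in range(1, len(years)):
            d_inv = inv[k] - inv[k - 1]
            resid = d_inv - (src[k] - snk[k])
            scale = max(abs(gross[k]), abs(inv[k]), 1.0)
            out.append({
                "year": int(years[k]), "species": total,
                "inventory_change": d_inv, "sources": src[k], "sinks": snk[k],
                "residual": resid, "relative_residual": resid / scale,
            })
    df = pd.DataFrame(out)
    worst = df["relative_residual"].abs().max() if len(df) else 0.0
    if raise_on_violation and worst > tol:
        bad = df.loc[df["relative_residual"].abs().idxmax()]
        raise BudgetViolationError(
            f"nitrogen budget violated: year {bad['year']} species "
            f"{bad['species']} relative residual {bad['relative_residual']:.3e}"
        )
    return df
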