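"""Deterministic scenario forcings for the Arctic nitrogen-cycle box model.

Three scenario families are provided:

* ``control`` — preindustrial drivers held flat apart from small deterministic
  multi-year oscillations (no stochastic weather; every run is bit-identical).
* ``reanalysis`` — historical era 1970–2019: monotone sea-ice decline,
  strengthening Atlantic inflow to the Barents/East Greenland boxes, and the
  anthropogenic aeolian reactive-nitrogen (N_r) deposition ramp.
* ``emissions`` — strong-warming trajectory 1850–2100: sea ice collapses to a
  near-zero summer state and the annual mean falls by more than half of its
  1986–2005 level by 2081–2100, with a stronger Atlantic-inflow ramp and the
  deposition schedule extended to 2100.

The global deposition total follows a piecewise-linear schedule anchored at
1850/2000/2030/2050/2100, flat at 11 Tg N yr⁻¹ before 1851, with 60% of the
1850→2000 increase placed after 1950.  Deposited nitrogen carries δ15N = −4‰;
riverine nitrate carries +2‰.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DepositionSchedule",
    "Endmember",
    "RegionConfig",
    "ForcingSeries",
    "ScenarioError",
    "DEFAULT_REGIONS",
    "PACIFIC_ENDMEMBER",
    "ATLANTIC_ENDMEMBER",
    "deposition_total_at",
    "regional_deposition",
    "build_scenario",
]

#: mmol N per Tg N  (1e12 g / 14.007 g mol-1 * 1e3 mmol mol-1)
TG_N_TO_MMOL = 1.0e15 / 14.007

SCENARIOS = ("control", "reanalysis", "emissions")
TOGGLES = ("no_anthropogenic_deposition", "no_assimilation_fractionation", "fixed_rivers")


class ScenarioError(ValueError):
    """Unknown scenario name, toggle, or out-of-range configuration."""


@dataclass(frozen=True)
class DepositionSchedule:
    """Globally integrated aeolian N_r deposition schedule (Tg N yr⁻¹)."""

    anchor_years: tuple[int, ...] = (1850, 2000, 2030, 2050, 2100)
    anchor_totals: tuple[float, ...] = (11.0, 39.0, 41.0, 43.0, 44.0)
    preindustrial_total: float = 11.0
    split_year: int = 1950
    post_split_fraction: float = 0.60
    delta_dep: float = -4.0

    def __post_init__(self) -> None:
        if list(self.anchor_years) != sorted(set(self.anchor_years)):
            raise ScenarioError("anchor years must be strictly increasing")
        if len(self.anchor_years) != len(self.anchor_totals):
            raise ScenarioError("anchor years/totals length mismatch")
        if not 0.0 <= self.post_split_fraction <= 1.0:
            raise ScenarioError("post_split_fraction outside [0, 1]")
        if not self.anchor_years[0] < self.split_year < self.anchor_years[1]:
            raise ScenarioError("split_year must fall inside the first segment")


def deposition_total_at(year: float, sched: DepositionSchedule | None = None) -> float:
    """Global deposition total (Tg N yr⁻¹) at a calendar year.

    Flat at the preindustrial total before 1851.  Over the first anchor
    segment the increase is split so that ``post_split_fraction`` of it occurs
    after ``split_year`` (two linear sub-segments, continuous at the split).
    Beyond the second anchor, linear interpolation between successive anchors.
    """
    sched = sched or DepositionSchedule()
    if not 1648 <= year <= sched.anchor_years[-1]:
        raise ScenarioError(f"year {year} outside supported range [1648, {sched.anchor_years[-1]}]")
    y0, y1 = sched.anchor_years[0], sched.anchor_years[1]
    d0, d1 = sched.anchor_totals[0], sched.anchor_totals[1]
    if year <= y0:
        return sched.preindustrial_total
    if year <= y1:
        rise = d1 - d0
        d_split = d0 + (1.0 - sched.post_split_fraction) * rise
        if year <= sched.split_year:
            frac = (year - y0) / (sched.split_year - y0)
            return d0 + frac * (d_split - d0)
        frac = (year - sched.split_year) / (y1 - sched.split_year)
        return d_split + frac * (d1 - d_split)
    return float(np.interp(year, sched.anchor_years, sched.anchor_totals))


@dataclass(frozen=True)
class Endmember:
    """Idealised inflow water type (Pacific or Atlantic)."""

    salinity: float
    no3: float
    po4: float
    d15n_no3: float
    pon: float = 0.1
    d15n_pon: float = 0.0

    @property
    def nstar(self) -> float:
        return self.no3 - 16.0 * self.po4


# Pacific water: fresher, N*-negative, δ15N elevated by 2–3‰ over Atlantic
# (the calibrated contrast is 2.9‰).
PACIFIC_ENDMEMBER = Endmember(salinity=32.0, no3=14.0, po4=1.40, d15n_no3=7.5,
                              pon=0.1, d15n_pon=3.5)
ATLANTIC_ENDMEMBER = Endmember(salinity=35.0, no3=12.0, po4=0.625, d15n_no3=4.6,
                               pon=0.1, d15n_pon=0.6)


@dataclass(frozen=True)
class RegionConfig:
    """Geometry plus scenario-forcing parameters for one surface box."""

    name: str
    sector: str                      # pacific_influenced | atlantic_sector | interior
    area: float                      # m2
    depth: float = 100.0             # m
    # subsurface reservoir (vertical-mixing target)
    sub_salinity: float = 33.5
    sub_no3: float = 12.0
    sub_po4: float = 1.0
    sub_d15n: float = 5.5
    # sea ice
    ice_base: float = 0.5            # annual-mean fraction, era start / control
    ice_seasonal_amp: float = 0.25
    ice_hist_loss: float = 0.2       # annual-mean loss over 1970-2019
    ice_future_floor: float = 0.05   # emissions end-of-century annual mean
    # exchange (volume fraction per year)
    inflow_pacific: float = 0.0
    inflow_atlantic: float = 0.0
    atl_ramp_hist: float = 0.0       # fractional Atlantic-inflow increase by 2019
    atl_ramp_future: float = 0.0     # by 2100
    mixing_supply: float = 0.3
    # external nitrogen
    dep_weight: float = 0.0          # share of the global deposition total
    river_flux: float = 1.0          # mmol N m-2 yr-1, era-start
    river_trend_hist: float = 0.2    # fractional increase by 2019
    river_trend_future: float = 0.4  # by 2100
    fw_amp: float = 0.1              # freshwater-cycle salinity tendency amplitude, psu yr-1


# Default eight-box geography, as calibrated (see docs/methods.md).  Areas
# are rounded regional sea areas; the deposition weights put the bulk of the
# anthropogenic increment in the Atlantic-sector seas at ~7 mmol N m-2 yr-1
# (~ 0.1 g N m-2 yr-1) by 2000.  Pacific-influenced boxes are strongly
# ice-covered and stratified (production light-limited at era start);
# Atlantic-sector boxes are vigorously flushed by Atlantic inflow.
DEFAULT_REGIONS: tuple[RegionConfig, ...] = (
    RegionConfig("chukchi", "pacific_influenced", 6.2e11,
                 sub_salinity=32.5, sub_no3=14.0, sub_po4=1.40, sub_d15n=7.5,
                 ice_base=0.78, ice_hist_loss=0.40, ice_future_floor=0.05,
                 inflow_pacific=0.20, inflow_atlantic=0.0, mixing_supply=0.12,
                 dep_weight=0.00031, river_flux=22.0, river_trend_hist=0.6,
                 fw_amp=0.35),
    RegionConfig("beaufort_gyre", "pacific_influenced", 1.0e12,
                 sub_salinity=32.5, sub_no3=14.0, sub_po4=1.40, sub_d15n=7.5,
                 ice_base=0.88, ice_hist_loss=0.35, ice_future_floor=0.03,
                 inflow_pacific=0.05, inflow_atlantic=0.0, mixing_supply=0.03,
                 dep_weight=0.0005, river_flux=18.0, river_trend_hist=0.5,
                 fw_amp=0.3),
    RegionConfig("canadian_archipelago", "pacific_influenced", 7.5e11,
                 sub_salinity=32.8, sub_no3=14.0, sub_po4=1.35, sub_d15n=7.5,
                 ice_base=0.85, ice_hist_loss=0.33, ice_future_floor=0.08,
                 inflow_pacific=0.10, inflow_atlantic=0.02, mixing_supply=0.06,
                 dep_weight=0.000375, river_flux=6.0, river_trend_hist=0.5,
                 fw_amp=0.25),
    RegionConfig("siberian_shelves", "interior", 2.0e12,
                 sub_salinity=33.0, sub_no3=10.0, sub_po4=1.0, sub_d15n=5.5,
                 ice_base=0.72, ice_hist_loss=0.25, ice_future_floor=0.05,
                 inflow_pacific=0.10, inflow_atlantic=0.05, mixing_supply=0.25,
                 dep_weight=0.001, river_flux=20.0, fw_amp=0.4),
    RegionConfig("barents", "atlantic_sector", 1.4e12,
                 sub_salinity=35.0, sub_no3=12.0, sub_po4=0.65, sub_d15n=4.6,
                 ice_base=0.32, ice_hist_loss=0.12, ice_future_floor=0.02,
                 inflow_pacific=0.0, inflow_atlantic=0.45, atl_ramp_hist=0.5,
                 atl_ramp_future=1.0, mixing_supply=0.35,
                 dep_weight=0.0049, river_flux=5.0, fw_amp=0.2),
    RegionConfig("east_greenland", "atlantic_sector", 5.5e11,
                 sub_salinity=34.8, sub_no3=12.0, sub_po4=0.65, sub_d15n=4.6,
                 ice_base=0.45, ice_hist_loss=0.12, ice_future_floor=0.05,
                 inflow_pacific=0.0, inflow_atlantic=0.40, atl_ramp_hist=0.5,
                 atl_ramp_future=1.0, mixing_supply=0.35,
                 dep_weight=0.0019, river_flux=3.0, fw_amp=0.2),
    RegionConfig("labrador", "atlantic_sector", 9.0e11,
                 sub_salinity=34.8, sub_no3=12.0, sub_po4=0.65, sub_d15n=4.6,
                 ice_base=0.22, ice_hist_loss=0.08, ice_future_floor=0.02,
                 inflow_pacific=0.0, inflow_atlantic=0.50, atl_ramp_hist=0.3,
                 atl_ramp_future=0.8, mixing_supply=0.40,
                 dep_weight=0.00315, river_flux=3.0, fw_amp=0.2),
    RegionConfig("irminger", "atlantic_sector", 6.0e11,
                 sub_salinity=35.0, sub_no3=12.0, sub_po4=0.65, sub_d15n=4.6,
                 ice_base=0.05, ice_seasonal_amp=0.05, ice_hist_loss=0.03,
                 ice_future_floor=0.0,
                 inflow_pacific=0.0, inflow_atlantic=0.60, atl_ramp_hist=0.3,
                 atl_ramp_future=0.8, mixing_supply=0.40,
                 dep_weight=0.0021, river_flux=2.0, fw_amp=0.15),
)


@dataclass(frozen=True)
class ForcingSeries:
    """Time-indexed scenario drivers for every box.

    All rate arrays have shape ``(n_years, n_boxes)``; rates are annual values
    applied uniformly across the monthly sub-steps (ice additionally carries a
    seasonal cycle of amplitude ``ice_seasonal_amp``).
    """

    scenario: str
    years: np.ndarray
    box_names: tuple[str, ...]
    ice_fraction: np.ndarray
    inflow_pacific: np.ndarray
    inflow_atlantic: np.ndarray
    mixing_supply: np.ndarray
    dep_flux: np.ndarray             # mmol N m-2 yr-1
    river_flux: np.ndarray           # mmol N m-2 yr-1
    ice_seasonal_amp: np.ndarray     # (n_boxes,)
    #: anthropogenic N_r accumulated in Atlantic inflow water (mmol m-3,
    #: carried at delta_dep): the far-field deposition delivered northwards
    #: by lateral transport; zero preindustrially and under the
    #: no_anthropogenic_deposition toggle
    atl_nr_no3: np.ndarray = field(default=None)  # (n_years,)
    #: net freshwater-cycle salinity tendency (psu yr-1, signed): river
    #: discharge, ice melt/growth and precipitation variability
    fw_salinity_tendency: np.ndarray = field(default=None)  # (n_years, n_boxes)
    pacific: Endmember = PACIFIC_ENDMEMBER
    atlantic: Endmember = ATLANTIC_ENDMEMBER
    delta_river: float = 2.0
    delta_dep: float = -4.0
    eps_assim_zero: bool = False
    toggles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n, b = len(self.years), len(self.box_names)
        if self.atl_nr_no3 is None:
            object.__setattr__(self, "atl_nr_no3", np.zeros(n))
        if self.atl_nr_no3.shape != (n,) or self.atl_nr_no3.min() < 0:
            raise ScenarioError("atl_nr_no3 must be a non-negative (n_years,) array")
        if self.fw_salinity_tendency is None:
            object.__setattr__(self, "fw_salinity_tendency", np.zeros((n, b)))
        if self.fw_salinity_tendency.shape != (n, b):
            raise ScenarioError("fw_salinity_tendency must have shape (n_years, n_boxes)")
        for name in ("ice_fraction", "inflow_pacific", "inflow_atlantic",
                     "mixing_supply", "dep_flux", "river_flux"):
            arr = getattr(self, name)
            if arr.shape != (n, b):
                raise ScenarioError(f"{name} has shape {arr.shape}, expected {(n, b)}")
            if name == "ice_fraction":
                if arr.min() < 0 or arr.max() > 1:
                    raise ScenarioError("ice_fraction outside [0, 1]")
            elif arr.min() < 0:
                raise ScenarioError(f"negative rate in {name}")

    def year_index(self, year: int) -> int:
        i = int(np.searchsorted(self.years, year))
        if i >= len(self.years) or self.years[i] != year:
            raise ScenarioError(f"year {year} not covered by this forcing")
        return i


def regional_deposition(
    year: float,
    sched: DepositionSchedule,
    regions: tuple[RegionConfig, ...],
    weights: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-box deposition flux (mmol N m⁻² yr⁻¹) from the global schedule.

    Each box receives ``weight × global total``, converted to an areal flux by
    its own area.  Default weights come from the region configuration and
    concentrate the anthropogenic increment in the Atlantic-sector seas.
    """
    weights = weights or {r.name: r.dep_weight for r in regions}
    if any(w < 0 for w in weights.values()):
        raise ScenarioError("deposition weights must be non-negative")
    if sum(weights.values()) > 1.0 + 1e-9:
        raise ScenarioError("deposition weights sum to more than 1")
    total_mmol = deposition_total_at(year, sched) * TG_N_TO_MMOL
    return {r.name: weights.get(r.name, 0.0) * total_mmol / r.area for r in regions}


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _wiggle(year: np.ndarray, periods: tuple[float, ...],
            amps: tuple[float, ...], phase: float) -> np.ndarray:
    """Deterministic multi-year variability: a sum of incommensurate
    sinusoids standing in for inter-annual weather, so runs need no seeds."""
    out = np.zeros(len(year), dtype=float)
    for k, (p, a) in enumerate(zip(periods, amps)):
        out += a * np.sin(2.0 * math.pi * (year + phase * (k + 1)) / p)
    return out


def build_scenario(
    name: str,
    toggles: tuple[str, ...] | list[str] = (),
    years: np.ndarray | range | None = None,
    regions: tuple[RegionConfig, ...] = DEFAULT_REGIONS,
    sched: DepositionSchedule | None = None,
    pacific: Endmember = PACIFIC_ENDMEMBER,
    atlantic: Endmember = ATLANTIC_ENDMEMBER,
    atl_nr_scale: float = 3.4,
) -> ForcingSeries:
    """Build the deterministic ForcingSeries for a named scenario.

    Toggles: ``no_anthropogenic_deposition`` holds deposition at preindustrial
    levels for all years; ``no_assimilation_fractionation`` signals ε_assim = 0
    to the model; ``fixed_rivers`` holds riverine fluxes at their era-start
    values.
    """
    if name not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    for t in toggles:
        if t not in TOGGLES:
            raise ScenarioError(f"unknown toggle {t!r}; expected one of {TOGGLES}")
    toggles = tuple(toggles)
    sched = sched or DepositionSchedule()

    if years is None:
        years = {"control": range(1850, 1950),
                 "reanalysis": range(1970, 2020),
                 "emissions": range(1850, 2101)}[name]
    years = np.asarray(list(years), dtype=int)
    if name == "reanalysis" and (years.min() < 1970 or years.max() > 2019):
        raise ScenarioError("reanalysis era is 1970-2019")
    if name == "emissions" and (years.min() < 1850 or years.max() > 2100):
        raise ScenarioError("emissions era is 1850-2100")

    nb = len(regions)
    ny = len(years)
    ice = np.zeros((ny, nb))
    inf_p = np.zeros((ny, nb))
    inf_a = np.zeros((ny, nb))
    mixs = np.zeros((ny, nb))
    dep = np.zeros((ny, nb))
    riv = np.zeros((ny, nb))
    fw = np.zeros((ny, nb))

    no_dep = "no_anthropogenic_deposition" in toggles
    fixed_rivers = "fixed_rivers" in toggles

    for j, r in enumerate(regions):
        phase = 3.7 * j  # de-phase boxes so oscillations are not collinear
        # each driver carries its own spectral signature so that predictors
        # derived from them are not mutually collinear at the cell level
        w_ice = _wiggle(years, (8.7, 4.3), (0.035, 0.02), phase)
        w_atl = _wiggle(years, (16.4, 6.1), (0.12, 0.06), phase + 5.0)
        w_pac = _wiggle(years, (12.7, 5.3), (0.10, 0.05), phase + 2.0)
        w_riv = _wiggle(years, (10.8, 4.9), (0.45, 0.22), phase + 8.0)
        w_mix = _wiggle(years, (6.7, 3.1), (0.10, 0.05), phase + 1.0)
        fw[:, j] = r.fw_amp * _wiggle(years, (14.9, 5.7), (1.0, 0.5), phase + 11.0)

        if name == "control":
            ice_j = r.ice_base + w_ice
            atl_fac = 1.0 + w_atl
            riv_fac = 1.0 + w_riv
        elif name == "reanalysis":
            prog = (years - 1970) / 49.0
            ice_j = r.ice_base - r.ice_hist_loss * prog + w_ice
            atl_fac = 1.0 + r.atl_ramp_hist * prog + w_atl
            riv_fac = 1.0 + r.river_trend_hist * prog + w_riv
        else:  # emissions
            sig = np.array([_logistic((2045.0 - y) / 25.0) for y in years])
            ice_j = r.ice_future_floor + (r.ice_base - r.ice_future_floor) * sig + w_ice
            ramp = np.array([_logistic((y - 2010.0) / 30.0) for y in years])
            atl_fac = 1.0 + r.atl_ramp_future * ramp + w_atl
            riv_fac = 1.0 + r.river_trend_future * ramp + w_riv

        if fixed_rivers:
            riv_fac = np.ones_like(riv_fac)

        ice[:, j] = np.clip(ice_j, 0.0, 1.0)
        inf_p[:, j] = r.inflow_pacific * np.clip(1.0 + w_pac, 0.0, None)
        inf_a[:, j] = r.inflow_atlantic * np.clip(atl_fac, 0.0, None)
        mixs[:, j] = r.mixing_supply * np.clip(1.0 + w_mix, 0.0, None)
        riv[:, j] = r.river_flux * np.clip(riv_fac, 0.0, None)

        for i, y in enumerate(years):
            if name == "control" or no_dep:
                total = sched.preindustrial_total
            else:
                total = deposition_total_at(float(y), sched)
            dep[i, j] = r.dep_weight * total * TG_N_TO_MMOL / r.area

    # Far-field anthropogenic N_r accumulated in Atlantic inflow water,
    # normalised so the year-2000 anomaly equals atl_nr_scale mmol m-3.
    d_ref = deposition_total_at(2000.0, sched) - sched.preindustrial_total
    if name == "control" or no_dep or d_ref <= 0:
        atl_nr = np.zeros(ny)
    else:
        atl_nr = np.array([
            atl_nr_scale
            * (deposition_total_at(float(y), sched) - sched.preindustrial_total)
            / d_ref
            for y in years
        ])

    return ForcingSeries(
        scenario=name,
        years=years,
        box_names=tuple(r.name for r in regions),
        ice_fraction=ice,
        inflow_pacific=inf_p,
        inflow_atlantic=inf_a,
        mixing_supply=mixs,
        dep_flux=dep,
        river_flux=riv,
        ice_seasonal_amp=np.array([r.ice_seasonal_amp for r in regions]),
        atl_nr_no3=atl_nr,
        fw_salinity_tendency=fw,
        pacific=pacific,
        atlantic=atlantic,
        delta_river=2.0,
        delta_dep=sched.delta_dep,
        eps_assim_zero="no_assimilation_fractionation" in toggles,
        toggles=toggles,
    )
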