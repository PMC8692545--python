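"""Exact nitrogen-isotope arithmetic.

Isotope state is carried as a pair of masses (total N, heavy ``15N``) rather
than as (total, delta).  Mixing is then ordinary addition, and conservation of
both masses is testable to machine precision; delta values are derived views.

Conventions
-----------
* delta (``δ15N``) is the per-mil deviation of the sample ratio
  ``15N/14N`` from a reference standard ratio ``r_std`` (atmospheric N2 by
  default, 0.0036765).
* A kinetic fractionation factor ``eps`` (per mil) acts on the instantaneous
  product: the ratio of a flux drawn from a pool is ``R_pool * (1 - eps/1000)``,
  i.e. the product is depleted and the residual pool enriched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_STD_AIR",
    "IsotopePair",
    "IsotopeError",
    "UndefinedDeltaError",
    "RatioOverflowError",
    "OverdrawError",
    "delta_of",
    "pool_of",
    "mix",
    "fractionating_flux",
    "rayleigh_substrate_delta",
]

#: 15N/14N ratio of atmospheric N2, the conventional reference standard.
R_STD_AIR = 0.0036765


class IsotopeError(ValueError):
    """Base class for isotope-arithmetic domain errors."""


class UndefinedDeltaError(IsotopeError):
    """delta requested for an empty pool."""


class RatioOverflowError(IsotopeError):
    """Pool is pure 15N; the 15N/14N ratio is unbounded."""


class OverdrawError(IsotopeError):
    """A flux larger than the source pool was requested."""


@dataclass(frozen=True, slots=True)
class IsotopePair:
    """A nitrogen mass (mmol) together with its heavy-isotope submass.

    Invariants: ``0 <= heavy <= total``; the empty pool has ``heavy == 0``.
    """

    total: float
    heavy: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.total) and math.isfinite(self.heavy)):
            raise IsotopeError(f"non-finite isotope pair ({self.total}, {self.heavy})")
        if self.total < 0:
            raise IsotopeError(f"negative total nitrogen: {self.total}")
        if self.heavy < 0 or self.heavy > self.total:
            raise IsotopeError(
                f"heavy mass {self.heavy} outside [0, total={self.total}]"
            )

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "IsotopePair") -> "IsotopePair":
        return IsotopePair(self.total + other.total, self.heavy + other.heavy)

    def __sub__(self, other: "IsotopePair") -> "IsotopePair":
        total = self.total - other.total
        heavy = self.heavy - other.heavy
        # Flux-limited model arithmetic can leave ~1 ulp of negative residue.
        if -1e-12 * max(self.total, 1.0) < total < 0.0:
            total = 0.0
        if -1e-12 * max(self.heavy, 1.0) < heavy < 0.0:
            heavy = 0.0
        if heavy > total:
            if heavy - total < 1e-12 * max(total, 1.0):
                heavy = total
        return IsotopePair(total, heavy)

    def scaled(self, factor: float) -> "IsotopePair":
        """Return the pair multiplied by a non-negative scalar."""
        if factor < 0:
            raise IsotopeError(f"negative scale factor {factor}")
        return IsotopePair(self.total * factor, self.heavy * factor)

    @property
    def light(self) -> float:
        """14N mass (mmol)."""
        return self.total - self.heavy

    @property
    def is_empty(self) -> bool:
        return self.total == 0.0

    def delta(self, r_std: float = R_STD_AIR) -> float:
        return delta_of(self, r_std)


EMPTY = IsotopePair(0.0, 0.0)


def delta_of(pool: IsotopePair, r_std: float = R_STD_AIR) -> float:
    """delta value (per mil) of a pool relative to the standard ratio."""
    if pool.total <= 0.0:
        raise UndefinedDeltaError("delta of an empty pool is undefined")
    if pool.heavy >= pool.total:
        raise RatioOverflowError("pool contains no light isotope")
    ratio = pool.heavy / (pool.total - pool.heavy)
    return (ratio / r_std - 1.0) * 1000.0


def pool_of(total_n: float, delta: float, r_std: float = R_STD_AIR) -> IsotopePair:
    """Construct a pool of ``total_n`` mmol at the given delta (per mil)."""
    if total_n < 0:
        raise IsotopeError(f"negative pool size {total_n}")
    if delta <= -1000.0:
        raise IsotopeError(f"delta {delta} per mil is below the physical bound")
    if total_n == 0.0:
        return EMPTY
    ratio = r_std * (1.0 + delta / 1000.0)
    return IsotopePair(total_n, total_n * ratio / (1.0 + ratio))


def mix(pools: list[IsotopePair] | tuple[IsotopePair, ...]) -> IsotopePair:
    """Conservative mixture: component-wise sums of total and heavy mass."""
    if not pools:
        raise IsotopeError("mix requires at least one pool")
    total = sum(p.total for p in pools)
    heavy = sum(p.heavy for p in pools)
    return IsotopePair(total, heavy)


def fractionating_flux(
    source: IsotopePair, flux_total: float, eps: float
) -> IsotopePair:
    """Draw ``flux_total`` mmol from ``source`` with kinetic fractionation.

    The flux carries the instantaneous-product ratio
    ``R_flux = R_source * (1 - eps/1000)``; subtracting the returned pair from
    the source leaves the residual enriched.  ``eps`` is per mil, ``>= 0`` for
    the usual light-isotope preference.
    """
    if not 0.0 <= eps < 1000.0:
        raise IsotopeError(f"fractionation factor {eps} outside [0, 1000) per mil")
    if flux_total < 0:
        raise IsotopeError(f"negative flux {flux_total}")
    if flux_total > source.total * (1.0 + 1e-12):
        raise OverdrawError(
            f"flux {flux_total} exceeds source pool {source.total}"
        )
    if flux_total == 0.0:
        return EMPTY
    if source.heavy >= source.total:
        raise RatioOverflowError("source contains no light isotope")
    r_source = source.heavy / (source.total - source.heavy)
    r_flux = r_source * (1.0 - eps / 1000.0)
    heavy = flux_total * r_flux / (1.0 + r_flux)
    heavy = min(heavy, source.heavy)
    return IsotopePair(min(flux_total, source.total), heavy)


def rayleigh_substrate_delta(delta0: float, f: float, eps: float) -> float:
    """Closed-system Rayleigh delta of the residual substrate.

    ``delta0 - eps * ln(f)`` with ``f`` the fraction of substrate remaining.
    Used as the analytic oracle against which sub-stepped kinetic
    fractionation is validated.
    """
    if f <= 0.0 or f > 1.0:
        raise IsotopeError(f"remaining fraction {f} outside (0, 1]")
    return delta0 - eps * math.log(f)
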