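"""Cell-geometry and buoyant-density calculations.

Coulter-counter diameters are converted to spherical volumes, and the
buoyant density of cells banding between two sucrose-gradient layers is
approximated by the midpoint of the neighbouring layer densities.  Values
stay at full precision internally; :func:`round_half_up` reproduces printed
figures at the reporting layer only.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from math import pi

__all__ = [
    "sphere_volume",
    "volume_increase_pct",
    "density_midpoint",
    "density_reduction_pct",
    "round_half_up",
]


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere from its diameter: V = (4/3)*pi*r^3 = pi*d^3/6 (um^3)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return pi * diameter**3 / 6.0


def volume_increase_pct(d_nd: float, d_nr: float) -> float:
    """Percent volume increase of an ND cell over an NR cell, from diameters."""
    if d_nd <= 0 or d_nr <= 0:
        raise ValueError("diameters must be positive")
    return 100.0 * ((d_nd / d_nr) ** 3 - 1.0)


def density_midpoint(lower: float, upper: float) -> float:
    """Midpoint of the two neighbouring sucrose layer densities (g/mL)."""
    if lower > upper:
        raise ValueError(f"lower layer density {lower} exceeds upper {upper}")
    return (lower + upper) / 2.0


def density_reduction_pct(d_nr: float, d_nd: float) -> float:
    """Percent buoyant-density reduction under ND relative to NR."""
    if d_nr <= 0:
        raise ValueError("reference density must be positive")
    return 100.0 * (d_nr - d_nd) / d_nr


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding for reported figures (1.2605 -> 1.261)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
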