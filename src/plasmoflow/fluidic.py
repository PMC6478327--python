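"""Fluidic parameters of endoplasm flow channels.

Dimensionless flow numbers (Reynolds, Womersley), lumped fluidic element
values (Poiseuille resistance, elastic-wall compliance) from channel geometry
and material properties, and conversion between the fluidic and electrical
unit systems used for circuit simulation.

All quantities are strict SI internally: metres, seconds, pascals, N·s/m⁵
for fluidic resistance and m⁵/N for compliance.  Convenience constants for
the μm / μm·min⁻¹ conventions used at the data boundary are provided at the
bottom of the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "FluidProperties", "TubeGeometry", "DimensionlessNumbers",
    "ElasticTubeState", "WindkesselElement",
    "reynolds_number", "womersley_number", "fluidic_resistance",
    "fluidic_capacitance", "normalized_radius", "to_electrical", "to_fluidic",
    "UM", "UM_PER_MIN", "MINUTE",
]

#: one micrometre in metres
UM = 1e-6
#: one μm/min in m/s
UM_PER_MIN = 1e-6 / 60.0
#: one minute in seconds
MINUTE = 60.0

UnitSystem = Literal["fluidic", "electrical"]


@dataclass(frozen=True)
class FluidProperties:
    """Bulk material properties of the cytoplasm.

    Parameters
    ----------
    density : float
        Cytoplasm density ρ in kg/m³.
    viscosity : float
        Dynamic viscosity η in N·s/m².
    youngs_modulus : float
        Young's modulus E of the channel wall in Pa.  Enters the
        compliance of an elastic channel, not the flow numbers.
    """

    density: float
    viscosity: float
    youngs_modulus: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0 or self.youngs_modulus <= 0:
            raise ValueError("fluid properties must be strictly positive")


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of one cylindrical vein segment (SI units).

    ``diameter`` defaults to ``2 * radius`` but may be supplied separately
    when the characteristic diameter used for the Reynolds number differs
    from the lumped-element radius.
    """

    radius: float
    length: float
    diameter: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.diameter is None:
            object.__setattr__(self, "diameter", 2.0 * self.radius)
        elif self.diameter <= 0:
            raise ValueError("diameter must be > 0")


@dataclass(frozen=True)
class DimensionlessNumbers:
    """Reynolds and Womersley numbers of a flow regime."""

    reynolds: float
    womersley: float

    def __post_init__(self) -> None:
        if self.reynolds < 0 or self.womersley < 0:
            raise ValueError("dimensionless numbers must be >= 0")


@dataclass(frozen=True)
class ElasticTubeState:
    """State of an elastic channel wall under a transmural pressure change.

    ``normalized_radius`` is h = a/a₀; for a linearly elastic wall
    h² = 1 + 2Δp/E, so h² itself tracks the pressure.  ``strain`` is
    ε = (h² − 1)/2 = Δp/E.  ``axial_position`` is carried for interface
    completeness in axially resolved descriptions.
    """

    pressure_change: float
    strain: float
    normalized_radius: float
    axial_position: float = 0.0

    def __post_init__(self) -> None:
        if self.normalized_radius <= 0:
            raise ValueError("normalized radius must be > 0")


@dataclass(frozen=True)
class WindkesselElement:
    """One three-element Windkessel unit.

    ``r1`` is the series resistance (internal friction of the cytoplasm),
    ``r2`` the leakage resistance through the permeable channel 'wall',
    ``c`` the compliance of the wall.  Values are either all fluidic
    (N·s/m⁵, m⁵/N) or all electrical (Ω, F); the products r1·c and r2·c
    are seconds in either system.
    """

    r1: float
    r2: float
    c: float
    unit_system: UnitSystem = "fluidic"

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("resistances must be > 0")
        if self.c < 0:
            raise ValueError("compliance must be >= 0")
        if self.unit_system not in ("fluidic", "electrical"):
            raise ValueError(f"unknown unit system {self.unit_system!r}")


def reynolds_number(fluid: FluidProperties, velocity: float, diameter: float) -> float:
    """Reynolds number Re = ρ·v·d/η of channel flow.

    Values ≪ 1 indicate inertia-free laminar (Poiseuille) flow; for
    endoplasm streaming at tens of μm/min in ~70 μm channels Re is of
    order 10⁻⁸.

    Parameters are SI: ``velocity`` in m/s, ``diameter`` in m.
    """
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return fluid.density * velocity * diameter / fluid.viscosity


def womersley_number(fluid: FluidProperties, radius: float, omega: float) -> float:
    """Womersley number α = a·sqrt(ω·ρ/η) of pulsatile channel flow.

    α ≪ 1 means the oscillatory flow profile is quasi-steady parabolic.
    ``omega`` is the angular frequency of the pulsation in rad/s.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return radius * math.sqrt(omega * fluid.density / fluid.viscosity)


def flow_numbers(
    fluid: FluidProperties, geometry: TubeGeometry, velocity: float, omega: float
) -> DimensionlessNumbers:
    """Both dimensionless numbers for one channel and flow condition."""
    return DimensionlessNumbers(
        reynolds=reynolds_number(fluid, velocity, geometry.diameter),
        womersley=womersley_number(fluid, geometry.radius, omega),
    )


def fluidic_resistance(viscosity: float, geometry: TubeGeometry) -> float:
    """Poiseuille resistance R = 8ηl/(πa⁴) of a cylindrical segment, N·s/m⁵."""
    if viscosity <= 0:
        raise ValueError("viscosity must be > 0")
    return 8.0 * viscosity * geometry.length / (math.pi * geometry.radius**4)


def fluidic_capacitance(geometry: TubeGeometry, youngs_modulus: float) -> float:
    """Compliance C = 2πa₀²l/E of a linearly elastic channel wall, m⁵/N.

    Volume stored per unit transmural pressure.  Softer walls (smaller E)
    store more volume per unit pressure.
    """
    if youngs_modulus <= 0:
        raise ValueError("Young's modulus must be > 0")
    return 2.0 * math.pi * geometry.radius**2 * geometry.length / youngs_modulus


def normalized_radius(
    pressure_change: float, youngs_modulus: float, axial_position: float = 0.0
) -> ElasticTubeState:
    """Wall state under a transmural pressure change Δp.

    For a linearly elastic wall the strain is ε = Δp/E and the normalized
    radius h = a/a₀ satisfies h² = 1 + 2Δp/E, so h² can be read as a
    pressure.  A pressure drop large enough to make h² ≤ 0 would collapse
    the channel and is rejected.
    """
    if youngs_modulus <= 0:
        raise ValueError("Young's modulus must be > 0")
    h_sq = 1.0 + 2.0 * pressure_change / youngs_modulus
    if h_sq <= 0:
        raise ValueError(f"channel collapse: h² = {h_sq:g} <= 0")
    h = math.sqrt(h_sq)
    return ElasticTubeState(
        pressure_change=pressure_change,
        strain=(h_sq - 1.0) / 2.0,
        normalized_radius=h,
        axial_position=axial_position,
    )


def to_electrical(element: WindkesselElement, reference_r1: float) -> WindkesselElement:
    """Convert a fluidic Windkessel element to its electrical twin.

    The conversion is a pure impedance rescaling anchored to a reference
    series resistance: with k = reference_r1 / r1, both resistances are
    multiplied by k and the compliance divided by k.  Every time constant
    (r1·c, r2·c) and hence every frequency-domain quantity (cut-off, gain,
    phase) is invariant; only the impedance level changes.  The inverse is
    :func:`to_fluidic`.
    """
    if element.unit_system != "fluidic":
        raise ValueError("to_electrical expects a fluidic element")
    if reference_r1 <= 0:
        raise ValueError("reference resistance must be > 0")
    k = reference_r1 / element.r1
    return WindkesselElement(
        r1=element.r1 * k,
        r2=element.r2 * k,
        c=element.c / k,
        unit_system="electrical",
    )


def to_fluidic(element: WindkesselElement, reference_r1: float) -> WindkesselElement:
    """Inverse of :func:`to_electrical`: rescale back to a fluidic r1."""
    if element.unit_system != "electrical":
        raise ValueError("to_fluidic expects an electrical element")
    if reference_r1 <= 0:
        raise ValueError("reference resistance must be > 0")
    k = reference_r1 / element.r1
    return WindkesselElement(
        r1=element.r1 * k,
        r2=element.r2 * k,
        c=element.c / k,
        unit_system="fluidic",
    )


def element_from_geometry(
    fluid: FluidProperties,
    geometry: TubeGeometry,
    r2_over_r1: float = 50.0,
) -> WindkesselElement:
    """Fluidic Windkessel element for one vein segment.

    The leakage resistance of the wall-less, permeable channels cannot be
    read from images; by analogy with highly permeable vessels it defaults
    to 50× the series resistance.
    """
    r1 = fluidic_resistance(fluid.viscosity, geometry)
    c = fluidic_capacitance(geometry, fluid.youngs_modulus)
    return WindkesselElement(r1=r1, r2=r2_over_r1 * r1, c=c, unit_system="fluidic")


def rescaled(element: WindkesselElement, **changes: float) -> WindkesselElement:
    """Copy of ``element`` with selected fields replaced."""
    return replace(element, **changes)
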