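"""Dimensionless characterization of the pressure–flow relation.

The three-element Windkessel response collapses onto two dimensionless
parameters, r̃ = R1/R2 and c̃ = C·R2·ω.  This module evaluates the
dimensionless flow amplitude q̃ = R2/|Z|, the relative phase shift θ_rel,
and the oscillatory power dissipation W on single points and on parameter
grids (surface scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fluidic import WindkesselElement
from .windkessel import impedance

__all__ = [
    "DimensionlessPoint", "SurfaceScan",
    "dimensionless_params", "relative_phase",
    "dimensionless_flow_amplitude", "dimensionless_flow",
    "power_dissipation", "surface_scan",
]


@dataclass(frozen=True)
class DimensionlessPoint:
    """One point in (r̃, c̃) parameter space with its derived quantities."""

    r_tilde: float
    c_tilde: float
    q_amplitude: float
    theta_rel_deg: float
    power_w: float


@dataclass(frozen=True)
class Extremum:
    """Location and value of a grid extremum; ``on_boundary`` marks edges."""

    r_tilde: float
    c_tilde: float
    value: float
    on_boundary: bool


@dataclass(frozen=True)
class SurfaceScan:
    """Quantities evaluated over a rectangular (r̃, c̃) grid.

    Matrices are indexed [i_r, i_c] matching ``r_grid``/``c_grid``.
    Extrema are reported with a tie-break to the smallest (r̃, c̃) pair and
    flagged when they lie on the grid boundary.
    """

    r_grid: np.ndarray = field(repr=False)
    c_grid: np.ndarray = field(repr=False)
    theta_rel: np.ndarray = field(repr=False)
    q_amplitude: np.ndarray = field(repr=False)
    power_w: np.ndarray = field(repr=False)
    impedance_magnitude: np.ndarray = field(repr=False)
    extrema: dict[str, dict[str, Extremum]] = field(default_factory=dict)


def dimensionless_params(element: WindkesselElement, omega: float) -> tuple[float, float]:
    """(r̃, c̃) = (r1/r2, c·r2·ω) for an element at angular frequency ω."""
    if element.r2 <= 0:
        raise ValueError("r2 must be > 0")
    return element.r1 / element.r2, element.c * element.r2 * omega


def relative_phase(r_tilde: float, c_tilde: float) -> float:
    """Relative phase shift θ_rel = arctan(c̃ / ((r̃+1) + r̃c̃²)), degrees.

    Identical to the impedance phase of the dimensional element whose
    (r̃, c̃) these are — the two formulations are the same physics.
    """
    if r_tilde < 0 or c_tilde < 0:
        raise ValueError("dimensionless parameters must be >= 0")
    return math.degrees(math.atan2(c_tilde, (r_tilde + 1.0) + r_tilde * c_tilde**2))


def dimensionless_flow_amplitude(
    r_tilde: float, c_tilde: float, *, literal_rendered: bool = False
) -> float:
    """Amplitude of the dimensionless flow q̃ = q·R2/Δp₀.

    The amplitude equals R2/|Z| and in dimensionless form

        |q̃| = sqrt((1 + c̃²) / (r̃²(1 + c̃²) + 2r̃ + 1)).

    ``literal_rendered=True`` evaluates instead the radical-free variant
    (r̃+1+r̃c̃²)/((r̃+1)²+r̃²c̃²), provided for comparison only; it is not
    consistent with θ_rel and flattens the flow peak at small r̃.
    """
    if r_tilde < 0 or c_tilde < 0:
        raise ValueError("dimensionless parameters must be >= 0")
    c2 = c_tilde**2
    if literal_rendered:
        return (r_tilde + 1.0 + r_tilde * c2) / ((r_tilde + 1.0) ** 2 + r_tilde**2 * c2)
    return math.sqrt((1.0 + c2) / (r_tilde**2 * (1.0 + c2) + 2.0 * r_tilde + 1.0))


def dimensionless_flow(
    r_tilde: float, c_tilde: float, time_phase: float | np.ndarray
) -> np.ndarray:
    """q̃(ωt) = |q̃|·cos(ωt − θ_rel) at the given time phase(s) ωt (rad)."""
    amp = dimensionless_flow_amplitude(r_tilde, c_tilde)
    theta = math.radians(relative_phase(r_tilde, c_tilde))
    return amp * np.cos(np.asarray(time_phase) - theta)


def power_dissipation(q_amplitude: float, impedance_magnitude: float, theta_deg: float) -> float:
    """Oscillatory power dissipation W = ½·Q²·|Z|·cos θ over one period.

    The steady part of the dissipation (mean pressure × mean flow) is small
    and excluded.  θ = 90° (purely reactive) dissipates nothing.
    """
    if q_amplitude < 0:
        raise ValueError("flow amplitude must be >= 0")
    return 0.5 * q_amplitude**2 * impedance_magnitude * math.cos(math.radians(theta_deg))


def point(element: WindkesselElement, omega: float) -> DimensionlessPoint:
    """Full dimensionless characterization of an element at ω."""
    r_t, c_t = dimensionless_params(element, omega)
    amp = dimensionless_flow_amplitude(r_t, c_t)
    theta = relative_phase(r_t, c_t)
    z_mag = impedance(element, omega).magnitude / element.r2
    return DimensionlessPoint(r_t, c_t, amp, theta, power_dissipation(amp, z_mag, theta))


def _extrema(r_grid: np.ndarray, c_grid: np.ndarray, values: np.ndarray) -> dict[str, Extremum]:
    """Grid max/min with tie-break to smallest (r̃, c̃), boundary-flagged."""
    out = {}
    for name, pick in (("max", np.nanmax), ("min", np.nanmin)):
        target = pick(values)
        # lexicographic tie-break: first index in row-major order is the
        # smallest r̃, then smallest c̃
        i, j = np.argwhere(values == target)[0]
        out[name] = Extremum(
            r_tilde=float(r_grid[i]),
            c_tilde=float(c_grid[j]),
            value=float(target),
            on_boundary=bool(
                i in (0, len(r_grid) - 1) or j in (0, len(c_grid) - 1)
            ),
        )
    return out


def surface_scan(
    r_range: tuple[float, float] = (0.0, 1.0),
    c_range: tuple[float, float] = (0.0, 10.0),
    n_points: int = 201,
) -> SurfaceScan:
    """Evaluate θ_rel, |q̃|, W and |Z̃| on a rectangular (r̃, c̃) grid.

    |Z̃| = |Z|/R2 = 1/|q̃| where finite.  Extrema of each surface are
    recorded; for the default ranges the phase maximum sits on the
    (r̃=0, c̃=c̃_max) corner.
    """
    if r_range[1] <= r_range[0] or c_range[1] <= c_range[0]:
        raise ValueError("ranges must be non-degenerate")
    r_grid = np.linspace(r_range[0], r_range[1], n_points)
    c_grid = np.linspace(c_range[0], c_range[1], n_points)
    r = r_grid[:, None]
    c = c_grid[None, :]
    c2 = c**2
    theta = np.degrees(np.arctan2(c, (r + 1.0) + r * c2)) + 0.0 * r
    q_amp = np.sqrt((1.0 + c2) / (r**2 * (1.0 + c2) + 2.0 * r + 1.0))
    z_mag = 1.0 / q_amp
    power = 0.5 * q_amp**2 * z_mag * np.cos(np.radians(theta))
    return SurfaceScan(
        r_grid=r_grid,
        c_grid=c_grid,
        theta_rel=theta,
        q_amplitude=q_amp,
        power_w=power,
        impedance_magnitude=z_mag,
        extrema={
            "theta_rel": _extrema(r_grid, c_grid, theta),
            "q_amplitude": _extrema(r_grid, c_grid, q_amp),
            "power_w": _extrema(r_grid, c_grid, power),
            "impedance_magnitude": _extrema(r_grid, c_grid, z_mag),
        },
    )
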