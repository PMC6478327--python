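"""Closed-form analysis of a single three-element Windkessel.

Complex impedance and its decomposition, the two RC time constants, the
low-pass cut-off frequency, and the analytical pressure-to-flow solution
for a cosine driving pressure with optional DC offset.

Sign convention: the reactance is stored as the *positive* magnitude of the
imaginary part, and the phase θ (degrees) is positive when the flow lags the
pressure.  Where complex arithmetic is needed internally the equivalent
form Z = z_real − j·z_imag is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fluidic import WindkesselElement

__all__ = [
    "ImpedanceResult", "TimeConstants", "PressureSource", "FlowWave",
    "impedance", "time_constants", "cutoff_frequency", "flow_response",
    "limiting_cases",
]


@dataclass(frozen=True)
class ImpedanceResult:
    """Complex impedance of a three-element Windkessel at one frequency.

    ``z_imag`` is the reactance magnitude (≥ 0); ``phase_deg`` is the angle
    by which flow lags pressure, in [0°, 90°) for passive elements.
    """

    z_real: float
    z_imag: float
    magnitude: float
    phase_deg: float
    omega: float

    def as_complex(self) -> complex:
        """Z with the lag convention folded in: Z = z_real − j·z_imag."""
        return complex(self.z_real, -self.z_imag)


@dataclass(frozen=True)
class TimeConstants:
    """The two RC time constants of the element, seconds.

    τ₂ = r2·c is the relaxation time of the shunt; τ₁ = τ₂·r1/(r1+r2) is
    the shorter constant governing the cut-off, so 0 < τ₁ ≤ τ₂.
    """

    tau1: float
    tau2: float


@dataclass(frozen=True)
class PressureSource:
    """Cosine pressure (voltage) source Δp(t) = Δp₀·cos(ωt) + dc_offset."""

    amplitude: float
    omega: float
    dc_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    def samples(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.cos(self.omega * np.asarray(t)) + self.dc_offset


@dataclass(frozen=True)
class FlowWave:
    """Flow response q(t) = Q·cos(ωt − θ) + q_dc on a time grid."""

    amplitude: float
    phase_lag_deg: float
    dc_component: float
    time: np.ndarray = field(repr=False)
    samples: np.ndarray = field(repr=False)


def impedance(element: WindkesselElement, omega: float) -> ImpedanceResult:
    """Impedance of the element at angular frequency ω (rad/s).

    Z_real = r1 + r2/(1 + ω²r2²c²);  Z_imag = r2²cω/(1 + ω²r2²c²);
    θ = arctan(Z_imag/Z_real) in degrees.  At ω = 0 the capacitor is open
    and Z = r1 + r2 with zero phase.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    r1, r2, c = element.r1, element.r2, element.c
    denom = 1.0 + (omega * r2 * c) ** 2
    z_real = r1 + r2 / denom
    z_imag = r2**2 * c * omega / denom
    magnitude = math.hypot(z_real, z_imag)
    phase = math.degrees(math.atan2(z_imag, z_real))
    return ImpedanceResult(z_real, z_imag, magnitude, phase, omega)


def time_constants(element: WindkesselElement) -> TimeConstants:
    """τ₁ = r1·r2·c/(r1+r2) and τ₂ = r2·c, seconds."""
    r1, r2, c = element.r1, element.r2, element.c
    if c <= 0:
        raise ValueError("compliance must be > 0 for time constants")
    tau2 = r2 * c
    tau1 = r1 * tau2 / (r1 + r2)
    return TimeConstants(tau1=tau1, tau2=tau2)


def cutoff_frequency(element: WindkesselElement) -> float:
    """Low-pass cut-off f_c = (r1+r2)/(2π·c·r1·r2) ≡ 1/(2π·τ₁), Hz.

    Frequency at which the voltage-divider transfer across the element
    falls 3 dB below its low-frequency plateau.  With zero compliance the
    element passes all frequencies; +inf is returned with a warning.
    """
    r1, r2, c = element.r1, element.r2, element.c
    if c == 0:
        warnings.warn("zero compliance: cut-off frequency is infinite")
        return math.inf
    return (r1 + r2) / (2.0 * math.pi * c * r1 * r2)


def flow_response(
    element: WindkesselElement,
    source: PressureSource,
    time_grid: np.ndarray,
) -> FlowWave:
    """Steady-state flow through the element for a cosine pressure source.

    The oscillatory part is q(t) = (Δp₀/|Z(ω)|)·cos(ωt − θ); a DC pressure
    offset adds the steady component dc_offset/(r1+r2) (the capacitor is
    open at DC).  For ω = 0 the source is entirely steady.
    """
    t = np.asarray(time_grid, dtype=float)
    dc_flow = source.dc_offset / (element.r1 + element.r2)
    if source.omega == 0:
        steady = (source.amplitude + source.dc_offset) / (element.r1 + element.r2)
        return FlowWave(
            amplitude=source.amplitude / (element.r1 + element.r2),
            phase_lag_deg=0.0,
            dc_component=dc_flow,
            time=t,
            samples=np.full_like(t, steady),
        )
    z = impedance(element, source.omega)
    amplitude = source.amplitude / z.magnitude
    theta = math.radians(z.phase_deg)
    samples = amplitude * np.cos(source.omega * t - theta) + dc_flow
    return FlowWave(
        amplitude=amplitude,
        phase_lag_deg=z.phase_deg,
        dc_component=dc_flow,
        time=t,
        samples=samples,
    )


def limiting_cases(element: WindkesselElement, omega: float = 0.08) -> dict[str, dict]:
    """The three degenerate limits of the element at a given ω.

    * c = 0  — purely resistive: θ = 0, |Z| = r1 + r2.
    * r2 = 0 — shunt shorted: θ = 0, |Z| = r1.
    * r1 = 0 — reactance unchanged, Z_real = r2/(1 + ω²r2²c²).

    Returns a report keyed by the limit name; each entry holds the limit's
    z_real, z_imag, magnitude and phase.
    """
    r1, r2, c = element.r1, element.r2, element.c
    denom = 1.0 + (omega * r2 * c) ** 2
    report = {
        "c_zero": {
            "z_real": r1 + r2, "z_imag": 0.0,
            "magnitude": r1 + r2, "phase_deg": 0.0,
        },
        "r2_zero": {
            "z_real": r1, "z_imag": 0.0, "magnitude": r1, "phase_deg": 0.0,
        },
        "r1_zero": {
            "z_real": r2 / denom,
            "z_imag": r2**2 * c * omega / denom,
        },
    }
    lim = report["r1_zero"]
    lim["magnitude"] = math.hypot(lim["z_real"], lim["z_imag"])
    lim["phase_deg"] = math.degrees(math.atan2(lim["z_imag"], lim["z_real"]))
    return report
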