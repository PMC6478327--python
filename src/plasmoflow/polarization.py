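"""Polarization and chemotaxis as a two-branch Windkessel circuit.

A stationary, unpolarized (micro)plasmodium is modelled as two identical
three-element Windkessel branches fed from a shared node by an oscillating
pressure source: the inflow splits evenly and the cycle-averaged source
current is zero.  Local softening of the cortex — a rise of one branch's
compliance — lowers that branch's impedance and diverts flow toward it,
which is the circuit-level statement of how a softness gradient polarizes
the cell and starts migration.

The module also carries the volumetric flow budget: total flow accumulated
by the advancing cell, per-vein backward flow, and the frontal flow they
imply through conservation (Kirchhoff's current law).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fluidic import WindkesselElement
from .network import CircuitNetwork, Stage, transient_solve
from .windkessel import PressureSource, impedance

__all__ = [
    "TwoBranchCircuit", "BranchCurrents", "FlowBudget",
    "branch_currents", "mean_source_current", "volumetric_flow",
    "kcl_flow_budget",
]


@dataclass(frozen=True)
class TwoBranchCircuit:
    """Two Windkessel branches sharing a sourced node.

    The circuit is symmetric iff both branches are identical; softening
    one side (larger compliance) makes it the effective 'front'.
    """

    left: WindkesselElement
    right: WindkesselElement
    source: PressureSource

    @property
    def symmetric(self) -> bool:
        return (
            self.left.r1 == self.right.r1
            and self.left.r2 == self.right.r2
            and self.left.c == self.right.c
        )

    def as_network(self) -> CircuitNetwork:
        return CircuitNetwork(
            stages=[
                Stage("N", "L", self.left.r1, self.left.r2, self.left.c),
                Stage("N", "R", self.right.r1, self.right.r2, self.right.c),
            ],
            source_node="N",
            source=self.source,
            probes=["L", "R"],
        )


@dataclass(frozen=True)
class BranchCurrents:
    """Phasor branch currents and their asymmetry.

    ``asymmetry_ratio`` = |i_left| / |i_right| = |Z_right| / |Z_left|;
    a ratio > 1 means the left branch (by convention the softened one)
    carries more flow.  ``i_source`` is the instantaneous total, equal to
    i_left + i_right at every instant (KCL at the shared node).
    """

    i_left_amplitude: float
    i_left_phase_deg: float
    i_right_amplitude: float
    i_right_phase_deg: float
    asymmetry_ratio: float
    time: np.ndarray = field(repr=False)
    i_source: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class FlowBudget:
    """Volumetric flow conservation for a migrating cell, μm³/min.

    ``q_front = q_total − Σ q_back``: whatever volume the advancing front
    accumulates beyond the backward vein flow must stream forward through
    the frontal sheet.
    """

    q_total: float
    q_back_per_vein: tuple[float, ...]
    q_front: float
    front_back_ratio: float
    assumed_height_um: float = 100.0
    vein_radius_um: float = 20.0

    @property
    def q_back_total(self) -> float:
        return sum(self.q_back_per_vein)


def branch_currents(
    circuit: TwoBranchCircuit, omega: float, n_samples: int = 512
) -> BranchCurrents:
    """Phasor currents of both branches for a cosine drive at ω.

    Each branch sees the full source voltage, so its current is simply
    the source amplitude divided by the branch impedance; the asymmetry
    ratio is amplitude-invariant.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    amp = circuit.source.amplitude
    z_l = impedance(circuit.left, omega)
    z_r = impedance(circuit.right, omega)
    i_l = amp / z_l.magnitude
    i_r = amp / z_r.magnitude
    period = 2.0 * math.pi / omega
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    i_src = i_l * np.cos(omega * t - math.radians(z_l.phase_deg)) + i_r * np.cos(
        omega * t - math.radians(z_r.phase_deg)
    )
    return BranchCurrents(
        i_left_amplitude=i_l,
        i_left_phase_deg=-z_l.phase_deg,
        i_right_amplitude=i_r,
        i_right_phase_deg=-z_r.phase_deg,
        asymmetry_ratio=z_r.magnitude / z_l.magnitude,
        time=t,
        i_source=i_src,
    )


def mean_source_current(
    circuit: TwoBranchCircuit,
    n_periods: int = 5,
    from_startup: bool = True,
    samples_per_period: int = 200,
) -> float:
    """Source current averaged over ``n_periods`` oscillation periods.

    ``from_startup=True`` integrates the transient from zero initial
    charge and averages the first ``n_periods`` periods — the charging of
    the compliances makes this mean non-zero even for a symmetric circuit,
    and markedly larger for an asymmetric one.  With
    ``from_startup=False`` the average is taken over ``n_periods`` whole
    periods of the settled (periodic steady state) response, which is
    exactly zero for a pure AC source.
    """
    if n_periods < 1:
        raise ValueError("need at least one period")
    omega = circuit.source.omega
    if omega <= 0:
        raise ValueError("source must oscillate")
    if circuit.source.amplitude == 0 and circuit.source.dc_offset == 0:
        return 0.0
    period = 2.0 * math.pi / omega
    dt = period / samples_per_period
    tau2 = max(circuit.left.r2 * circuit.left.c, circuit.right.r2 * circuit.right.c)
    settle = 0.0 if from_startup else 10.0 * tau2
    # round the settling window to whole periods so the average window is
    # aligned with the drive
    settle_periods = math.ceil(settle / period)
    t_end = (settle_periods + n_periods) * period
    result = transient_solve(circuit.as_network(), (0.0, t_end), dt)
    i_src = result.stage_current[0] + result.stage_current[1]
    n_avg = n_periods * samples_per_period
    window = i_src[:n_avg] if from_startup else i_src[-n_avg - 1 : -1]
    return float(np.mean(window))


def volumetric_flow(velocity_um_min: float, radius_um: float) -> float:
    """Volumetric flow Q = v·πa² through a circular vein cross-section.

    ``velocity_um_min`` in μm/min, ``radius_um`` in μm; result in μm³/min.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    return velocity_um_min * math.pi * radius_um**2


def kcl_flow_budget(
    q_total: float,
    q_back_list: list[float] | tuple[float, ...],
    assumed_height_um: float = 100.0,
    vein_radius_um: float = 20.0,
) -> FlowBudget:
    """Frontal flow from total and backward flows by conservation.

    All flows in μm³/min.  A negative frontal flow signals inconsistent
    measurements and is reported with a warning rather than rejected.
    """
    q_back = tuple(float(q) for q in q_back_list)
    q_front = q_total - sum(q_back)
    if q_front < 0:
        warnings.warn(
            "negative frontal flow: backward flows exceed the total; "
            "check the measurements"
        )
    back_sum = sum(q_back)
    ratio = math.inf if back_sum == 0 else q_front / back_sum
    return FlowBudget(
        q_total=q_total,
        q_back_per_vein=q_back,
        q_front=q_front,
        front_back_ratio=ratio,
        assumed_height_um=assumed_height_um,
        vein_radius_um=vein_radius_um,
    )
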