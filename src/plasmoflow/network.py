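"""Frequency- and time-domain solution of Windkessel networks.

A network is a directed tree of three-element Windkessel stages hanging off
one ideal pressure (voltage) source: each stage contributes a series
resistance r1 from node A to node B plus a shunt {compliance c parallel to
leakage r2} from node B to ground.  The module provides

* complex nodal (AC) analysis at a single angular frequency,
* Bode sweeps and −3 dB cut-off extraction (absolute or plateau-referenced),
* transient integration of the capacitor ODEs (trapezoidal, A-stable),
* single-frequency phase extraction between two time series.

Networks in this problem have tens of nodes at most, so the solver is dense.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fluidic import WindkesselElement
from .windkessel import PressureSource

__all__ = [
    "Stage", "CircuitNetwork", "ACSolution", "BodeResult", "TransientResult",
    "build_single_stage", "build_y_cascade", "ac_solve", "bode",
    "cutoff_from_bode", "transient_solve", "phase_between",
]

GROUND = "gnd"


@dataclass(frozen=True)
class Stage:
    """One Windkessel stage: series r1 from ``from_node`` to ``to_node``,
    shunt {c ∥ r2} from ``to_node`` to ground."""

    from_node: str
    to_node: str
    r1: float
    r2: float
    c: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("stage resistances must be > 0")
        if self.c < 0:
            raise ValueError("stage compliance must be >= 0")
        if self.from_node == self.to_node:
            raise ValueError("stage endpoints must differ")


@dataclass
class CircuitNetwork:
    """Directed netlist of Windkessel stages with one pressure source.

    ``probes`` lists shunt-node names in path order from the source
    (position 1, 2, 3, … of a cascade).
    """

    stages: list[Stage]
    source_node: str
    source: PressureSource
    probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def nodes(self) -> list[str]:
        """All non-ground node names, source first, in stage order."""
        seen = {self.source_node: None}
        for st in self.stages:
            seen.setdefault(st.from_node, None)
            seen.setdefault(st.to_node, None)
        seen.pop(GROUND, None)
        return list(seen)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("network has no stages")
        nodes = set(self.nodes)
        if self.source_node not in nodes:
            raise ValueError(f"source node {self.source_node!r} not in network")
        # connectivity from the source through stage edges
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for st in self.stages:
            adj[st.from_node].add(st.to_node)
            adj[st.to_node].add(st.from_node)
        reached, frontier = {self.source_node}, [self.source_node]
        while frontier:
            n = frontier.pop()
            for m in adj[n]:
                if m not in reached:
                    reached.add(m)
                    frontier.append(m)
        unreached = nodes - reached
        if unreached:
            raise ValueError(f"nodes not connected to source: {sorted(unreached)}")
        for p in self.probes:
            if p not in nodes:
                raise ValueError(f"probe {p!r} is not a network node")

    def to_json(self, path: str | Path) -> None:
        """Write the netlist as JSON."""
        payload = {
            "nodes": self.nodes,
            "stages": [
                {"from": s.from_node, "to": s.to_node,
                 "r1": s.r1, "r2": s.r2, "c": s.c}
                for s in self.stages
            ],
            "source": {
                "node": self.source_node,
                "amplitude": self.source.amplitude,
                "omega": self.source.omega,
                "dc": self.source.dc_offset,
            },
            "probes": self.probes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CircuitNetwork":
        payload = json.loads(Path(path).read_text())
        stages = [
            Stage(s["from"], s["to"], s["r1"], s["r2"], s["c"])
            for s in payload["stages"]
        ]
        src = payload["source"]
        return cls(
            stages=stages,
            source_node=src["node"],
            source=PressureSource(src["amplitude"], src["omega"], src.get("dc", 0.0)),
            probes=payload.get("probes", []),
        )


@dataclass(frozen=True)
class ACSolution:
    """Phasor solution of the network at one angular frequency.

    Voltages are complex phasors relative to the source phase; stage
    currents flow from ``from_node`` to ``to_node``.
    """

    omega: float
    node_voltage: dict[str, complex]
    stage_current: list[complex]
    kcl_residual: float

    def gain(self, node: str, source_amplitude: float) -> float:
        return abs(self.node_voltage[node]) / source_amplitude

    def phase_deg(self, node: str) -> float:
        return math.degrees(np.angle(self.node_voltage[node]))


@dataclass(frozen=True)
class BodeResult:
    """Gain/phase sweep of selected probes over a log frequency grid.

    Gain is in dB relative to the source amplitude.  The originating
    network is kept so cut-off extraction can refine crossings by re-solving.
    """

    frequency_hz: np.ndarray = field(repr=False)
    gain_db: dict[str, np.ndarray] = field(repr=False)
    phase_deg: dict[str, np.ndarray] = field(repr=False)
    network: CircuitNetwork = field(repr=False, compare=False)


@dataclass(frozen=True)
class TransientResult:
    """Node voltages and stage currents integrated over time."""

    time: np.ndarray = field(repr=False)
    node_voltage: dict[str, np.ndarray] = field(repr=False)
    stage_current: dict[int, np.ndarray] = field(repr=False)


def build_single_stage(
    element: WindkesselElement, source: PressureSource | None = None
) -> CircuitNetwork:
    """Single three-element Windkessel as a one-stage network."""
    if source is None:
        source = PressureSource(amplitude=1.0, omega=0.08)
    return CircuitNetwork(
        stages=[Stage("in", "n1", element.r1, element.r2, element.c)],
        source_node="in",
        source=source,
        probes=["n1"],
    )


def build_y_cascade(
    element: WindkesselElement,
    n_stem: int = 2,
    n_arms: int = 2,
    source: PressureSource | None = None,
) -> CircuitNetwork:
    """Y-shaped cascade of identical Windkessel stages.

    ``n_stem`` stages in series from the source, then ``n_arms`` identical
    single-stage arms in parallel from the last stem node — the branching
    topology of a mesoplasmodial vein, which splits only in its final
    third.  Probes 1..n_stem sit on the stem shunt nodes; the last probe
    (the paper-reading 'position 3' for the 2+2 circuit) is the first arm
    end.  Arms are symmetric, so every arm end carries the same voltage.
    """
    if n_stem < 1:
        raise ValueError("need at least one stem stage")
    if n_arms < 0:
        raise ValueError("arm count must be >= 0")
    if source is None:
        source = PressureSource(amplitude=1.0, omega=0.08)
    stages = []
    prev = "in"
    probes = []
    for i in range(1, n_stem + 1):
        node = f"stem{i}"
        stages.append(Stage(prev, node, element.r1, element.r2, element.c))
        probes.append(node)
        prev = node
    for j in range(1, n_arms + 1):
        stages.append(Stage(prev, f"arm{j}", element.r1, element.r2, element.c))
    if n_arms:
        probes.append("arm1")
    return CircuitNetwork(stages=stages, source_node="in", source=source, probes=probes)


def _assemble(network: CircuitNetwork, omega: float):
    """Complex admittance system over unknown (non-source) nodes.

    Returns (unknown node list, matrix A, rhs b) with A v = b.
    """
    unknowns = [n for n in network.nodes if n != network.source_node]
    index = {n: i for i, n in enumerate(unknowns)}
    n = len(unknowns)
    A = np.zeros((n, n), dtype=complex)
    b = np.zeros(n, dtype=complex)
    v_src = complex(network.source.amplitude)

    def stamp(node_a: str, node_b: str, y: complex) -> None:
        # admittance y between two nodes; GROUND and the source node are fixed
        for p, q in ((node_a, node_b), (node_b, node_a)):
            if p in index:
                A[index[p], index[p]] += y
                if q in index:
                    A[index[p], index[q]] -= y
                elif q == network.source_node:
                    b[index[p]] += y * v_src

    for st in network.stages:
        stamp(st.from_node, st.to_node, 1.0 / st.r1)
        stamp(st.to_node, GROUND, 1.0 / st.r2 + 1j * omega * st.c)
    return unknowns, A, b


def ac_solve(network: CircuitNetwork, omega: float) -> ACSolution:
    """Solve the complex nodal system at angular frequency ω.

    The source node is held at the source amplitude (phase reference);
    ground at zero.  Kirchhoff's current law is checked at every solved
    node; the residual is reported relative to the largest branch current.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    unknowns, A, b = _assemble(network, omega)
    diag = np.abs(np.diag(A))
    if np.any(diag == 0):
        dead = unknowns[int(np.argmin(diag))]
        raise np.linalg.LinAlgError(f"singular system: node {dead!r} has no admittance")
    try:
        v = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"singular nodal system: {err}") from err

    volts = {network.source_node: complex(network.source.amplitude)}
    volts[GROUND] = 0.0 + 0.0j
    volts.update(dict(zip(unknowns, v)))
    currents = [
        (volts[st.from_node] - volts[st.to_node]) / st.r1 for st in network.stages
    ]
    # KCL residual at every unknown node
    residual = 0.0
    scale = max((abs(i) for i in currents), default=1.0) or 1.0
    for node in unknowns:
        net = 0.0 + 0.0j
        for st, i_series in zip(network.stages, currents):
            if st.from_node == node:
                net -= i_series
            if st.to_node == node:
                net += i_series
                net -= volts[node] * (1.0 / st.r2 + 1j * omega * st.c)
        residual = max(residual, abs(net) / scale)
    volts.pop(GROUND)
    return ACSolution(
        omega=omega, node_voltage=volts, stage_current=currents, kcl_residual=residual
    )


def bode(
    network: CircuitNetwork,
    probes: list[str] | None = None,
    f_min: float = 1e-4,
    f_max: float = 10.0,
    n_points: int = 200,
) -> BodeResult:
    """Gain (dB re source) and phase sweep over a log-spaced frequency grid."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    probes = probes if probes is not None else network.probes
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    amp = network.source.amplitude
    gains = {p: np.empty(n_points) for p in probes}
    phases = {p: np.empty(n_points) for p in probes}
    for k, f in enumerate(freqs):
        sol = ac_solve(network, 2.0 * math.pi * f)
        for p in probes:
            gains[p][k] = 20.0 * math.log10(abs(sol.node_voltage[p]) / amp)
            phases[p][k] = math.degrees(np.angle(sol.node_voltage[p]))
    return BodeResult(frequency_hz=freqs, gain_db=gains, phase_deg=phases, network=network)


def cutoff_from_bode(
    bode_result: BodeResult,
    probe: str,
    convention: str = "absolute",
) -> float:
    """−3 dB cut-off frequency of one probe, Hz.

    * ``absolute``: frequency where the probe gain equals 1/√2 of the
      *source* amplitude (−3.0103 dB re source) — the read-off used for
      cascade Bode plots.
    * ``relative``: 1/√2 of the probe's own low-frequency (DC) plateau —
      for a single stage this is analytically identical to
      f_c = (r1+r2)/(2π·c·r1·r2).

    The bracketing grid crossing is refined by bisection on the re-solved
    network to 1e-4 relative accuracy.
    """
    from scipy.optimize import brentq

    network = bode_result.network
    amp = network.source.amplitude
    if convention == "absolute":
        target = amp / math.sqrt(2.0)
    elif convention == "relative":
        dc = ac_solve(network, 0.0)
        target = abs(dc.node_voltage[probe]) / math.sqrt(2.0)
    else:
        raise ValueError("convention must be 'absolute' or 'relative'")

    def excess(f: float) -> float:
        sol = ac_solve(network, 2.0 * math.pi * f)
        return abs(sol.node_voltage[probe]) - target

    freqs = bode_result.frequency_hz
    lo, hi = freqs[0], freqs[-1]
    if excess(lo) <= 0 or excess(hi) >= 0:
        raise ValueError(
            f"no -3 dB crossing for probe {probe!r} in "
            f"[{lo:g}, {hi:g}] Hz; widen the sweep range"
        )
    return brentq(excess, lo, hi, rtol=1e-5)


def _conductance_system(network: CircuitNetwork):
    """Real conductance matrix G, capacitance diagonal Cd and source
    coupling vector g_src over unknown nodes, for transient analysis."""
    unknowns = [n for n in network.nodes if n != network.source_node]
    index = {n: i for i, n in enumerate(unknowns)}
    n = len(unknowns)
    G = np.zeros((n, n))
    Cd = np.zeros(n)
    g_src = np.zeros(n)
    for st in network.stages:
        g = 1.0 / st.r1
        for p, q in ((st.from_node, st.to_node), (st.to_node, st.from_node)):
            if p in index:
                G[index[p], index[p]] += g
                if q in index:
                    G[index[p], index[q]] -= g
                elif q == network.source_node:
                    g_src[index[p]] += g
        if st.to_node in index:
            G[index[st.to_node], index[st.to_node]] += 1.0 / st.r2
            Cd[index[st.to_node]] += st.c
    return unknowns, G, Cd, g_src


def transient_solve(
    network: CircuitNetwork,
    t_span: tuple[float, float],
    dt: float,
) -> TransientResult:
    """Integrate the capacitor ODEs of the network over ``t_span``.

    The linear system C·dv/dt = −G·v + g·u(t) is advanced with the
    implicit trapezoidal rule (A-stable, exact DC behaviour) from zero
    initial charge on every capacitor; purely resistive nodes are
    initialized consistently.  ``dt`` must resolve the source period with
    at least 50 samples.  After several τ₂ the periodic steady state
    matches the AC solution.
    """
    omega = network.source.omega
    if omega > 0:
        period = 2.0 * math.pi / omega
        if dt > period / 50.0:
            raise ValueError(
                f"dt={dt:g} s too coarse for source period {period:g} s; "
                f"use dt <= {period / 50.0:g} s"
            )
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("empty time span")
    unknowns, G, Cd, g_src = _conductance_system(network)
    times = np.arange(t0, t1 + 0.5 * dt, dt)
    u = network.source.samples(times)
    n = len(unknowns)
    V = np.zeros((len(times), n))

    # consistent start: resistive (capacitor-free) nodes solved with the
    # capacitor nodes clamped at zero charge
    alg = Cd == 0
    if alg.any():
        v0 = np.zeros(n)
        sub = np.ix_(alg, alg)
        v0[alg] = np.linalg.solve(G[sub], (g_src * u[0])[alg])
        V[0] = v0

    C = np.diag(Cd)
    lhs = C + 0.5 * dt * G
    rhs_m = C - 0.5 * dt * G
    lhs_inv = np.linalg.inv(lhs)
    for k in range(len(times) - 1):
        rhs = rhs_m @ V[k] + 0.5 * dt * g_src * (u[k] + u[k + 1])
        V[k + 1] = lhs_inv @ rhs

    volts = {network.source_node: u}
    for i, node in enumerate(unknowns):
        volts[node] = V[:, i]
    currents = {
        i: (volts[st.from_node] - volts[st.to_node]) / st.r1
        for i, st in enumerate(network.stages)
    }
    return TransientResult(time=times, node_voltage=volts, stage_current=currents)


def phase_between(
    trace_a,
    trace_b,
    omega: float,
    dt: float | None = None,
) -> float:
    """Phase of ``trace_b`` relative to ``trace_a`` at frequency ω, degrees.

    Single-frequency quadrature projection: each trace is projected onto
    e^(−jωt) over an integer number of periods taken from the end of the
    records (so start-up transients are excluded).  Result in (−180, 180];
    a negative value means b lags a.  Requires identically sampled traces
    covering at least 3 periods.

    Accepts plain arrays (with ``dt`` given) or objects carrying
    ``samples`` and ``dt`` attributes such as
    :class:`~plasmoflow.spectral.OscillationTrace`.
    """
    if hasattr(trace_a, "samples") and hasattr(trace_a, "dt"):
        if hasattr(trace_b, "dt") and trace_b.dt != trace_a.dt:
            raise ValueError("traces must share the sampling interval")
        dt = trace_a.dt
        trace_a, trace_b = trace_a.samples, trace_b.samples
    if dt is None:
        raise ValueError("dt is required for plain-array traces")
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and identically sampled")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    period = 2.0 * math.pi / omega
    samples_per_period = period / dt
    n_periods = int(len(a) / samples_per_period)
    if n_periods < 3:
        raise ValueError("need at least 3 full periods of data")
    n_use = int(round(n_periods * samples_per_period))
    t = np.arange(n_use) * dt
    kernel = np.exp(-1j * omega * t)
    pa = np.dot(a[-n_use:], kernel)
    pb = np.dot(b[-n_use:], kernel)
    if abs(pa) == 0 or abs(pb) == 0:
        raise ValueError("a trace has no component at the requested frequency")
    phase = math.degrees(np.angle(pb) - np.angle(pa))
    phase = (phase + 180.0) % 360.0 - 180.0
    return 180.0 if phase == -180.0 else phase
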