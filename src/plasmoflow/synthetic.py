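"""Ground-truthed synthetic oscillation data.

Generators for the signal classes the analysis pipeline consumes: uroid
oscillation traces (sums of tones plus noise), per-segment vein velocity
profiles with propagation lag and progressive decorrelation, frontal
signals filtered through a Windkessel network, and contour time series
(area, perimeter, front velocity).  Every generator is fully determined by
the config seed and returns enough ground truth to predict every derived
statistic, so the whole pipeline is testable without measurement data.

Generated series use the figure conventions of the experimental literature
(minutes, μm, μm/min); the circuit modules operate in SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .fluidic import WindkesselElement
from .network import CircuitNetwork, ac_solve
from .spectral import OscillationTrace

__all__ = [
    "GeneratorConfig", "SyntheticRecording",
    "generate_uroid_signal", "propagate_through_network",
    "network_frequency_response",
    "generate_vein_profiles", "generate_contour_series",
    "generate_recording",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators.

    Defaults emulate the observed statistics of migrating mesoplasmodia:
    uroid oscillations carrying a fundamental tone of period 1.14 min with
    a first harmonic at 0.57 min; area oscillations of period 1.20 min;
    circularity fluctuating within 0.84–0.92; membrane extension lasting
    1.4–2.3× longer than retraction; leading-edge speeds of 6–17 μm/min.
    Tone amplitudes are model assumptions (the literature reports periods,
    not amplitudes); noise is additive Gaussian with σ defaulting to 0.1×
    the largest tone amplitude.
    """

    seed: int = 0
    duration_min: float = 60.0
    dt_s: float = 1.0
    # uroid tones
    tone_periods_min: tuple[float, ...] = (1.14, 0.57)
    tone_amplitudes: tuple[float, ...] = (1.0, 0.5)
    noise_sigma: float = 0.1
    # vein segments
    n_segments: int = 5
    segment_lag_s: float = 5.0
    segment_attenuation: float = 0.9
    segment_noise_sigma: float = 0.05
    # contour series
    area_period_min: float = 1.20
    area_mean_um2: float = 2.5e5
    area_rel_amplitude: float = 0.02
    area_noise_rel: float = 0.005
    circularity_mean: float = 0.88
    circularity_amplitude: float = 0.03
    circularity_period_min: float = 2.40
    ext_ret_ratio: float = 1.8
    mean_speed_um_min: float = 11.0
    retraction_amplitude_um_min: float = 15.0
    velocity_noise_um_min: float = 0.5

    def __post_init__(self) -> None:
        if len(self.tone_periods_min) != len(self.tone_amplitudes):
            raise ValueError("one amplitude per tone period required")
        shortest = min(self.tone_periods_min) * 60.0
        if self.dt_s > shortest / 20.0:
            raise ValueError(
                f"dt={self.dt_s} s does not resolve the shortest tone period "
                f"({shortest} s) with >= 20 samples per period"
            )
        if self.duration_min <= 0 or self.dt_s <= 0:
            raise ValueError("duration and dt must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 / self.dt_s))

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s


@dataclass(frozen=True)
class SyntheticRecording:
    """Bundle of generated traces plus the ground truth that produced them."""

    traces: dict[str, OscillationTrace]
    ground_truth: dict = field(default_factory=dict)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _tone_sum(config: GeneratorConfig, t_s: np.ndarray, delay_s: float = 0.0,
              gains: tuple[float, ...] | None = None,
              phase_shifts_rad: tuple[float, ...] | None = None) -> np.ndarray:
    out = np.zeros_like(t_s)
    for k, (period, amp) in enumerate(
        zip(config.tone_periods_min, config.tone_amplitudes)
    ):
        w = 2.0 * math.pi / (period * 60.0)
        g = gains[k] if gains is not None else 1.0
        phi = phase_shifts_rad[k] if phase_shifts_rad is not None else 0.0
        out += amp * g * np.cos(w * (t_s - delay_s) + phi)
    return out


def generate_uroid_signal(config: GeneratorConfig) -> OscillationTrace:
    """Uroid oscillation trace: sum of configured cosine tones plus noise.

    Deterministic per seed; with ``noise_sigma=0`` the trace is the exact
    tone sum.
    """
    t = config.time_s()
    x = _tone_sum(config, t)
    if config.noise_sigma > 0:
        x = x + _rng(config, 1).normal(0.0, config.noise_sigma, size=len(t))
    return OscillationTrace(samples=x, dt=config.dt_s, units="a.u.", position="uroid")


def network_frequency_response(
    network: CircuitNetwork, freqs_hz: np.ndarray, probe: str
) -> np.ndarray:
    """Complex transfer H(f) = V_probe/V_source over a frequency grid."""
    amp = network.source.amplitude
    h = np.empty(len(freqs_hz), dtype=complex)
    for i, f in enumerate(freqs_hz):
        sol = ac_solve(network, 2.0 * math.pi * f)
        h[i] = sol.node_voltage[probe] / amp
    return h


def propagate_through_network(
    trace: OscillationTrace,
    network: CircuitNetwork | None,
    probe: str | None = None,
    transfer: np.ndarray | None = None,
) -> OscillationTrace:
    """Apply a network's frequency response at a probe to a trace.

    The trace is taken to the spectral domain; each frequency bin is
    multiplied by the complex transfer H(f) = V_probe/V_source from the
    nodal solution at that frequency, then transformed back.  A pure tone
    therefore comes out with amplitude × |H| and phase + ∠H.  With
    ``network=None`` (or the probe at the source node) the trace passes
    unchanged.

    ``transfer`` may supply a precomputed response from
    :func:`network_frequency_response` on the trace's rfft grid, to avoid
    re-solving the network when many identically sampled traces are
    propagated.
    """
    if network is None:
        return trace
    probe = probe if probe is not None else network.probes[-1]
    if probe == network.source_node:
        return trace
    x = trace.samples
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=trace.dt)
    h = transfer if transfer is not None else network_frequency_response(
        network, freqs, probe
    )
    if len(h) != len(freqs):
        raise ValueError("precomputed transfer does not match the trace's grid")
    y = np.fft.irfft(spec * h, n=n)
    return OscillationTrace(
        samples=y, dt=trace.dt, units=trace.units, position=probe
    )


def generate_vein_profiles(
    config: GeneratorConfig,
    filter_element: WindkesselElement | None = None,
) -> tuple[list[OscillationTrace], dict]:
    """Per-segment vein velocity profiles from uroid to front.

    Segment i (i = 0 closest to the uroid) is the tone sum delayed by
    i × ``segment_lag_s`` with per-stage attenuation applied i times, plus
    independent seeded noise.  By default the attenuation is the
    frequency-independent factor ``segment_attenuation`` per stage, which
    keeps the inter-segment delay exactly i·lag; passing a
    ``filter_element`` instead applies that Windkessel stage's dispersive
    divider transfer per stage (frequency-dependent gain *and* phase, the
    physical low-pass).  The returned ground truth records the true lags
    and the per-tone gains actually applied.
    """
    if config.n_segments < 2:
        raise ValueError("need at least two segments")
    t = config.time_s()
    rng = _rng(config, 2)

    tone_gains: list[tuple[float, ...]] = []
    tone_phases: list[tuple[float, ...]] = []
    if filter_element is not None:
        from .network import build_single_stage

        net = build_single_stage(filter_element)
        for period in config.tone_periods_min:
            w = 2.0 * math.pi / (period * 60.0)
            sol = ac_solve(net, w)
            h = sol.node_voltage["n1"] / net.source.amplitude
            tone_gains.append(abs(h))
            tone_phases.append(float(np.angle(h)))

    segments = []
    truth_gains = []
    for i in range(config.n_segments):
        if filter_element is None:
            gains = tuple(config.segment_attenuation**i for _ in config.tone_periods_min)
            phases = tuple(0.0 for _ in config.tone_periods_min)
        else:
            gains = tuple(g**i for g in tone_gains)
            phases = tuple(p * i for p in tone_phases)
        x = _tone_sum(config, t, delay_s=i * config.segment_lag_s,
                      gains=gains, phase_shifts_rad=phases)
        if config.segment_noise_sigma > 0:
            x = x + rng.normal(0.0, config.segment_noise_sigma, size=len(t))
        segments.append(
            OscillationTrace(
                samples=x, dt=config.dt_s, units="um/min", position=f"segment{i + 1}"
            )
        )
        truth_gains.append(gains)
    ground_truth = {
        "lags_s": [i * config.segment_lag_s for i in range(config.n_segments)],
        "tone_gains": truth_gains,
        "dispersive": filter_element is not None,
    }
    return segments, ground_truth


def generate_contour_series(
    config: GeneratorConfig,
) -> tuple[OscillationTrace, OscillationTrace, OscillationTrace, dict]:
    """Area, perimeter and front-velocity traces of a migrating cell.

    * Area oscillates at ``area_period_min`` around its mean with
      multiplicative measurement noise.
    * Circularity follows a smooth oscillation around its configured mean;
      the perimeter is derived as P = sqrt(4πA/f_circ), so contour noise
      enters area and perimeter jointly and the circularity stays within
      its configured band at every sample.
    * Front velocity is a piecewise-sinusoidal cycle with a longer
      extension lobe than retraction lobe (duty set by ``ext_ret_ratio``)
      whose amplitudes are solved so the cycle mean equals
      ``mean_speed_um_min``.

    Returns (area, perimeter, velocity, ground_truth).
    """
    t = config.time_s()
    rng = _rng(config, 3)

    w_area = 2.0 * math.pi / (config.area_period_min * 60.0)
    area = config.area_mean_um2 * (1.0 + config.area_rel_amplitude * np.sin(w_area * t))
    if config.area_noise_rel > 0:
        area = area * (1.0 + rng.normal(0.0, config.area_noise_rel, size=len(t)))

    w_circ = 2.0 * math.pi / (config.circularity_period_min * 60.0)
    f_circ = config.circularity_mean + config.circularity_amplitude * np.sin(w_circ * t)
    perimeter = np.sqrt(4.0 * math.pi * area / f_circ)

    # asymmetric velocity cycle: extension fraction from the target ratio,
    # extension amplitude from the target mean speed
    ratio = config.ext_ret_ratio
    f_ext = ratio / (1.0 + ratio)
    f_ret = 1.0 - f_ext
    vn = config.retraction_amplitude_um_min
    # cycle mean of the two half-sine lobes: (2/π)(vp·f_ext − vn·f_ret)
    vp = (config.mean_speed_um_min * math.pi / 2.0 + vn * f_ret) / f_ext
    period_s = config.area_period_min * 60.0
    phase = (t % period_s) / period_s
    v = np.where(
        phase < f_ext,
        vp * np.sin(math.pi * phase / f_ext),
        -vn * np.sin(math.pi * (phase - f_ext) / f_ret),
    )
    if config.velocity_noise_um_min > 0:
        v = v + rng.normal(0.0, config.velocity_noise_um_min, size=len(t))

    ground_truth = {
        "area_period_min": config.area_period_min,
        "circularity_band": (
            config.circularity_mean - config.circularity_amplitude,
            config.circularity_mean + config.circularity_amplitude,
        ),
        "ext_ret_ratio": ratio,
        "extension_amplitude_um_min": vp,
        "retraction_amplitude_um_min": vn,
        "mean_speed_um_min": config.mean_speed_um_min,
    }
    return (
        OscillationTrace(area, config.dt_s, units="um^2", position="contour"),
        OscillationTrace(perimeter, config.dt_s, units="um", position="contour"),
        OscillationTrace(v, config.dt_s, units="um/min", position="front"),
        ground_truth,
    )


def generate_recording(
    config: GeneratorConfig,
    network: CircuitNetwork | None = None,
    probe: str | None = None,
) -> SyntheticRecording:
    """Full synthetic recording: uroid, filtered front, vein segments, contour.

    If ``network`` is given, the front trace is the uroid signal propagated
    through it to ``probe`` (default: the network's last probe) — the
    synthetic realization of low-pass frequency selection.
    """
    uroid = generate_uroid_signal(config)
    traces: dict[str, OscillationTrace] = {"uroid": uroid}
    truth: dict = {
        "config": asdict(config),
        "tones": {
            "periods_min": list(config.tone_periods_min),
            "amplitudes": list(config.tone_amplitudes),
        },
    }
    if network is not None:
        front = propagate_through_network(uroid, network, probe)
        traces["front"] = OscillationTrace(
            front.samples, front.dt, units=uroid.units, position="front"
        )
        probe_name = probe if probe is not None else network.probes[-1]
        gains = {}
        for period in config.tone_periods_min:
            w = 2.0 * math.pi / (period * 60.0)
            sol = ac_solve(network, w)
            gains[period] = abs(sol.node_voltage[probe_name]) / network.source.amplitude
        truth["network_gains"] = gains
    segments, seg_truth = generate_vein_profiles(config)
    for s in segments:
        traces[s.position] = s
    truth["segments"] = seg_truth
    area, perimeter, velocity, contour_truth = generate_contour_series(config)
    traces["area"] = area
    traces["perimeter"] = perimeter
    traces["front_velocity"] = velocity
    truth["contour"] = contour_truth
    return SyntheticRecording(traces=traces, ground_truth=truth)
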