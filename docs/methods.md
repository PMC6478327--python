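# Methods

## The model

Migrating *Physarum polycephalum* mesoplasmodia move by rhythmic
actomyosin contractions in the trailing uroid that pump endoplasm through
internal veins toward the soft leading front. The flow regime in those
veins is extreme: with cytoplasm density ρ ≈ 1120 kg/m³, viscosity
η ≈ 0.275 N·s/m², channel diameters of tens of micrometres and velocities
of 5–100 μm/min, the Reynolds number is of order 10⁻⁸ and the Womersley
number of order 10⁻⁴. Inertia is negligible at both the mean-flow and the
pulsation scale, so each vein segment is quasi-steady Poiseuille flow
through a compliant, leaky channel — exactly the regime in which lumped
("Windkessel") models are quantitative.

One vein segment is a **three-element Windkessel**: a series resistance

    R₁ = 8ηl/(πa⁴)

for the internal friction of the cytoplasm, a shunt compliance

    C = 2πa₀²l/E

for the elastic channel wall (strain linear in transmural pressure:
ε = Δp/E, normalized radius h² = 1 + 2Δp/E), and a leakage resistance R₂
to ground for the wall-less, permeable channel boundary. R₂ cannot be read
from images; by analogy with strongly filtrating vessels it defaults to
50 × R₁. An inertance (fourth element) is deliberately omitted — at these
frequencies it would be ~10 orders of magnitude below the resistive terms.

The element's complex impedance is

    Z(ω) = R₁ + R₂/(1 + jωR₂C),

reported as Z_real = R₁ + R₂/(1+ω²R₂²C²), a positive reactance magnitude
Z_imag = R₂²Cω/(1+ω²R₂²C²), and a phase θ = arctan(Z_imag/Z_real) by which
the flow wave trails the pressure wave. The two RC time constants are
τ₂ = R₂C and τ₁ = τ₂R₁/(R₁+R₂); the voltage-divider transfer across the
element falls 3 dB below its plateau at

    f_c = (R₁+R₂)/(2πCR₁R₂) = 1/(2πτ₁).

For a drive Δp(t) = Δp₀cos(ωt) the steady flow is
q(t) = (Δp₀/|Z|)·cos(ωt−θ); a DC pressure offset adds Δp₀_dc/(R₁+R₂).
The limiting cases C = 0 and R₂ = 0 are purely resistive (θ = 0 with
|Z| = R₁+R₂ and R₁ respectively); R₁ = 0 leaves the reactance unchanged.
Some published renderings of the analytical flow solution drop the radical
over (R₁+R₂)²; we use the self-consistent form Δp₀/(R₁+R₂), which agrees
with the impedance route.

### Dimensionless form

The response collapses onto r̃ = R₁/R₂ and c̃ = CR₂ω, with dimensionless
flow amplitude |q̃| = R₂/|Z| = √((1+c̃²)/(r̃²(1+c̃²)+2r̃+1)), relative phase
θ_rel = arctan(c̃/((r̃+1)+r̃c̃²)) and oscillatory dissipation
W = ½Q²|Z|cosθ per period (the steady part is negligible and excluded).
θ_rel and the impedance phase are the same quantity, which the tests assert
across random parameters. A widely circulated radical-free rendering of the
q̃ formula (amplitude → 1 as r̃ → 0 for all c̃) is inconsistent with θ_rel
and with the flow peak at small r̃/large c̃; it is available behind
`literal_rendered=True` for comparison but is not the default. The surface
scans default to r̃ ∈ [0,1], c̃ ∈ [0,10]; the upper c̃ limit is a
reconstruction chosen so the phase maximum arctan(10) = 84.3° sits on the
scanned corner, and extrema falling on grid edges are flagged as boundary
extrema.

### Unit systems

The library is strict SI internally (m, s, Pa, N·s/m⁵, m⁵/N); μm, μm/min
and minutes are accepted only at the CLI/config boundary. For circuit
simulation the fluidic element is converted to an electrical twin by pure
impedance rescaling anchored to a reference series resistance: with
k = R₁ᵉ/R₁ᶠ both resistances multiply by k and the compliance divides by
k. Every time constant and therefore every gain, phase and cut-off is
exactly invariant (asserted to 1e-10), and the typical vein segment
(R₁ᶠ = 2.19×10¹⁵ N·s/m⁵, C_f = 2.42×10⁻¹⁶ m⁵/N with E = 5.2 kPa, the
modulus of a cross-linked actin network rather than the stiffer 16.4 kPa
whole-cell indentation value) maps to the convenient 10 Ω / 500 Ω /
0.053 F set used throughout.

## Network solution

Networks are directed trees of stages (series R₁ into a node, shunt
{C ∥ R₂} to ground) fed by one ideal pressure source. The branching-vein
model is a Y: two stages in series (the stem), then two identical
single-stage arms in parallel — mesoplasmodial veins branch only in their
final third. Probes 1 and 2 are the stem shunt nodes, probe 3 an arm end.

* **AC analysis** is dense complex nodal analysis over the non-source
  nodes (networks here have < 100 nodes; sparse machinery would be noise).
  Kirchhoff's current law is re-checked at every solved node and the
  residual reported (≤ 1e-9 of the largest branch current).
* **Cut-off extraction** supports two conventions: *absolute* (gain =
  1/√2 of the source amplitude, the read-off used for cascade Bode plots)
  and *relative* (1/√2 of the probe's own DC plateau, which for a single
  stage is analytically identical to f_c above). The grid crossing is
  refined by root bracketing on the re-solved network to ~1e-5 relative.
* **Transient analysis** integrates C·dv/dt = −Gv + g·u(t) with the
  implicit trapezoidal rule (A-stable, exact at DC) from zero initial
  charge, matching the SPICE default; capacitor-free nodes are initialized
  consistently by solving the resistive subnetwork. Steps coarser than 50
  samples per source period are refused with a suggested dt. After the
  start-up transient the periodic state reproduces the AC solution to
  within 1%.
* **Phase extraction** between two traces uses single-frequency quadrature
  projection over whole periods taken from the end of the records, so
  start-up transients never contaminate the estimate.

Sign conventions: internally the solver uses ordinary complex phasors
(capacitive reactance negative, current angle positive); the reporting
layer follows the flow-lags-pressure convention, stating θ and the
reactance as positive magnitudes.

## Polarization circuit and flow budget

An unpolarized plasmodium is two identical Windkessel branches sharing a
sourced node: the inflow splits evenly, and over whole periods of the
settled state the mean source current is exactly zero. Softening one
branch (compliance × 5, the circuit reading of a softer frontal actin
cortex) cuts that branch's impedance magnitude at the typical drive
ω = 0.08 rad/s from ≈ 218 to ≈ 49, diverting ≈ 4.45× more current into the
soft side; current share increases strictly monotonically with compliance
at every tested frequency, which is the circuit-level statement of
"softening attracts flow". Averages "over the first 5 periods" are taken
from t = 0 including the charging transient, which is why they are small
but non-zero even for the symmetric circuit; a steady-state option
averages whole settled periods and is exactly zero. Because the source
amplitude behind the published absolute currents is not stated, all
asymmetric-case outputs are reported as amplitude-invariant ratios.

The volumetric budget uses Q = vπa² per vein (μm³/min) and conservation
Q_front = Q_total − ΣQ_back, with the default constant cell height 100 μm
and vein radius 20 μm; a negative front flow warns rather than raises,
since it signals inconsistent measurements, not a usage error.

## Spectral and contour statistics

Spectra are one-sided amplitude FFTs after mean removal, unwindowed by
default so peak amplitudes read like a plain FFT plot (a Hann option
exists for noisy data); amplitude normalization is exact for bin-aligned
tones. Dominant periods are local maxima above 3 × the median spectral
amplitude (configurable), amplitude-ordered. The frequency-selection index
compares front/back amplitude ratios at a low and a high tone; an index
below 1 detects low-pass behaviour and is invariant under uniform
rescaling of either spectrum. Correlation decay along a vein reports both
zero-lag Pearson correlation and the optimum over lags (with the lag).
Circularity is 4πA/P²; extension/retraction timing counts signed samples
of the front-velocity trace with exact zeros split evenly.

## Synthetic data

The generators define the study conditions and are fixed:

| parameter | default | basis |
|---|---|---|
| tone periods | 1.14, 0.57 min | observed uroid spectrum (fundamental + harmonic) |
| tone amplitudes | 1.0, 0.5 a.u. | assumption; only periods are reported for real cells |
| noise σ | 0.1 × largest tone | assumption (no noise model is reported) |
| duration, dt | 60 min, 1 s | resolves the 0.57 min tone with ≥ 34 samples/period |
| segments, lag | 5, 5 s | propagation delay along a dominant vein |
| T_area | 1.20 min | observed area-oscillation period |
| circularity | 0.88 ± 0.03 oscillation | observed band 0.84–0.92 |
| ext/ret ratio | 1.8 | observed range 1.4–2.3 |
| mean speed | 11 μm/min | observed range 6–17 μm/min |

The uroid signal is the exact tone sum plus seeded Gaussian noise. The
front signal is the uroid trace propagated through the Y-cascade in the
spectral domain (per-bin complex transfer from the nodal solver), so a
pure tone emerges with amplitude × |H| and phase + ∠H exactly. Vein
segments apply per-stage attenuation and an analytic delay of i·lag; the
default attenuation is frequency-independent so that noiseless
cross-correlation recovers the lags exactly, while an optional dispersive
mode filters each segment through the Windkessel stage transfer i times
(physical, but the tone-dependent group delay then adds to the nominal
lag). Contour series couple noise into area and perimeter jointly through
P = √(4πA/f_circ) with a smooth circularity oscillation, so the
circularity band holds at every sample by construction. The front-velocity
cycle is two half-sine lobes whose duty sets the extension/retraction
ratio and whose amplitudes are solved so the cycle mean equals the
configured migration speed (retraction amplitude 15 μm/min, giving an
extension amplitude of ≈ 35 μm/min).

What the generators do **not** emulate: the unknown primary biochemical
oscillator (tones are stationary; real spectra drift between individuals),
amplitude distributions of real oscillations, spatially distributed wall
mechanics, gel–sol transitions and membrane-reservoir effects at the
front, and any imaging noise structure. Passing tests therefore validate
the analysis chain and the circuit physics, not biological parameter
values.

## Problem sizes and numerical choices

Everything is desk-scale by design: single-element results are closed
form; Bode sweeps use 60–200 log-spaced points; the dimensionless surface
scan uses a 401 × 401 grid; the solver-vs-closed-form oracle runs 1000
random draws; pipeline classification uses 20 noiseless and 100 noisy
seeded replicates on 60 min @ 1 s traces with the cascade transfer
precomputed once per grid. The full test suite runs in a few seconds.
Tie-breaks: grid extrema resolve ties toward the smallest (r̃, c̃);
spectral peak ties resolve toward higher amplitude, then lower frequency;
identical parallel arms are probed at the first-listed arm.

## Known limitations

* Linear wall elasticity and Newtonian viscosity; real cytoplasm is
  shear-thinning and the wall law is only locally linear.
* Lumped stages discretize a distributed channel; the small intra-segment
  pressure delay (≈ 2.4° per 500 μm segment at ω = 0.08 rad/s) is the
  first signature of the distributed behaviour the model truncates.
* Tree topologies with a single ideal source only — adequate for the
  branching-vein and two-branch circuits modelled here, not for meshed
  networks with multiple sources.
* The ~50× branch-current ratio and the absolute mean source currents
  sometimes quoted for the polarized case depend on unstated component and
  source values; the package reproduces the ratio implied by the stated
  element values (≈ 4.45) and the qualitative orderings, and deliberately
  does not chase the absolute numbers.
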