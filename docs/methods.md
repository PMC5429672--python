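# Methods

## Transport model

The device is modeled as a 1-D transport problem along the lumen→gel axis.
The lumen is a well-stirred reservoir whose concentration ramps linearly
from 0 to C_lumen over `fill_time` and is then held constant; the feed
volume (microliters) is so much larger than the gel volume (nanoliters)
that depletion is negligible. The endothelial monolayer is a
zero-thickness membrane with flux

    J(t) = P_d · (C_lumen(t) − C(0⁺, t))            [Robin boundary condition]

into an initially empty gel where the tracer diffuses freely with
coefficient D_gel. At the gel midline, symmetry with the opposite channel
imposes zero flux (a single-channel variant uses the same zero-flux far
wall). Convective transport is assumed absent — the assay is run with no
pressure head across the barrier — and the fibrin pore size (µm scale) is
far above tracer size, so gel diffusion is unhindered.

Transverse to the diffusion axis the problem is treated as independent
1-D columns. This is exact for a uniform membrane and a good early-time
approximation for a focal leak (a sub-segment of one gap at
`multiplier × P_d`), before transverse diffusion smears the plume.

For validation the solver is compared against the closed-form
surface-resistance solution of the semi-infinite problem with a step
reservoir: with h = P_d/D,

    C(y,t) = C0·[ erfc(u) − exp(hy + h²Dt)·erfc(u + h√(Dt)) ],  u = y/(2√(Dt)),

evaluated via the scaled complementary error function for stability.

## The estimator

The permeability formula pairs the rate of rise of the mean gel-box
intensity with the transmembrane intensity difference:

    P_d = A_gel·(dI_ave,gel/dt) / (w_monolayer·ΔI),   ΔI = I_lumen − I_y=0,

at the lumen-filling time t₀. Two timescales decide how this must be
evaluated from 30-s frames:

* interface saturation, τ_s = D/P_d² — for D = 10⁻⁶ cm²/s this is ~13 min
  at P_d = 3.5×10⁻⁵ cm/s but only ~100 s at 10⁻⁴ cm/s, so ΔI decays
  appreciably *within* any usable fit window;
* front transit, τ_box = (box depth)²/4D — the diffusive front crosses a
  shallow gel box within the window, leaking mass past its far edge.

A naive OLS slope over the window divided by ΔI(t₀) is therefore biased
low by tens of percent in the leaky-barrier regime. Because the membrane
flux obeys J(t) = P_d·ΔC(t) at every instant, integrating the mass balance
once gives an identity that holds for any window:

    I_ave,gel(t) = I_ave,gel(t₀) + (w/A_gel)·P_d·∫_{t₀}^{t} ΔI dt′ ,

provided the gel box captures the entering mass. The estimator regresses
I_ave,gel on X(t) = ∫ΔI dt′ (trapezoid over frames); the slope β gives
P_d = (A_gel/w)·β. The plain slope-vs-time and its r² are still reported,
and the recorded `delta_I = slope/β` is the window-effective value, so
`P_d = A_gel·slope/(w·delta_I)` holds exactly in every output row and
converges to the instantaneous ΔI(t₀) form as the window shrinks.
Residual error comes from trapezoid discretization of a fast ΔI decay
(~0.5% at P_d = 10⁻⁴ cm/s, 30-s frames) and from mass passing the far
edge of the gel box.

Two consequences drive ROI defaults:

* the gel box must include the interface line, so that slowly diffusing
  tracers accumulating at the membrane are counted (this is what makes the
  estimate sensitive to the membrane rather than the gel: fast and slow
  diffusers with equal P_d agree within a few %);
* the gel box must be deep enough to contain the diffusive front over the
  window — `gel_depth` defaults to 600 µm (√(4Dt) ≈ 380 µm at the end of
  the default window for D = 10⁻⁶ cm²/s). Doubling an already
  front-capturing depth changes P_d by <5%; shallow boxes do not.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `Pd_true` | 3.5×10⁻⁵ | cm/s | leaky (tumor-like) barrier scale |
| `D_gel` | 1×10⁻⁶ | cm²/s | ~6 nm probe via Stokes–Einstein at 37 °C |
| `gel_half_width` | 650 | µm | membrane to symmetry midline |
| `gap_width` / `n_gaps` | 120 / 3 | µm / — | exposed monolayer between posts |
| `pixel_size`, `grid_dx` | 2 | µm | pixel grid aligned with solver cells |
| `frame_interval` | 30 | s | acquisition cadence |
| `duration` | 1800 | s | dextran-like acquisition (2700 for slow probes) |
| `fill_time` | 60 | s | lumen ramp; t₀ detected at the 0.95-plateau |
| `fit_window` | 10 | frames | 5 min; bias–variance compromise |
| noise gain / read / offset | 500 / 20 / 100 | counts | EMCCD-like shot + read noise |
| `leak_threshold` | 1.0 | — | on the (max−median)/median interface score |

Channel dimensions and camera gain are not published for this class of
device; the defaults above are declared, configurable, and recorded in
every output sidecar.

Stokes–Einstein (D = k_B·T/(3πη·d_H), evaluated at 310 K, η = 6.9×10⁻⁴
Pa·s) maps nanoparticle hydrodynamic diameters (20–200 nm → 3×10⁻⁷ …
3×10⁻⁸ cm²/s) onto gel diffusivities for size-series simulations.

## Numerical choices

* Explicit finite-volume solver, sub-stepped to dt ≤ 0.4·dx²/D; the lumen
  ramp is sampled at sub-step midpoints. Mass conservation (gel mass vs
  integrated membrane flux) holds to round-off; grid refinement dx 4→2 µm
  changes fields by <0.5%; solver vs closed form <0.2% relative L2.
* Background subtraction clips the ROI *mean* at zero, not individual
  pixels. Per-pixel clipping rectifies read noise, adding a
  signal-dependent positive offset (~σ/√2π per dark pixel) that decays as
  the signal grows and suppresses the fitted slope by 10–40% where the
  gel signal is weak.
* t₀ detection: plateau = median of the top quartile of the lumen trace;
  t₀ = first frame ≥ 95% of it; an explicit `t0_index` overrides.
* ΔI ≤ 0 over the window is an error (mis-detected t₀ or pre-filled gel),
  not silently clipped. Zero-uptake traces fall back to ΔI(t₀) so a
  near-zero or negative slope propagates its sign to P_d.
* r² < 0.9 is a warning-level QC signal only; only focal-leak flags
  exclude points from aggregation.
* Rectangles are half-open, 0-based; all geometry is in µm internally and
  P_d is reported in cm/s (µm/s × 10⁻⁴).

## QC: focal leaks

Leaks are scored on the spatial profile of the interface line averaged
over the 20 frames (10 min) after t₀: score = (max − median)/median,
flagged above 1.0. On the reference device a 10× leak over 10% of one gap
scores ~1.2 (detected in >95% of renders) while clean monolayers score
~0.1 at default noise (false positives ≲1%). A zero-median profile scores
+inf and is flagged for review. Flagged points are retained in the
measurement table and excluded from aggregation. The score is an
operational rule validated on simulated leaks, not a mechanistic model of
junctional failure.

## Statistics

Aggregation (mean ± SEM, n = data points = ROI triples) excludes flagged
points; n = 1 groups report SEM 0 with a warning. Comparisons use the
pooled-variance two-tailed Student's t-test (Welch optional), α = 0.05,
no multiple-testing correction. Fold-changes are ratios of condition
means (3 significant figures). TNR = P_d,tumor/P_d,normal per probe size;
its first-order propagated SEM is this package's addition and is labeled
as such in outputs.

## What the generator does and does not emulate

Emulated: lumen filling kinetics, membrane-limited uptake with interface
saturation, gel diffusion with probe-size-dependent D, post/gap layout
with dark (blocked) gel behind posts, mirrored two-channel geometry,
shot + read camera noise, blank pre-injection frames, focal leaks.

Not emulated: convective flow, photobleaching, flat-field variation,
EMCCD excess-noise factor (raise `read_noise_sd` to mimic), transverse
diffusion between columns, monolayer thickness and biology (treatments
are condition labels only), protein-corona kinetics. Recovery tests
therefore demonstrate correctness of the *measurement chain* under the
stated physics, not robustness to every real-microscopy artifact.

## Problem sizes in tests

The validation suite truncates acquisitions to the frames the estimator
actually uses (10–22 min) and uses a single-gap, single-channel device
for Monte-Carlo loops (leak operating characteristics: 50 renders per
arm; recovery: 20 devices per permeability; size-invariance: 25 runs of
10 devices × 4 sizes), keeping the full suite and the acceptance script
each within a few minutes on one CPU.
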