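# Methods

## The Kir4.1 current law

The current density across an astrocyte membrane is modelled as

    I_Kir = g_Kir · V_f(V1) · [K⁺]_out^(1/2) · (1 + exp(V_f(V2)/V3))^(-1/2)
    V_f(V_i) = V_m − A_K·E_K − V_i,   E_K = (RT/F)·ln([K⁺]_out/[K⁺]_in)

with V1 = −14.83 mV, V2 = −105.82 mV, V3 = 19.23 mV (fits to whole-cell
recordings of the Ba²⁺/VU-sensitive astrocyte current), [K⁺]_in = 110 mM,
and the convention that inward current is negative. With g in mS/cm² and
voltages in mV the product is in μA/cm². The law is exactly linear in g_Kir
and vanishes on the manifold V_m = A_K·E_K + V1.

**Thermal voltage.** RT/F is fixed at 25.0 mV (T ≈ 290 K, in the 32–34 °C
recording range's vicinity). No temperature is attached to the published
constants; 25 mV is the unique round value under which the stated
normalization A_K = 0.6891 zeroes the current at (2.5 mM, −80 mV) to within
0.03%. The Nernst logarithm is natural — only ln reproduces that property.

**Normalization.** `normalization_factor` solves V_f(V1) = 0 at rest in
closed form: A_K = (V_rest − V1)/E_K(rest). At (−80 mV, 2.5 mM) this gives
0.68887, matching the published rounding 0.6891 to < 4×10⁻⁴. Because the
rounded factor is carried as the default, a residual current of
|I| < 6×10⁻⁴ μA/cm² survives at exactly 2.5 mM; the true zero crossing sits
at ≈ 2.5024 mM. This is visible only in long unforced integrations (a
~0.003 mM creep over 60 s) and is deliberately kept: the rounded constant
is part of the model's published parameterization.

**Conductance density.** g_Kir = 0.175 mS/cm² derives from ~1 nA of
whole-cell Kir current at V_m = −80 mV over ~20,000 μm² of membrane, i.e. a
current density of 5 μA/cm². (The nA-over-area arithmetic fixes the unit:
1 nA / 2×10⁻⁴ cm² = 5×10⁻⁶ A/cm².) The 1-nA figure is an empirical anchor
for this derivation only — the normalized law is zero at rest by
construction, so the model does not predict 1 nA at rest.

**Rectification index.** Published I-V figures label an "RI" without a
formula. Here RI is defined as the ratio of chord conductances at symmetric
offsets (default ±40 mV) from the interpolated zero-current voltage:
RI = 1 for ohmic data, > 1 for inward rectification, invariant under
conductance scaling. A slope-conductance variant would be equally defensible;
the chord definition was chosen because it is robust on coarsely sampled
curves and directly testable.

## Reduced 3D territory model

Extracellular K⁺ on a regular voxel grid obeys

    ∂[K⁺]_out/∂t = D ∇²[K⁺]_out − k(r)·([K⁺]_out − [K⁺]_ss)

with D = 0.6 μm²/ms (tortuosity included), [K⁺]_ss = 2.5 mM, uniform initial
condition 5 mM, zero-flux boundaries, arena 130×150×42 μm³ centered at
(2, −1, −3) μm, grid 19×28×15 (pitch ≈ 6.84×5.36×2.80 μm, voxel-centered,
arena-centered coordinates). The relaxation term is a first-order lumped
proxy for Kir4.1 uptake: k = 1/τ with τ = 40 s corresponds to the reference
density 0.175 mS/cm² at ~10% astrocyte tissue-volume fraction. Inside the
central astrocyte's territory the rate is scaled by the conductance ratio
g_ratio (2.0 over-expressing, 0.5 under-expressing, 1.0 control), inheriting
the current law's linearity in g. A published variant of the under-expression
figure with a *negative* total conductance is rejected as a typo (a negative
total would make the astrocyte a K⁺ source); the ratio 0.087/0.175 ≈ 0.5 is
used.

**Territory geometry.** The astrocyte territory is a sphere of radius 23 μm
(configurable). The choice follows the budget arithmetic: ~10⁴ μm³ of ECS at
20% ECS fraction implies ~5×10⁴ μm³ of territory tissue, a sphere of radius
≈ 23 μm. The sphere is clipped by the default arena in z (half-depth 21 μm),
as a morphology placed in this arena would be.

**Mirror rule.** On territory voxels, intracellular K⁺ is
[K⁺]_in(r,t) = 110 + 2·([K⁺]_out(r,0) − [K⁺]_out(r,t)) mM, the factor 2
being the average extracellular/intracellular volume-fraction ratio.
Intracellular diffusion is not modelled (the mirrored field is local), and
diffusion does not act on [K⁺]_in.

**Integration.** Explicit forward Euler at dt = 1 ms over 20 s (defaults).
Construction enforces 2·D·dt·(1/hx² + 1/hy² + 1/hz²) ≤ 1 (0.22 for the
default grid). The Neumann stencil mirrors the boundary-adjacent value, so
the discrete volume integral of the diffusion operator is exactly zero and
pure diffusion conserves mass to rounding error. For a spatially uniform
field the scheme reduces exactly to the scalar recurrence
k_ss + (k0 − k_ss)(1 − dt/τ)ⁿ, within 2×10⁻⁵ of e^{−t/τ} at t = τ.

**Boundary sensitivity.** `boundary_sensitivity` reruns the scenario in an
arena whose linear dimensions are scaled (default 2×) at unchanged voxel
pitch, with the territory mask clipped to the *original* arena box so both
runs share identical uptake sources and differ only in boundary placement.
The enlarged run, linearly interpolated to the base voxel centers, is the
reference; the statistic is the maximum over snapshot times and over voxels
within 15 μm of the territory-sphere surface of |Δ[K⁺]_out| divided by the
local reference departure from steady state, in percent. For the default
over-expression scenario this is ≈ 2.7%, under the 5% design claim.

## Well-mixed whole-cell budget

Geometry defaults: 20,000 μm² membrane, 5×10³ μm³ cell volume, SVR 7 μm⁻¹
(soma) to 22 μm⁻¹ (periphery), astrocyte tissue fraction 10%, ECS fraction
20%, resting [K⁺]_in = 110 mM. Hence one territory overlies
5×10³·(0.20/0.10) = 10⁴ μm³ of ECS lumen.

A local uptake event (default: [K⁺]_out 2.5→5 mM in a 10-μm-diameter sphere
for 5 s at V_m = −80 mV) involves membrane area
SVR_periphery × (astro fraction × sphere volume) ≈ 1.15×10³ μm²; the Kir
flux at the elevated concentration is treated as constant (no [K⁺]
rundown or depolarization feedback — a conservative overestimate of the
transferred charge), giving a peak whole-cell [K⁺]_in change of ≈ 0.064%
(control) and ≈ 0.129% (doubled density) — both far below 1%, which is the
point: a single astrocyte absorbs physiological K⁺ transients without
materially moving its own pool. The peripheral SVR is used because such
events occur in the fine-process neuropil. The event sphere is read as
10 *μm* wide; a 10 mm sphere would exceed the brain.

`ecs_decay_curve` integrates the coupled two-pool budget (ECS lumen at 10⁴
μm³, cell at 5×10³ μm³) under the whole-cell Kir current at fixed
V_m = −80 mV with scipy's RK45 at rtol 1e-10, so mole conservation between
the pools is a genuine integrator check, not an identity. A least-squares
mono-exponential fit of the 5→2.5 mM decay gives an effective first-order
constant ≈ 22 s — same order as, and deliberately not tuned to, the 40-s
lumped rate (the grid model's τ also absorbs diffusion out of the
neighborhood, which the two-pool budget lacks).

Ion-budget arithmetic: a single-stimulus astrocyte current of 20–50 pA over
5–10 s carries ~2×10⁻¹⁰ C ≈ 1.25×10⁹ K⁺ ions (the coulomb figure is read at
10⁻¹⁰ order; at 10⁻¹ C it would be nine orders away from its own ion count);
10⁹ ions in 10⁴ μm³ is 0.166 mM — order 0.1 mM, matching the
volume-average elevation measured with K⁺-sensitive electrodes.

## Estimators

- **GINKO2 calibration**: y = a·ln(x + b), defaults (a, b) = (9340 a.u.,
  2.74 mM) (the published "2:74" is a typesetting artifact for 2.74).
  Inversion is exact (exp(y/a) − b) with a domain check; fitting uses
  scipy's Levenberg–Marquardt with positivity bounds and needs ≥ 3 distinct
  concentrations.
- **ΔF/F₀**: baseline-window mean F₀; default window length 100 ms
  pre-stimulus where a caller does not specify one. Invariant under
  multiplicative gain by construction.
- **PPR from ΔF/F₀**: response windows are [stim1, stim2) and
  [stim2, stim2 + ISI); within each, the peak is located and the trace
  averaged over 10 ms around it; PPR = second/first. Window edges carry a
  relative tolerance of 10⁻⁹ of the trace span so regularly sampled traces
  keep sample-symmetric windows despite accumulated floating-point error in
  the time base (without it, a one-sample asymmetry biases the ratio by
  several percent). For alpha-function responses 50 ms apart the
  window-averaging bias is < 2%, and the two windows' biases largely cancel
  in the ratio.
- **P_r and PPR from trials**: P_r = total successes / total trials per
  pulse; PPR = P_r2/P_r1, with an explicit error (not NaN) when P_r1 = 0.
  A 15-trials-per-bouton floor mirrors the acquisition rule and can be
  lowered explicitly.
- **Decay time**: mono-exponential least-squares fit (baseline + amplitude +
  τ) from the post-onset peak; invariant under scaling and offset; an
  R² diagnostic flags non-mono-exponential input, and a 1/e-crossing
  alternative (`efold_time`) is exposed for sensitivity checks. Whether the
  published decay times came from fits or threshold crossings is unstated;
  the fit was chosen as the more noise-robust default.
- **Residual subtraction** (transporter-current isolation): pointwise on a
  shared time base, linear interpolation when bases are offset by less than
  half a sample.

## Synthetic data

Generators are bit-reproducible functions of (parameters, seed) via numpy's
`default_rng` and return truth metadata. Defaults are the study conditions:
release probabilities (0.46, 0.69), transient decay 1.85 s (1.13 s for the
fast phenotype), calibration truth (9340, 2.74), paired stimuli 50 ms apart
(2 × 20 Hz), ≥ 15 trials. Unpublished nuisance parameters were fixed once at
field-typical values: additive Gaussian noise for current/fluorescence
traces (default 2–5% of amplitude), multiplicative Gaussian noise (CV 2%)
for calibration ratios, alpha-function kinetics (t/τ_r)·e^{1−t/τ_r} with
τ_r = 5 ms for indicator responses, 1–2 kHz sampling.

What the generators do *not* emulate: photon shot noise and bleaching,
correlated (pink) noise in electrophysiology, release-site heterogeneity
and use-dependent depression within a bouton, spillover between boutons, and
indicator saturation kinetics. Passing recovery tests therefore demonstrate
estimator correctness under the declared statistical structure, not
robustness to every artifact of real recordings.

## Problem sizes and numerical choices

The long-relaxation check integrates the default grid (7,980 voxels) for
400 s of model time (4×10⁵ Euler steps); the boundary check doubles the
arena to 63,840 voxels for 20 s. Both complete in well under a minute each
with the vectorized stepper. Short property checks use a 9×9×9 cube.
CSV output is fixed at 9 significant digits so identical runs are
byte-identical; NRRD snapshots use ASCII encoding with pitch and origin in
the header. Fits are seeded with moment-based initial guesses; degenerate
inputs (all-equal concentrations, non-decaying traces, empty windows,
zero baselines) raise typed errors rather than returning NaN.

## Known limitations

- No membrane-potential dynamics: V_m is clamped at −80 mV everywhere, so
  depolarization feedback on the Kir driving force is absent (uptake is
  modestly overestimated during large challenges).
- No Na⁺/K⁺-ATPase, NKCC1, gap-junction syncytium, or electrodiffusion
  coupling; the relaxation term lumps all of background clearance into one
  rate.
- The spherical territory is a stand-in for a reconstructed morphology; the
  published voxelization of the real cell onto the 19×28×15 grid is not
  specified, so territory-shape-sensitive quantities (e.g. the exact
  boundary-sensitivity percentage) should be read as model-class results.
- The mirrored [K⁺]_in field ignores intracellular transport entirely.
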