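# astrokir

Astrocytes are the brain's principal managers of extracellular potassium:
intense synaptic activity raises [K⁺]_out from its ~2.5 mM resting level, and
the inwardly rectifying channel Kir4.1 — the dominant resting K⁺ conductance
of these cells — draws the excess into the astrocyte's territory. How much
buffering a *single* astrocyte provides depends on how much Kir4.1 it
expresses. `astrokir` is a reduced, fully testable model of that relationship,
for computational neuroscientists and electrophysiologists who want the
biophysics without a full compartmental-morphology simulator.

The package implements:

- **Kir4.1 current kinetics** — the fitted current-density law

  I_Kir = g_Kir · V_f(V1) · [K⁺]_out^½ · (1 + e^{V_f(V2)/V3})^{−½},
  V_f(V_i) = V_m − A_K·E_K − V_i,

  with the Nernst reversal E_K = (RT/F) ln([K⁺]_out/[K⁺]_in), best-fit voltage
  parameters V1 = −14.83, V2 = −105.82, V3 = 19.23 mV, and a normalization
  factor A_K ≈ 0.689 that zeroes the current at rest (2.5 mM, −80 mV).
  Inward current is negative; g_Kir = 0.175 mS/cm² is the reference CA1
  density, doubled (0.35) or halved for over-/under-expressing cells.

- **A reduced 3D territory model** — forward-Euler reaction–diffusion of
  [K⁺]_out on a 130×150×42 μm³ arena (19×28×15 voxels, zero-flux boundaries,
  D = 0.6 μm²/ms): d[K⁺]_out/dt = D∇²[K⁺]_out − k(r)([K⁺]_out − 2.5 mM), with
  the lumped uptake rate k(r) = 1/40 s⁻¹ in background tissue and scaled by the
  central astrocyte's relative Kir conductance inside its territory.
  Intracellular K⁺ mirrors local depletion with the extra/intracellular
  volume-fraction factor 2.

- **A well-mixed whole-cell budget** — territory ECS volume (~10⁴ μm³),
  charge→ions→concentration arithmetic, and the peak fractional [K⁺]_in change
  from a local [K⁺]_out challenge integrated through the Kir law.

- **Estimators** — the logarithmic GINKO2 K⁺-indicator calibration
  y = 9340·ln(x + 2.74) with exact inverse and least-squares fitting; ΔF/F₀;
  paired-pulse ratio (10-ms average peak convention); quantal release
  probability P_r = successes/trials with a 15-trial floor; mono-exponential
  decay-time fitting; residual-trace subtraction.

- **Seeded synthetic-data generators** for every estimator input, with truth
  metadata, so all recovery properties are testable offline.

## Worked example

How strongly does a local K⁺ challenge perturb the astrocyte's own K⁺ pool?
Raise [K⁺]_out from 2.5 to 5 mM in a 10-μm sphere for 5 s and integrate the
Kir flux over the membrane inside the sphere:

```bash
$ astrokir uptake-event --csv up.csv
peak |d[K+]in|/[K+]in = 0.0643 %
```

At control density the 110-mM intracellular pool moves by only ~0.06% (~0.13%
at doubled density) — the cell is a near-infinite sink at these scales. The
territory-average extracellular decay implied by the same current law:

```bash
$ astrokir ecs-decay --csv decay.csv
fitted first-order tau = 22.47 s
```

i.e. the full nonlinear Kir law relaxes a 5→2.5 mM elevation with an effective
first-order constant of a few tens of seconds, the same order as the 40-s
lumped rate used by the grid model. The same package analyzes quantal release
data:

```bash
$ astrokir synth quantal --seed 3 --out trials.csv
$ astrokir estimate pr --trials trials.csv
{"p1": 0.5, "p2": 0.65, "ppr": 1.3, "n_trials": 20}
```

Here 20 simulated paired-pulse trials (true p₁ = 0.46, p₂ = 0.69) give
P_r estimates of 0.50 and 0.65 and a paired-pulse ratio of 1.3. The 3D run
itself is driven by a TOML scenario file
(`astrokir simulate-territory --print-defaults` shows every parameter) and
writes a summary CSV, ASCII-NRRD volume snapshots, and a checksummed JSON
manifest.

Python API mirrors the CLI: see `astrokir.kir_kinetics`,
`astrokir.territory_model`, `astrokir.cell_uptake`, `astrokir.estimators`,
`astrokir.synthetic_data`.

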