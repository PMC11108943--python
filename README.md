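# cutigas

Cuticular-conductance-aware analysis of leaf gas exchange.

## The problem

Gas-exchange instruments infer the intercellular CO₂ mole fraction
C_i from the measured CO₂ and water fluxes through the ternary-corrected
diffusion equation

```
C_i = ((g_tc − E/2)·C_a − A) / (g_tc + E/2)
```

and, by convention, build the total conductance to CO₂ `g_tc` from the
*leaf* conductance to water as if it were all stomatal
(`g_tc = g_sw/1.6`, plus a boundary-layer term).  But leaves also lose
water across the cuticle, and the cuticle discriminates against CO₂
roughly 20-fold (vs 1.6-fold for the stomatal pore).  When stomata are
nearly closed — drought, high CO₂, low-conductance species — the
cuticular share `g_cw` inflates the apparent CO₂ supply and C_i is
overestimated, sometimes grossly.  The corrected calculus is

```
g_sw = g_lw − g_cw            (partition the water flux)
g_lc = g_sw/1.6 + g_cw/20     (rebuild the CO₂-side conductance)
C_i_mis = (C_i_uncorr − C_i_cor) / C_i_cor
```

`cutigas` implements this correction end to end, for people who fit
A/C_i curves for a living:

* **conductance / fvcb** — the conductance calculus and a coupled
  Farquhar–von Caemmerer–Berry forward model: for a prescribed g_lw it
  solves supply = demand for the unique (A, C_i);
* **misestimation** — sweeps of corrected vs uncorrected C_i over the
  g_lw grid, threshold ratios, deterministic ±1 sd instrument-noise
  bands, and the combined worst-case error envelope;
* **racir** — empty-chamber polynomial calibration of constant-ramp
  (RACiR) A/C_i curves;
* **aci** — FvCB parameter fitting (V_cmax, J_1200, TPU, R_dark, the
  limitation transitions C_itrans1/2) and the ΔCV method-precision
  statistic;
* **redlight** — cuticular-conductance estimation by the red-light
  method (biochemical C_i inversion + conductance-system solve);
* **synthetic** — an LI-6800-style instrument emulator (steady-state,
  ramp, empty-chamber and red-light protocols, CO₂-responsive stomatal
  dynamics, Gaussian conductance noise) used by the tests and usable
  for power analyses.

## Worked example

```python
from cutigas import sweep_glw, threshold_ratio, NoiseSpec, sweep_noise, noise_threshold_ratio

profile = sweep_glw(g_cw=0.0056, ca_values=(400.0,))
print(threshold_ratio(profile, threshold=0.05, ca=400.0))
# 0.1107...  -> ignoring the cuticle misestimates C_i by >5% once
#               g_cw exceeds ~11% of g_lw at ambient CO2

noise = sweep_noise(g_cw=0.0056, noise=NoiseSpec(sd_glw=0.00415), ca=400.0)
print(noise_threshold_ratio(noise))
# 0.1291...  -> after correcting, the instrument's own conductance
#               noise only moves C_i by >5% above a ratio of ~0.13
```

The `examples/` directory holds one short script per capability
(misestimation thresholds, simulate-and-fit, ramp calibration,
red-light g_cw, ΔCV), each printing what it computes and what the
numbers mean.  A thin CLI mirrors the shell workflows:
`cutigas simulate|calibrate-racir|fit-aci|gcw-redlight|misestimation-sweep|noise-analysis`.

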