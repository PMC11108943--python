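# Methods

## Conductance calculus

All conductances are in mol m⁻² s⁻¹, assimilation in µmol m⁻² s⁻¹,
CO₂ mole fractions in µmol mol⁻¹ and pressures in kPa — the mixed-unit
convention of commercial gas-exchange instruments, evaluated exactly as
such (no internal unit normalisation).

The water-side leaf conductance partitions as `g_lw = g_sw + g_cw`.
The CO₂ side books each path with its own discrimination factor:
stomata at 1.6, boundary layer at 1.37, cuticle at 20 (fixed; reported
cuticle ratios span roughly 20–40, and 20 — the conservative end — is
used throughout).  The total conductance to CO₂ combines stomatal and
boundary-layer resistances per leaf surface, weighted by the
adaxial:abaxial stomatal-resistance ratio K.  Defaults: K = 0
(hypostomatous / low-conductance leaves), g_bw = 2.23 (a 3×3 cm
chamber); both configurable.

The corrected pathway rebuilds `g_lc = g_sw/1.6 + g_cw/20` and
re-enters the standard total-conductance formula through a *pseudo*
water-side conductance `1.6·g_lc`, so any component that internally
assumes `g_tc = g_lw/1.6` (including our own Eq-2 implementation)
receives the corrected value with the boundary layer still applied.

A computed C_i may be negative at very low conductance.  This is
reported with a quality flag, never clamped or raised: the unreliable
regime is precisely the object of study.

## Coupled forward model

Net assimilation is the hard minimum of the Rubisco-, RuBP- and
TPU-limited rates minus day respiration.  The hard minimum (no
hyperbolic smoothing) keeps the limitation transitions exact
intersections, with closed forms

```
C_itrans1 = (J·K_m − 8Γ*·V_cmax) / (4V_cmax − J)       if 4V_cmax > J
C_itrans2 = Γ*(J + 24·TPU) / (J − 12·TPU)              if J > 12·TPU
```

and "absent" a normal outcome otherwise.  Kinetic constants default to
25 °C values (Γ* = 42.75 µmol mol⁻¹, K_c = 404.9 µmol mol⁻¹,
K_o = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹, so K_m ≈ 710.3); the
forward-model defaults are V_cmax = 50, J = 100, R_d = 1.5
µmol m⁻² s⁻¹.  No temperature response is applied anywhere.

`coupled_solve` finds the C_i at which the diffusion (supply) equation
and the demand function agree, by Brent root search with the residual
closed to ≤ 10⁻⁸.  Transpiration is modelled as `E = g_lw·VPD/P_atm`
(VPD default 1.5 kPa, P_atm 101.325 kPa); the boundary-layer
contribution to E is neglected (g_bw ≫ g_lw in every regime of
interest).  The nominal bracket is (Γ*·10⁻³, C_a]; when C_a sits at or
below the operational compensation point the leaf is a net CO₂ source
and the solution lies *above* C_a, so the bracket is extended upward
by the largest possible respiratory reversal.  This degenerate-input
handling is what lets the 50 µmol mol⁻¹ setpoint of the steady-state
protocol be simulated at all.  The solver is fully deterministic.

Note one consequence of `E ∝ g_lw`: as g_lw → ∞ the diffusion
drawdown A/g_tc vanishes but the ternary E/2 term converges to a
constant offset (E/g_tc is independent of g_lw), so C_i approaches
C_a·(1 − ~1.6·VPD/P_atm)/(1 + ~0.8·VPD/P_atm·...) rather than C_a
itself; C_i → C_a exactly only as VPD → 0.

## Misestimation and noise analyses

The standard sweep runs g_lw from 0.001 to 1 in 0.001 steps at
C_a ∈ {100, 400, 2000}, computing corrected and uncorrected C_i per
grid point and the proportional misestimation between them.  Grid rows
with g_lw ≤ g_cw (corrected pathway undefined) are flagged, not
dropped.  Threshold crossings are located by linear interpolation
between bracketing grid rows on the g_cw:g_lw axis and reported to two
decimals; at the 0.001 grid step, interpolation vs nearest-row differs
below that precision.

Instrument noise is treated as the deterministic ±1 sd envelope the
empty-chamber measurements justify (sd 0.00415 mol m⁻² s⁻¹ on g_lw),
not Monte-Carlo: C_i is evaluated at g_lw − sd, g_lw, g_lw + sd and
the worst proportional deviation reported.  Where the lower
perturbation is non-physical the band is one-sided and flagged.  The
combined envelope takes the maximum deviation of *uncorrected*
perturbed C_i from the *corrected* unperturbed value; it dominates
both single-source errors pointwise.

The corrected-below-uncorrected ordering of C_i holds wherever the
leaf assimilates (A > 0); when A < 0 the ordering flips, correctly —
a smaller corrected g_tc pushes C_i further above C_a.

## Synthetic instrument

The generator couples first-order stomatal dynamics to the forward
model and then logs what an instrument would log.

* **Stomatal dynamics.**  Target opening
  `g_sw* = g_min + (g_max − g_min)·clip(1 − s·(C_a − 400), 0, 1)` with
  exponential relaxation at time constant τ.  The clip keeps
  g_sw ∈ [g_min, g_max] (an unclipped linear target would exceed g_max
  without bound below 400 ppm).  This is the simplest mechanism that
  reproduces stomatal closure as a ramp passes high CO₂; species
  presets encode measured leaf means (daylight g_lw of 0.09 / 0.12 /
  0.33 / 0.17 and g_cw of 0.0053 / 0.0045 / 0.0076 / 0.0056 for
  magnolia, citrus, bell pepper, papaya).
* **Protocols.**  Steady state: the 16-setpoint progression starting
  at 380 µmol mol⁻¹, one record per setpoint after a 120 s hold.
  Constant ramp: 100 µmol mol⁻¹ min⁻¹, logged every 2 s, with 30 s of
  endpoint padding per side — the logged window is the nominal ramp
  duration plus one minute, giving 270 records for 100→900 and 600 for
  100→2000.  Red light: 7 s cadence, induction followed by a 300 s
  steady window of 42 complete intervals.
* **Truth vs report.**  The true (A, C_i, E) come from the coupled
  solver with the true stomatal/cuticular partition.  The *reported*
  g_lw adds Gaussian noise (default sd 0.00415; seed mandatory
  whenever any noise is on), and the reported C_i is recomputed from
  the noisy observables through the uncorrected pathway — exactly the
  instrument's computation, bias included.  Ground-truth columns ride
  along for closure tests.
* **Empty chamber.**  Apparent assimilation is a polynomial (degree
  ≤ 5) of reference CO₂; reported conductance is pure noise around
  zero, the empirical basis of the 0.00415 figure.
* **Red-light runs** are generated from the RuBP-limited rate alone
  with a low operating J and a non-limiting boundary layer: a leaf
  under 100 µmol m⁻² s⁻¹ red light is electron-transport limited
  throughout, and a hard-minimum model with a daylight V_cmax would
  spuriously hand the low-C_i region to Rubisco.  This also makes the
  estimator's algebraic inversion close exactly at zero noise, which
  is the property the closure tests exercise.

What the emulator deliberately omits: chamber gas mixing and
sample/reference drawdown (both CO₂ columns carry the setpoint),
match-mode mechanics beyond the empty-chamber polynomial, humidity
dynamics, leaks, and temperature responses.  Passing closure tests
therefore demonstrate the *analysis* pipeline's correctness under the
stated physics, not robustness to every instrument artefact.

## Ramp calibration

The empty-chamber signal is fitted by least-squares polynomials of
degree 1–5 with the degree chosen by BIC — a deterministic, testable
stand-in for the visual inspection the field's protocol prescribes.
Correction subtracts the fitted signal from the leaf A and recomputes
C_i through the *uncorrected* conductance pathway, matching instrument
behaviour; the cuticular correction is applied later, in curve
recomputation, keeping the two corrections orthogonal.  Rows outside
the model's fitted reference-CO₂ span are flagged as extrapolations.
Trimming bounds are explicit arguments, never defaulted.

## A/C_i fitting

Bounded nonlinear least squares (trust-region reflective) of the
hard-minimum model against observed A, fitting V_cmax, J, R_d and
optionally TPU, with Γ* and K_m held fixed (a single-O₂ curve cannot
separate them from V_cmax).  Initialisation is a deterministic
multi-start grid derived from segment-wise linearised estimates: a
Rubisco proxy from the low-C_i limb, a RuBP proxy from the upper C_i
quantile (plus a 1.4× inflated-J start, because the plateau-derived
guess is biased low whenever TPU binds).  No randomness anywhere in
the fit.  Standard errors come from the local curvature
(rss/(n−p)·(JᵀJ)⁻¹); hyperbolic smoothing of the minimum is available
as a fitting option but off by default so fitted transitions remain
exact intersections.

TPU is reported absent — with C_itrans2 absent alongside — when its
optimum carries no information: the fitted gross plateau 3·TPU exceeds
the largest observed *gross* assimilation (max A + fitted R_d) by more
than twice the residual RMSE; or TPU sits at its optimiser bound; or
fewer than two points actually bind at the TPU rate (a one-point
plateau lets a degenerate J/TPU pair mimic a short RuBP limb on
truncated curves).  Fitting with TPU is refused outright, with a
warning, when the curve never reaches C_i = 500.

ΔCV compares replicate precision between curve methods:
`1 − CV_ramp/CV_SS`, CV = sd/mean across replicate fits.  Published
mean ± SE summaries work identically when both arms share n (the √n
cancels).

## Red-light g_cw estimation

Per steady-window record: gross assimilation G = A + R_dark (R_dark
measured separately before induction; no light-inhibition factor is
applied to it), C_i from the algebraic inversion
`C_i = Γ*(J_a + 8G)/(J_a − 4G)` (valid for 0 ≤ G < J_a/4), the
CO₂-side leaf conductance from the exact inversion of the ternary
diffusion equation with the boundary layer non-limiting, and the
stomatal/cuticular split from the 2×2 water/CO₂ linear system.  The
reported g_cw is the mean over the 42-record window; records whose
split falls outside [0, g_lw] are excluded with the count reported,
and estimation fails if more than half the window is excluded.
(J_a, Γ*) come from a least-squares fit of the RuBP-limited form to a
companion curve with R_dark fixed; the fit refuses curves that never
reach below C_i = 300, where Γ* is unidentifiable.  J_a is taken from
the companion fit directly, with no interpolation to the red-light
operating condition — an explicit assumption of the implementation.

## Problem sizes and tolerances

The threshold analyses use the full 1000-point grid (seconds of
runtime).  Closure tests use 0.001-grid exhaustive search oracles (100
random draws), 50 seeded noisy curves for parameter-recovery
statistics, and 8 replicate leaves for the red-light averaging check —
sizes at which every stochastic check is comfortably stable under its
fixed seeds.  Solver tolerance is 10⁻¹² on C_i (residual ≤ 10⁻⁸
asserted); polynomial recovery is exact to 10⁻⁶ on noise-free data.

## Known limitations

Mesophyll conductance is not modelled (C_i, not C_c, is the target
quantity); the cuticular ratio is fixed at 20; C₄ photosynthesis and
temperature responses are out of scope; the stomatal model is
phenomenological and its presets are calibrated to means, not to
dynamic traces; the ΔCV statistic inherits the usual fragility of CVs
near zero-mean parameters (R_dark fitted near zero makes it
undefined).
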