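# Methods

This note records the models implemented in `torquetweezers`, their
assumptions, the tunable parameters that matter, the design choices made
where the design was genuinely open, and the known limitations.

## Angular trap and torque measurement

The bead's rotation about the tether axis is modelled as an overdamped
harmonic degree of freedom: a dwell at fixed applied turns *N* is an
Ornstein–Uhlenbeck (OU) process with stationary variance
`k_B T / k_ROT` and relaxation time `τ_c`. Equipartition gives the trap
calibration `k_ROT = k_B T / Var(Θ)`; the molecular torque follows from
the mean-angle shift, `Γ_mol = −k_ROT (⟨Θ_N⟩ − Θ_0)`.

**Frame convention.** The generator emits absolute unwrapped angles: when
the magnets turn *N* times the trap equilibrium moves to
`θ₀ + 2πN − Γ_mol(N)/k_ROT`. The torque extractor therefore works in the
rotating magnet frame — it subtracts `2πN` from each dwell's mean — so
the Γ relation above holds with Θ measured relative to the relaxed
reference step. Positive *N* means overwinding the right-handed helix and
yields positive torque; unwinding (clockwise magnet rotation as seen from
above) gives negative torque. This mapping is defined in one place
(`params` module docstring) and used consistently.

**Error model.** Per-step torque standard errors use an effective sample
size `n_eff = n / (2 τ_c f)` (OU autocorrelation correction), with τ_c
estimated per segment by a log-linear fit to the empirical
autocorrelation restricted to lags where it exceeds 0.3 — longer lags are
noise-dominated and bias the decay time low.

**Reference-offset removal.** Because Θ₀ is estimated from a single
reference dwell, every molecule's torque curve carries a common additive
offset with standard deviation `k_ROT·Std(Θ)/√n_eff` (≈ 3 pN·nm under
default conditions). Before averaging curves across molecules, each
molecule's torque origin is re-zeroed by the free intercept of a line
fitted to its central (linear-regime) points — the torque analogue of
equalizing extension offsets at zero turns. Without this step the
±1 pN·nm-level plateau comparisons would be dominated by reference noise.

## Angle tracking

The orbit center and radius come from an algebraic (Kåsa) circle fit
refined by one geometric Gauss–Newton pass; degenerate (collinear) input
raises an error rather than guessing, and arcs below 45° warn. Angles are
`atan2` values unwrapped with ±2π corrections at jumps larger than π;
samples within 0.2 of the fitted radius from the center are flagged
unreliable. Angle noise propagates as `σ_Θ ≈ σ_xy / r`, about 0.017 rad
for 5 nm tracking noise on a 300 nm orbit. Dwell segments discard the
first 5 s as equilibration; magnet-ramp samples are excluded via flags.

## Curve averaging

Below 1 pN the extension–rotation curve is symmetric; each molecule's
relaxed linking offset Lk₀ is the center of a least-squares Gaussian
(amplitude, center, width, baseline free), curves are shifted by −Lk₀ and
pooled into 2-turn bins with edges `[2k−1, 2k+1)` (centers on even
turns), and per-bin mean/STD/SEM are computed across molecules. Shifts
that are numerically integer are snapped exactly, since integer-centered
samples would otherwise sit on the half-open bin edges and be assigned by
floating-point noise.

Above 1 pN each curve is aligned to the population-mean buckling point
(shifts rounded to whole turns so the per-turn averaging grid is
preserved), extension offsets at zero turns are equalized, and data are
averaged per turn value. Molecules with no detectable buckling are
excluded from the mean buckling point (with a warning) and aligned by
their torque-curve zero crossing instead.

## Buckling observables

- **Detection rule (default).** A line is fitted to the constant
  pre-buckling region (|N| ≤ half of a coarse two-segment breakpoint
  estimate) and the curve is scanned outward; the first point falling
  below the line by more than one times its own standard error is the
  buckling point. The error multiplier is configurable.
- **Refined estimate (`refine=True`, used by the pipeline).** The side is
  partitioned into flat-then-line at the SSE-optimal breakpoint and the
  buckling point is the intersection of the two lines; buckling is only
  declared if the post branch slopes downward and drops by more than five
  times the noise floor. The first-below rule is exquisitely sensitive to
  the per-point error scale (with thousands of averaged frames per step
  the per-point SE is ~0.1 nm, and ~16 % of plateau points dip below a
  1-SE band by chance); the partition estimate is continuous, robust to
  2-turn binning and unbiased at the kink.
- **Post-buckling slope**: weighted line fit to the extension beyond the
  buckling point, skipping 1.5 turns around the kink (the kink bin mixes
  both phases).
- **Buckling torque**: mean of the torque plateau from 2 turns beyond the
  buckling point, with the larger of the scatter-based and propagated SE.
- **Melting / B-to-P plateaus**: the torque branch on one side is
  partitioned into line-then-constant at the SSE-optimal breakpoint; the
  plateau is the mean beyond the breakpoint plus a 2-turn margin. A
  partition that does not beat a single line by 5 % in SSE means no
  plateau (e.g. a branch that never saturates).

## Effective-torsional-stiffness fit

`C_eff = L_C/(2π k_B T) · slope` with the slope from a weighted
least-squares line with free intercept; the intercept is reported as a
quality metric, not forced to zero. The fit window is chosen once per
force condition from the population-mean torque curve (each molecule
de-offset by its central-line intercept first): each side is tested for a
saturation plateau with the line-then-plateau partition (permissive
0.995 SSE-ratio threshold — missing a real plateau biases the slope,
while a spurious one merely trims the window) and the symmetric window
ends two turns before the earlier onset. Each molecule is then fitted
over that window centered on its own torque zero crossing — the
"fit window kept constant per force" convention. Verified against the
generator: per-population bias −1.8 nm, seed-to-seed scatter 3.5 nm at
6.5 pN with ten molecules.

## Worm-like-chain models

`C_eff(F) = C[1 − (C/4A)√(k_B T/(A F))]` (Moroz–Nelson, high-force
perturbative result; errors outside its regime). The coexistence model
uses the MN effective stiffness for the stretched phase at the given
force, the high-force WLC relative extension `ẑ = 1 − ½√(k_B T/(A F))`
(no enthalpic stretching — forces here stay ≤ 6.5 pN), and requires
`P < C_eff(F)` and `g(F) > 0`, raising a regime error naming the violated
inequality otherwise. The closed forms are verified in the test suite
against an independent common-tangent (Maxwell) construction on the two
quadratic free-energy branches, treated as black-box convex functions,
to 1e−6 relative accuracy.

The plectonemic stiffness fit holds A and C fixed and fits P individually
to the buckling points, post-buckling slopes and buckling torques across
forces, then averages the three estimates (their scatter gives the
quoted uncertainty) — mirroring the measurement protocol. A
force-dependent `C_eff(F)` table can be supplied in place of the MN form
where an anisotropic-rod description is preferred; its computation is out
of scope here.

## Synthetic data generator

The generator emulates the instrument so the analysis can be validated by
parameter recovery:

- **OU dwells** with the exact discrete update
  `Θ_{t+Δ} = θ_eq + (Θ_t − θ_eq) e^{−Δ/τc} + ξ`,
  `Var(ξ) = (k_B T/k_ROT)(1 − e^{−2Δ/τc})`, so equipartition holds in
  distribution at any sampling rate (no Euler error). The first sample of
  a run is drawn from the stationary distribution.
- **Rotation response** (piecewise twistable WLC): linear torque
  `2π k_B T C_eff(F) N / L_C` and constant extension pre-buckling; beyond
  the coexistence buckling point the torque caps at τ_buck and the
  extension falls at the coexistence slope. Regime by condition force:
  < 1 pN — buckling on both winding directions (odd-symmetric);
  1–6 pN — unwinding melts at −10 pN·nm (extension held constant; the
  mild asymmetry of real melting curves is not modelled); > 6 pN — no
  supercoiling, overwinding caps at the B-to-P torque +35 pN·nm. The
  regime class follows the *nominal* condition force rather than the
  per-bead jittered force: bead-to-bead magnetization spread perturbs the
  force magnitude, not the qualitative response class of the condition.
- **Geometry**: X = x₀ + r cos Θ, Y = y₀ + r sin Θ (orbit radius default
  300 nm — the attachment geometry is not quantified, this is a typical
  value), Z = extension; Gaussian tracking noise 5 nm (XY) and 10 nm (Z),
  instrument-typical defaults. Magnet ramps between dwells run at 0.1
  turns/s and are emitted as flagged samples so segmentation logic has
  something realistic to discard. Optional camera blur (boxcar over the
  exposure) is off by default — the 17 ms integration time is much
  shorter than τ_c.
- **Population spread**: per molecule, trap stiffness and force are
  scaled by `1 + cv·g` (g standard normal clipped at ±2.5, cv = 0.10 —
  the bead magnetization spread), the intrinsic torsional stiffness by
  the same rule with cv = 0.15 (the 10–20 % molecule-to-molecule
  variability of torsional measurements), plus Gaussian linking-number
  (sd 1 turn) and extension (sd 50 nm) offsets. A ground-truth table
  records every jittered value. Identical seeds give bit-identical
  output.
- **Defective tethers**: nicked — free swivel, zero torque, no
  supercoiling at any force; multiply-tethered — zero net torque and a
  symmetric, force-independent braiding extension loss of 40 nm per turn
  beyond the first.
- **Thermal energy** k_B T = 4.1 pN·nm (T ≈ 297 K) throughout,
  configurable.

What passing recovery tests do *not* show about real data: the generator
has no camera-localization artifacts, no drift, no bead–bead or
bead–surface hydrodynamics, no sequence dependence, no plectoneme
dynamics (hopping), and its torque plateaus are perfectly sharp; real
curves round off at the transitions.

## Magnet-field simulation

A uniformly axially magnetized cylinder is represented by ±Br surface
charges on its end faces; ring magnets are two coaxial cylinders of
opposite remanence, assemblies superpose linearly. The disk integrals are
evaluated with the radial integral in closed form and adaptive quadrature
over azimuth (relative tolerance 1e−9); on-axis values match the
closed-form solid-cylinder expression to 1e−6 or better. Default
geometry: three ring magnets (6 mm outer diameter, 2 mm bore, 2 mm
height) stacked, plus a 3 mm × 6 mm side cylinder with a 1 mm lateral gap
(the exact standoff is not documented; 1 mm is the assumption), remanence
1.4 T (N-grade NdFeB). All uniformity metrics are Br-independent.
Gradients use central differences with a 10 μm step; bead forces use the
saturated-moment approximation `F = m·∇|B|`. The mapping from transverse
field to rotational trap stiffness is not computed — the transverse field
magnitude serves as a proxy.

## Problem sizes and numerical choices

Recovery analyses use 10–20 molecules per condition, 100 s dwells at
60 Hz (≥ 100 relaxation times for τ_c ≤ 0.5 s beads, matching the
measurement protocol's dwell range), and turn schedules reaching ~10
turns beyond the expected buckling point at each force. Quality control
thresholds: contour-length test within 35 % of L_C, extension-loss
threshold 5 % of L_C. Degenerate inputs (zero variance, collinear points,
flat curves, branches without plateaus) raise typed errors rather than
returning numbers.

## Known limitations

- The coexistence model treats the plectonemic phase as a pure quadratic
  medium; electrostics enter only through the fitted A and P values.
- The melting and B-to-P branches are pure torque caps with constant
  extension; coexistence-style gradual transitions are not modelled.
- Twist–stretch coupling and the stretch modulus are ignored, so
  extensions above ~7 pN would be underestimated.
- The Gaussian Lk₀ model is an alignment device, not a physical model of
  the curve apex; it is exact for symmetric coverage and can bias the
  center by a fraction of a turn when the schedule truncates one flank.
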