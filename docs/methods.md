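# Methods

This note records the models, numerical choices and known limitations of
`oscelast`, in the order data flows through the package.

## Units and environment

Forces in pN, lengths in nm, energies in pN·nm. Boltzmann's constant is
0.0138065 pN·nm/K; the default temperature is 296.15 K (23 °C), giving
kBT ≈ 4.090 pN·nm. All modules take an `EnvParams` so other temperatures
are possible, but every default reproduces room-temperature conditions.

## Elasticity models

**WLC.** The Marko–Siggia interpolation in its standard ordering,
F = (kBT/lp)[1/(4(1−z)²) − 1/4 + z], z = x/L, which vanishes at zero
extension and is linear at low force with slope 3kBT/(2·lp·L). The
stiffness k(x) and stretching free energy are its exact derivative and
antiderivative. The leading relative error of the linear approximation is
z/2, so "linear to 1%" means z ≲ 0.02. Domain is 0 ≤ x < L; callers get a
`ValueError` outside it rather than silently extrapolated values.

**Two-state FJC.** Each monomer is a two-level system (gauche length
`l_gauche`, trans length `l_trans`) whose populations follow the
force-tilted gap ΔG(F) = ΔG0·kBT − F·(l_trans−l_gauche); the mean monomer
length multiplies the Langevin orientational factor
coth(Fb/kBT) − kBT/(Fb) of a Kuhn chain. The Langevin factor is evaluated
by series below u = 1e−4 and with a capped sinh above, so both limits
(u/3 and 1 − 1/u) are exact to double precision. The model is defined for
F > 0 only — the Langevin expression is singular at zero force and the
analysis never needs the compressive branch. `l_trans` defaults to
0.256 nm (two C–C backbone repeats). ΔG0 = 3 kBT and
`l_gauche` = 0.2 nm are stand-in defaults that place the conformer
transition near 220 pN, inside the 100–300 pN band where a plain WLC fails
on PEG; the experiments this package emulates never report their fitted
values, so these two numbers are calibration choices, not measurements.

## Cantilever response

The interferometer reads cantilever displacement at a point, so the probe
is a point mass m* = kc/(2πf0)² with drag γc = √(m*·kc)/Q; a tether adds a
parallel Voigt element. `sho_steady_state` solves the driven system
exactly. Defaults: kc = 800 pN/nm, f0 = 13 kHz, drive 500 Hz, A0 = 0.5 nm,
Q = 2 (liquid-like damping; the exact Q barely matters 26-fold below
resonance).

The instrument's working relation A = A0(1 − ki/kc) is the first-order
expansion of the static series response A0·kc/(kc+ki). Its error budget,
which the tests assert explicitly, is worth stating: drag and inertia
contribute < 0.2% of A0 at 500 Hz (the off-resonance premise), while the
linearization term is A0·r²/(1+r) with r = ki/kc — about 1% of A0 at
r = 0.1 and 3.3% at r = 0.2. The synthetic instrument generates amplitudes
from the working relation itself, so the conversion ki = kc(1 − R/A0) is
its exact inverse and parameter recovery is unbiased; with the full SHO as
forward model the recovered stiffness would be low by a factor 1/(1+r),
the documented accuracy limit of off-resonance stiffness spectroscopy.

**Extension axis.** A stiffness–extension curve's natural axis is the base
displacement D, but the tether extension is x = D − F/kc. The static
deflection F/kc (≤ 0.6 nm at 500 pN) looks negligible and is not: it warps
the steep approach to the contour length enough to bias fitted persistence
lengths by ~9%. Because dF/dD = ki·kc/(ki+kc), the force — and hence the
deflection — is recoverable from the stiffness trace alone by cumulative
integration, which `amplitude_to_stiffness` does by default
(`deflection="integrate"`); integration averages the amplitude noise down
to ~0.02 nm of axis error. `"none"` and a constant offset remain available.

**Clipping.** Noise can push R above A0, which would invert to negative
stiffness; such points are clipped to zero and flagged, with the pre-clip
values retained in metadata. Estimators use the pre-clip values: fitting
the clipped series would censor the noise distribution and bias the
low-extension region upward by roughly +σ/√(2π).

**Phase check.** `phase_validity_check` passes a curve iff the median
|δ| < 5° and the spread < 10°; the tolerance is a declared default (the
experimental statement is only "close to zero").

## Synthetic instrument

The generator replaces the unavailable raw data and defines the study
conditions:

* per-curve contour length L ~ log-normal(median, shape=0.1) — tethers
  attach at random points, so apparent contour lengths vary and the
  analysis must normalize by the fitted L_app exactly as the experiment
  does;
* series coupling solved self-consistently per sample: x + F(x)/kc = D for
  extension-explicit models (safeguarded vectorized Newton, bracketed, to
  1e−13·L), or L·z(F) + F/kc = D for the force-explicit two-state chain;
* curve layout: a zero-force approach segment (10% of the stretch span),
  the stretch to a 500 pN rupture, and a detached tail (20%) that provides
  the per-curve A0 reference; rupture at the PEG–thiol–gold force scale,
  with the exact value a declared default;
* sampling 2 kHz at 70–80 nm/s retraction (≈ 0.04 nm per sample), enough
  to resolve the transition window;
* noise: force σ = 5 pN; amplitude σ = 0.002 nm (0.4% of A0 — an
  interferometric detector resolves picometres, and this is the level at
  which the fits recover parameters within the printed experimental error
  bars, which is the calibration rule the defaults follow); phase σ = 1°.

Conditions: `peg_water_pull` (WLC lp = 0.12 nm with transition dip, median
L = 30 nm, 25 curves, 80 nm/s), `peg_water_osc` (lp = 0.5 nm with dip over
extension fractions 0.5–0.7, median L = 100 nm — i.e. 50–70 nm — 25
curves, 70 nm/s), `peg_water_fjc2` (two-state FJC, b = 0.24 nm, median
L = 60 nm), `ps_water_osc` (lp = 0.26 nm, 26 curves), `ps_water_pull`
(lp = 0.23 nm), `ps_urea_osc` (lp = 0.88 nm, 14 curves), PS tethers at
median L = 150 nm.

**Transition dip.** No generative model exists for the PEG conformer
transition seen as a misfit region, so `wlc_plus_transition` multiplies
the WLC stiffness by (1 − d·bump(z)) with a raised-cosine bump over the
configured extension-fraction window and depth d = 0.5; the pulling force
is the cumulative integral of the dipped stiffness. For the pulling preset
the window (0.75, 0.83) is the extension band that maps to 100–300 pN at
lp = 0.12 nm. Outside the window the curve is exactly WLC, which is what
makes exclusion-windowed fitting recover the ground truth.

Determinism: every curve's randomness derives from
`SeedSequence([root_seed, curve_index])`, so ensembles are reproducible
per curve and across platforms at double precision.

**File format.** Plain TSV, `# key<TAB>value` headers (kc, f0,
quality_factor, drive_freq, A0, velocity, temperature, plus `meta:`
entries), full-precision (`repr`) floats: lossless, inspectable, diff-able.
Presets serialize to flat key/value config files the same way.

## Event detection

Contact is the first run of 10 samples above 3σ; rupture is the largest
single-step drop, required to exceed 5σ; the post-rupture segment is the
A0/baseline reference. σ is estimated robustly from *second* differences
(MAD/√6) — first differences would absorb the stretch slope and inflate σ
on clean data; with second differences the detector reproduces the
generator's indices exactly on noiseless curves. Oscillatory curves are
detected on the stiffness-scaled amplitude drop, referenced to the median
amplitude of the final 5% of samples. Thresholds are standard practice,
exposed as arguments.

## Fitting

Plain (unweighted) nonlinear least squares, `scipy.optimize.least_squares`
with bounds, parameter tolerance 1e−10; non-convergence flags the result
rather than raising. Standard errors come from the Gauss–Newton covariance
(pseudo-inverse of JᵀJ, scaled by RSS/dof); a residual-resampling bootstrap
is available as an independent check.

* WLC fits: free (lp, L), lp ∈ [0.01, 10] nm, L above the maximum observed
  extension; initialization lp = 0.3 nm, L = 1.1 × max extension. FEC fits
  regress force on extension; stiffness fits regress stiffness on
  extension.
* Exclusion windows only remove points from the residual set. Force-axis
  windows cut on the measured force; extension-fraction windows need
  L_app, so those fits run two passes (fit → window on x/L_app → refit).
* Two-state FJC: extension is the response at the measured force (the
  model is explicit in that direction), free (ΔG0, l_gauche, b_kuhn,
  L_app) with l_trans fixed. The fit uses forces above 25 pN (5× the force
  noise): below that, the Langevin factor's curvature makes the predicted
  extension hypersensitive to regressor noise and the errors-in-variables
  bias on the Kuhn length exceeds the experiment's printed uncertainty;
  above it the bias is a few per mil.
* Normalization and selection: extension axes are rescaled by L_app;
  curves are kept only if the fit converged and L_app lies within
  [0.5×, 2×] of the maximum extension (the "normalizable" rule). Every
  dropped curve carries a reason, and selected + dropped = input.

## Probe-convolution statistics

`boltzmann_average` integrates the moments of x under
exp(−β[F(x) + kc(D−x)²/2]) with adaptive quadrature at relative tolerance
1e−10, after locating the energy minimum and restricting to x* ± 60 local
thermal widths (clipped to the physical domain [0, L(1−1e−6)], where the
WLC free energy's divergence is integrable). The windowing matters: with a
stiff probe the weight is a ~0.007 nm peak inside a 100 nm domain and
unwindowed adaptive quadrature misses it entirely. An independent
Metropolis sampler (`mc_oracle`) cross-checks the moments: Gaussian
proposals with step 2.4·√(kBT/E″(x*)) — the 1-D optimal-scaling rule,
acceptance ≈ 0.45, inside the sampler's [0.1, 0.9] health band — burn-in
of max(1000, n/10), batch-means standard errors (50 batches).

Closed-form anchors: for a harmonic "molecule" km, ⟨x⟩ = kc·D/(km+kc),
Var = kBT/(km+kc), and the measured force per displacement is the series
stiffness km·kc/(km+kc) — all reproduced to 1e−6. The stiff-probe limit
reverts the convolved force to the molecular force law (0.05% at 100× the
experimental kc), and the force-clamp ensemble inverts the WLC force law
to better than 1% over 5–100 pN (the residual is the genuine thermal
shift −k′·kBT/(2k²), largest at low force).

**Magnitude of the bias.** At the experimental kc = 800 pN/nm the
equilibrium probe bias on a 100 nm tether is ~1e−6 in relative force —
real, directionally consistent (fitted lp below truth, recovering truth as
kc → ∞), but far too small to explain a four-fold lp discrepancy on its
own; the equilibrium convolution is the *mechanism*, and the package
demonstrates it where it is measurable. The demonstration scale is a
short tether (L = 10 nm, lp = 1.0 nm) probed softly (kc = 5 pN/nm,
tweezer-like), where per-point thermal widths are a sizeable fraction of
the tether and the deviation between the differentiated pulling curve and
the intrinsic stiffness reaches tens of percent.

**Hydrophobic penalty.** Poor-solvent stretching cost is modelled as
εh·kBT·profile(x/L), εh default 20. Two profiles are provided. The
*linear* profile (x/L) is the minimal monotone choice: it adds a constant
force εh·kBT/L, which reduces the *relative* force bias (the same absolute
bias over a larger intrinsic force) but contributes exactly zero stiffness
— so it cannot move a stiffness-based comparison at all. The *quadratic*
profile ((x/L)²) additionally contributes stiffness 2εh·kBT/L², which is
what the good/poor-solvent dichotomy is about: when the molecular free
energy (not the probe) dominates the system's curvature, the probe's
biasing weight becomes nominal. The solvent-dichotomy demonstration
therefore uses the quadratic profile; at the demo scale the poor-solvent
deviation is ~0.37× the good-solvent one. `FreeEnergySpec.profile` is
pluggable for other shapes.

**Fluctuation scaling.** Treating the chain as N independent Kuhn
segments in the force-tilted orientation ensemble, the per-segment mean is
b·(coth u − 1/u) and the variance b²(⟨cos²θ⟩ − ⟨cosθ⟩²) with u = Fb/kBT,
so the *relative* extension fluctuation falls exactly as 1/√N — short
tethers fluctuate visibly, long ones look smooth. (Summed independent
contributions always give the square-root law for the relative width;
"fluctuations go as 1/N" statements refer to the variance-to-mean² ratio.)

## Pipeline and comparison

`run_pipeline` is deterministic given (config, seed): the root seed offsets
every preset's stream, reports serialize to sorted JSON with a config hash
and no timestamps, and reruns are byte-identical.
`compare_stiffness_vs_fec_derivative` interpolates contour-normalized
curves onto a common grid, differentiates FECs with a Savitzky–Golay
filter (window 11, order 2 — raw differencing of noisy force is unusable),
trims the filter's edge region, and reports the mean absolute relative
difference plus its sign. The filter's derivative floor on smooth curves
is ~0.5%, an order of magnitude below the physical deviations the demos
report.

## What the synthetic tests do and do not show

The generator shares its force laws with the fitted models, so parameter
recovery demonstrates that the pipeline is unbiased and correctly
propagates amplitude → stiffness → normalized fit under realistic noise,
heterogeneity, contact/rupture structure and exclusion windows — not that
the WLC is the true model of PEG. Real data add tip–surface adhesion,
multiple tethers, drift, piezo nonlinearity and non-equilibrium rupture
kinetics, none of which are simulated. The constant-velocity pulling
curves are generated in mechanical equilibrium (quasi-static retraction at
70–80 nm/s), so the package probes equilibrium probe bias only; dynamic
(finite-rate) bias is out of scope. The two-state defaults ΔG0 and
l_gauche, the dip depth, the rupture force, noise magnitudes and the
tether-length distribution are declared stand-ins for unreported
experimental quantities; conclusions that depend on them (e.g. exactly
where the transition window falls) should be read as conditional on those
choices.
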