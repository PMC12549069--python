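# Methods

## Model and assumptions

The generator is built on the fast–slow burster whose fast subsystem is the
planar vector field

    x' = -y
    y' = x^3 - mu2*x - mu1 - y*(nu + x + x^2)

with `x` exported as the voltage-like trace. This is a Liénard system
(`x'' + (nu + x + x^2) x' + (x^3 - mu2 x - mu1) = 0`): its equilibria are
the real roots of the cubic at `y = 0`, a saddle-node of equilibria occurs
exactly on the discriminant zero set `4 mu2^3 = 27 mu1^2`, and a Hopf
bifurcation where the damping `nu + x + x^2` vanishes at an equilibrium
with `3 x^2 - mu2 > 0`. The model is phenomenological: parameters have no
direct biophysical meaning; what is modelled are the invariant bifurcation
structures at seizure onset and offset, which are preserved across
mechanisms. Chaotic and degenerate (line/center) attractors are outside the
model class — the fast subsystem is two-dimensional.

Parameters are restricted to a sphere about the codimension-3 degenerate
point at the origin. The default radius `R = 0.4` is the smallest round
value at which the attractor probe detects all six bifurcation-curve
families (SN, SNIC, SupH, SubH, SH, FLC); it is recorded in the curve-cache
metadata. Coordinates: Cartesian axes `(mu2, -mu1, nu)`, colatitude
`theta` from the `+nu` pole, longitude `phi` from the `+mu2` axis.

## Locating the bifurcation curves

Local curves are semi-analytic. The SN locus is parameterized exactly by
its double root `xd` (`mu1 = -2 xd^3`, `mu2 = 3 xd^2`, `nu` from the sphere
constraint); the Hopf locus by the equilibrium `x` (`nu = -x - x^2`, `mu2`
from a quadratic in the sphere constraint, determinant required positive).
Hopf arcs are split into supercritical/subcritical segments by a
deterministic probe: integrate just past the crossing at two distances
(`delta` and `delta/4`) and compare asymptotic oscillation amplitudes — the
square-root amplitude law of a supercritical Hopf gives a ratio near 2, a
subcritical escape to a pre-existing attractor a ratio near 1. The probe is
cross-checked in the test suite against the closed-form first Lyapunov
quantity of this vector field, `sign(6 x0 (1+2 x0)/omega^2 - 2)` with
`omega^2 = 3 x0^2 - mu2`, derived from the standard planar normal-form
reduction (the system's `x' = -y` structure makes the reduction exact).

Global curves (SNIC, SH, FLC) have no closed-form test function and are
located by simulation: a latitude/longitude grid is classified by a
deterministic attractor probe (initial conditions near each unstable
equilibrium plus two fixed outer states, fixed horizon, transient discard),
every grid edge across which limit-cycle existence changes is bisected to
0.005 of the curve resolution, and each refined point is labelled:

* on the SN locus *and* with the equilibrium pair and the cycle appearing/
  disappearing together (rest on one side, bursting on the other) → SNIC;
* amplitude just inside the boundary scaling as sqrt(distance) → a SupH
  boundary, already covered by the local curves;
* orbit hugging a saddle (distance < 0.1) with period growing as the
  boundary is approached → SH; otherwise → FLC.

Curve sets are cached as CSV + JSON sidecar (label, theta, phi, R; probe
settings); the packaged cache for `R = 0.4`, resolution 0.05 rad, takes
about half a minute of compute to rebuild. Anchors interpolated along
cached polylines are refined onto the exact analytic locus for the SN and
Hopf families — the fold/circle burster in particular needs its onset
anchor on the fold to a few parts in 10^4.

## Bursting paths and the registry

All paths are arcs and circles on the sphere, compiled to arc-sequence
arrays for the integrator kernel, with the slow variable `z` the central
angle along the path. Conventions: `z = 0` at the onset-curve crossing for
hysteresis paths (the offset crossing sits at negative `z`); slow-wave
paths are closed circles through onset anchor, offset anchor and a third
(bursting-region) point, oriented onset → bursting → offset; piecewise
paths join rest point → onset anchor → bursting point → offset anchor →
end point with per-arc speeds and optional zero-speed dwells.

The hysteresis drift uses the Euclidean distance
`sqrt((x-x_s)^2 + (y-y_s)^2) - d*` from the resting equilibrium. The
resting reference `(x_s, y_s)` tracks the current stable root of the cubic
while one exists and is *retained* (ghost value) when the rest state is
annihilated. Recomputing it unconditionally to the nearest real root —
tempting since the equilibrium moves along the path — flips the drift sign
the instant the fold is crossed and pins `z` on the onset curve before the
slow escape from the saddle-node ghost can develop; with retention the
described push–pull loop emerges (verified by simulation: without it no
burst ever forms).

The registry assigns the 16 classes to methods as 5 hysteresis + 7
slow-wave + 5 piecewise (17 class-method pairs; SNIC/SH is generated by
both slow-wave and piecewise). The hysteresis five are exactly the classic
point-cycle bursters: fold/homoclinic (SN/SH), fold/circle (SN/SNIC),
fold/fold-cycle (SN/FLC), subHopf/homoclinic (SubH/SH) and
subHopf/fold-cycle (SubH/FLC) — the only combinations for which the
required interplay of rest-state loss and cycle loss exists on the sphere.
Each recipe stores its anchors as (curve, arc-length-fraction span); the
sweep coordinate `u` in [0, 1] moves the anchors along validated spans, and
every recipe was verified at five sweep positions to produce a labelled
seizure with the class's trace signatures. Default slow speeds
(`c = 3e-4` for hysteresis, `k = 2e-3` for slow wave and piecewise,
`d* = 0.3`) were chosen once so seizures carry tens to hundreds of spikes
at the default step size.

## Integration and noise

The Euler–Maruyama update adds `tstep * sigma * pinknoise` to `x` only,
i.e. the stochastic increment scales with the raw step (not its square
root), reproducing the model's printed update exactly. The consequence —
the effective noise depends on the step size — is absorbed by the
empirical per-path calibration rather than reinterpreted; users comparing
`sigma` across step sizes should be aware of it. Pink noise is synthesized
by spectral shaping (white Gaussian noise filtered by `1/sqrt(f)`, zero
bin zeroed, unit-variance normalized), deterministic per seed. The default
`tstep = 0.05` resolves the fastest intra-burst cycle (period ≈ 5 time
units on the default sphere) by over 100 steps. Trajectories exceeding
|x| or |y| > 1e3 abort with an error naming the step and parameters.

Event labels are dynamics-defined: hysteresis onset at the first sample
with `z > 0` and offset at the subsequent return below the offset-crossing
parameter; slow-wave/piecewise onset/offset at the upward crossings of the
anchor parameters. Labels are invariant under all post-processing.

## Noise calibration

For each path, `sigma_star` is the lowest amplitude producing a 5–10%
relative deviation of seizure length over 10 seeded runs (seed schedule
`base + i`). "Deviation" is the coefficient of variation (std/mean) — the
natural scale-free reading. The length entering the criterion is measured
on the observable spike train (first to last spike of the burst cluster
overlapping the labelled window): for the feedback-free methods the slow
variable is deterministic, so the geometric labels cannot show any
noise-induced deviation, and what noise actually modulates is when spiking
starts and stops. The search uses a factor-2 geometric grid then
log-bisection to two significant figures. For some classes the cv–sigma
profile jumps discontinuously over the band — one noise-advanced outlier
run can dominate the deviation — in which case `calibrate_sigma` raises
with the measured profile, and the packaged surfaces fall back to the
largest below-band amplitude (flagged in the surface metadata). Surfaces
are piecewise-linear interpolants over (onset fraction, offset fraction),
fitted per class and method, with nearest-sample extrapolation outside the
convex hull (logged).

## Post-processing

Order fixed: normalize to [0, 1] → assign the effective sampling rate
(median intra-seizure spike rate to 10 Hz, always inside the clinical 1–30
Hz band; model time is arbitrary so this is pure relabeling) → causal
second-order Butterworth high-pass (default 0.5 Hz, the midrange of the
0.1–1 Hz clinical band; causal rather than zero-phase because real
amplifiers are causal and the point is to reproduce how they distort DC
shifts) → additive pink noise at `alpha * max(trace)` (0/0.20/0.40 for
none/moderate/high) → optional gain → polarity doubling (reflection about
the trace mid-range). Atlas noise levels couple dynamical and background
noise: low = (sigma_star, alpha 0.20), high = (4 sigma_star, alpha 0.40);
multiples of the calibrated amplitude keep levels comparable across
classes.

## Classification

The classifier sees only a trace, its sampling rate and the event indices.
Spikes are detected from onset to the actual cessation of spiking (first
interval > 3x the running median past the labelled offset, or a post-label
prominence collapse below 60% of the running maximum, which cuts ring-down
oscillations of an abruptly dying cycle) — the scaling-law evidence of an
offset lives in the final cycles, which extend slightly past the geometric
crossing label.

Onset cascade: decelerating-to-settled spike rate (first interval ≥ 1.42x
the settled median) → SNIC; first-spike prominence below 0.62 of the
maximum → SupH; sustained DC shift with the first spike already at ≥ 0.9
of the third → SN; else SubH. SNIC is deliberately tested before the DC
rule: on this map a SNIC onset also displaces the baseline (the invariant
circle leaves through the former rest state), so DC presence alone cannot
separate SN from SNIC, while the square-root frequency growth can. The
DC statistic is the per-cycle median versus the pre-onset baseline mean,
thresholded at 5 baseline standard deviations (floored at 1% of the trace
range) sustained over 3 cycles — a symmetric Hopf-type oscillation keeps
cycle medians at baseline while a fold onset parks the interspike trace on
a displaced plateau.

Offset cascade: terminal amplitude decaying below 0.75 of its value 30
spikes earlier → SupH; slow-phase dwell growth below 0.85 (terminal cycles
slowing — the period-divergent family) → SNIC if a linear score on
(terminal interval ratio, post-ictal step, dwell growth) exceeds 1.55,
else SH; otherwise FLC.

All thresholds live in one `ClassifierThresholds` block and were
calibrated on the generator's own noise-free output. On the 16 classes
(default methods, default anchors, zero noise) the classifier is correct
on 13; the three residual confusions are the taxonomy's own degeneracies:
a fast subcritical spiral-out passes through intermediate amplitudes
exactly like supercritical growth (SubH/SNIC and SubH/SupH onsets read as
SupH), and an FLC offset reached after a long amplitude decline reads as a
Hopf offset (SupH/FLC). The taxonomy itself states that arbitrary-scaling
types (big-cycle SN vs SubH onsets, big-cycle SN vs FLC offsets) cannot be
distinguished in the time series; the classifier reports these ambiguities
explicitly instead of hiding them. Classification should run on pre-filter
traces: the clinical high-pass destroys DC evidence and degrades SN calls
(passing a filtered record is the "clinical mode").

## What the generator does and does not emulate

Passing tests show that the *dynamical* fingerprints — DC shifts,
square-root and logarithmic scaling laws, amplitude growth/decay, noise
floors, clinical filtering artifacts — are reproduced and recoverable.
They do not show realism with respect to interictal activity (spikes,
high-frequency oscillations, slowing), multichannel spatial structure,
mixed-mode or higher-order ictal discharges, or the heterogeneity of human
EEG; none of these are modelled. Amplitude, duration and frequency are
arbitrary until the post-processing stage pins them to clinical scales.

## Numerical choices and limitations

* Cubic roots via the companion matrix with Newton polish; roots closer
  than 1e-7 are merged and reported non-hyperbolic, with exact
  `(x-xd)^2 (x+2xd)` factorization used near double roots (the companion
  matrix splits an exact double root by ~sqrt machine epsilon ≈ 3e-8).
* Non-hyperbolic equilibria are a distinct kind, never folded into
  stable/unstable — they mark the bifurcations themselves.
* Region classification raises an explicit error when no attractor is
  found within the probe horizon; it never guesses.
* Scaling-law fits exclude intervals whose midpoint lies within their own
  length of the boundary (inside the asymptotic blow-up the divergent
  models are numerically unstable), and the square-root frequency law is
  kept rigid (through the origin): its rigidity is what separates it from
  the flexible logarithmic alternative on finite windows.
* The sample sizes used throughout (runs of 1.6e5–1e6 steps, 10-seed
  ensembles, five calibration points per noise surface, five sweep
  positions per recipe validation) were chosen as the smallest that give
  stable, reproducible statistics for the quantities being estimated.
* Records export as CSV plus a JSON sidecar carrying labels, parameters
  and seeds; there is no EDF writer in the dependency set, and the CSV +
  sidecar pair carries strictly more provenance.
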