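# Methods

## Model structure

The model tracks five species of the FRQ/WC-1 oscillator. Transcription of
*frq* is the sum of a light pathway (Hill activation by WC-1*, exponent n,
half-saturation b2) and a dark pathway (Hill activation by WC-1, exponent
m, half-saturation b4); each pathway carries its own FRQ repression factor
1/(1 + (P_F/b)^e) with thresholds b1 (light, exponent g) and b3 (dark,
exponent h). All mRNA and active-protein degradation is Michaelis–Menten.
Light enters only through the photoconversion term r1·L(t)·P_W; the
reversion r2 operates in light and dark alike, so WC-1* decays in darkness
through r2 and its own degradation d5.

The delay between translation and appearance of active protein is
gamma-distributed with kernel G(τ) = f^p τ^(p−1) e^(−(f+γ)τ)/(p−1)! and is
realised as a chain of p first-order intermediates with progression rate f
and loss rate γ (the linear chain trick). The chain's total conversion
efficiency is (f/(f+γ))^p; with the packaged rates about 82% of translated
FRQ matures. Chain lengths are structural, not fitted: the defaults
p = q = 2 are frozen after a one-time calibration of the functional-form
choices against the free-running behaviour (period ≈ 22 h, transcript →
protein peak delay ≈ 5 h, dawn-locked *frq* induction, midnight
conidiation in 12:12). Two alternatives were rejected on those grounds:
chain length 1 on either arm gives a damped (non-oscillating) system, and
a single WC-1 intermediate (q = 1) additionally exposes a runaway branch in
strong light where the light-driven positive loop (P_L → M_W → P_W → P_L)
escapes its Michaelis–Menten degradation ceiling. The repression terms use
the threshold form (P_F/b)^e; the multiplicative reading (b·P_F)^e of the
same constants lengthens the free-running period to ≈ 26 h and displaces
every entrained phase, and was rejected in the same calibration. That
calibration used constant-darkness and 12:12 observables only; all
entrainment and sensitivity analyses below were run once, afterwards, with
the configuration frozen.

The plotted and analysed "FRQ protein" is total FRQ, F_T = P_F + ΣF_i.
By construction dF_T/dt = a3·M_F − d2·P_F/(b6+P_F) − γ1·ΣF_i, so when FRQ
degradation is saturated (P_F ≫ b6) the night-time FRQ profile decays at a
nearly constant rate — the mechanistic basis of the saturation-index
analysis.

## Integration and orbits

Square-wave light makes the vector field discontinuous in time, so each
interval of constant light is integrated separately with LSODA
(rtol 1e−8, atol 1e−10); state is clamped at zero inside the right-hand
side to keep fractional powers real against solver undershoot, and a
trajectory whose states dip below −1e−9 nM is an error. Optional smooth
lights-on/off transitions are approximated by short piecewise-constant
ramp steps.

Free-running orbits discard a 600 h transient and estimate the period from
upward mean-crossings of F_T over a 200 h window (≥ 5 cycles, cubic
refinement of each crossing). A solution is arrhythmic if the F_T
amplitude is below 1e−4 nM, crossing intervals vary by more than 1%, or
the amplitude envelope decays by more than 30% across the window — the
last test catches slowly damped spirals near the Hopf bifurcation that
would otherwise masquerade as small limit cycles for hundreds of hours.

Entrained orbits run cycle-by-cycle from dawn; the clock is entrained 1:1
when dawn-sampled states agree to 1e−4 (relative) over five consecutive
cycles after a 40-cycle transient (up to 80 cycles are allowed) and F_T
has exactly one peak per cycle (peaks counted with a 1%-of-amplitude
prominence floor, so the light-transition kinks in short photoperiods do
not register as extra peaks). Period-doubled and quasiperiodic responses
are therefore `not_entrained`.

Phase markers use a quadratic fit through five grid points around each
extremum. Conidiation phase φ_FRQ is the unique crossing of
F_min + θ(F_max − F_min) on the falling limb of F_T. Of the two candidate
thresholds θ = 1/2 ± α, the minus sign places φ_FRQ at midnight in 12:12
cycles with the packaged parameters (17.84 h after dawn vs 18 h) and is
the frozen default; α = 0.15 throughout.

## Dusk sensitivity, evaluation and robustness

s = [φ(t_DUSK+δ) − φ(t_DUSK−δ)]/2δ with dawn fixed at 0 and δ = 0.5 h; in
fixed-length LD cycles moving dusk means moving the photoperiod, in
symmetric T-cycles dusk sits at T/2 so a dusk shift of δ is a cycle-length
change of 2δ. Phase differences are unwrapped modulo the cycle. The
central difference is converged: at δ = 0.25 h the standard-condition
values change by < 0.01. Exact reference measures (dawn, dusk, mid-night)
are evaluated on the protocol alone and give 0, 1, ½ to machine precision.

The evaluation function is the tent map E(s) = clamp(1 − |2s − 1|, 0, 1):
E = 1 for perfectly systematic entrainment, E = 0 for pure dawn- or
dusk-driving, with values outside [0, 1] (and non-entrained conditions)
scoring 0. R averages E over photoperiods 6–18 h on a 2 h grid by
trapezoid; the lower limit respects the model's entrainment limit, and the
trapezoid is grid-converged to < 0.02 on refinement to 0.5 h.

## Flexibility analysis

The response matrix stacks five channels (M_F, F_T, M_W, P_W, P_L) at 120
samples per 12:12 cycle, each channel divided by its baseline mean level,
against central differences in ln k_j (±1% proportional steps) for the 33
kinetic parameters; perturbed systems are re-entrained from the baseline
dawn state. Mean-level scaling (relative concentration change) was chosen
over peak-trough amplitude scaling: amplitude scaling equalises channels
with very different absolute swings and in doing so suppresses the
coupling-dependence of the spectrum almost entirely, whereas relative
concentrations preserve it; the scaling is recorded in the spectrum's
normalisation field. The leading pair (u1, v1) is sign-fixed so that a
positive step along v1 delays the cycle (u1's projection on the negative
orbit derivative is positive). The spectrum is converged: doubling the
sampling changes the singular-value sum by < 2%, and halving the
finite-difference step changes σ1 by well under 5%.

The phase–amplitude decomposition fits, per channel,
δx(t) ≈ −s·ẋ(t) + ρ·(x(t) − x̄) by least squares over one cycle;
mean-centering the amplitude regressor keeps offset-dominated channels
(near-constant *wc-1* mRNA in DD) from leaking amplitude into phase. The
linearised fit is accurate for smooth channels; at the square-wave light
transitions (the acute *frq* and WC-1* edges, which are pinned to the
light schedule and cannot shift) it systematically underestimates imposed
time shifts, so recovery tests of the decomposition use smooth synthetic
orbits, and the conidiation-phase change is always re-measured directly
from the threshold crossing rather than taken from the fit. A caveat
discovered in validation: a +2% step along the delay direction v1 carries
the wild type across its 12:12 entrainment boundary (locking fails);
demonstrations therefore use 1% steps, which remain well inside the locked
region on both sides.

## Bifurcation scans

Coupling scans reduce a7 to a fraction c of its packaged value, inheriting
each initial condition from the previous grid point (continuation), and
record the free-running amplitude (0 when arrhythmic), period and mean.
Classification: supercritical Hopf requires a continuous amplitude
collapse (no jump above 20% of the maximum between adjacent rhythmic
points, amplitude at the last rhythmic point below half the maximum), A²
linear in c near c* (R² > 0.9 over the five nearest rhythmic points) and a
bounded period (< 2× the full-coupling period); a period diverging beyond
3× flags a SNIC; an amplitude jump with hysteresis between downward and
upward sweeps flags a subcritical Hopf or fold of cycles. For the packaged
model the scan gives a clean supercritical signature with c* ≈ 0.25 and an
essentially constant ~21.5 h period on the rhythmic branch.

## Cost function and refinement

Features are reproducible circadian observables: DD period, peak/trough
times of M_F, F_T and P_W relative to the F_T peak (reduced modulo the
period; the FRQ/WC-1 relationship is summarised as the circular peak
separation in [0, T/2]), the relative amplitude of *wc-1* mRNA, and the
12:12 phases (φ_FRQ vs midnight, M_F peak vs dawn, M_F trough vs dusk).
The packaged target table sets targets from the qualitative wild-type
picture with scales of 1–3 h reflecting the spread of the underlying
phase measurements (0.05 for the dimensionless *wc-1* amplitude); each
missing feature (arrhythmia, failed entrainment) adds a flat penalty of
100, which dominates any achievable weighted mismatch. Refinement is a
budget-capped Nelder–Mead simplex in log-parameter space over a chosen
subset, returning the start if no improvement is found; global search is
out of scope by design.

Two properties of the fitted parameter set matter when interpreting
refinement experiments. First, the wild type sits close to the oscillation
boundary in many single-parameter directions: 30% displacement of most
production/degradation rates (a2–a6, b5, b8, d1, d3, d4, h) already damps
the rhythm, while the delay-chain, repression-threshold and positive-loop
parameters tolerate it. Second, once the rhythm is lost the cost surface
is a flat penalty plateau with no gradient, so derivative-free local
refinement cannot recover an arrhythmic start; parameter-recovery
evaluations are accordingly defined over displaced-but-rhythmic starts.

## Synthetic data

Parameter ensembles perturb each kinetic constant as k → k·exp(ε),
ε ~ N(0, σ²) i.i.d., keeping rates positive and matching the proportional
convention of the flexibility analysis; Hill coefficients are floored at
1. The default σ = 0.05 (5%) produces predominantly rhythmic ensembles
with a ~1 h period spread. Noisy time courses subsample a trajectory every
2 h and apply mean-preserving multiplicative log-normal noise at a 10%
coefficient of variation — emulating the sampling density and scatter of
densitometry-style series, but not replicate structure, baseline drift or
detection floors, so recovery results speak to sampling and noise only.
All generators are pure functions of (spec, seed).

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: 600 h DD
transients with 200 h analysis windows (400/160 h inside the refinement
loops); entrainment transients of 40 cycles (15 when warm-started inside
the response matrix); response matrices at 120 samples/cycle; coupling
scans of 12 grid points; refinement budgets of 40–80 evaluations; the
flexibility–robustness comparison at coupling fractions {1, 0.3, 0.01}.

## Known limitations

* The reconstruction misses two printed behaviours: FRQ and WC-1 peak
  ~17 h apart in DD rather than strictly in antiphase (~11 h), and the
  dusk sensitivity in symmetric T-cycles overshoots dusk-tracking (≈ 1.29
  vs ≈ 1), as does the long-day LD value slightly (0.64 vs ≈ 0.5). The
  driven character of T-cycle entrainment and the systematic character of
  LD entrainment are nonetheless unambiguous.
* Temperature compensation, FRQ isoforms, the *vvd* gene, phase-response
  curves and stochastic (molecular-noise) simulation are out of scope.
* Entrainment classification is 1:1 only; n:m locking is reported as
  `not_entrained` rather than resolved.
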