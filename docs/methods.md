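# Methods

`pulsescreen` builds an in-silico study of whether common arterial diseases
can be detected by machine-learning classifiers from a handful of peripheral
pressure and flow-rate waveforms.  Everything is simulated: virtual subjects
are instances of a reduced human arterial network solved with a nonlinear 1D
pulse-wave model, disease is a parametric geometric perturbation, and the
classifiers see only truncated Fourier descriptions of the waveforms.

## 1. Forward model: 1D pulse-wave haemodynamics

Each vessel is a 1D compliant tube carrying cross-sectional area A(x,t) and
volumetric flow Q(x,t):

    dA/dt + dQ/dx = 0
    dQ/dt + d(alpha Q^2/A)/dx + (A/rho) dp/dx = - f Q/A - (zeta/2) Q|Q|/A

with the tube law `p = p_ext + (beta/A_d)(sqrt(A) - sqrt(A_d))`, reference
(zero-transmural-pressure) area A_d(x) and stiffness coefficient beta.
Defaults: blood density rho = 1.06 g/cm³, viscosity mu = 0.04 P, a power-law
axial velocity profile of order gamma = 9 giving the momentum correction
alpha = (gamma+2)/(gamma+1) = 1.1 and wall friction
f = 2 (gamma+2) pi mu / rho.

The last term is a distributed **expansion loss**: dynamic pressure is not
recovered where the reference lumen widens,
`zeta(x) = K * max(0, d ln A_d / dx)` with K = 1 by default.  Integrated
across a severe stenosis this reproduces the Borda–Carnot magnitude
`~ (rho/2) u_min^2 (1 - A_min/A_0)^2` of post-stenotic separation losses;
without it a 1D model recovers nearly all Bernoulli pressure downstream and
severe stenoses become almost haemodynamically silent.  For healthy tapered
vessels (A_d non-increasing) the term vanishes identically.

**Numerics.**  Explicit MacCormack predictor–corrector (forward/backward
flux differences) on per-vessel uniform grids; the pressure gradient is
evaluated from tube-law pressures at cell centres, which makes the scheme
well-balanced: a uniform-pressure network at rest stays exactly at rest for
arbitrary A_d(x).  The global time step is CFL-limited (default CFL 0.9 with
a 0.8 safety factor against the systolic wave-speed rise) and frozen per
cardiac cycle so each cycle lands on a uniform sample grid.  Boundary and
interface states use the Riemann invariants W = u ± 4c of the square-root
tube law, c = sqrt(beta sqrt(A) / (2 rho A_d)):

- **Inlet**: prescribed periodic flow plus the backward characteristic from
  the first interior cell (scalar Newton solve).
- **Junctions** (up to 3 children): conservation of mass and continuity of
  total pressure p + rho u²/2, together with the outgoing characteristics —
  a (m+1)-dimensional Newton solve with analytic Jacobian, converged to
  1e-10; the worst scaled mass defect over a run is reported
  (`WaveformSet.junction_residual`, typically ~1e-10).
- **Terminals**: three-element Windkessel (proximal resistance R1,
  compliance C, distal resistance R2) with a semi-implicit capacitor update;
  the vessel/Windkessel interface is a scalar Newton solve.

The network starts from a uniform pressure (default 70 mmHg; cohort
generation uses 95 mmHg, close to the working mean, to shorten the
transient) and runs until the cycle-to-cycle relative L∞ change, scaled per
site by pulse amplitude (floored at 1% of the signal scale so constant
signals converge), drops below 1e-3, with a configurable cycle budget.
Large compliant lesions (wide high-severity aneurysms) have filling time
constants of ~10 cycles, hence the cohort default budget of 80 cycles.
Convergence is first-order under grid refinement (the boundary treatment
dominates); the suite verifies observed order >= 1.

**Grid refinement for lesions.**  The minimum admissible lesion spans 10%
of its chain, so chain segments are gridded at chain-length/80 (>= 8 cells
across any lesion) whenever a lesion is present.  Crucially the *healthy
twin of a diseased patient is simulated on the identical grid*
(`refine_chain`): otherwise healthy and diseased waveforms would differ by
numerical resolution and classifiers could key on a solver artefact instead
of haemodynamics.

## 2. The packaged reduced network

A symmetric 29-segment tree (ascending aorta → arch with L/R common
carotids and L/R subclavian→brachial→radial; thoracic aorta → four
abdominal aortic segments → L/R iliac→external iliac→femoral×2→popliteal)
with six Windkessel outlets, shipped as `data/default_network.json` with
explicit units.  Parameter magnitudes (lengths, areas, wave speeds
~4.7–9 m/s, outlet impedances) are adapted from published 1D benchmark
models; abdominal aortic reference areas taper 1.76 → 1.09 cm².  Outlet
resistances distribute a 92 mL/s mean inflow (period 0.9 s, smoothed
half-sine systolic ejection) at ~95 mmHg mean pressure with R1 set to the
characteristic impedance where that is below half the total.  The network
hosts the four disease chains — common carotid (CA), subclavian (SA),
iliac–femoral–popliteal (PA), abdominal aorta (AA) — and six bilateral
measurement sites (carotid/brachial/radial pressure; carotid/brachial/
femoral flow), placed at segment midpoints since finer placement is not
specified by the study design.

## 3. Disease model

A lesion on a chain is a multiplicative cosine profile of the normalised
chain coordinate x_n (arc-length normalised across segment boundaries):
A_n = 1 outside [b, e] and

    A_n = (1 -/+ S/2) +/- (S/2) cos(2 pi (x_n - b)/(e - b)),  b <= x_n <= e

(upper signs: stenosis), i.e. continuous, symmetric, equal to 1 at both
edges, with extremum 1−S (stenosis) or 1+S (aneurysm) at the midpoint.
Parameters are drawn sequentially from uniform distributions — reference
location r ~ U(0.2, 0.8), start b ~ U(0.1, r−0.05), end e ~ U(r+0.05, 0.9)
(so lesions span at least 10% of the chain), severity S ~ U(0.5, 0.95) for
stenoses, U(7.13, 25.93) for abdominal aneurysms and U(3.0, 7.0) for the
low-severity AAA-L variant — and the side is chosen with equal probability
for the bilateral chains.  Each virtual patient carries exactly one lesion.

## 4. Virtual subjects and cohorts

A healthy subject is the reference network perturbed by global scale
factors: cardiac period T ~ U(0.7, 1.1) s; inflow amplitude, global area,
global stiffness, outlet resistance and outlet compliance each ~ U(0.8,
1.2); plus mild per-side area asymmetry ~ U(0.95, 1.05) (healthy left/right
haemodynamic differences of this order are commonly reported).  Subjects
are accepted only if the right brachial pressure is plausible (systolic in
[90, 180] mmHg, diastolic in [50, 100] mmHg); implausible draws are
rejected and redrawn, with an error once the attempt budget implies a
rejection rate far above the configured cap.  These bands are package
choices standing in for a population generator, not literature estimates.

Each diseased patient is the **twin** of a healthy subject: identical
subject parameters plus one sampled lesion, re-simulated on the matched
grid.  A solver failure resamples the lesion/subject (counted, capped at
5% of the cohort) so twin pairing and class balance stay exact.

**Dataset assembly** (per disease form): Step 1 — a random half of the
healthy subjects enters labelled healthy, and the diseased twins of the
*other* half enter labelled diseased, so no subject identity ever appears
with both labels; Step 2 — pooled, exactly 50/50 (for odd pools both halves
take floor(n/2), dropping one diseased twin at random, keeping the balance
exact); Step 3 — uniform random 2/3 train / 1/3 test split (floor on the
test size), or 50/25/25 train/validation/test when a validation set is
needed for early stopping.  "Fivefold validation" means five independent
Step-3 resplits of one fixed Step-2 pool, with metrics averaged across
folds — not disjoint-fold cross-validation, following the study design's
own description.

## 5. Features

Each single-cycle waveform (64 uniform samples) is projected onto a Fourier
series truncated at N = 5: u(t) = sum a_n sin(n w t) + b_n cos(n w t),
w = 2 pi / T.  The n = 0 sine term is identically zero, leaving 11
coefficients per waveform, ordered [b0, a1..a5, b1..b5]; a bilateral
measurement contributes 22 (right side first).  Discrete projection on the
uniform grid equals least squares there and is exact for signals
band-limited to N harmonics.  Feature columns follow the canonical
measurement order Q1, Q2, Q3, P1, P2, P3 and are stable across runs.
Features are Z-score standardised per column with the population (1/M)
variance convention; the transform is fitted on the training partition only
and applied unchanged to validation/test data (zero-variance training
columns are dropped with a warning).

## 6. Classifiers

Six methods behind one interface (scikit-learn implementations): random
forest (RF), gradient boosting (GB), Gaussian naive Bayes (NB), RBF-kernel
SVM with variance-scaled kernel width ("scale"), L2 logistic regression
(liblinear), and an MLP with logistic activations and equal-width hidden
layers.  Architecture grids: RF trees 10–400 step 10 × depth 20–200 step 10
(760 points); GB depth 2–20 × trees 10–100 step 10 (190); MLP neurons
10–200 step 10 × layers 1–6 (120).  These full grids are kept behind
`FULL_GRIDS` / the `--full-grids` flag; the default `DESK_GRIDS` are
thinned subsets for desk-scale runs.  Grid search maximises mean held-out
F1 across the five resplits; ties keep the first point in iteration order.

MLP early stopping: epoch-wise training on the 50/25/25 split; after each
epoch the validation log-loss is recorded, and training stops once more
than 75 epochs have run and the consecutive improvement falls below 1e-3
(cap 200 epochs; "iteration" is taken as an epoch).  The returned model is
the state at the stopping epoch, and train/validation loss traces are kept
for overfitting diagnostics.  Early stopping is applied to the MLP only.

## 7. Metrics and analyses

The diseased class is positive.  Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN); zero-denominator
cases return 0 with a degeneracy flag.  Metrics are computed per fold and
averaged (not pooled over an aggregate confusion matrix).

Analyses over the 63 non-empty subsets of the six bilateral measurements:
per-method records (method × combination × fold, failures recorded rather
than dropped); per-count mean/max/min F1 with argmax combinations;
histograms of fold-averaged F1 split by carotid-flow (Q1) inclusion (32
include, 31 exclude; bins of width 0.05 on [0.4, 1.0]); summed
split-improvement feature importance of a GB model per measurement (22
coefficients per bilateral block, normalised to 100%); per-combination F1
ratios of low-severity to high-severity aneurysm classification; and
unilateral (right/left/both) comparisons for carotid flow and radial
pressure at 11 features per unilateral site.

## 8. Problem sizes and what the synthetic study can show

Package defaults are desk-scale: cohorts of 150 twin pairs per disease form
(the acceptance script's size), test fixtures of 60 pairs, ~0.5–2 s per
simulated patient.  A Step-2 pool of 150 leaves only 100 training
patients — two orders of magnitude below a cluster-scale virtual patient
database — so:

- High-severity abdominal aneurysms (7–26× area) are detected almost
  perfectly even from a single unilateral carotid flow waveform, and the
  qualitative patterns (carotid-flow dominance, degradation at low
  severity away from saturated combinations) replicate.
- Mild stenoses (S near 0.5) are genuinely subtle — a 50% area reduction
  of a short carotid segment changes mean carotid flow by only a few per
  cent at rest — and with 100 training samples against ±20% inter-subject
  variability the stenosis scores plateau around F1 ≈ 0.8, below what a
  28k-subject database supports.  This is a data-size effect, not a
  failure of the forward model; the misclassified patients are
  overwhelmingly the low-severity ones.

The generator emulates inter-subject variability with seven global scale
factors; it does **not** emulate the dozens of per-segment parameters, age
structure, or measurement noise of a real population (measurement errors
are deliberately ignored, following the study design).  Passing tests on
this cohort therefore demonstrate the machinery and the direction of the
physiological effects, not clinical-grade accuracy estimates.

## 9. Other numerical choices

- Chain-coordinate boundary ties map to the downstream segment (chains are
  mapped proportionally to arc length).
- Reference areas taper linearly within a segment; the lesion multiplies
  the tapered profile.
- Time step, cells and all Newton tolerances are settings with the
  defaults above; junction children are limited to 3 (enough for any
  anatomical bifurcation/trifurcation here).
- All randomness flows from numpy `Generator`/`SeedSequence` objects;
  every pipeline artifact records its seed and config hash, and reruns are
  byte-identical.
- Pipeline tables are written with a fixed float format; stages resume
  from manifests and refuse to mix configs.

## 10. Known limitations

Rigid (elastic, not viscoelastic) walls; no curvature or 3D effects; the
reduced network lacks visceral/cerebral branches, so outlet flow fractions
are only loosely physiological; lesions are single, smooth and cosine-
shaped; subjects vary only through global scales; classifiers use the
study's fixed feature recipe (N = 5 Fourier) rather than learned features.
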