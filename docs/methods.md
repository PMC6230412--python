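# Methods

## Model

`fddlelm` classifies labeled feature vectors by an encode-then-classify
architecture.

**Encoding.**  Given training columns `A = [A_1, …, A_c]` (samples
grouped by class), Fisher discrimination dictionary learning finds a
class-structured dictionary `D = [D_1, …, D_c]` with unit-ℓ₂ atoms and a
coefficient matrix `X` minimizing

    J(D, X) = Σ_i r(A_i, D, X_i) + λ₁‖X‖₁ + λ₂ f(X),

with the discriminative fidelity
`r(A_i, D, X_i) = ‖A_i − D X_i‖²_F + ‖A_i − D_i X_i^i‖²_F +
Σ_{j≠i}‖D_j X_i^j‖²_F` (class i should be reconstructed well by the full
dictionary and by its own sub-dictionary, and badly by everyone else's)
and the Fisher penalty `f(X) = tr S_W(X) − tr S_B(X) + η‖X‖²_F` on the
codes.  The η-ridge keeps `f` convex in each class block; η defaults to 1.
The model's assumption is that class structure survives — indeed
sharpens — under sparse reconstruction: training proceeds on `B = D X`
rather than on `A`.

**Classification.**  A regularized extreme learning machine: hidden
parameters are drawn once, i.i.d. uniform on [−1, 1] (seeded, never
trained); the hidden map is `g(a_iᵀx + b_i)` with sigmoid `g` by default
(tanh and a Gaussian radial unit are available).  Output weights solve
`min ‖β‖² + C‖Hβ − Y‖²` in closed form through whichever Gram matrix
(m × m or N × N) is smaller; the two forms are algebraically identical and
the N = m boundary uses the dual.  `C` is chosen on {e⁻⁵, …, e⁵} by the
PRESS statistic — the exact leave-one-out MSE of a linear smoother,
`(y_j − ŷ_j)/(1 − hat_jj)` — with ties broken toward stronger
regularization.  Decisions are 1-based arg-max of the network scores, ties
to the lowest class index.

**Prediction.**  Test columns are scaled exactly as training columns were,
sparse-coded over the full learned dictionary by the ℓ₁-only objective
`min_x ‖a − Dx‖² + λ₁‖x‖₁` (labels are unknown at test time, so the
class-discriminative terms do not apply; an optional flag adds the η‖x‖²
ridge), reconstructed, and passed to the ELM.

**EEG front end.**  Epochs are cut to the 0.5–2.5 s post-cue window,
band-passed 8–30 Hz with a fifth-order Butterworth filter applied
zero-phase, and reduced by CSP: the generalized eigenproblem of the two
mean trace-normalized spatial covariances (shrinkage
`Σ ← (1−γ)Σ + γ·tr(Σ)/ch·I`, γ = 10⁻⁶, for conditioning), keeping 3
filter pairs from the ends of the eigenvalue spectrum.  Multi-class data
use one-vs-rest CSP with concatenated blocks.  Features are
`log(v_k / Σ v_k)` of the per-filter variances, normalized within each
block — invariant to global trial scaling.

## Optimization

The joint objective is minimized by alternating block minimization; every
step is non-increasing by construction, which the tests check to a
relative slack of 1e-8.

* **X step** (per class block): ISTA — proximal gradient on the smooth
  part (fidelity plus λ₂-weighted Fisher penalty, quadratic in `X_i`) with
  soft-thresholding at λ₁·step.  The step starts at the inverse of a
  spectral curvature bound and backtracks by halving until the quadratic
  majorization holds, so descent is guaranteed even where the −tr S_B term
  contributes curvature.  The Fisher gradient accounts for the dependence
  of the class and global means on the block:
  `2(x_k − m_i) − 2(m_i − m) + 2η x_k` per column.
  Default 50 inner iterations, stalling at a relative decrease of 1e-10.
* **D step** (per atom): for a fixed coefficient row `z`, `‖d z‖²_F` is
  constant over unit atoms, so the constrained minimizer is the normalized
  residual correlation `d = E zᵀ/‖E zᵀ‖` — an exact update.  Atoms whose
  coefficient row is entirely zero contribute nothing; they are re-seeded
  from the currently worst-reconstructed sample of their class, which
  leaves the objective unchanged.
* **Outer loop**: starts from a seeded sample of class columns
  (`svd` initialization available), coefficients from zero; stops when the
  relative objective change over a full iteration falls below 1e-4
  (default) or after 30 iterations.
* **Test-time coder**: FISTA (Nesterov momentum with gradient restart) at
  the fixed safe step 1/L, stopping when the lasso KKT residual drops
  below 1e-6; deterministic, and within 1e-6 of an exhaustive
  sign-enumeration oracle on every tested instance.  Exactly-threshold
  magnitudes soft-threshold to 0; there is no randomness anywhere in the
  encoder beyond the seeded initialization.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ₁ | grid {0.001, 0.005, 0.01, 0.05, 0.1} | code sparsity weight |
| λ₂ | same grid | Fisher discrimination weight |
| η | 1 | convexifying ridge inside f(X) |
| atoms/class | min(min nᵢ, 30) | sub-dictionary width |
| m | grid {100, …, 1500} (generic), {10, …, 100} (EEG) | hidden nodes |
| C | PRESS-selected on {e⁻⁵, …, e⁵} | ridge strength |
| band, order | 8–30 Hz, 5 | Butterworth band-pass (EEG) |
| segment | 0.5–2.5 s post-cue | analysis window (EEG) |
| CSP pairs | 3 | filters kept per spectrum end |

(λ₁, λ₂, m) are selected by stratified 5-fold cross-validation on the
training set, ties toward smaller m, then smaller λ₁, then λ₂; evaluation
repeats fit/predict 10 times with consecutive seeds and reports mean ±
sample standard deviation of test accuracy.

Two deliberate design choices:

* **Sample normalization.**  Columns are scaled to unit ℓ₂ norm at dataset
  construction (standard in discriminative dictionary learning); a flag
  disables it, and zero-norm columns are rejected.
* **ELM input scaling.**  `elm_train` divides each feature by its training
  max-abs before the hidden layer and stores the divisor on the model.
  With uniform [−1, 1] hidden weights the sigmoid is informative only for
  pre-activations of order one; without this step large-scale features
  saturate the layer and the random-feature expansion loses resolution.

## Zero-phase filtering

Band-pass filtering is forward-backward (the pipeline is offline, so
non-causality is harmless), which squares the magnitude response and
doubles the effective order.  It is applied per second-order section with
Gustafsson initial conditions rather than edge padding: Gustafsson's
method makes forward-then-backward equal backward-then-forward, so
filtering commutes with time reversal to machine precision, whereas
pad-based filtfilt leaves visible edge asymmetries.

## Synthetic data

The generators are pure functions of their spec, including the seed.

* **Gaussian clusters**: class i's mean sits at `separation·sd·i` along
  one seeded random unit direction; isotropic noise.  Because the class
  means are collinear and differ radially, this generator constructs its
  dataset *without* unit-norm scaling — projecting the samples onto the
  sphere would erase precisely the separation the spec of the fixture
  promises.
* **Motor-imagery EEG**: broadband Gaussian noise on all channels plus a
  band-limited (8–30 Hz by default) oscillatory component, synthesized by
  pushing white noise through the front end's own Butterworth filter
  (padded by a second per side and cropped, so edge transients do not
  leak broadband power) and rescaled to exact per-channel variance.  On a
  class's active channels the oscillation variance is `modulation_depth`
  times baseline — exactly the variance-ratio structure CSP diagonalizes.

What they do **not** emulate: ocular/muscular artifacts, nonstationarity,
volume-conduction mixing, inter-subject variability, label noise, or
class-conditional covariance structure beyond planted variance ratios.
Passing the recovery studies therefore demonstrates correctness of the
machinery on data satisfying each stage's assumptions, not performance on
real recordings.

## Verification studies and problem sizes

The acceptance script and test suite use:

* solver identities on instances up to 20 × 15 (50–100 random draws);
* descent diagnostics on 20 Gaussian fixtures (p = 8, 15/class, 4
  atoms/class, 5 outer iterations);
* Gaussian recovery: p = 10, 4σ separation, 120/class split 1:1,
  30 atoms/class, λ₁ = λ₂ = 0.01, m = 500, 10 seeds;
* EEG recovery: 60 trials/class, 10 channels, 250 Hz, 3 s epochs,
  modulation depth 3, 3 CSP pairs, 15 atoms/class, m = 50, 10 seeds.

These sizes keep a full verification run around a minute on one CPU while
leaving the statistical conclusions stable across seeds.

## Known limitations

* The Fisher penalty's −tr S_B term makes the smooth block objective only
  conditionally convex; η = 1 is relied upon (and checked numerically)
  for positive semidefiniteness rather than proven per instance.
* The test-time coder's FISTA stalls near KKT residuals of ~10⁻⁶–10⁻⁷ on
  heavily overcomplete dictionaries (degenerate lasso solutions); a
  warning is emitted if the tolerance is not met and the best iterate is
  returned.  This is far below any level that affects classification.
* No native readers for EEG acquisition formats; epochs enter as plain
  arrays or the package's binary container with a JSON sidecar.
* Dictionary learning cost grows with c·atoms²; the implementation is
  dense and single-threaded.
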