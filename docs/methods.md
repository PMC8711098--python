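# Methods

## Model and assumptions

The regressor is a two-stage RBF network.  The unsupervised stage z-scores
the predictors (sample sd, ddof=1; statistics always come from the training
rows and are reapplied to held-out rows), selects `p` centers by k-means
(k-means++ initialization, 10 restarts, fixed seed) and assigns all bases
one shared Gaussian width `σ = σ_max/√(2p)`, with `σ_max` the largest
pairwise center distance.  The supervised stage solves the linear readout;
the plain baseline uses the unpenalized normal equations, the regularized
model the alternating scheme described in the README.

Assumptions worth making explicit:

* **Local smoothness in predictor space.**  Gaussian bumps and graph
  penalties both presume that patients close in (standardized) predictor
  space have similar dry weight.
* **Transductive graphs, inductive prediction.**  The four similarity
  graphs are built on training rows only and act purely as a training-time
  penalty; prediction is `Φ_new W`, so test rows never influence the graphs.
* **No intercept.**  The readout is a pure linear combination of basis
  activations.  The target's mean level is representable only where basis
  coverage is good; see *Limitations*.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| `p` | 140 | 2 ≤ p ≤ N | hidden nodes = k-means clusters; the clinical operating point |
| `tmax` | 10 | ≥ 1 | alternating iterations; the objective plateaus well before 10 on every fixture we generate |
| `lambda1` | 2⁻³ | ≥ 0 | weight of the fused-Laplacian smoothness penalty |
| `lambda2` | 2⁻³ | ≥ 0 | weight of the L2,1 row-sparsity penalty |
| `rho` | 2 | > 1 | simplex smoothing exponent; ρ=2 makes η_v ∝ 1/h_v, the simplest admissible case, and ρ→∞ flattens η toward uniform |
| `gamma` | 1 | > 0 | kernel constant of all four similarity kernels |
| `kernels` | (1,2,3,4) | subset | Gaussian, cosine, polynomial, sigmoid views |
| `eps_irls` | 1e-8 | — | floor on row norms in the IRLS diagonal `G_jj = 1/(2‖W_j‖)` |
| `eps_trace` | 1e-12 | — | floor on the η-step smoothness traces |

The polynomial and sigmoid kernels are implemented exactly as
`(−γ xᵀx′ + 0.1)²` and `tanh(−γ xᵀx′ + 0.1)` — decreasing in the inner
product, which is unusual for kernels of this family, but the orientation
is part of the method definition and is kept verbatim.

## Numerical choices

* **Signed-graph degrees.**  The cosine and sigmoid kernels produce
  mixed-sign similarities on z-scored data, and their plain row sums can
  vanish or go negative; normalizing by them makes `D^{−1/2}` explode and
  the W-step system indefinite.  The package therefore uses the
  signed-graph degree `D_ii = Σ_j |S_ij|`, which coincides with the plain
  row sum for the nonnegative kernels and makes *every* view Laplacian
  positive semidefinite with normalized spectrum in [0, 2].  This is the
  hypothesis under which the alternating scheme is provably monotone
  (`ΦᵀΦ + λ₁ΦᵀL*Φ + λ₂G` is then positive definite) and the η-step traces
  are nonnegative.  Similarities themselves are never clamped.
* **Monotonicity.**  The W-step minimizes the convex surrogate in which
  `G` majorizes the row norms (`‖w‖ ≤ ‖w‖²/(2‖w₀‖) + ‖w₀‖/2`), and the
  η-step is the exact constrained minimizer of the weighted-trace
  objective, so the full objective never increases across a
  G → W → η cycle; the test suite asserts this on every run at relative
  tolerance 1e-9.
* **Linear solves.**  All symmetric systems go through a LAPACK symmetric
  solve, never explicit inversion.  The plain baseline adds no ridge — a
  rank-deficient `ΦᵀΦ` is an error advising a smaller `p` — while the
  solver's W-step retries once with `1e-10·I` jitter (logged) before
  failing.
* **Degenerate guards.**  Zero readout rows are floored at `eps_irls`
  inside `G`; non-positive traces at `eps_trace` inside the η-step (if all
  views clamp, η falls back to uniform with a warning); η is floored at
  1e-15 and renormalized so it stays strictly inside the simplex even when
  trace ratios exceed float precision; degrees at `eps_deg = 1e-8` against
  isolated rows.  Constant predictor columns and missing values are
  rejected with the offending column/row named.
* **Ties and determinism.**  k-means uses a fixed seed and 10 restarts;
  fold shuffling uses the CV seed; the whole pipeline is bit-reproducible
  for fixed (data, hyperparameters, seed), and every written artifact
  embeds the package version, a config hash and the seed.
* **Bland–Altman conventions.**  Differences are `pred − ref` in target
  units (kg); sd uses ddof=1; limits and CI use the conventional 1.96
  multiplier; points exactly on a limit count as inside; the acceptability
  threshold is `⌈0.05·N⌉` (24 at N=476).  Folded-ECDP reporting is reduced
  to the min/median/max of the signed errors.

## Gender coding

Gender is encoded female=1, male=0.  With this orientation the gender
column correlates *negatively* with dry weight (females are lighter), which
matches the sign convention of the published cohort summary.  Since
predictors are z-scored, flipping the coding would only flip the sign of
one standardized column and leaves the model's predictions unchanged.

## The synthetic cohort generator

The clinical dataset is private, so `generate_cohort` draws stand-in
cohorts that reproduce its published structure:

* Continuous predictors come from normals truncated at invented physiologic
  floors (age ≥ 18 y, BMI ≥ 12, HR ≥ 30/min, pressures ≥ 40 mmHg, vintage
  ≥ 0.25 y).  The parent (loc, scale) of each is moment-matched numerically
  so the *truncated* law has exactly the published mean ± sd — naive
  truncation would bias the vintage sd ~8% low.
* Gender is Bernoulli(164/476 female) and females get a lower BMI mean
  inside a mixture whose overall mean/sd still match the published
  22.96 ± 2.95.  This coupling is deliberate: the published BMI and gender
  correlations with dry weight satisfy 0.9558² + 0.4489² > 1, which no
  independent-predictor design can reproduce; routing part of the gender
  effect through BMI is the simplest realistic mechanism that can.
* Dry weight is `BMI · (3.10 − 0.13·female)` — BMI times a gender-dependent
  height-squared proxy, mirroring the identity weight = BMI·height² — plus
  small centered contributions of the remaining vitals and N(0, 1.3²) kg
  noise, the scale of the irreducible error reported for this problem.
  Coefficients were calibrated once by simulation at n = 200,000 and are
  frozen; at that size the generator lands corr(BMI, DW) = 0.937 and
  corr(gender, DW) = −0.450 with every minor correlation matching the
  published sign at |r| ≤ 0.25.

**What the emulation does not capture.**  Only marginals and the
correlation pattern are emulated; the joint geometry of the real cohort is
unknown.  In particular the synthetic predictor cloud is intrinsically
~7-dimensional, whereas the performance reported on the real data implies
an effectively very low-dimensional cohort (BMI alone carries r = 0.956).
This matters because the width rule is dimension-sensitive: nearest-center
spacing shrinks like `p^{−1/D}` while `σ` shrinks like `p^{−1/2}`, so for
intrinsic dimension D > 2 coverage *worsens* as `p` grows.  At the clinical
operating point `p = 140` on the synthetic cohort, many patients activate
no basis function, both the plain and the regularized model degenerate (the
70 kg target offset is unrepresentable without an intercept), and their
cross-validated RMSEs agree to ~0.1%.  Passing solver tests on these
cohorts therefore validates the optimization identities, the evaluation
protocol and the generator's moments — not clinical-grade predictive
accuracy.  The regularization benefit itself is real and is demonstrated
where the method operates in its intended regime: on low-dimensional smooth
fixtures in an overfitting regime (n = 60, d = 3, p = 30, noise sd 0.5) the
regularized model beats the plain readout in 9 of 10 seeds.

`generate_multiview_fixture` provides those fixtures: predictors uniform on
[−1,1]^d and a smooth two-Gaussian-bump target plus optional noise, sized
for sub-second solver tests (n = 60, d = 3 by default).

## Problem sizes used in the test battery

Solver identities (reduction, monotonicity, oracle equivalence of the W and
η steps) run on the n = 60 fixtures; the study-scale comparison runs ten
476-patient synthetic cohorts at the clinical defaults; generator fidelity
is checked at n = 50,000.

## Known limitations

* No intercept and a fixed width rule: on predictors of intrinsic
  dimension ≳ 3 the basis under-covers and accuracy collapses (see above);
  practitioners applying this to other tabular problems should check basis
  coverage (e.g., row maxima of Φ) before trusting the output.
* Dense N×N graphs per view: memory and time are O(VN²); the package
  targets cohort sizes in the hundreds, not tens of thousands.
* The CV refits η per fold; with few informative views the per-fold η can
  vary noticeably between folds.
* The generator is a moment emulator, not a clinical simulator: no
  comorbidity structure, no longitudinal dynamics, no measurement error
  model beyond the additive target noise.
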