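# Methods

`pkgan` is a proof-of-concept pipeline for augmenting a small population
pharmacokinetic (PopPK) study with artificial patients produced by a
generative adversarial network, and for quantifying what the augmentation
does to non-linear mixed-effects (NLME) parameter estimates. Everything is
simulated from a known ground truth, so every downstream claim can be checked
against the generating parameters.

## Study simulation (`pkgan.popsim`)

The virtual study enrols 20 adults (10 female, 10 male). Ages are uniform on
18–65 years. Weight is normal with sex-specific means 64 kg (F) and 85 kg (M),
SD 10 kg; height is normal with means 164 cm (F) and 179 cm (M), SD 7 cm.
Each patient receives a single extravascular 300 mg dose of a hypothetical
drug following a one-compartment model with first-order absorption and linear
elimination:

    C(t) = D·ka / (V·(ka − ke)) · (e^{−ke·t} − e^{−ka·t}),   ke = Cl/V,

with bioavailability fixed at 1, so V and Cl are apparent quantities. The
closed form is evaluated as `D·ka/V · t · e^{−k_slow·t} · φ(|ka−ke|·t)` with
`φ(x) = (1−e^{−x})/x` (series for |x| < 1e−4), which is exact in the
ka → ke limit, overflow-free whichever rate dominates, and analytic — hence
safe for complex-step differentiation.

Population parameters (ground truth): ka 0.5 h⁻¹, V 14 L, Cl 5 L/h; diagonal
log-normal inter-individual variability with SDs ω_ka 0.2, ω_V 0.3, ω_Cl 0.2;
allometric weight effect on V only, `V_i = V·(WT/w_ref)^0.75·e^{η_V}`;
combined residual error `y = C + (a + b·C)·ε` with a 0.2 mg/L, b 0.1.
Observations are drawn at 0.5, 1, 1.5, 2, 4, 6, 8 and 12 h and censored below
the LLOQ of 0.5 mg/L (dropped before fitting, flagged when building the
generative-model table).

Choices where a convention had to be fixed:

- **w_ref = 70 kg** (configurable). The allometric exponent is
  scale-equivariant only through V, so simulation and fitting must share the
  same reference weight; the package uses one `w_ref` throughout.
- **Bioavailability = 1**: a single extravascular dose cannot identify F.
- **Negative simulated observations are floored at 0** before censoring;
  they fall below the LLOQ anyway, so this only affects the `flag` mode used
  for the feature table.
- Age and height are carried as features of the generative model but are not
  covariates of the structural model; only weight enters.

## Feature encoding (`pkgan.encode`)

The generative model consumes one wide row per patient with a fixed column
order: one-hot sex (SEX_F, SEX_M), AGE, WT, HT, DOSE, and the eight
concentrations C_0.5 … C_12. BLQ entries are imputed at LLOQ/2 = 0.25 mg/L so
rows are complete (the imputation constant is configurable; the published
handling of BLQ values in the training table is not documented anywhere we
could rely on). All columns are min-max scaled to [−1, 1] per column;
constant columns (DOSE) map to 0 and are restored exactly on inversion.
Generator outputs are *not* clipped to [−1, 1] — the output layer is linear —
so the inverse transform extrapolates linearly, and physical-validity checks
(positive weight/height/age, at least one quantifiable concentration) reject
pathological rows instead. Sex is decoded by argmax with exact ties resolved
to female under a logged warning.

## Generative model (`pkgan.wgan`)

A Wasserstein GAN with gradient penalty. Both sub-networks have two hidden
leaky-ReLU layers (slope 0.2) and linear outputs; the critic carries dropout
(rate 0.3) on both hidden layers. Widths are 64/64 (generator, latent
dimension 16) and 64/32 (critic) — depths follow the study design, widths are
sized to the 20 × 14 training table. Training is full batch: one epoch is
five critic updates followed by one generator update, with the optimistic
Adam variant (lr 1e−4, β₁ 0.5, β₂ 0.9 — the momentum decays follow
adversarial-training convention) for both networks. The critic loss is

    mean f(G(z)) − mean f(x) + λ · mean (‖∇_x̂ f(x̂)‖₂ − 1)²,

with λ = 10 and x̂ = u·x + (1−u)·G(z), u ~ U(0,1) per row; the generator loss
is −mean f(G(z)). The full study setting is 150,000 epochs; the tests and the
acceptance script train 20,000-epoch runs, which already pass the
distributional checks on this 20-row problem.

The networks and their gradients are written out in numpy. The gradient
penalty needs the derivative of the input-gradient norm with respect to the
weights; for a leaky-ReLU network the activation pattern is piecewise
constant, so that double backpropagation has an exact closed form (activation
masks treated as constants, valid almost everywhere). All gradients are
verified against central finite differences in the test suite.

Dropout is active during critic updates (one mask set per update, shared by
the real, fake and interpolated batches so a single, fixed network is
differentiated) and inactive when the generator queries the critic.

A convergence monitor runs after training: losses must be finite, a 50-row
probe must contain ≥ 90% distinct rows (mode-collapse guard), and the
decoded mean concentration profile must be grossly unimodal (rise to a single
peak then fall, wiggles up to 25% of the range tolerated). Failing runs are
flagged (`converged_ = False`, CLI exit code 3), not silently accepted.

## Diverse subset selection (`pkgan.select`)

From a 200-row candidate pool, subsets are chosen by greedy farthest-point
(max-min) selection on Euclidean distances over all scaled columns. The
first pick is the row farthest from the pool centroid (deterministic and
spread-promoting; the greedy seed is otherwise arbitrary); each later pick
maximizes the minimum distance to the already-selected set, ties broken
toward the lowest index. Greedy farthest-point is a 2-approximation of the
exact max-min objective; the tests check this against exhaustive enumeration
on small pools.

## Distributional similarity (`pkgan.mmdtest`)

Original and artificial patients are compared with a two-sample maximum mean
discrepancy test, Gaussian RBF kernel `k(x,y) = exp(−‖x−y‖²/(2σ²))` with
σ = 0.1 (this bandwidth convention is the common one; with the kernel this
narrow the test is mainly sensitive to whether the artificial sample
reproduces the near-neighbour structure of the originals). The default
statistic is the biased V-statistic, computed on the scaled concentration
columns; the unbiased U-statistic and full-row features are available via
flags. The p-value is a permutation p, `(1 + #{perm ≥ obs})/(1 + B)` with
B = 1000 by default, and the permutation stream is drawn over a canonically
sorted pooling of the two samples so the result is invariant to argument
order. Permutation tests are exact by construction, which the null
calibration test confirms empirically on this pipeline's features.

## NLME estimation (`pkgan.nlme`)

The estimator maximizes a Laplace-approximate marginal likelihood. Fixing
notation per subject i with random effects η = (η_ka, η_V, η_Cl):

1. **Inner problem** — the penalized deviance h(η) = Σ_j [log σ_ij +
   ½((y_ij − C_ij)/σ_ij)²] + ½ηᵀΩ⁻¹η, σ_ij = a + b·C_ij, is minimized by a
   damped Newton iteration with a Gauss-Newton (expected-information)
   Hessian, which is positive definite by construction. Concentration
   sensitivities are analytic; steps are capped in norm (trust region 4 on
   the log scale) so extreme outer parameters cannot overflow the
   exponentials. The solver runs per subject in a compiled numba kernel; a
   vectorized numpy implementation using complex-step Jacobians is retained
   as a reference engine and the two are cross-checked to ~1e−9 in the tests.
2. **Laplace term** — at the mode, −log L_i = h(η̂) + ½·n_i·log 2π +
   Σ log ω + ½ log|H(η̂)|. The log-determinant uses the *exact* Hessian
   (complex-step of the analytic gradient). Away from a true local minimum
   the data part of the exact Hessian can be indefinite, so its eigenvalues
   are clamped at zero before the prior precision diag(1/ω²) is added back:
   the clamp is continuous in the parameters (no branch jumps that would
   derail outer line searches) and inactive wherever the data part is
   positive semi-definite. Against a high-accuracy quadrature oracle on a
   one-dimensional random-effect toy this Laplace value agrees to ~0.01%.
3. **Outer problem** — L-BFGS-B over log-transformed positive parameters
   (the weight exponent is unconstrained), finite-difference gradients.
   The inner warm start is frozen between optimizer iterations and refreshed
   once per accepted iterate, so the objective seen by the finite
   differences is deterministic. Multi-start (default 5; jitter log-normal
   with 20% CV, seeded) guards against local optima — a degenerate
   "flat-line" attractor (C ≈ 0, everything absorbed into the error model)
   exists for poorly informed datasets. Finite-difference noise can abort a
   quasi-Newton line search at a non-stationary point, so every start is
   checked by its projected gradient (magnitudes ~1 at genuine optima versus
   ~100 at stalls); a flagged start is rescued with a derivative-free
   Nelder-Mead pass from the stall point followed by an L-BFGS-B polish.
   Initial values are deliberately neutral (ka 1.0, V 10, Cl 3, β 0,
   ω 0.3, a 0.5, b 0.1), not the ground truth.

Random effects are diagonal (per-parameter IIV only). BLQ rows are excluded
from the likelihood rather than modelled with a censored term; both follow
the study design being emulated. An ω fixed at 0 removes that random effect
from the integral exactly, which is how the degenerate limits are tested.

**Bootstrap** — subjects are resampled with replacement to the original
count; each replicate is a single-start refit initialized at the full-data
estimate, with the resampling multiplicities entering as subject weights (so
a replicate costs one weighted fit regardless of duplication). Replicates
that fail to converge are dropped and counted; more than 20% failures flags
the summary. Reported intervals are 2.5/50/97.5 percentiles.

**Dataset mixes** — original (20/0), artificial (0/60), combined-low
(20/10), combined-equal (20/20), combined-high (20/40); artificial subjects
enter in max-min selection order and ids are re-keyed per mix.

**VPC** — the fitted model simulates the observed design n_sim times
(default 500); the table reports observed 10/50/90th percentiles per time
point against the median and 95% band of the simulated percentiles.

## What the synthetic data does and does not emulate

The generator is trained on rich, noise-free-in-design data: every patient
has all eight samples at exact nominal times, one dose level, no missing
covariates, no model misspecification (the fitted structural model is the
generating one). Passing tests therefore demonstrate internal consistency
of the machinery — estimation recovers the generating parameters, the
generative model reproduces the training distribution — and the
augmentation checks probe whether adding artificial patients sharpens the
weakly identified weight exponent. That effect reproduces across pipeline
seeds at the scaled-down settings, but it is a stochastic comparison — the
bootstrap interval widths respond to the candidate-pool draw and the
training length — and it needs well-converged fits: a stalled optimizer run
inflates replicate scatter and can mask the narrowing entirely. None of
this says anything about sparse or irregular sampling, wrong structural
models, or real-data covariate structure. Artificial patients are interpolations of 20 originals; the
narrowing of bootstrap intervals under augmentation is a sample-size
artefact, not new information, and the package is meant for exploring that
effect, not for confirmatory analysis.

## Problem sizes used by the tests and the acceptance script

Generator trainings in the automated runs use 20,000 epochs (the full study
setting of 150,000 is the `WGANGP` default); parameter-recovery checks use
300 subjects with 2 optimizer starts and medians over 5 seeds; bootstrap
comparisons use 100 replicates (the study's validation setting of 200 is the
`bootstrap` default). These sizes are the package's own choices for its
automated checks and already reproduce the qualitative results; all of them
are plain arguments that can be turned up.

## Known limitations

- Laplace (not SAEM/FOCE-I) marginal likelihood; on rich designs like this
  one the approximation error is far below sampling noise, but very sparse
  designs would deserve a quadrature check.
- The residual-error bound set allows b up to 5; jointly weak (a, b) can
  trade off against each other at n = 20, mirroring the additive/proportional
  trade-off visible in the original analysis.
- The MMD bandwidth convention (σ in `exp(−d²/2σ²)`) and the feature set
  (concentration columns) are choices; with σ = 0.1 the kernel is narrow and
  the absolute MMD² value is dominated by the diagonal terms of the biased
  estimator, so its magnitude should be compared across runs rather than
  across conventions.
- Single dose, one compartment, weight-on-V only; no inter-occasion
  variability, no correlated random effects, no covariate search.
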