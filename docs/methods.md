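# Methods

## Models

All three models describe a concatenated (time × regions) matrix `D` of
zero-mean (per-session standardised) signals as switching between K discrete
states, each state a distribution over region space.

**HMM-PCA.** State k emits `d_t ~ N(0, C_k)` with `C_k = W_k W_k' + σ²_k I`,
`W_k ∈ R^{n×p}`, `1 ≤ p < n`. The state sequence is an order-1 Markov chain
with transition matrix Θ and initial distribution π; π applies afresh at
every session start, so sessions are conditionally independent given the
parameters. The model is fitted by maximum-likelihood EM:

1. *E-step.* Per-state log-densities are computed through the p×p core
   `M_k = σ²_k I + W_k'W_k`, using `log|C_k| = (n−p) log σ²_k + log|M_k|`
   and `C_k⁻¹ = (I − W_k M_k⁻¹ W_k')/σ²_k`; forward–backward recursions then
   give the posteriors γ_tk, the aggregated expected transition counts ξ,
   and the log-evidence.
2. *M-step.* With `S_k` the γ-weighted (uncentred) sample covariance, the
   coupled updates
   `Ŵ_k = S_k W_k (σ²_k I + M_k⁻¹ W_k'S_k W_k)⁻¹` and
   `σ̂²_k = tr(S_k − S_k W_k M_k⁻¹ Ŵ_k')/n` are applied once per iteration,
   both using the pre-update `M_k`; Θ rows are normalised expected counts
   and π is the mean posterior over session starts.

Latent-factor posterior moments (`<y> = d W M⁻¹`,
`<y'y> = σ² M⁻¹ + <y>'<y>`) are exposed for diagnostic use; the M-step
itself only needs `S_k`.

**Mix-PCA** uses the same emissions with exchangeable time points:
γ_tk ∝ π_k N(d_t; 0, C_k), weights update as mean posteriors. An HMM whose
transition rows are all equal to w is exactly this mixture with weights w
(tested), so the mixture-of-Gaussians variant is likewise the equal-rows
special case of the Gaussian HMM and gets no separate code path.

**HMM-Gaussian** emits `d_t ~ N(0, Σ_k)` with full covariances, and is
conventionally run on a PCA projection of the data (the two-step pipeline);
the projection is recorded on the fitted model so held-out sessions are
reduced with the *training* loadings.

## Why one step matters: invariance structure

Gaussian-state inference is invariant to per-channel rescaling (Σ_k absorbs
any diagonal transform) but not to rotations — in particular not to a PCA
rotation, even a lossless full-rank one. PCA ranks directions by variance,
the HMM then ignores those variances, so projecting first biases the
estimation towards low-order components. The package quantifies this with:

- **PCA concentration**: the mean cumulative explained-variance fraction
  over the first n−1 components. Averaging over n−1 rather than n components
  makes the limits exact: 0.5 for uncorrelated equal-variance regions
  (cumulative fraction j/n) and 1.0 for rank-one data. Averaging over all n
  would give (n+1)/2n ≠ 0.5 in the uncorrelated case.
- **PCA distortion**: one minus the mean correlation between matched state
  time courses inferred on the original data vs its PCA projection. Courses
  are matched on γ correlations (not FC similarity) because the two runs
  live in different data representations; values up to 2 are possible when
  matched courses anticorrelate.
- The **eigenvalue-randomisation probe**: rescaling each principal
  component's scores by a random positive factor changes the data's
  covariance genuinely; a sound estimator should react. The two-step
  baseline is blind to it (score rescaling is channel scaling in PC space),
  HMM-PCA is not.

## Fitting defaults and their rationale

| parameter | default | notes |
|---|---|---|
| `n_restarts` | 5 | random EM restarts; best final log-evidence wins |
| `max_iterations` | 500 | per restart |
| `relative_tolerance` | 1e-5 | stop when the relative log-evidence change falls below this |
| `standardize` | on | per-session, per-column z-scoring before fitting |
| `noise_tying` | off | per-state σ²_k (the emission definition); on ties σ² across states as the occupancy-weighted mean of the per-state updates |
| `dead_state_threshold` | 1e-3 | occupancy fraction below which a state is flagged "obliterated" |
| σ² floor | 1e-8 × mean data variance | prevents likelihood blow-up on near-rank-deficient data |
| `ridge` (Gaussian states) | 1e-8 | **diagonal-proportional**: `S += ridge·diag(diag(S))` |

Initialisation draws per-time-point responsibilities from a symmetric
Dirichlet(α=2), smooths them along time with a width-10 moving average
within each session, renormalises, and takes one M-step (closed-form PPCA of
the weighted covariances for the PCA models; the weighted covariances
themselves for the Gaussian model). This is stateless and reproducible from
the seed; restart r uses the r-th spawn of the seed sequence. Passing
`initial_gamma` fixes the initialisation exactly, which is what the
invariance experiments require.

Noise tying exists because the per-state emission definition and the
common-error-variance view of the model's invariance analysis are both
defensible readings; the default follows the emission equations, and the
tied variant is one flag away.

The Gaussian-state ridge is proportional to the covariance diagonal rather
than isotropic: a diagonal ridge transforms exactly as the covariance under
per-channel rescaling, so regularisation never breaks the scale-invariance
that the model family is supposed to have (an isotropic ridge, even at
1e-8, seeds a divergence that EM amplifies over iterations).

Dead states are flagged, never removed or re-seeded: degenerate solutions
(accuracy ≈ 0.5 in two-state problems) are treated as observable outcomes
of the inference, not failures to hide.

## Numerical choices

- Forward–backward runs entirely in log space (numba-compiled), so it
  cannot underflow at any T or any spread of log-likelihoods, including
  −inf entries; per-session evidences are summed. Equality with brute-force
  path enumeration is tested to 1e-10 on small instances.
- EM monotonicity of the log-evidence trace is asserted to a 1e-6 relative
  tolerance across all three models.
- `ppca_closed_form` (eigendecomposition solution: σ² the mean trailing
  eigenvalue, loadings the leading eigenvectors scaled by √(λ_j − σ²))
  serves as an independent fixed-point oracle for the coupled update and as
  the exact solution a K=1 EM fit must reach.
- Loadings are reported as-is; W_k is identifiable only up to a p×p
  rotation, so all state comparisons use implied covariances.

## Synthetic designs

- **Scenario 1** (`generate_scenario1`): latents with standard deviations
  (2.0, 1.5) for p₀=2 or (2.0, 1.5, 1.0) for p₀=3 projected through
  `A + A_1` (state 1) or `A + A_2` (state 2), `A, A_1, A_2` standard
  Gaussian n×p₀, plus isotropic noise of sd 0.001; 10 sessions × 1000 time
  points, n = 10 regions, and a sticky two-state chain whose stay
  probability 0.9615 is 25× the switch probability (mean dwell ≈ 26 time
  points).
- **Scenario 2** (`generate_scenario2`): state covariances share the base
  covariance's first eigenvector (the time-invariant FC component), carry
  different entry-permutations of eigenvectors 2..p₀ (the time-varying
  components), and zero the rest.
- **Multistate** (`generate_multistate`): six 100-region states; each
  permutes the entries of a random set of base eigenvectors whose cumulative
  variance share stays ≤ ε (0.1 hard / 0.2 easy), keeping the others — so
  every state is full-rank with 100·99/2 = 4950 free FC parameters, 29700
  across six states. Each subject is one session; session-initial states
  are uniform.

Two choices the designs leave open, decided here: (i) the base covariance is
a synthetic stand-in `C = BB' + diag jitter` with B an n×(n/5) Gaussian
factor matrix, which reproduces the concentrated spectrum of parcellated
fMRI without any external data; (ii) permuting an eigenvector's entries
breaks orthonormality, so permuted columns are re-orthogonalised by
Gram–Schmidt against the preceding columns (norms preserved) before the
covariance is reassembled — this keeps the stated eigenvalue spectrum exact.

What these generators do **not** emulate: haemodynamic autocorrelation,
non-Gaussian and nonstationary artefacts, subject-level parameter
variability, and measurement at realistic fMRI SNR. Passing recovery tests
therefore demonstrates correctness of the inference under the model family's
own assumptions (plus controlled misspecification in the eigenvalue
experiments), not performance on real scans.

## Evaluation conventions

- `permutation_accuracy` hard-assigns by argmax and corrects labels
  exhaustively (K=2) or by the Hungarian algorithm on the agreement matrix.
- `lsq_prediction_error` regresses each true course on all estimated ones
  plus an intercept and reports residual variance normalised by the truth's
  total centred variance (0 perfect, 1 uninformative); the raw residual sum
  is returned alongside. The multivariate-with-intercept form makes the
  metric invariant to any invertible linear transform (hence any
  relabelling) of the estimates.
- `match_states` correlates Fisher-z off-diagonal correlation vectors and
  matches with the Hungarian algorithm.
- `cv_likelihood_grid` partitions whole sessions into folds (seeded
  shuffle, 2 folds by default); the two-step baseline refits its PCA on
  each training split. Test data never enters a fit.

## Problem sizes used in the shipped experiments

The recovery-ordering experiment runs 20 repetitions per scenario at the
design size (10 sessions × 1000 points, n = 10). The model-selection
experiment uses the six-state generator at 20 sessions × 1000 points with
ε = 0.2, 2-fold CV over K ∈ {4, 5, 6} at p = 10 with 2 restarts — enough to
separate K = 6 from K ∈ {4, 5} while keeping a single-workstation runtime.
The invariance and probe experiments use 2 × 500-point sessions at n = 8–10
with a shared fixed initialisation.

## Known limitations

- Maximum-likelihood EM only: no priors on W_k, no variational Bayes, no
  free-energy model selection; the cross-validated likelihood is the model
  selection tool.
- Zero state means throughout (amplitude changes are deliberately not
  modelled); no missing-data handling.
- Multiple EM runs can return different local optima; restarts mitigate but
  do not eliminate this. Degenerate (dead-state) solutions are reported,
  not repaired.
- HMM-PCA has n·p parameters per state, so in very high dimension it can
  overfit where the p×p-parameter two-step baseline does not; the model is
  intended for intermediate (parcellated/ICA) spaces.
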