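# hmmpca

Estimation of **time-varying functional connectivity (FC)** from multichannel
time series — typically parcellated or ICA-reduced fMRI — using a hidden
Markov model whose states are themselves probabilistic PCA decompositions
(**HMM-PCA**), together with the two standard baselines it is designed to
improve on.

## The problem and the model

Within-session changes in the correlation structure between brain regions are
subtle, and the data are high-dimensional relative to the number of volumes.
The common remedy — reduce with PCA, then run a Gaussian-state HMM on the
leading components — has two intrinsic costs: connectivity information in the
discarded components is lost, and because Gaussian HMM inference is
scale-invariant but *not* rotation-invariant, a PCA rotation systematically
biases the state estimates towards low-order components.

HMM-PCA fuses the two steps. Each state *k* is a zero-mean probabilistic PCA
model: when state *k* is active,

    d_t ~ N(0, C_k),    C_k = W_k W_k' + σ²_k I,

with loadings `W_k` (n regions × p components) and isotropic noise σ²_k. The
state mean is pinned to zero so the model spends its capacity on covariance
(i.e. FC) rather than amplitude. A row-stochastic transition matrix Θ and
initial probabilities π govern switching. Inference is maximum-likelihood EM:
log-space forward–backward recursions give the state time courses γ_tk, and
the M-step applies the coupled updates

    Ŵ_k  = S_k W_k (σ²_k I + M_k⁻¹ W_k' S_k W_k)⁻¹
    σ̂²_k = tr(S_k − S_k W_k M_k⁻¹ Ŵ_k') / n,     M_k = σ²_k I + W_k' W_k,

where `S_k` is the γ-weighted sample covariance. All densities go through the
p×p core `M_k` (Woodbury / determinant-lemma form), so the cost per time point
is O(n p²), never O(n³).

Also provided:

- **Mix-PCA** (`fit_mix_pca`) — the same emissions with temporally
  independent state membership (a mixture of probabilistic PCA analysers);
- **HMM-Gaussian** (`fit_hmm_gaussian`) — zero-mean full-covariance Gaussian
  states on a PCA projection (the two-step baseline);
- seeded generators for the three synthetic designs used to study these
  models, with full ground truth;
- evaluation metrics: permutation-corrected accuracy, least-squares state
  time-course prediction error, Hungarian state matching on Fisher-z FC,
  fractional occupancy, PCA concentration/distortion diagnostics,
  cross-validated likelihood grids over (K, p), and connectedness maps.

## Worked example

```python
import numpy as np
import hmmpca as h

# two latent dimensions projected through two state-specific random maps,
# 10 sessions of 1000 time points, 10 regions
data, truth = h.generate_scenario1(p0=2, seed=3)

opts = h.FitOptions(n_states=2, n_components=2, n_restarts=5, seed=0)
model, stc = h.fit_hmm_pca(data, opts)

acc = h.permutation_accuracy(stc, truth.state_path)
fo = h.fractional_occupancy(stc, data.session_starts)
print(f"accuracy = {acc:.4f}")
print(f"stay probability = {model.transition[0, 0]:.3f}")
print(f"fractional occupancy, session 1 = {np.round(fo[0], 3)}")
```

Output:

```
accuracy = 0.9999
stay probability = 0.956
fractional occupancy, session 1 = [0.503 0.497]
```

The accuracy is the fraction of time points assigned to the correct
generating state after the best label permutation (0.5 means a degenerate
one-state solution for K=2; 1.0 is perfect recovery). The fitted stay
probability recovers the generator's sticky transition design (0.9615), and
the fractional occupancy is the share of session time spent in each state.

The same data can be fitted from the shell:

```sh
hmmpca simulate scenario1 --p0 2 --seed 3 --out sim/
hmmpca fit --data sim/data.csv --sessions sim/sessions.txt \
           --model hmm-pca --states 2 --pcs 2 --out model.h5
hmmpca eval --model model.h5 --data sim/data.csv --sessions sim/sessions.txt \
            --truth sim/ground_truth.h5 --out report.json
```

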