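"""Recovery, model-selection and bias diagnostics.

Everything needed to score a fitted model against ground truth or against
another model: permutation-corrected accuracy, least-squares prediction
error of the true state time courses, Hungarian state matching on
Fisher-transformed connectivity, fractional occupancy, the PCA
concentration/distortion pair, instantaneous connectivity, connectedness
(degree) maps, and cross-validated likelihood grids over (K, p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import (
    FitOptions,
    StateTimeCourses,
    TimeSeriesDataset,
    fit_hmm_gaussian,
    fit_hmm_pca,
    fit_mix_pca,
    held_out_log_evidence,
    pca_project,
)

__all__ = [
    "StateMatching",
    "EvaluationReport",
    "permutation_accuracy",
    "lsq_prediction_error",
    "match_states",
    "fractional_occupancy",
    "pca_concentration",
    "pca_distortion",
    "instantaneous_fc",
    "connectedness_maps",
    "cv_likelihood_grid",
]

logger = logging.getLogger("hmmpca")


@dataclass
class StateMatching:
    """Bijection between two models' state labels plus their similarities."""

    permutation: np.ndarray  # permutation[i] = index in B matched to state i of A
    similarity_matrix: np.ndarray


@dataclass
class EvaluationReport:
    """Aggregated evaluation quantities for one fitted model."""

    accuracy: float | None = None
    lsq_error: float | None = None
    lsq_residual_sum: float | None = None
    cv_log_evidence: np.ndarray | None = None
    fractional_occupancy: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for key in ("accuracy", "lsq_error", "lsq_residual_sum"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        if self.cv_log_evidence is not None:
            out["cv_log_evidence"] = np.asarray(self.cv_log_evidence).tolist()
        if self.fractional_occupancy is not None:
            out["fractional_occupancy"] = np.asarray(
                self.fractional_occupancy
            ).tolist()
        out["diagnostics"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.diagnostics.items()
        }
        return out


def _hard_path(gamma_or_path) -> np.ndarray:
    if isinstance(gamma_or_path, StateTimeCourses):
        gamma_or_path = gamma_or_path.gamma
    arr = np.asarray(gamma_or_path)
    if arr.ndim == 2:
        return arr.argmax(axis=1) + 1
    return arr.astype(int)


def permutation_accuracy(gamma_est, path_true) -> float:
    """Fraction of time the correct state is guessed, after the best label
    permutation.

    States are hard-assigned by argmax of gamma; the label permutation
    maximising agreement is found exhaustively for K = 2 and by the Hungarian
    algorithm on the agreement matrix otherwise.  For balanced two-state
    problems the value is bounded below by 0.5 (a constant single-state
    estimate against a balanced truth scores exactly 0.5 -- the signature of
    a degenerate solution).
    """
    est = _hard_path(gamma_est)
    true = _hard_path(path_true)
    if est.shape[0] != true.shape[0]:
        raise ValueError("estimated and true paths differ in length")
    K = int(max(est.max(), true.max()))
    agreement = np.zeros((K, K))
    for k in range(1, K + 1):
        mask = est == k
        for j in range(1, K + 1):
            agreement[k - 1, j - 1] = np.sum(true[mask] == j)
    if K == 2:
        best = max(
            agreement[0, 0] + agreement[1, 1], agreement[0, 1] + agreement[1, 0]
        )
    else:
        rows, cols = linear_sum_assignment(-agreement)
        best = agreement[rows, cols].sum()
    return float(best / est.shape[0])


def lsq_prediction_error(gamma_est, gamma_true) -> tuple[float, float]:
    """Least-squares error in predicting the true state time courses.

    Each true course is regressed (with intercept) on all estimated courses;
    the residual variance is summed over true states and normalised by the
    true courses' total centred variance.  0 means perfect prediction, 1 an
    uninformative estimate.  Returns (normalised error, raw residual sum).
    """
    G_est = gamma_est.gamma if isinstance(gamma_est, StateTimeCourses) else np.asarray(gamma_est, dtype=float)
    G_true = gamma_true.gamma if isinstance(gamma_true, StateTimeCourses) else np.asarray(gamma_true, dtype=float)
    if G_est.ndim == 1:
        G_est = G_est[:, None]
    if G_true.ndim == 1:
        G_true = G_true[:, None]
    if G_est.shape[0] != G_true.shape[0]:
        raise ValueError("state time courses differ in length")
    T = G_est.shape[0]
    X = np.column_stack([np.ones(T), G_est])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design; using the pseudo-inverse")
    beta, *_ = np.linalg.lstsq(X, G_true, rcond=None)
    resid = G_true - X @ beta
    rss = float(np.sum(resid**2))
    total = float(np.sum((G_true - G_true.mean(axis=0)) ** 2))
    if total <= 0:
        return 0.0 if rss <= 1e-12 else 1.0, rss
    return rss / total, rss


def _fisher_offdiag(cov: np.ndarray) -> np.ndarray:
    """Off-diagonal Fisher-z correlations of a covariance matrix."""
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    iu = np.triu_indices_from(corr, k=1)
    z = np.clip(corr[iu], -0.999999, 0.999999)
    return np.arctanh(z)


def match_states(states_a, states_b) -> StateMatching:
    """Match two models' states by their connectivity patterns.

    Each state covariance is turned into a correlation matrix, Fisher
    z-transformed, and the off-diagonal elements of every state pair are
    Pearson-correlated; the Hungarian algorithm then finds the label pairing
    with maximal total similarity.
    """
    covs_a = [np.asarray(S, dtype=float) for S in _covs_of(states_a)]
    covs_b = [np.asarray(S, dtype=float) for S in _covs_of(states_b)]
    if len(covs_a) != len(covs_b) or covs_a[0].shape != covs_b[0].shape:
        raise ValueError("state sets must have equal K and dimension")
    za = [_fisher_offdiag(S) for S in covs_a]
    zb = [_fisher_offdiag(S) for S in covs_b]
    K = len(za)
    sim = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            if np.std(za[i]) == 0 or np.std(zb[j]) == 0:
                warnings.warn("constant off-diagonal vector; similarity set to 0")
                sim[i, j] = 0.0
            else:
                sim[i, j] = np.corrcoef(za[i], zb[j])[0, 1]
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return StateMatching(permutation=perm, similarity_matrix=sim)


def _covs_of(states) -> list[np.ndarray]:
    if hasattr(states, "state_covariances"):
        return states.state_covariances()
    return list(states)


def fractional_occupancy(
    stc: StateTimeCourses, session_starts: list[int] | None = None
) -> np.ndarray:
    """Per-session fraction of time spent in each state (rows sum to 1)."""
    gamma = stc.gamma if isinstance(stc, StateTimeCourses) else np.asarray(stc)
    T = gamma.shape[0]
    starts0 = [s - 1 for s in (session_starts or [1])]
    bounds = starts0 + [T]
    return np.vstack(
        [gamma[a:b].mean(axis=0) for a, b in zip(bounds, bounds[1:])]
    )


def pca_concentration(eigenvalues: np.ndarray) -> float:
    """Average cumulative explained-variance fraction across components.

    The average runs over the first n - 1 components (the n-th cumulative
    fraction is identically 1), so uncorrelated equal-variance regions give
    exactly 0.5 and perfectly correlated regions give exactly 1.0.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < -1e-12):
        raise ValueError("eigenvalues must be nonnegative")
    ev = np.sort(np.maximum(ev, 0.0))[::-1]
    total = ev.sum()
    if total <= 0:
        raise ValueError("spectrum is all zero")
    cum = np.cumsum(ev) / total
    if ev.size == 1:
        return 1.0
    return float(cum[:-1].mean())


def _match_courses(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Hungarian matching of state time courses by Pearson correlation."""
    K = ga.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            sa, sb = np.std(ga[:, i]), np.std(gb[:, j])
            if sa == 0 or sb == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(ga[:, i], gb[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return corr[rows, cols]


def pca_distortion(gamma_original, gamma_projected) -> float:
    """One minus the mean correlation between matched state time courses
    inferred on the original data vs on its PCA projection.

    0 means the projection left the inference untouched; values up to 2 are
    possible when matched courses anticorrelate.
    """
    ga = gamma_original.gamma if isinstance(gamma_original, StateTimeCourses) else np.asarray(gamma_original)
    gb = gamma_projected.gamma if isinstance(gamma_projected, StateTimeCourses) else np.asarray(gamma_projected)
    if ga.shape != gb.shape:
        raise ValueError("state time courses must share T and K")
    if np.any(ga.std(axis=0) == 0) or np.any(gb.std(axis=0) == 0):
        warnings.warn("zero-variance state time course in distortion computation")
    matched = _match_courses(ga, gb)
    return float(1.0 - matched.mean())


def instantaneous_fc(weights: np.ndarray, model) -> np.ndarray:
    """Instantaneous connectivity: sum_k gamma_tk C_k for one time point."""
    w = np.asarray(weights, dtype=float)
    covs = _covs_of(model)
    if w.shape[0] != len(covs):
        raise ValueError("need one weight per state")
    if not np.isclose(w.sum(), 1.0, atol=1e-8) or np.any(w < -1e-12):
        raise ValueError("weights must lie on the simplex")
    out = np.zeros_like(covs[0])
    for wk, Ck in zip(w, covs):
        out += wk * Ck
    return out


def connectedness_maps(states) -> np.ndarray:
    """Per-state region degree maps, centred across states (K x n).

    degree_j is the sum of region j's correlations with every other region in
    the state correlation matrix; subtracting the across-state mean leaves
    each column summing to zero over states.
    """
    covs = _covs_of(states)
    maps = []
    for S in covs:
        d = np.sqrt(np.diag(S))
        corr = S / np.outer(d, d)
        maps.append(corr.sum(axis=1) - 1.0)
    M = np.vstack(maps)
    return M - M.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Cross-validated likelihood
# ---------------------------------------------------------------------------

_FITTERS = {
    "hmm-pca": fit_hmm_pca,
    "mix-pca": fit_mix_pca,
    "hmm-gauss": fit_hmm_gaussian,
}


def _subset_sessions(data: TimeSeriesDataset, idx: list[int]) -> TimeSeriesDataset:
    slices = data.session_slices()
    blocks = [data.values[slices[i]] for i in idx]
    starts = [1]
    for b in blocks[:-1]:
        starts.append(starts[-1] + b.shape[0])
    return TimeSeriesDataset(np.vstack(blocks), starts, data.region_labels)


def cv_likelihood_grid(
    data: TimeSeriesDataset,
    model_kind: str,
    K_grid: list[int],
    p_grid: list[int],
    folds: int = 2,
    seed: int = 0,
    fit_options: FitOptions | None = None,
) -> np.ndarray:
    """Cross-validated log-evidence over a (K, p) grid.

    Folds partition whole sessions (seeded shuffle).  For each (K, p) and
    fold, the model is fitted on the training sessions and its forward-pass
    log marginal likelihood is evaluated on the held-out sessions; fold
    contributions are summed.  For the two-step baseline (``hmm-gauss``) the
    PCA projection is estimated on the training sessions only and applied to
    the held-out data.  Returns a |K_grid| x |p_grid| matrix.
    """
    if model_kind not in _FITTERS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    S = data.n_sessions
    if folds < 2 or folds > S:
        raise ValueError("folds must partition whole sessions (2 <= folds <= S)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(S)
    fold_sets = [sorted(order[f::folds].tolist()) for f in range(folds)]
    base = fit_options if fit_options is not None else FitOptions()
    grid = np.zeros((len(K_grid), len(p_grid)))
    for ik, K in enumerate(K_grid):
        for ip, p in enumerate(p_grid):
            total = 0.0
            for f, test_idx in enumerate(fold_sets):
                train_idx = [i for i in range(S) if i not in test_idx]
                if not train_idx or not test_idx:
                    raise ValueError("every fold needs at least one session")
                train = _subset_sessions(data, train_idx)
                test = _subset_sessions(data, test_idx)
                opts = replace(base, n_states=K, n_components=p, seed=base.seed + f)
                if model_kind == "hmm-gauss":
                    # two-step: per-session standardisation, then training PCA
                    train_std = train.standardized() if opts.standardize else train
                    proj, W, evs = pca_project(train_std, p)
                    record = dict(
                        loadings=W,
                        mean=train_std.values.mean(axis=0),
                        eigenvalues=evs,
                    )
                    inner = replace(opts, standardize=False)
                    model, _ = fit_hmm_gaussian(proj, inner, projection=record)
                    model.config = replace(inner, standardize=opts.standardize)
                    total += held_out_log_evidence(model, test)
                else:
                    model, _ = _FITTERS[model_kind](train, opts)
                    total += held_out_log_evidence(model, test)
            grid[ik, ip] = total
            logger.info(
                "cv %s K=%d p=%d log-evidence %.2f", model_kind, K, p, total
            )
    return grid
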