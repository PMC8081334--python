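"""Zero-mean probabilistic PCA states.

A state is the Gaussian latent-factor model d ~ N(0, W W' + sigma^2 I) with
loadings W (n x p, p < n) and isotropic noise variance sigma^2.  The state
mean is pinned to zero so that the model's explanatory power concentrates on
covariance (functional-connectivity) structure rather than amplitude.

All densities and posterior moments are computed through the p x p core
matrix M = sigma^2 I + W'W (matrix-inversion and determinant lemmas), so the
cost per observation is O(n p^2) rather than O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "PPCAState",
    "EStepMoments",
    "WeightedCovariance",
    "ppca_log_density",
    "e_step_moments",
    "weighted_covariance",
    "m_step_update",
    "ppca_closed_form",
]

#: Absolute floor applied to sigma^2 updates, expressed as a fraction of the
#: mean data variance (callers rescale); prevents likelihood blow-up on
#: near-rank-deficient data.
NOISE_FLOOR_FRACTION = 1e-8

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PPCAState:
    """One PPCA state: loadings ``W`` (n x p) and noise variance ``sigma2``.

    The implied observation covariance is ``C = W W' + sigma2 * I``.
    """

    loadings: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        n, p = self.loadings.shape
        if not (1 <= p < n):
            raise ValueError(f"need 1 <= p < n, got n={n}, p={p}")
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("loadings must be finite")
        sv = float(self.noise_variance)
        if not np.isfinite(sv) or sv <= 0:
            raise ValueError(f"noise variance must be positive and finite, got {sv}")
        self.noise_variance = sv

    @property
    def n_regions(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def core_matrix(self) -> np.ndarray:
        """M = sigma^2 I + W'W (p x p, symmetric positive-definite)."""
        W = self.loadings
        return self.noise_variance * np.eye(self.n_components) + W.T @ W

    @property
    def covariance(self) -> np.ndarray:
        """Implied n x n observation covariance C = W W' + sigma^2 I."""
        W = self.loadings
        return W @ W.T + self.noise_variance * np.eye(self.n_regions)


@dataclass
class EStepMoments:
    """Posterior latent moments for observations under one PPCA state.

    ``posterior_mean`` holds <y_t> row-wise (T x p); ``posterior_second_moment``
    holds <y_t' y_t> (T x p x p); ``precision_core`` is the shared M matrix.
    """

    posterior_mean: np.ndarray
    posterior_second_moment: np.ndarray
    precision_core: np.ndarray


@dataclass
class WeightedCovariance:
    """Responsibility-weighted second-moment matrix S_k and its total weight."""

    matrix: np.ndarray
    total_weight: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


def _core_factors(state: PPCAState):
    """Cholesky of M plus derived pieces reused by density and moments."""
    M = state.core_matrix
    try:
        L = scipy.linalg.cholesky(M, lower=True)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FloatingPointError(f"core matrix M is not positive definite: {exc}")
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(L))))
    M_inv = scipy.linalg.cho_solve((L, True), np.eye(state.n_components))
    return M_inv, logdet_M


def ppca_log_density(observation: np.ndarray, state: PPCAState) -> np.ndarray | float:
    """Log N(d; 0, W W' + sigma^2 I), evaluated through the p x p core.

    Uses log|C| = (n - p) log sigma^2 + log|M| and
    C^{-1} = (I - W M^{-1} W') / sigma^2.  Accepts a single row (returns a
    scalar) or a T x n matrix (returns a length-T vector).
    """
    D = np.asarray(observation, dtype=float)
    single = D.ndim == 1
    D = np.atleast_2d(D)
    if not np.all(np.isfinite(D)):
        raise ValueError("observations must be finite")
    if D.shape[1] != state.n_regions:
        raise ValueError(
            f"observation has {D.shape[1]} columns, state expects {state.n_regions}"
        )
    n, p = state.n_regions, state.n_components
    s2 = state.noise_variance
    M_inv, logdet_M = _core_factors(state)
    logdet_C = (n - p) * np.log(s2) + logdet_M
    DW = D @ state.loadings  # T x p
    quad = (np.einsum("ij,ij->i", D, D) - np.einsum("ij,ij->i", DW @ M_inv, DW)) / s2
    out = -0.5 * (n * _LOG_2PI + logdet_C + quad)
    return float(out[0]) if single else out


def e_step_moments(observation: np.ndarray, state: PPCAState) -> EStepMoments:
    """Posterior moments of the latent factors y for each observation row.

    <y> = d W M^{-1},  <y'y> = sigma^2 M^{-1} + <y>'<y>,  M = sigma^2 I + W'W.
    """
    D = np.atleast_2d(np.asarray(observation, dtype=float))
    if not np.all(np.isfinite(D)):
        raise ValueError("observations must be finite")
    M_inv, _ = _core_factors(state)
    mean = D @ state.loadings @ M_inv  # T x p
    second = state.noise_variance * M_inv[None, :, :] + np.einsum(
        "ti,tj->tij", mean, mean
    )
    M = state.core_matrix
    return EStepMoments(
        posterior_mean=mean, posterior_second_moment=second, precision_core=M
    )


def weighted_covariance(values: np.ndarray, weights: np.ndarray) -> WeightedCovariance:
    """State-specific sample covariance S_k = sum_t g_tk d_t' d_t / sum_t g_tk.

    ``weights`` is one column of the state time courses (responsibilities in
    [0, 1]).  With unit weights this is the plain (uncentred, zero-mean)
    sample covariance.
    """
    D = np.asarray(values, dtype=float)
    g = np.asarray(weights, dtype=float).ravel()
    if g.shape[0] != D.shape[0]:
        raise ValueError("weights must have one entry per time point")
    if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    total = float(g.sum())
    if total <= 1e-12:
        raise ZeroDivisionError("total responsibility is ~0 (empty state)")
    S = (D * g[:, None]).T @ D / total
    S = 0.5 * (S + S.T)
    return WeightedCovariance(matrix=S, total_weight=total)


def m_step_update(
    S_k: WeightedCovariance, state: PPCAState, noise_floor: float = 1e-12
) -> PPCAState:
    """Coupled EM update of (W_k, sigma2_k) given the weighted covariance.

    W_new = S W (sigma2 I + M^{-1} W' S W)^{-1}
    sigma2_new = trace(S - S W M^{-1} W_new') / n

    Both right-hand sides use the *pre-update* state (its M matrix); the
    returned noise variance is floored at ``noise_floor``.
    """
    S = S_k.matrix
    W = state.loadings
    n, p = W.shape
    s2 = state.noise_variance
    M_inv, _ = _core_factors(state)
    SW = S @ W  # n x p
    inner = s2 * np.eye(p) + M_inv @ (W.T @ SW)
    try:
        W_new = scipy.linalg.solve(inner.T, SW.T).T
    except scipy.linalg.LinAlgError as exc:
        raise FloatingPointError(f"singular inner p x p system in M-step: {exc}")
    s2_new = float(np.trace(S - SW @ M_inv @ W_new.T)) / n
    s2_new = max(s2_new, noise_floor)
    return PPCAState(loadings=W_new, noise_variance=s2_new)


def ppca_closed_form(S: WeightedCovariance | np.ndarray, p: int) -> PPCAState:
    """Maximum-likelihood PPCA solution of a covariance matrix.

    sigma^2 is the mean of the n - p trailing eigenvalues of S; the loadings
    are the leading p eigenvectors scaled by sqrt(lambda_j - sigma^2).  This
    is a stationary point of :func:`m_step_update` and serves as the
    independent closed-form reference for the iterative fits.
    """
    S = S.matrix if isinstance(S, WeightedCovariance) else np.asarray(S, dtype=float)
    n = S.shape[0]
    if not (1 <= p < n):
        raise ValueError(f"need 1 <= p < n, got n={n}, p={p}")
    evals, evecs = scipy.linalg.eigh(S)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    sigma2 = float(np.mean(evals[p:]))
    if sigma2 < 0:
        sigma2 = 0.0
    if evals[p - 1] < sigma2 - 1e-12:
        raise np.linalg.LinAlgError(
            f"degenerate spectrum: lambda_{p} = {evals[p - 1]:.3g} <= "
            f"sigma^2 = {sigma2:.3g}"
        )
    scale = np.sqrt(np.maximum(evals[:p] - sigma2, 0.0))
    W = evecs[:, :p] * scale[None, :]
    return PPCAState(loadings=W, noise_variance=max(sigma2, 1e-15))
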