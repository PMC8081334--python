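"""Hidden Markov and mixture models over PPCA or Gaussian states.

Implements maximum-likelihood EM for three models of time-varying functional
connectivity on a (time x regions) matrix of concatenated sessions:

* ``fit_hmm_pca``   -- HMM whose emission per state k is the zero-mean PPCA
  density N(0, W_k W_k' + sigma2_k I); dimensionality reduction and state
  estimation happen in one step, in the original region space.
* ``fit_mix_pca``   -- the same emission model with temporally independent
  state membership (a mixture of probabilistic PCA analysers).
* ``fit_hmm_gaussian`` -- HMM with zero-mean full-covariance Gaussian states,
  conventionally run on a PCA projection of the data (the two-step baseline).

State posteriors gamma_tk are obtained with scaled forward-backward
recursions that restart at every session boundary, so concatenating sessions
never couples them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.special
from numba import njit
from sklearn.decomposition import PCA

from .ppca import (
    NOISE_FLOOR_FRACTION,
    PPCAState,
    m_step_update,
    ppca_closed_form,
    ppca_log_density,
    weighted_covariance,
)

__all__ = [
    "TimeSeriesDataset",
    "StateTimeCourses",
    "FitOptions",
    "HMMPCAModel",
    "MixPCAModel",
    "HMMGaussianModel",
    "forward_backward",
    "m_step_dynamics",
    "fit_hmm_pca",
    "fit_mix_pca",
    "fit_hmm_gaussian",
    "held_out_log_evidence",
    "pca_project",
]

logger = logging.getLogger("hmmpca")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesDataset:
    """Concatenated multi-session (time x regions) matrix.

    ``session_starts`` uses 1-based indices (the first session always starts
    at 1), matching the on-disk convention.
    """

    values: np.ndarray
    session_starts: list[int] | None = None
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("data values must be finite")
        T = self.values.shape[0]
        if self.session_starts is None:
            self.session_starts = [1]
        starts = [int(s) for s in self.session_starts]
        if starts[0] != 1:
            raise ValueError("session_starts must begin at 1")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("session_starts must be strictly increasing")
        if starts[-1] > T:
            raise ValueError("session start beyond the data length")
        bounds = starts + [T + 1]
        if any(b - a < 2 for a, b in zip(bounds, bounds[1:])):
            raise ValueError("every session must contain at least 2 time points")
        self.session_starts = starts

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return len(self.session_starts)

    def session_slices(self) -> list[slice]:
        starts0 = [s - 1 for s in self.session_starts]
        bounds = starts0 + [self.n_timepoints]
        return [slice(a, b) for a, b in zip(bounds, bounds[1:])]

    def standardized(self) -> "TimeSeriesDataset":
        """Z-score every column separately within every session."""
        out = self.values.copy()
        for sl in self.session_slices():
            block = out[sl]
            mu = block.mean(axis=0)
            sd = block.std(axis=0)
            sd[sd == 0] = 1.0
            out[sl] = (block - mu) / sd
        return TimeSeriesDataset(out, list(self.session_starts), self.region_labels)


@dataclass
class StateTimeCourses:
    """Posterior state probabilities gamma (T x K) and aggregated expected
    transition counts xi (K x K)."""

    gamma: np.ndarray
    pairwise: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        rows = self.gamma.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("gamma rows must sum to 1")


@dataclass
class FitOptions:
    """Hyperparameters and run controls for the EM fits."""

    n_states: int = 2
    n_components: int = 2
    max_iterations: int = 500
    relative_tolerance: float = 1e-5
    n_restarts: int = 5
    seed: int = 0
    noise_tying: bool = False
    dead_state_threshold: float = 1e-3
    standardize: bool = True
    ridge: float = 1e-8
    initial_gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


@dataclass
class HMMPCAModel:
    states: list[PPCAState]
    transition: np.ndarray
    initial: np.ndarray
    fit_trace: list[float] = field(default_factory=list)
    config: FitOptions | None = None
    converged: bool = True
    dead_states: list[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_covariances(self) -> list[np.ndarray]:
        return [s.covariance for s in self.states]


@dataclass
class MixPCAModel:
    states: list[PPCAState]
    weights: np.ndarray
    fit_trace: list[float] = field(default_factory=list)
    config: FitOptions | None = None
    converged: bool = True
    dead_states: list[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_covariances(self) -> list[np.ndarray]:
        return [s.covariance for s in self.states]


@dataclass
class HMMGaussianModel:
    states: list[np.ndarray]  # per-state SPD covariances
    transition: np.ndarray
    initial: np.ndarray
    fit_trace: list[float] = field(default_factory=list)
    config: FitOptions | None = None
    converged: bool = True
    dead_states: list[int] = field(default_factory=list)
    #: optional record of the PCA used to reduce the training data
    #: (keys: "loadings", "mean", "eigenvalues"); applied to held-out data.
    projection: dict | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_covariances(self) -> list[np.ndarray]:
        return [np.asarray(S) for S in self.states]


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _lse2(acc, x):  # pragma: no cover - compiled
    """Running log-sum-exp accumulator step."""
    if x == -np.inf:
        return acc
    if acc == -np.inf:
        return x
    if acc > x:
        return acc + np.log1p(np.exp(x - acc))
    return x + np.log1p(np.exp(acc - x))


@njit(cache=True)
def _fb_core(logB, logTheta, logpi, starts0):  # pragma: no cover - compiled
    """Log-space forward-backward over concatenated sessions.

    Immune to underflow for any T and any spread of log-likelihoods
    (including -inf entries).  Returns (gamma, xi, log-evidence).
    """
    T, K = logB.shape
    S = starts0.shape[0]
    la = np.empty((T, K))
    lb = np.empty((T, K))
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    logev = 0.0
    for s in range(S):
        a = starts0[s]
        b = starts0[s + 1] if s + 1 < S else T
        for k in range(K):
            la[a, k] = logpi[k] + logB[a, k]
        for t in range(a + 1, b):
            for j in range(K):
                acc = -np.inf
                for k in range(K):
                    acc = _lse2(acc, la[t - 1, k] + logTheta[k, j])
                la[t, j] = acc + logB[t, j]
        ev = -np.inf
        for k in range(K):
            ev = _lse2(ev, la[b - 1, k])
        logev += ev
        for k in range(K):
            lb[b - 1, k] = 0.0
        for t in range(b - 2, a - 1, -1):
            for k in range(K):
                acc = -np.inf
                for j in range(K):
                    acc = _lse2(acc, logTheta[k, j] + logB[t + 1, j] + lb[t + 1, j])
                lb[t, k] = acc
        for t in range(a, b):
            norm = -np.inf
            for k in range(K):
                gamma[t, k] = la[t, k] + lb[t, k]
                norm = _lse2(norm, gamma[t, k])
            for k in range(K):
                gamma[t, k] = np.exp(gamma[t, k] - norm)
        for t in range(a, b - 1):
            for k in range(K):
                for j in range(K):
                    v = la[t, k] + logTheta[k, j] + logB[t + 1, j] + lb[t + 1, j] - ev
                    if v > -np.inf:
                        xi[k, j] += np.exp(v)
    return gamma, xi, logev


def forward_backward(
    log_likelihoods: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
    session_starts: list[int] | None = None,
) -> tuple[StateTimeCourses, float]:
    """Posterior state probabilities and log-evidence of an HMM.

    The chain is re-initialised with ``initial`` at every session start; the
    returned log-evidence is the sum of per-session log marginal likelihoods.
    Per-time-step scaling keeps the recursion finite at any T.
    """
    logB = np.asarray(log_likelihoods, dtype=float)
    T, K = logB.shape
    Theta = np.asarray(transition, dtype=float)
    pi = np.asarray(initial, dtype=float)
    if not np.allclose(Theta.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition rows must sum to 1")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("initial probabilities must sum to 1")
    bad = np.where(np.all(np.isneginf(logB), axis=1))[0]
    if bad.size:
        raise FloatingPointError(
            f"all states have zero likelihood at time point {bad[0] + 1}"
        )
    if not np.all(np.isfinite(logB) | np.isneginf(logB)):
        raise ValueError("log-likelihoods must be finite or -inf")
    starts0 = np.array(
        [s - 1 for s in (session_starts or [1])], dtype=np.int64
    )
    with np.errstate(divide="ignore"):
        logTheta = np.log(Theta)
        logpi = np.log(pi)
    gamma, xi, log_evidence = _fb_core(
        np.ascontiguousarray(logB), logTheta, logpi, starts0
    )
    if not np.isfinite(log_evidence):
        raise FloatingPointError("log-evidence is not finite (impossible path)")
    gamma /= gamma.sum(axis=1, keepdims=True)
    return StateTimeCourses(gamma=gamma, pairwise=xi), float(log_evidence)


def m_step_dynamics(
    stc: StateTimeCourses, session_starts: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Transition-matrix and initial-probability updates from the posteriors.

    Theta row k is the expected transition count out of k, normalised; pi is
    the mean posterior over session-start time points.  A state with no
    outgoing mass gets a uniform row (with a warning).
    """
    if stc.pairwise is None:
        raise ValueError("pairwise expected counts are required")
    xi = np.asarray(stc.pairwise, dtype=float)
    K = xi.shape[0]
    rows = xi.sum(axis=1, keepdims=True)
    Theta = np.empty_like(xi)
    for k in range(K):
        if rows[k, 0] <= 0:
            warnings.warn(f"state {k} has no outgoing transition mass; uniform row")
            Theta[k] = 1.0 / K
        else:
            Theta[k] = xi[k] / rows[k, 0]
    starts0 = [s - 1 for s in (session_starts or [1])]
    pi = stc.gamma[starts0].mean(axis=0)
    pi = pi / pi.sum()
    return Theta, pi


# ---------------------------------------------------------------------------
# Emission log-likelihoods
# ---------------------------------------------------------------------------


def _ppca_loglik(D: np.ndarray, states: list[PPCAState]) -> np.ndarray:
    return np.column_stack([ppca_log_density(D, s) for s in states])


def _gauss_loglik(D: np.ndarray, covs: list[np.ndarray]) -> np.ndarray:
    T, n = D.shape
    out = np.empty((T, len(covs)))
    for k, S in enumerate(covs):
        L = np.linalg.cholesky(S)
        z = scipy.linalg.solve_triangular(L, D.T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (
            n * np.log(2.0 * np.pi) + logdet + np.einsum("ij,ij->j", z, z)
        )
    return out


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------


def _initial_responsibilities(
    T: int, K: int, rng: np.random.Generator, slices: list[slice]
) -> np.ndarray:
    """Random start: per-time-point Dirichlet(2) draws smoothed along time by
    a width-10 moving average within each session, then renormalised."""
    g = rng.dirichlet(2.0 * np.ones(K), size=T)
    width = 10
    kernel = np.ones(width) / width
    for sl in slices:
        block = g[sl]
        for k in range(K):
            pad = np.pad(block[:, k], width, mode="edge")
            block[:, k] = np.convolve(pad, kernel, mode="same")[width:-width]
        g[sl] = block
    g /= g.sum(axis=1, keepdims=True)
    return g


def _dynamics_from_gamma(
    gamma: np.ndarray, slices: list[slice], starts: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate initial (Theta, pi) from soft assignments alone."""
    K = gamma.shape[1]
    xi = np.zeros((K, K))
    for sl in slices:
        g = gamma[sl]
        xi += g[:-1].T @ g[1:]
    xi += 1e-10
    Theta = xi / xi.sum(axis=1, keepdims=True)
    pi = gamma[[s - 1 for s in starts]].mean(axis=0)
    return Theta, pi / pi.sum()


def _occupancies(gamma: np.ndarray) -> np.ndarray:
    return gamma.sum(axis=0)


def _update_ppca_states(
    D: np.ndarray,
    gamma: np.ndarray,
    states: list[PPCAState],
    noise_floor: float,
    noise_tying: bool,
) -> list[PPCAState]:
    occ = _occupancies(gamma)
    new_states = list(states)
    for k, state in enumerate(states):
        if occ[k] <= 1e-10:
            continue  # dead state: parameters frozen
        S_k = weighted_covariance(D, gamma[:, k])
        new_states[k] = m_step_update(S_k, state, noise_floor=noise_floor)
    if noise_tying:
        tied = float(
            np.sum(occ * np.array([s.noise_variance for s in new_states])) / occ.sum()
        )
        new_states = [
            PPCAState(s.loadings, max(tied, noise_floor)) for s in new_states
        ]
    return new_states


def _update_gauss_states(
    D: np.ndarray, gamma: np.ndarray, states: list[np.ndarray], ridge: float
) -> list[np.ndarray]:
    occ = _occupancies(gamma)
    n = D.shape[1]
    out = list(states)
    for k in range(gamma.shape[1]):
        if occ[k] <= 1e-10:
            continue
        S = weighted_covariance(D, gamma[:, k]).matrix
        # diagonal-proportional ridge: equivariant under per-channel rescaling,
        # so regularisation never breaks the scale-invariance of the inference
        S = S + ridge * np.diag(np.diag(S))
        if np.linalg.matrix_rank(S) < n:
            warnings.warn(f"state {k} covariance singular; ridge increased")
            S = S + 1e-6 * (np.trace(S) / n + 1e-12) * np.eye(n)
            if np.linalg.matrix_rank(S) < n:
                raise np.linalg.LinAlgError(f"state {k} covariance is degenerate")
        out[k] = S
    return out


def _init_ppca_states(
    D: np.ndarray, gamma: np.ndarray, p: int, noise_floor: float
) -> list[PPCAState]:
    states = []
    for k in range(gamma.shape[1]):
        S_k = weighted_covariance(D, gamma[:, k])
        st = ppca_closed_form(S_k, p)
        states.append(PPCAState(st.loadings, max(st.noise_variance, noise_floor)))
    return states


def _prepare(data: TimeSeriesDataset, opts: FitOptions) -> TimeSeriesDataset:
    return data.standardized() if opts.standardize else data


def _restart_seeds(opts: FitOptions) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(opts.seed)
    return [np.random.default_rng(c) for c in ss.spawn(opts.n_restarts)]


def _check_size(data: TimeSeriesDataset, opts: FitOptions, dim: int) -> None:
    if data.n_timepoints <= opts.n_states * dim:
        raise ValueError("not enough time points for the requested model size")


def _flag_dead(gamma: np.ndarray, opts: FitOptions) -> list[int]:
    occ = _occupancies(gamma)
    dead = [int(k) for k in np.where(occ < opts.dead_state_threshold * gamma.shape[0])[0]]
    if dead:
        logger.warning("states %s were obliterated by the inference", dead)
    if len(dead) == gamma.shape[1]:
        raise np.linalg.LinAlgError("all states died during the fit")
    return dead


def _em_hmm(data, opts, init_states, update_states, loglik):
    """Shared EM loop for the two HMM variants.

    ``init_states``/``update_states``/``loglik`` close over the emission
    family.  Returns the best restart by final log-evidence.
    """
    D = _prepare(data, opts).values
    slices = data.session_slices()
    starts = data.session_starts
    best = None
    for rng in _restart_seeds(opts):
        if opts.initial_gamma is not None:
            gamma = np.asarray(opts.initial_gamma, dtype=float)
            gamma = gamma / gamma.sum(axis=1, keepdims=True)
        else:
            gamma = _initial_responsibilities(
                D.shape[0], opts.n_states, rng, slices
            )
        states = init_states(D, gamma)
        Theta, pi = _dynamics_from_gamma(gamma, slices, starts)
        trace: list[float] = []
        converged = False
        while True:
            logB = loglik(D, states)
            stc, logev = forward_backward(logB, Theta, pi, starts)
            trace.append(logev)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(logev - prev) < opts.relative_tolerance * abs(prev):
                    converged = True
                    break
            if len(trace) >= opts.max_iterations:
                break
            states = update_states(D, stc.gamma, states)
            Theta, pi = m_step_dynamics(stc, starts)
        if best is None or trace[-1] > best[4][-1]:
            best = (states, Theta, pi, stc, trace, converged)
    states, Theta, pi, stc, trace, converged = best
    if not converged:
        logger.warning("EM did not converge in %d iterations", opts.max_iterations)
    dead = _flag_dead(stc.gamma, opts)
    return states, Theta, pi, stc, trace, converged, dead


def fit_hmm_pca(
    data: TimeSeriesDataset, opts: FitOptions
) -> tuple[HMMPCAModel, StateTimeCourses]:
    """Fit the HMM with probabilistic-PCA states by maximum-likelihood EM.

    Each EM iteration evaluates the per-state PPCA log-densities, runs
    forward-backward for the posteriors, and applies the coupled
    (W_k, sigma2_k) update to the responsibility-weighted covariances,
    followed by the transition/initial-probability updates.  The best of
    ``opts.n_restarts`` seeded restarts (by final log-evidence) is returned.
    """
    _check_size(data, opts, opts.n_components)
    D = _prepare(data, opts).values
    floor = NOISE_FLOOR_FRACTION * float(np.mean(np.var(D, axis=0)))
    p = opts.n_components

    def init(Dm, gamma):
        return _init_ppca_states(Dm, gamma, p, floor)

    def update(Dm, gamma, states):
        return _update_ppca_states(Dm, gamma, states, floor, opts.noise_tying)

    states, Theta, pi, stc, trace, converged, dead = _em_hmm(
        data, opts, init, update, _ppca_loglik
    )
    model = HMMPCAModel(
        states=states,
        transition=Theta,
        initial=pi,
        fit_trace=trace,
        config=opts,
        converged=converged,
        dead_states=dead,
    )
    return model, stc


def fit_hmm_gaussian(
    data: TimeSeriesDataset, opts: FitOptions, projection: dict | None = None
) -> tuple[HMMGaussianModel, StateTimeCourses]:
    """Fit the zero-mean Gaussian HMM (the two-step baseline's second step).

    ``data`` is typically a PCA projection produced by :func:`pca_project`;
    pass that projection's record through ``projection`` so held-out data can
    be reduced consistently.  Covariances are regularised by a small relative
    ridge.
    """
    _check_size(data, opts, data.n_regions)

    def init(Dm, gamma):
        n = Dm.shape[1]
        return _update_gauss_states(
            Dm, gamma, [np.eye(n)] * opts.n_states, opts.ridge
        )

    def update(Dm, gamma, states):
        return _update_gauss_states(Dm, gamma, states, opts.ridge)

    states, Theta, pi, stc, trace, converged, dead = _em_hmm(
        data, opts, init, update, lambda Dm, st: _gauss_loglik(Dm, st)
    )
    model = HMMGaussianModel(
        states=states,
        transition=Theta,
        initial=pi,
        fit_trace=trace,
        config=opts,
        converged=converged,
        dead_states=dead,
        projection=projection,
    )
    return model, stc


def fit_mix_pca(
    data: TimeSeriesDataset, opts: FitOptions
) -> tuple[MixPCAModel, StateTimeCourses]:
    """Fit the mixture of probabilistic PCA analysers (no temporal structure).

    Posteriors are pointwise: gamma_tk is proportional to
    pi_k N(d_t; 0, C_k); the mixing weights update as the mean posterior.
    """
    _check_size(data, opts, opts.n_components)
    D = _prepare(data, opts).values
    floor = NOISE_FLOOR_FRACTION * float(np.mean(np.var(D, axis=0)))
    p = opts.n_components
    slices = data.session_slices()
    best = None
    for rng in _restart_seeds(opts):
        if opts.initial_gamma is not None:
            gamma = np.asarray(opts.initial_gamma, dtype=float)
            gamma = gamma / gamma.sum(axis=1, keepdims=True)
        else:
            gamma = _initial_responsibilities(D.shape[0], opts.n_states, rng, slices)
        states = _init_ppca_states(D, gamma, p, floor)
        weights = gamma.mean(axis=0)
        trace: list[float] = []
        converged = False
        while True:
            logB = _ppca_loglik(D, states) + np.log(weights)[None, :]
            logev = float(scipy.special.logsumexp(logB, axis=1).sum())
            gamma = np.exp(logB - scipy.special.logsumexp(logB, axis=1)[:, None])
            trace.append(logev)
            if len(trace) > 1 and abs(logev - trace[-2]) < opts.relative_tolerance * abs(
                trace[-2]
            ):
                converged = True
                break
            if len(trace) >= opts.max_iterations:
                break
            states = _update_ppca_states(D, gamma, states, floor, opts.noise_tying)
            weights = gamma.mean(axis=0)
            weights = weights / weights.sum()
        if best is None or trace[-1] > best[3][-1]:
            best = (states, weights, gamma, trace, converged)
    states, weights, gamma, trace, converged = best
    if not converged:
        logger.warning("EM did not converge in %d iterations", opts.max_iterations)
    dead = _flag_dead(gamma, opts)
    model = MixPCAModel(
        states=states,
        weights=weights,
        fit_trace=trace,
        config=opts,
        converged=converged,
        dead_states=dead,
    )
    return model, StateTimeCourses(gamma=gamma, pairwise=None)


# ---------------------------------------------------------------------------
# Held-out evidence and PCA projection
# ---------------------------------------------------------------------------


def held_out_log_evidence(model, data: TimeSeriesDataset) -> float:
    """Log marginal likelihood of unseen sessions under a fitted model.

    No parameters are updated.  For an HMM-Gaussian model fitted on a PCA
    projection, the training projection recorded on the model is applied to
    the held-out data first.
    """
    opts = model.config
    if opts is not None and opts.standardize:
        data = data.standardized()
    if isinstance(model, HMMGaussianModel):
        D = data.values
        if model.projection is not None:
            D = (D - model.projection["mean"]) @ model.projection["loadings"]
        if D.shape[1] != model.states[0].shape[0]:
            raise ValueError("data dimension does not match the model states")
        logB = _gauss_loglik(D, model.states)
        _, logev = forward_backward(
            logB, model.transition, model.initial, data.session_starts
        )
        return logev
    if data.n_regions != model.states[0].n_regions:
        raise ValueError("data dimension does not match the model states")
    logB = _ppca_loglik(data.values, model.states)
    if isinstance(model, MixPCAModel):
        return float(
            scipy.special.logsumexp(logB + np.log(model.weights)[None, :], axis=1).sum()
        )
    _, logev = forward_backward(
        logB, model.transition, model.initial, data.session_starts
    )
    return logev


def pca_project(
    data: TimeSeriesDataset, p: int
) -> tuple[TimeSeriesDataset, np.ndarray, np.ndarray]:
    """Project a dataset onto its leading p principal components.

    Returns the projected dataset (columns ordered by decreasing variance and
    mutually uncorrelated over the full dataset), the n x p loading matrix W,
    and the full eigenvalue spectrum for concentration diagnostics.
    """
    n = data.n_regions
    if p > n:
        raise ValueError(f"cannot keep p={p} components of {n} regions")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(data.values)
    W = pca.components_.T[:, :p]
    projected = TimeSeriesDataset(
        scores[:, :p], list(data.session_starts), region_labels=None
    )
    return projected, W, pca.explained_variance_.copy()
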