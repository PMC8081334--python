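"""Seeded synthetic-data generators with ground truth.

Three designs, each emulating a facet of multichannel fMRI with switching
functional connectivity, plus two data-manipulation probes:

* ``generate_scenario1`` -- latent Gaussian factors pushed through two
  state-specific random projections (low-rank-plus-noise observations).
* ``generate_scenario2`` -- zero-mean Gaussian states whose covariances share
  a leading eigenvector but differ by permutations of the next eigenvectors.
* ``generate_multistate`` -- six 100-region states built by permuting the
  entries of randomly chosen eigenvectors of a base covariance, under a
  sticky Markov chain; the large-scale model-selection testbed.
* ``apply_probe`` -- channel rescaling and eigenvalue randomisation, the two
  transforms that separate scale-invariant from rotation-sensitive inference.

Every generator is a pure function of its seed and returns
(TimeSeriesDataset, GroundTruth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .models import TimeSeriesDataset

__all__ = [
    "GroundTruth",
    "ProbeSpec",
    "sample_markov_chain",
    "sticky_transition_matrix",
    "realistic_covariance",
    "generate_scenario1",
    "generate_scenario2",
    "generate_multistate",
    "apply_probe",
]


@dataclass
class GroundTruth:
    """Generating state path, state covariances, and full generator record."""

    state_path: np.ndarray  # length T, labels 1..K
    state_covariances: list[np.ndarray]
    transition: np.ndarray
    generator_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=int)
        K = len(self.state_covariances)
        if self.state_path.min() < 1 or self.state_path.max() > K:
            raise ValueError("state path labels must lie in 1..K")

    @property
    def n_states(self) -> int:
        return len(self.state_covariances)


@dataclass
class ProbeSpec:
    """A data manipulation: per-channel rescaling or eigenvalue randomisation."""

    kind: str  # "channel-scaling" | "eigenvalue-randomisation"
    scale_vector: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("channel-scaling", "eigenvalue-randomisation"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        if self.scale_vector is not None:
            v = np.asarray(self.scale_vector, dtype=float)
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError("scales must be positive and finite")
            self.scale_vector = v


def sticky_transition_matrix(K: int, stickiness: float = 25.0) -> np.ndarray:
    """Row-stochastic matrix whose diagonal is ``stickiness`` times each
    off-diagonal entry (25x gives the .9615/.0385 two-state design)."""
    off = 1.0 / (stickiness + K - 1)
    Theta = np.full((K, K), off)
    np.fill_diagonal(Theta, stickiness * off)
    return Theta


def sample_markov_chain(
    transition: np.ndarray,
    initial: np.ndarray,
    T: int,
    seed: int | np.random.Generator,
    session_starts: list[int] | None = None,
) -> np.ndarray:
    """Sample a state path (labels 1..K); the initial state is re-drawn from
    ``initial`` at every session start."""
    Theta = np.asarray(transition, dtype=float)
    pi = np.asarray(initial, dtype=float)
    if not np.allclose(Theta.sum(axis=1), 1.0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("transition rows and initial must sum to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    K = Theta.shape[0]
    cum_T = np.cumsum(Theta, axis=1)
    cum_pi = np.cumsum(pi)
    starts0 = set((s - 1) for s in (session_starts or [1]))
    path = np.empty(T, dtype=int)
    u = rng.random(T)
    for t in range(T):
        if t in starts0:
            path[t] = np.searchsorted(cum_pi, u[t])
        else:
            path[t] = np.searchsorted(cum_T[path[t - 1]], u[t])
    return path + 1


def realistic_covariance(
    n: int, seed: int | np.random.Generator, rank: int | None = None
) -> np.ndarray:
    """Synthetic base covariance with the concentrated spectrum typical of
    parcellated fMRI: C = B B' + diagonal jitter, B an n x (n/5) Gaussian
    factor matrix.  A stand-in for an empirical region-by-region covariance."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r = rank if rank is not None else max(n // 5, 1)
    B = rng.standard_normal((n, r))
    low = B @ B.T
    jitter = rng.uniform(0.05, 0.2, size=n) * (np.trace(low) / n)
    return low + np.diag(jitter)


def _session_starts(sessions: int, session_length: int) -> list[int]:
    return [1 + s * session_length for s in range(sessions)]


def _sample_path(
    K: int, sessions: int, session_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    Theta = sticky_transition_matrix(K)
    starts = _session_starts(sessions, session_length)
    path = sample_markov_chain(
        Theta, np.full(K, 1.0 / K), sessions * session_length, rng, starts
    )
    return path, Theta, starts


def generate_scenario1(
    p0: int = 2,
    n: int = 10,
    sessions: int = 10,
    session_length: int = 1000,
    latent_sds: tuple[float, ...] | None = None,
    noise_sd: float = 0.001,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Latent factors through state-specific random projections.

    Independent zero-mean Gaussian latents Y0 (standard deviations 2.0, 1.5
    for p0 = 2; 2.0, 1.5, 1.0 for p0 = 3) are projected as Y0 (A + A1)' while
    state 1 is active and Y0 (A + A2)' while state 2 is active, with A, A1,
    A2 standard-Gaussian n x p0 matrices, plus isotropic observational noise.
    """
    if p0 not in (2, 3):
        raise ValueError("p0 must be 2 or 3")
    if latent_sds is None:
        latent_sds = (2.0, 1.5) if p0 == 2 else (2.0, 1.5, 1.0)
    if len(latent_sds) != p0:
        raise ValueError("need one latent standard deviation per dimension")
    rng = np.random.default_rng(seed)
    T = sessions * session_length
    path, Theta, starts = _sample_path(2, sessions, session_length, rng)
    A = rng.standard_normal((n, p0))
    A1 = rng.standard_normal((n, p0))
    A2 = rng.standard_normal((n, p0))
    sds = np.asarray(latent_sds, dtype=float)
    Y0 = rng.standard_normal((T, p0)) * sds[None, :]
    eps = rng.standard_normal((T, n)) * noise_sd
    proj = [A + A1, A + A2]
    D = np.empty((T, n))
    for k in (1, 2):
        mask = path == k
        D[mask] = Y0[mask] @ proj[k - 1].T
    D += eps
    covs = [
        P @ np.diag(sds**2) @ P.T + noise_sd**2 * np.eye(n) for P in proj
    ]
    truth = GroundTruth(
        state_path=path,
        state_covariances=covs,
        transition=Theta,
        generator_config=dict(
            scenario=1,
            p0=p0,
            n=n,
            sessions=sessions,
            session_length=session_length,
            latent_sds=list(sds),
            noise_sd=noise_sd,
            seed=seed,
            A=A,
            A1=A1,
            A2=A2,
            Y0=Y0,
        ),
    )
    return TimeSeriesDataset(D, starts), truth


def _permute_and_orthogonalise(
    V: np.ndarray, permute_idx: dict[int, np.ndarray]
) -> np.ndarray:
    """Permute the entries of selected eigenvector columns, then restore
    orthonormality by Gram-Schmidt in column order (norms preserved)."""
    U = V.copy()
    for j, perm in permute_idx.items():
        U[:, j] = U[perm, j]
    for j in range(U.shape[1]):
        v = U[:, j]
        for i in range(j):
            v = v - (U[:, i] @ v) * U[:, i]
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise np.linalg.LinAlgError("permuted eigenvector collapsed")
        U[:, j] = v / nrm
    return U


def generate_scenario2(
    base_covariance: np.ndarray | None = None,
    p0: int = 2,
    n: int = 10,
    sessions: int = 10,
    session_length: int = 1000,
    noise_sd: float = 0.001,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Two states built by eigenvector permutation of a base covariance.

    The base covariance C (synthetic stand-in by default) is eigendecomposed;
    both state covariances keep C's first eigenvector (the time-invariant
    connectivity component), assign different entry-permutations of
    eigenvectors 2..p0 (the time-varying components), and zero the rest.
    """
    if p0 not in (2, 3):
        raise ValueError("p0 must be 2 or 3")
    rng = np.random.default_rng(seed)
    C = (
        realistic_covariance(n, rng)
        if base_covariance is None
        else np.asarray(base_covariance, dtype=float)
    )
    n = C.shape[0]
    if p0 > n:
        raise ValueError("p0 exceeds the base covariance rank")
    evals, evecs = scipy.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[p0 - 1] <= 0:
        raise ValueError("base covariance rank below p0")
    covs = []
    perms_used = []
    for _state in range(2):
        perms = {
            j: rng.permutation(n) for j in range(1, p0)
        }  # eigenvector 1 (index 0) is shared
        U = _permute_and_orthogonalise(evecs[:, :p0], perms)
        covs.append(U @ np.diag(evals[:p0]) @ U.T)
        perms_used.append(perms)
    T = sessions * session_length
    path, Theta, starts = _sample_path(2, sessions, session_length, rng)
    D = np.empty((T, n))
    for k in (1, 2):
        mask = path == k
        L = np.linalg.cholesky(covs[k - 1] + 1e-12 * np.eye(n))
        D[mask] = rng.standard_normal((int(mask.sum()), n)) @ L.T
    D += rng.standard_normal((T, n)) * noise_sd
    sampled_covs = [Ck + noise_sd**2 * np.eye(n) for Ck in covs]
    truth = GroundTruth(
        state_path=path,
        state_covariances=sampled_covs,
        transition=Theta,
        generator_config=dict(
            scenario=2,
            p0=p0,
            n=n,
            sessions=sessions,
            session_length=session_length,
            noise_sd=noise_sd,
            seed=seed,
            base_covariance=C,
            eigenvalues=evals,
            eigenvectors=evecs,
            permutations=perms_used,
        ),
    )
    return TimeSeriesDataset(D, starts), truth


def generate_multistate(
    base_covariance: np.ndarray | None = None,
    n: int = 100,
    K: int = 6,
    epsilon: float = 0.2,
    subjects: int = 100,
    session_length: int = 1000,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Six (by default) states by within-eigenvector permutation.

    For each state, principal components of the base covariance are chosen at
    random while their cumulative explained-variance share stays at or below
    ``epsilon``; the entries of the chosen eigenvectors are then permuted
    (with re-orthogonalisation) to produce a state-specific covariance.  A
    sticky Markov chain (diagonal 25x the off-diagonal) drives state
    switching; each subject is one session.
    """
    if not (0 <= epsilon < 1):
        raise ValueError("epsilon must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    C = (
        realistic_covariance(n, rng)
        if base_covariance is None
        else np.asarray(base_covariance, dtype=float)
    )
    n = C.shape[0]
    evals, evecs = scipy.linalg.eigh(C)
    evals, evecs = np.maximum(evals[::-1], 0.0), evecs[:, ::-1]
    shares = evals / evals.sum()
    covs = []
    chosen_sets = []
    for _state in range(K):
        order = rng.permutation(n)
        chosen: list[int] = []
        total = 0.0
        for j in order:
            if total + shares[j] <= epsilon:
                chosen.append(int(j))
                total += shares[j]
        perms = {j: rng.permutation(n) for j in chosen}
        U = _permute_and_orthogonalise(evecs, perms) if perms else evecs
        covs.append(U @ np.diag(evals) @ U.T)
        chosen_sets.append(sorted(chosen))
    T = subjects * session_length
    path, Theta, starts = _sample_path(K, subjects, session_length, rng)
    chols = [np.linalg.cholesky(Ck + 1e-10 * np.trace(Ck) / n * np.eye(n)) for Ck in covs]
    D = np.empty((T, n))
    for k in range(1, K + 1):
        mask = path == k
        D[mask] = rng.standard_normal((int(mask.sum()), n)) @ chols[k - 1].T
    truth = GroundTruth(
        state_path=path,
        state_covariances=covs,
        transition=Theta,
        generator_config=dict(
            scenario="multistate",
            n=n,
            K=K,
            epsilon=epsilon,
            subjects=subjects,
            session_length=session_length,
            seed=seed,
            base_covariance=C,
            eigenvalues=evals,
            chosen_components=chosen_sets,
        ),
    )
    return TimeSeriesDataset(D, starts), truth


def apply_probe(data: TimeSeriesDataset, probe: ProbeSpec) -> TimeSeriesDataset:
    """Apply a channel-scaling or eigenvalue-randomisation manipulation.

    Channel scaling multiplies column j by w_j.  Eigenvalue randomisation
    computes the full PCA of the data, multiplies each component's scores by
    an independent positive random factor, and back-projects; this keeps the
    covariance eigenvectors while rescaling the eigenvalues.
    """
    D = data.values
    if probe.kind == "channel-scaling":
        w = probe.scale_vector
        if w is None:
            raise ValueError("channel-scaling probe needs a scale vector")
        if w.shape[0] != data.n_regions:
            raise ValueError("scale vector length must equal the region count")
        out = D * w[None, :]
    else:
        rng = np.random.default_rng(probe.seed)
        mean = D.mean(axis=0)
        Dc = D - mean
        # full PCA via SVD of the centred data
        _, svals, Vt = np.linalg.svd(Dc, full_matrices=False)
        scores = Dc @ Vt.T
        factors = (
            probe.scale_vector
            if probe.scale_vector is not None
            else rng.uniform(0.2, 2.0, size=Vt.shape[0])
        )
        if len(factors) != Vt.shape[0]:
            raise ValueError("need one eigenvalue factor per component")
        out = mean + (scores * np.asarray(factors)[None, :]) @ Vt
    return TimeSeriesDataset(out, list(data.session_starts), data.region_labels)
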