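"""Gaussian-mixture hidden Markov models: emission densities, forward
likelihood, Viterbi decoding, and multi-sequence EM (Baum-Welch) training.

Each hidden state j emits a feature vector through a finite Gaussian
mixture b_j(o) = sum_m c_jm N(o | mu_jm, Sigma_jm) with full (or diagonal)
covariances.  The E-step computes state/component responsibilities
gamma_t(j, m) and pairwise posteriors xi_t(i, j) by forward-backward; the
M-step is the standard closed-form reweighting of means, covariances,
mixture weights and transition rows, with sums extended over all training
sequences.  Recursions run in scaled linear space after a per-step log-max
shift, which is exactly equivalent to log-space evaluation but considerably
faster for the short (T ~ 30-50) sequences this package handles.

The default topology is left-to-right (Bakis): states form an ordered
progression (an "first/second/third-order" structure of the initiation
process), with an ergodic switch available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .preprocess import FeatureSequence

__all__ = [
    "GaussianComponent", "StateEmission", "HmmModel", "FitOptions",
    "gmm_logdensity", "forward_loglik", "viterbi_decode", "em_fit",
    "sample_sequences",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianComponent:
    """One mixture component: weight c_m, mean mu_m, covariance Sigma_m."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray


class StateEmission:
    """Gaussian-mixture emission density of one hidden state.

    Parameters are stored as stacked arrays -- weights (M,), means (M, p),
    covariances (M, p, p) -- with Cholesky factors cached for fast batched
    evaluation.  Mixture weights must sum to 1.
    """

    def __init__(self, weights: np.ndarray, means: np.ndarray,
                 covariances: np.ndarray) -> None:
        self.weights = np.asarray(weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(means, dtype=float))
        self.covariances = np.asarray(covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < -1e-15):
            raise ValueError("mixture weights must be non-negative")
        self._chol: list[np.ndarray] = []
        self._logdet = np.empty(self.n_components)
        for m in range(self.n_components):
            cov = self.covariances[m]
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance of component {m} is not symmetric")
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"covariance of component {m} is not positive definite"
                ) from err
            self._chol.append(L)
            self._logdet[m] = 2.0 * np.log(np.diag(L)).sum()

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def components(self) -> list[GaussianComponent]:
        return [GaussianComponent(float(self.weights[m]), self.means[m],
                                  self.covariances[m])
                for m in range(self.n_components)]

    @classmethod
    def from_components(cls, comps: Sequence[GaussianComponent]
                        ) -> "StateEmission":
        return cls(np.array([c.weight for c in comps]),
                   np.array([np.asarray(c.mean, float) for c in comps]),
                   np.array([np.asarray(c.covariance, float) for c in comps]))

    def component_logpdfs(self, X: np.ndarray) -> np.ndarray:
        """log N(x | mu_m, Sigma_m) for all rows of X; returns (n, M)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(
                f"observation dimension {X.shape[1]} does not match "
                f"emission dimension {self.dim}")
        out = np.empty((X.shape[0], self.n_components))
        for m in range(self.n_components):
            z = solve_triangular(self._chol[m], (X - self.means[m]).T,
                                 lower=True)
            out[:, m] = -0.5 * (np.sum(z * z, axis=0)
                                + self.dim * _LOG2PI + self._logdet[m])
        return out

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """log b(x) = log sum_m c_m N(x | mu_m, Sigma_m), per row (stable)."""
        lp = self.component_logpdfs(X)
        with np.errstate(divide="ignore"):
            return logsumexp(lp + np.log(self.weights)[None, :], axis=1)


def gmm_logdensity(x: np.ndarray, emission: StateEmission) -> float:
    """Log mixture density of a single observation vector."""
    return float(emission.log_density(np.atleast_2d(x))[0])


@dataclass
class HmmModel:
    """lambda = (pi, A, B): initial distribution, transitions, GMM emissions."""

    n_states: int
    startprob: np.ndarray
    transmat: np.ndarray
    emissions: list[StateEmission]
    topology: str = "left-to-right"

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        N = self.n_states
        if self.startprob.shape != (N,) or self.transmat.shape != (N, N):
            raise ValueError("pi / A shapes inconsistent with n_states")
        if abs(self.startprob.sum() - 1.0) > 1e-12:
            raise ValueError("startprob must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("every transition row must sum to 1")
        if self.topology == "left-to-right" and np.any(
                np.tril(self.transmat, -1) > 1e-300):
            raise ValueError("left-to-right topology forbids backward transitions")
        if len(self.emissions) != N:
            raise ValueError("need one StateEmission per state")

    @property
    def feature_dim(self) -> int:
        return self.emissions[0].dim

    def log_emission_matrix(self, X: np.ndarray) -> np.ndarray:
        """(T, N) matrix of log b_j(O_t)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([e.log_density(X) for e in self.emissions])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "topology": self.topology,
            "feature_dim": self.feature_dim,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emissions": [
                {"weights": e.weights.tolist(), "means": e.means.tolist(),
                 "covariances": e.covariances.tolist()}
                for e in self.emissions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        emissions = [StateEmission(np.array(e["weights"]),
                                   np.array(e["means"]),
                                   np.array(e["covariances"]))
                     for e in d["emissions"]]
        return cls(n_states=int(d["n_states"]),
                   startprob=np.array(d["startprob"]),
                   transmat=np.array(d["transmat"]),
                   emissions=emissions, topology=d["topology"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HmmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitOptions:
    """EM training knobs (initialization, stopping, regularization)."""

    max_iter: int = 100
    rel_tol: float = 1e-4
    n_init: int = 3
    seed: int = 0
    cov_floor: float | None = None   # None: 1e-6 * mean pooled feature variance
    init_method: str = "kmeans"      # "kmeans" | "random"
    covariance: str = "full"         # "full" | "diag"

    def validate(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.init_method not in ("kmeans", "random"):
            raise ValueError("init_method must be 'kmeans' or 'random'")
        if self.covariance not in ("full", "diag"):
            raise ValueError("covariance must be 'full' or 'diag'")


def _as_array(seq) -> np.ndarray:
    if isinstance(seq, FeatureSequence):
        return seq.vectors
    return np.atleast_2d(np.asarray(seq, dtype=float))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def forward_loglik(seq, model: HmmModel) -> float:
    """log P(O | lambda) by the scaled forward recursion.

    alpha_1(j) = pi_j b_j(O_1); alpha_t(j) = [sum_i alpha_{t-1}(i) a_ij]
    b_j(O_t); the likelihood is the sum of the final-step alphas, with
    per-step rescaling accumulated in log space for numerical stability.
    """
    X = _as_array(seq)
    logB = model.log_emission_matrix(X)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transmat)
        lalpha = np.log(model.startprob) + logB[0]
    for t in range(1, X.shape[0]):
        lalpha = logsumexp(lalpha[:, None] + logA, axis=0) + logB[t]
    return float(logsumexp(lalpha))


def viterbi_decode(seq, model: HmmModel) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log-probability.

    Ties are broken toward the lower state index (argmax takes the first
    maximum), making decoding deterministic.
    """
    X = _as_array(seq)
    logB = model.log_emission_matrix(X)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transmat)
        delta = np.log(model.startprob) + logB[0]
    T, N = logB.shape
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA          # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(N)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    score = float(delta[path[-1]])
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path, score


def sample_sequences(model: HmmModel, n_sequences: int, length: int,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Draw observation sequences (and their state paths) from the model."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    seqs, paths = [], []
    for _ in range(n_sequences):
        states = np.empty(length, dtype=int)
        obs = np.empty((length, model.feature_dim))
        s = rng.choice(model.n_states, p=model.startprob)
        for t in range(length):
            states[t] = s
            e = model.emissions[s]
            m = rng.choice(e.n_components, p=e.weights)
            obs[t] = rng.multivariate_normal(e.means[m], e.covariances[m])
            s = rng.choice(model.n_states, p=model.transmat[s])
        seqs.append(obs)
        paths.append(states)
    return seqs, paths


# ---------------------------------------------------------------------------
# EM training
# ---------------------------------------------------------------------------

def _floor_covariance(cov: np.ndarray, floor: float, diag: bool) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    if diag:
        cov = np.diag(np.maximum(np.diag(cov), floor))
        return cov
    lam, V = np.linalg.eigh(cov)
    lam = np.maximum(lam, floor)
    return (V * lam) @ V.T


def _init_transitions(n_states: int, topology: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    if topology == "left-to-right":
        A = np.zeros((n_states, n_states))
        for j in range(n_states - 1):
            A[j, j], A[j, j + 1] = 0.8, 0.2
        A[-1, -1] = 1.0
        pi = np.zeros(n_states)
        pi[0] = 1.0
    elif topology == "ergodic":
        A = np.full((n_states, n_states), 1.0 / n_states)
        pi = np.full(n_states, 1.0 / n_states)
    else:
        raise ValueError("topology must be 'left-to-right' or 'ergodic'")
    return pi, A


def _init_emissions(X_list: list[np.ndarray], n_states: int, M: int,
                    topology: str, floor: float, diag: bool,
                    options: FitOptions, rng: np.random.Generator
                    ) -> list[StateEmission]:
    """Seed emissions: assign samples to states (by within-sequence time
    position for left-to-right, by k-means for ergodic), then k-means the
    mixture components within each state."""
    pooled = np.vstack(X_list)
    p = pooled.shape[1]
    if topology == "left-to-right":
        buckets: list[list[np.ndarray]] = [[] for _ in range(n_states)]
        for X in X_list:
            T = X.shape[0]
            edges = np.linspace(0, T, n_states + 1).round().astype(int)
            for j in range(n_states):
                if edges[j + 1] > edges[j]:
                    buckets[j].append(X[edges[j]:edges[j + 1]])
        state_data = [np.vstack(b) if b else pooled for b in buckets]
    else:
        if options.init_method == "kmeans" and pooled.shape[0] >= n_states:
            km = KMeans(n_clusters=n_states, n_init=1,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(pooled)
            state_data = [pooled[lab == j] if np.any(lab == j) else pooled
                          for j in range(n_states)]
        else:
            state_data = [pooled] * n_states
    pooled_cov = np.cov(pooled.T, ddof=0).reshape(p, p)
    pooled_cov = _floor_covariance(pooled_cov, floor, diag)
    emissions = []
    for j in range(n_states):
        data = state_data[j]
        if options.init_method == "random" or data.shape[0] < M:
            idx = rng.choice(data.shape[0], size=M, replace=data.shape[0] < M)
            means = data[idx]
            covs = np.array([pooled_cov] * M)
        else:
            km = KMeans(n_clusters=M, n_init=1,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(data)
            means = km.cluster_centers_.copy()
            covs = np.empty((M, p, p))
            for m in range(M):
                sub = data[lab == m]
                if sub.shape[0] > p + 1:
                    covs[m] = _floor_covariance(
                        np.cov(sub.T, ddof=0).reshape(p, p), floor, diag)
                else:
                    covs[m] = pooled_cov
        weights = np.full(M, 1.0 / M)
        emissions.append(StateEmission(weights, means, covs))
    return emissions


def _pad_sequences(X_list: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    S = len(X_list)
    lengths = np.array([X.shape[0] for X in X_list])
    Tmax, p = int(lengths.max()), X_list[0].shape[1]
    X = np.zeros((S, Tmax, p))
    mask = np.zeros((S, Tmax), dtype=bool)
    for s, Xs in enumerate(X_list):
        X[s, :Xs.shape[0]] = Xs
        mask[s, :Xs.shape[0]] = True
    return X, mask, lengths


def _e_step(X: np.ndarray, mask: np.ndarray, pi: np.ndarray, A: np.ndarray,
            emissions: list[StateEmission]):
    """Batched forward-backward over padded sequences.

    Padded steps carry emission probability 1 (log 0) so their scaling
    contributions vanish and the backward recursion propagates beta = 1
    through them; per-sequence log-likelihoods and posteriors are exact.
    Returns (total loglik, gamma (S,T,N), xi_sum (N,N), comp_post
    (S,T,N,M): gamma further split over mixture components).
    """
    S, Tmax, p = X.shape
    N = len(emissions)
    M = emissions[0].n_components
    flat = X.reshape(-1, p)
    comp_lp = np.empty((S * Tmax, N, M))
    for j, e in enumerate(emissions):
        comp_lp[:, j, :] = e.component_logpdfs(flat)
    comp_lp = comp_lp.reshape(S, Tmax, N, M)
    logw = np.log(np.maximum([e.weights for e in emissions], 1e-300))  # (N, M)
    logB = logsumexp(comp_lp + logw[None, None], axis=3)               # (S,T,N)
    # component responsibilities within each state
    comp_post = np.exp(comp_lp + logw[None, None] - logB[..., None])
    shift = np.where(mask, logB.max(axis=2), 0.0)                      # (S,T)
    B = np.exp(logB - shift[..., None])
    B[~mask] = 1.0

    alpha = np.empty((S, Tmax, N))
    c = np.empty((S, Tmax))
    a = pi[None, :] * B[:, 0]
    c[:, 0] = np.maximum(a.sum(axis=1), 1e-300)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, Tmax):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = np.maximum(a.sum(axis=1), 1e-300)
        alpha[:, t] = a / c[:, t, None]
    loglik = float((np.log(c)[mask] + shift[mask]).sum())

    beta = np.empty((S, Tmax, N))
    beta[:, -1] = 1.0
    for t in range(Tmax - 2, -1, -1):
        beta[:, t] = ((B[:, t + 1] * beta[:, t + 1]) @ A.T) \
            / c[:, t + 1, None]
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    gamma[~mask] = 0.0

    # xi summed over sequences and valid transitions
    xi_mask = mask[:, 1:] & mask[:, :-1]
    left = alpha[:, :-1] * xi_mask[..., None]
    right = B[:, 1:] * beta[:, 1:] / c[:, 1:, None]
    xi_sum = np.einsum("sti,stj->ij", left, right) * A
    return loglik, gamma, xi_sum, comp_post


def em_fit(seqs: Iterable, n_states: int = 3, n_components: int = 4,
           options: FitOptions | None = None,
           topology: str = "left-to-right"
           ) -> tuple[HmmModel, list[float]]:
    """Multi-sequence EM with seeded restarts; returns the best model and
    its per-iteration log-likelihood trace (non-decreasing within a restart).

    The M-step is the closed-form update of means, covariances, mixture
    weights and transition rows from the forward-backward responsibilities,
    with sums extended over sequences; covariance eigenvalues are floored;
    a component whose responsibility mass collapses is re-seeded at the
    observation the current model fits worst.
    """
    options = options or FitOptions()
    options.validate()
    X_list = [_as_array(s) for s in seqs]
    if not X_list:
        raise ValueError("need at least one training sequence")
    dims = {X.shape[1] for X in X_list}
    if len(dims) != 1:
        raise ValueError("sequences have inconsistent feature dimensions")
    n_obs = sum(X.shape[0] for X in X_list)
    if n_obs < n_states * n_components:
        raise ValueError(
            f"{n_obs} observations cannot support "
            f"{n_states} states x {n_components} components")
    X, mask, _ = _pad_sequences(X_list)
    pooled = np.vstack(X_list)
    floor = options.cov_floor
    if floor is None:
        floor = 1e-6 * float(pooled.var(axis=0).mean())
        floor = max(floor, 1e-12)
    diag = options.covariance == "diag"
    ss = np.random.SeedSequence(options.seed)

    best: tuple[float, HmmModel, list[float]] | None = None
    for child in ss.spawn(options.n_init):
        rng = np.random.default_rng(child)
        pi, A = _init_transitions(n_states, topology)
        emissions = _init_emissions(X_list, n_states, n_components, topology,
                                    floor, diag, options, rng)
        trace: list[float] = []
        for _ in range(options.max_iter):
            ll, gamma, xi_sum, comp_post = _e_step(X, mask, pi, A, emissions)
            trace.append(ll)
            # ---- M-step ----
            w = gamma[..., None] * comp_post          # (S, T, N, M)
            Wf = w[mask]                              # (K, N, M)
            Xf = X[mask]                              # (K, p)
            S0 = Wf.sum(axis=0)                       # (N, M)
            # re-seed collapsed components at the worst-fit observation
            if np.any(S0 < 1e-8):
                flat_ll = logsumexp(
                    np.stack([e.log_density(Xf) for e in emissions], axis=1),
                    axis=1)
                worst = Xf[np.argmin(flat_ll)]
                for j, m in zip(*np.where(S0 < 1e-8)):
                    logger.info("re-seeding empty component (%d, %d)", j, m)
                    e = emissions[j]
                    means = e.means.copy()
                    means[m] = worst
                    covs = e.covariances.copy()
                    covs[m] = _floor_covariance(
                        np.cov(pooled.T, ddof=0).reshape(
                            pooled.shape[1], pooled.shape[1]),
                        floor, diag)
                    weights = np.maximum(e.weights, 1e-3)
                    emissions[j] = StateEmission(weights / weights.sum(),
                                                 means, covs)
                continue
            S1 = np.einsum("kjm,kp->jmp", Wf, Xf)
            S2 = np.einsum("kjm,kp,kq->jmpq", Wf, Xf, Xf)
            new_emissions = []
            for j in range(n_states):
                means = S1[j] / S0[j][:, None]
                covs = np.empty_like(S2[j])
                for m in range(n_components):
                    cov = S2[j, m] / S0[j, m] - np.outer(means[m], means[m])
                    covs[m] = _floor_covariance(cov, floor, diag)
                weights = S0[j] / S0[j].sum()
                new_emissions.append(StateEmission(weights, means, covs))
            emissions = new_emissions
            row = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(row > 0, xi_sum / np.maximum(row, 1e-300), A)
            A /= A.sum(axis=1, keepdims=True)
            pi_new = gamma[:, 0].mean(axis=0)
            pi = pi_new / pi_new.sum()
            if len(trace) > 1:
                prev = trace[-2]
                if abs(trace[-1] - prev) <= options.rel_tol * abs(prev):
                    break
        # final evaluation after the last M-step
        ll, *_ = _e_step(X, mask, pi, A, emissions)
        trace.append(ll)
        model = HmmModel(n_states=n_states, startprob=pi, transmat=A,
                         emissions=emissions, topology=topology)
        if best is None or ll > best[0]:
            best = (ll, model, trace)
    assert best is not None
    return best[1], best[2]
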