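"""Replicator dynamics with mutation, iterated-learning Markov chains,
and their shared equilibrium.

The continuous model tracks population proportions x over a finite set
of cultural hypotheses:

    dx_i/dt = sum_j q_ij f_j x_j - phi x_i,    phi = sum_j f_j x_j,

where q_ij is the probability that a learner ends up with hypothesis i
after learning from a teacher holding hypothesis j (columns of Q sum to
one).  With uniform fitness (f = 1) the system is linear ("neutral"
model) and converges to the leading eigenvector of Q — which is also
the stationary distribution of the iterated-learning Markov chain whose
transition matrix is Q.  For learners that sample hypotheses from a
Bayesian posterior, that stationary distribution equals the learners'
prior; this module verifies the identity by exact enumeration on a
small ring-structured hypothesis space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class HypothesisSpace:
    """Enumerable hypothesis set with a prior and a noisy-labelling
    likelihood.

    ``labels`` is a (K, N) 0/1 array: hypothesis h assigns category
    labels[h, s] to site s.  A teacher holding h emits data as i.i.d.
    (site, label) observations: the site uniform over the N sites, the
    label flipped with probability ``noise_eps``.
    """

    labels: np.ndarray
    prior: np.ndarray
    noise_eps: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.prior = np.asarray(self.prior, dtype=np.float64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a (n_hypotheses, n_sites) array")
        if self.prior.shape != (self.labels.shape[0],):
            raise ValueError("prior length must match the number of hypotheses")
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")
        if not 0.0 <= self.noise_eps < 0.5:
            raise ValueError("noise_eps must lie in [0, 0.5)")

    @property
    def n_hypotheses(self) -> int:
        return self.labels.shape[0]

    @property
    def n_sites(self) -> int:
        return self.labels.shape[1]


def ring_space(n_sites: int, beta: float = 1.0, noise_eps: float = 0.1) -> HypothesisSpace:
    """All binary labellings of an N-site ring, with a smoothness prior
    prior(h) proportional to exp(-beta * boundary count).

    The ring is the smallest colour-like (circular) structure; the prior
    favours hypotheses with few category boundaries, so contiguous
    two-category partitions are exactly the high-prior hypotheses.
    """
    if n_sites < 2 or n_sites > 16:
        raise ValueError("ring enumeration supported for 2..16 sites")
    codes = np.arange(2 ** n_sites)
    labels = ((codes[:, None] >> np.arange(n_sites)[None, :]) & 1).astype(np.int8)
    boundaries = (labels != np.roll(labels, -1, axis=1)).sum(axis=1)
    w = np.exp(-beta * boundaries)
    return HypothesisSpace(labels, w / w.sum(), noise_eps)


# --- replicator dynamics ---------------------------------------------------


def replicator_derivative(x: np.ndarray, Q: np.ndarray,
                          f: Optional[np.ndarray] = None) -> np.ndarray:
    """dx_i/dt = sum_j q_ij f_j x_j - phi x_i with phi the mean fitness.
    The subtraction keeps x on the simplex: the rates sum to zero."""
    x = np.asarray(x, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if Q.shape != (x.size, x.size):
        raise ValueError("Q must be square and match the state dimension")
    f = np.ones_like(x) if f is None else np.asarray(f, dtype=np.float64)
    if f.shape != x.shape:
        raise ValueError("fitness vector must match the state dimension")
    fx = f * x
    return Q @ fx - fx.sum() * x


def integrate_dynamics(x0: np.ndarray, Q: np.ndarray,
                       f: Optional[np.ndarray] = None,
                       t_end: float = 50.0, n_points: int = 101,
                       rtol: float = 1e-12, atol: float = 1e-14
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the mutation-selection dynamics to ``t_end``.

    Returns (times, states) with states of shape (n_points, K); every
    state stays on the simplex to within the integration tolerance.
    With f = 1 this is the neutral (linear) model.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite initial state")

    def rhs(_t, x):
        d = replicator_derivative(x, Q, f)
        # sum(d) = phi (1 - sum(x)) vanishes on the simplex; subtracting
        # sum(d) * x is therefore exact there and suppresses the slow
        # floating-point drift of sum(x) away from 1
        return d - d.sum() * x

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), x0, method="DOP853",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y.T


def stationary_distribution(Q: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """The eigenvalue-1 eigenvector of a column-stochastic Q, normalized
    to a probability vector.

    Raises if the unit eigenvalue is not simple or the chain is periodic
    (another eigenvalue on the unit circle), i.e. when no unique
    stationary distribution exists.
    """
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if not np.allclose(Q.sum(axis=0), 1.0, atol=1e-10):
        raise ValueError("Q must be column-stochastic")
    eigvals, eigvecs = np.linalg.eig(Q)
    unit = np.abs(eigvals - 1.0) < tol
    on_circle = np.abs(np.abs(eigvals) - 1.0) < tol
    if unit.sum() != 1 or on_circle.sum() != 1:
        raise ValueError("no unique stationary distribution "
                         "(reducible or periodic transition matrix)")
    v = np.real(eigvecs[:, np.argmax(unit)])
    v = v / v.sum()
    if v.min() < -1e-10:
        raise ValueError("leading eigenvector is not a probability vector")
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


# --- Bayesian learners and the mutation matrix -----------------------------


def _posteriors_and_likelihoods(space: HypothesisSpace, sites: np.ndarray,
                                label_seqs: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray]:
    """For one site sequence: P(d | h) and posterior P(h | d) for every
    label sequence.  Returns (likelihood, posterior), both (2^m, K)."""
    eps = space.noise_eps
    H = space.labels[:, sites]  # (K, m)
    match = (label_seqs[:, None, :] == H[None, :, :]).sum(axis=2)  # (2^m, K)
    m = sites.size
    lik = (1.0 - eps) ** match * eps ** (m - match)
    post = lik * space.prior[None, :]
    post /= post.sum(axis=1, keepdims=True)
    return lik, post


def build_q_matrix(space: HypothesisSpace, data_size: int,
                   n_samples: Optional[int] = None,
                   seed: int = 0) -> np.ndarray:
    """Q[i, j] = P(learner adopts i | teacher holds j) for
    posterior-sampling Bayesian learners seeing ``data_size``
    observations per generation.

    Exact by enumeration over all (site, label) data sequences when
    ``n_samples`` is None; otherwise Monte-Carlo over ``n_samples``
    datasets per teacher (with sampling error ~ 1/sqrt(n_samples)).
    Columns sum to one.
    """
    K, N = space.n_hypotheses, space.n_sites
    if data_size < 0:
        raise ValueError("data_size must be non-negative")
    if data_size == 0:
        return np.tile(space.prior[:, None], (1, K))
    if n_samples is not None:
        return _q_matrix_mc(space, data_size, n_samples, seed)
    m = data_size
    label_seqs = np.array(list(itertools.product((0, 1), repeat=m)), dtype=np.int8)
    Q = np.zeros((K, K))
    for sites in itertools.product(range(N), repeat=m):
        lik, post = _posteriors_and_likelihoods(space, np.array(sites), label_seqs)
        # sum over data of P(adopt i | d) P(labels | j); sites are uniform
        Q += post.T @ lik
    Q /= float(N) ** m
    return Q


def _q_matrix_mc(space: HypothesisSpace, data_size: int, n_samples: int,
                 seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    K, N = space.n_hypotheses, space.n_sites
    eps = space.noise_eps
    Q = np.zeros((K, K))
    for j in range(K):
        for _ in range(n_samples):
            sites = rng.integers(N, size=data_size)
            labels = space.labels[j, sites] ^ (rng.random(data_size) < eps)
            match = (space.labels[:, sites] == labels[None, :]).sum(axis=1)
            lik = (1.0 - eps) ** match * eps ** (data_size - match)
            post = lik * space.prior
            post /= post.sum()
            Q[:, j] += post
        Q[:, j] /= n_samples
    return Q


def simulate_markov_chain(Q: np.ndarray, steps: int, seed: int = 0,
                          start: Optional[int] = None) -> np.ndarray:
    """Sample a hypothesis sequence from the iterated-learning chain with
    transition matrix Q (column-stochastic); returns ``steps`` indices."""
    Q = np.asarray(Q, dtype=np.float64)
    rng = np.random.default_rng(seed)
    K = Q.shape[0]
    cum = np.cumsum(Q, axis=0)
    state = int(rng.integers(K)) if start is None else int(start)
    out = np.empty(steps, dtype=np.int64)
    us = rng.random(steps)
    for t in range(steps):
        state = int(np.searchsorted(cum[:, state], us[t]))
        out[t] = state
    return out


def empirical_distribution(states: np.ndarray, n_hypotheses: int) -> np.ndarray:
    counts = np.bincount(states, minlength=n_hypotheses)
    return counts / counts.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
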