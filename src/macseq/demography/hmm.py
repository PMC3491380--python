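"""Scaled forward-backward kernels for the discretised SMC HMM.

The hidden state of a bin is the atomic time interval containing its
TMRCA.  Transitions have the jump structure
``A[k, j] = stay_k * delta_kj + (1 - stay_k) * jump_j`` — with
probability ``exp(-rho * tbar_k)`` no recombination occurs within the
bin and the state persists; otherwise the new state is drawn from the
length-biased coalescent prior ``jump_j ~ pi_j * tbar_j`` (full
resampling; the length bias makes the chain stationary around the plain
coalescent prior ``pi``, which is also the first-bin distribution).
Emissions are ``P(K | k) = 1 - exp(-theta * tbar_k)``, ``N`` bins are
uninformative (emission probability 1 in every state).

Kernels use scaled (normalised) forward variables so likelihoods never
underflow; forward and backward recursions exploit the rank-one-plus-
diagonal transition structure for O(n) work per bin, while the expected
transition-count matrix is accumulated densely for the M-step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["HmmParams", "forward", "backward_stats", "sequence_stats",
           "transition_matrix"]


class HmmParams:
    """Dense per-state HMM quantities derived from model parameters."""

    def __init__(self, stay: np.ndarray, pi0: np.ndarray, jump: np.ndarray,
                 emit: np.ndarray):
        self.stay = np.ascontiguousarray(stay, dtype=np.float64)
        self.pi0 = np.ascontiguousarray(pi0, dtype=np.float64)
        self.jump = np.ascontiguousarray(jump, dtype=np.float64)
        self.emit = np.ascontiguousarray(emit, dtype=np.float64)  # (n, 3)
        for p in (self.pi0, self.jump):
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("state distributions must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.pi0)


def transition_matrix(stay: np.ndarray, jump: np.ndarray) -> np.ndarray:
    """Dense transition matrix (for oracles and the M-step Q function)."""
    n = len(jump)
    return stay[:, None] * np.eye(n) + (1.0 - stay)[:, None] * jump[None, :]


@njit(cache=True)
def _forward_kernel(obs, stay, pi0, jump, emit):
    L = obs.shape[0]
    n = pi0.shape[0]
    alpha = np.empty((L, n))
    c = np.empty(L)
    loglik = 0.0
    for k in range(n):
        alpha[0, k] = pi0[k] * emit[k, obs[0]]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for i in range(1, L):
        leave = 0.0
        for k in range(n):
            leave += alpha[i - 1, k] * (1.0 - stay[k])
        tot = 0.0
        for k in range(n):
            a = (alpha[i - 1, k] * stay[k] + leave * jump[k]) * emit[k, obs[i]]
            alpha[i, k] = a
            tot += a
        c[i] = tot
        for k in range(n):
            alpha[i, k] /= tot
    for i in range(L):
        loglik += np.log(c[i])
    return loglik, alpha, c


@njit(cache=True)
def _backward_kernel(obs, stay, jump, emit, alpha, c):
    """Backward pass accumulating EM sufficient statistics.

    Returns (xi_sum, emit_counts, gamma0, loglik_check) where ``xi_sum``
    is the expected transition-count matrix summed over positions,
    ``emit_counts[k, s]`` the expected number of bins in state k with
    symbol s, and ``gamma0`` the posterior of the first bin.
    """
    L = obs.shape[0]
    n = jump.shape[0]
    beta = np.ones(n)
    xi = np.zeros((n, n))
    emit_counts = np.zeros((n, 3))
    gamma = np.empty(n)
    # last position posterior
    tot = 0.0
    for k in range(n):
        gamma[k] = alpha[L - 1, k]
        tot += gamma[k]
    for k in range(n):
        emit_counts[k, obs[L - 1]] += gamma[k] / tot
    for i in range(L - 2, -1, -1):
        o = obs[i + 1]
        # w[j] = emit[j, o] * beta[j] / c[i+1]
        w = np.empty(n)
        dot = 0.0
        for j in range(n):
            w[j] = emit[j, o] * beta[j] / c[i + 1]
            dot += jump[j] * w[j]
        # xi accumulation: diagonal stay part + rank-one jump part
        for k in range(n):
            u = alpha[i, k] * (1.0 - stay[k])
            for j in range(n):
                xi[k, j] += u * jump[j] * w[j]
            xi[k, k] += alpha[i, k] * stay[k] * w[k]
        # new beta and posterior at i
        tot = 0.0
        for k in range(n):
            beta[k] = stay[k] * w[k] + (1.0 - stay[k]) * dot
            gamma[k] = alpha[i, k] * beta[k]
            tot += gamma[k]
        for k in range(n):
            emit_counts[k, obs[i]] += gamma[k] / tot
    g0sum = 0.0
    for k in range(n):
        g0sum += alpha[0, k] * beta[k]
    gamma0 = np.empty(n)
    for k in range(n):
        gamma0[k] = alpha[0, k] * beta[k] / g0sum
    return xi, emit_counts, gamma0


def forward(obs: np.ndarray, params: HmmParams):
    """Scaled forward pass: (log-likelihood, alpha-hat, scaling factors)."""
    obs = np.ascontiguousarray(obs, dtype=np.uint8)
    return _forward_kernel(obs, params.stay, params.pi0, params.jump, params.emit)


def backward_stats(obs: np.ndarray, params: HmmParams, alpha, c):
    obs = np.ascontiguousarray(obs, dtype=np.uint8)
    return _backward_kernel(obs, params.stay, params.jump, params.emit, alpha, c)


def sequence_stats(sequences: list[np.ndarray], params: HmmParams):
    """Forward-backward over independent sequences, summing statistics.

    Returns (loglik, xi_sum, emit_counts, gamma0_sum, n_sequences).
    """
    n = params.n_states
    loglik = 0.0
    xi = np.zeros((n, n))
    emit_counts = np.zeros((n, 3))
    gamma0 = np.zeros(n)
    for obs in sequences:
        if len(obs) == 0:
            continue
        ll, alpha, c = forward(obs, params)
        loglik += ll
        x, e, g0 = backward_stats(obs, params, alpha, c)
        xi += x
        emit_counts += e
        gamma0 += g0
    return loglik, xi, emit_counts, gamma0
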