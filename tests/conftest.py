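"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from cimcs import generate_random_cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance():
    """A well-conditioned random instance (N=12, M=8, 3 active entries)."""
    return generate_random_cs(12, 8 / 12, 0.25, nu=0.0, seed=7)


def brute_force_local_field(A, y, weights):
    """O(N²M) double-loop evaluation of h_r = −Σ_{r'≠r}Σ_k A A w_{r'} + Σ_k A y."""
    M, N = A.shape
    h = np.zeros(N)
    for r in range(N):
        for rp in range(N):
            if rp == r:
                continue
            h[r] -= sum(A[k, r] * A[k, rp] * weights[rp] for k in range(M))
        h[r] += sum(A[k, r] * y[k] for k in range(M))
    return h


def objective_hamiltonian(A, y, R, sigma, lam):
    """½‖y − A(σ∘R)‖² + λ‖σ‖₀ − ½‖y‖², the expanded QUBO energy."""
    w = np.asarray(sigma, float) * np.asarray(R, float)
    r = y - A @ w
    return 0.5 * float(r @ r) + lam * float(np.sum(sigma)) - 0.5 * float(y @ y)


def enumerate_ground_state(A, y, R, lam):
    """Exhaustive minimum of the QUBO energy over all 2^N supports (N ≤ 16)."""
    M, N = A.shape
    best = np.inf
    best_sigma = np.zeros(N)
    # vectorised: energies of all supports at once
    sigmas = ((np.arange(2 ** N)[:, None] >> np.arange(N)) & 1).astype(float)
    W = sigmas * R[None, :]
    res = y[None, :] - W @ A.T
    energies = 0.5 * np.einsum("ij,ij->i", res, res) \
        + lam * sigmas.sum(axis=1) - 0.5 * float(y @ y)
    idx = int(np.argmin(energies))
    return float(energies[idx]), sigmas[idx]
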