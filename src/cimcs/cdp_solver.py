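"""Classical digital processor (CDP): restricted least squares at fixed support.

Given the binary support σ produced by the Ising machine, the continuous
signal values R solve the stationarity system of the QUBO Hamiltonian at
fixed σ,

    R_r Σ_k (A_r^k)² = σ_r ℍ_r,
    ℍ_r = −Σ_{r'≠r} (AᵀA)_{rr'} R_{r'} σ_{r'} + (Aᵀy)_r,

i.e. the normal equations of min_R ½‖y − A(σ∘R)‖² restricted to the active
set.  Two solvers are provided: a relaxed Jacobi iteration (the protocol
used on random Gaussian instances) and conjugate gradients on an implicit
operator (required at MRI scale).  Entries of R outside the support are
returned as zero — only σ∘R is ever consumed downstream.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .observation import as_observation

__all__ = ["binarise", "cdp_local_field", "solve_jacobi", "solve_cgd",
           "CDPConvergenceWarning"]


class CDPConvergenceWarning(UserWarning):
    pass


def binarise(v: np.ndarray) -> np.ndarray:
    """Heaviside binarisation σ_r = 1 if v_r > 0 else 0 (H(0) = 0)."""
    v = np.asarray(v)
    if not np.all(np.isfinite(v)):
        raise ValueError("binarise requires finite input")
    return (v > 0).astype(np.int8)


def cdp_local_field(R: np.ndarray, sigma: np.ndarray, A, y=None) -> np.ndarray:
    """CDP local field ℍ_r = −Σ_{r'≠r} (AᵀA)_{rr'} R_{r'} σ_{r'} + (Aᵀy)_r."""
    obs = as_observation(A, y)
    w = np.asarray(R, float) * np.asarray(sigma, float)
    return -(obs.gram_matvec(w) - obs.gram_diag * w) + obs.zeeman


def solve_jacobi(A, y, sigma, dt_c: float = 0.1, iters: int = 100,
                 R0: Optional[np.ndarray] = None) -> np.ndarray:
    """Relaxed Jacobi iteration toward R_r Σ_k (A_r^k)² = σ_r ℍ_r.

    Each sweep updates all entries simultaneously,
    R ← R + Δt_c (σ ∘ ℍ(R)/d − R), with d the Gram diagonal and Δt_c the
    relaxation step (0.1 with 100 sweeps in the reference protocol).
    """
    obs = as_observation(A, y)
    sigma = np.asarray(sigma, float)
    d = obs.gram_diag
    bad = np.flatnonzero((sigma > 0) & (d <= 0))
    if bad.size:
        raise ValueError(
            f"zero column norm on active index {int(bad[0])}: "
            "the restricted system is singular")
    d_safe = np.where(d > 0, d, 1.0)
    R = np.zeros(obs.n) if R0 is None else np.asarray(R0, float).copy()
    for _ in range(iters):
        H = cdp_local_field(R, sigma, obs)
        R = R + dt_c * (sigma * H / d_safe - R)
    return R * sigma


def solve_cgd(A, y=None, sigma=None, tol: float = 1e-10, max_iter: int = 10_000,
              R0: Optional[np.ndarray] = None, callback=None) -> np.ndarray:
    """Conjugate-gradient solution of the restricted normal equations.

    Accepts a dense matrix or an implicit-operator observation model.  The
    operator is extended by the identity off the support so that it stays
    symmetric positive (semi)definite on the full coordinate space; the
    right-hand side is zero there, so inactive entries solve to zero.
    """
    obs = as_observation(A, y)
    sigma = np.asarray(sigma, float)
    N = obs.n

    def mv(v):
        w = sigma * v
        return sigma * obs.gram_matvec(w) + (v - w)

    op = LinearOperator((N, N), matvec=mv, dtype=float)
    b = sigma * obs.zeeman
    x0 = None if R0 is None else sigma * np.asarray(R0, float)
    x, info = cg(op, b, x0=x0, rtol=tol, atol=0.0, maxiter=max_iter,
                 callback=callback)
    if info > 0:
        res = float(np.linalg.norm(b - op @ x) / max(np.linalg.norm(b), 1e-300))
        warnings.warn(
            f"CGD did not reach rtol={tol:g} within {max_iter} iterations "
            f"(final relative residual {res:.3e})", CDPConvergenceWarning)
    return x * sigma
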