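"""Classical baselines: single-flip simulated annealing and L1 (LASSO).

The SA baseline runs Metropolis dynamics on the support vector σ against
the same QUBO Hamiltonian the Ising machine minimises, with the signal
estimate R held fixed.  The energy change of a single flip is maintained
incrementally in O(N), so one Monte-Carlo step is one proposed flip.

The LASSO baseline minimises ½‖y − Ax‖² + λ₁‖x‖₁ with FISTA (proximal
gradient with Nesterov momentum and function-value restarts), expressed
through the Gram operator so it also runs on the implicit MRI operators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .observation import as_observation

__all__ = ["AnnealSchedule", "sa_metropolis", "lasso_fista",
           "soft_threshold", "FISTAConvergenceWarning"]


class FISTAConvergenceWarning(UserWarning):
    pass


@dataclass
class AnnealSchedule:
    """Cooling schedule for the Metropolis baseline.

    ``zero_temperature`` accepts only downhill moves (ties with probability
    ½); ``exponential`` interpolates the temperature geometrically from
    ``T_start`` down to ``T_end`` over ``n_steps`` proposed flips.
    """
    kind: str = "exponential"
    T_start: float = 0.02
    T_end: float = 0.00002
    n_steps: int = 46_000

    def __post_init__(self) -> None:
        if self.kind not in ("zero_temperature", "exponential"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if not (self.T_start >= self.T_end >= 0):
            raise ValueError("require T_start >= T_end >= 0")
        if self.kind == "exponential" and not (self.T_start > 0 and self.T_end > 0):
            raise ValueError("exponential cooling requires positive temperatures")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def temperature(self, step: int) -> float:
        if self.kind == "zero_temperature":
            return 0.0
        if self.n_steps == 1:
            return self.T_start
        frac = step / (self.n_steps - 1)
        return self.T_start * (self.T_end / self.T_start) ** frac


def sa_metropolis(obs, R, lam: float, schedule: AnnealSchedule,
                  seed=None, sigma0: Optional[np.ndarray] = None,
                  return_energy: bool = False):
    """Single-flip Metropolis on σ ∈ {0,1}^N at fixed signal estimate R.

    Flipping spin r changes the energy by

        ΔH = s (φ_r + ½ d_r R_r² − z_r R_r + λ),   s = ±1,
        φ_r = Σ_{r'≠r} (AᵀA)_{rr'} R_r R_{r'} σ_{r'},

    with d the Gram diagonal; φ is updated incrementally after each
    accepted flip.  The run starts from the empty support unless
    ``sigma0`` is given.
    """
    if not hasattr(obs, "gram_matvec"):
        raise TypeError("sa_metropolis expects an ObservationModel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = np.asarray(R, float)
    N = obs.n
    G = obs.gram_dense()
    Q = G * np.outer(R, R)
    diag = np.diag(Q).copy()
    np.fill_diagonal(Q, 0.0)
    # linear (field) part of the energy change of switching a spin on
    lin = 0.5 * diag - obs.zeeman * R + lam

    sigma = (np.zeros(N) if sigma0 is None
             else np.asarray(sigma0, float).copy())
    phi = Q @ sigma
    energies = [] if return_energy else None
    # pre-draw per-step randomness in fixed order for bit-reproducibility
    for step in range(schedule.n_steps):
        r = int(rng.integers(N))
        s = 1.0 - 2.0 * sigma[r]
        dH = s * (phi[r] + lin[r])
        T = schedule.temperature(step)
        if T == 0.0:
            accept = dH < 0 or (dH == 0 and rng.random() < 0.5)
        else:
            accept = dH <= 0 or rng.random() < math.exp(-dH / T)
        if accept:
            sigma[r] += s
            phi += s * Q[:, r]
        if return_energy:
            energies.append(dH if accept else 0.0)
    sigma = sigma.astype(np.int8)
    if return_energy:
        return sigma, np.cumsum(energies)
    return sigma


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Elementwise sign(z)·max(|z| − t, 0), the proximal map of t‖·‖₁."""
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _lipschitz(obs, rng: np.random.Generator, iters: int = 60) -> float:
    """Largest eigenvalue of the Gram operator via power iteration."""
    v = rng.standard_normal(obs.n)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(iters):
        w = obs.gram_matvec(v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 1.0
        lam = nw
        v = w / nw
    return float(lam)


def lasso_fista(A, y=None, lam1: float = 0.0, tol: float = 1e-10,
                max_iter: int = 10_000, x0: Optional[np.ndarray] = None):
    """FISTA minimiser of ½‖y − Ax‖² + λ₁‖x‖₁.

    Works on dense matrices and on implicit Gram operators alike, since the
    smooth part ½xᵀAᵀAx − (Aᵀy)ᵀx only needs the Gram matvec and the
    matched filter.  A function-value restart keeps the objective
    non-increasing.
    """
    if lam1 < 0:
        raise ValueError("lam1 must be >= 0")
    obs = as_observation(A, y)
    rng = np.random.default_rng(0)  # only for the power iteration
    L = max(_lipschitz(obs, rng), 1e-12)
    z = obs.zeeman

    def smooth(x):
        return 0.5 * x @ obs.gram_matvec(x) - z @ x

    def objective(x):
        return smooth(x) + lam1 * np.abs(x).sum()

    x = np.zeros(obs.n) if x0 is None else np.asarray(x0, float).copy()
    v = x.copy()
    t = 1.0
    f_prev = objective(x)
    for it in range(max_iter):
        grad = obs.gram_matvec(v) - z
        x_new = soft_threshold(v - grad / L, lam1 / L)
        f_new = objective(x_new)
        if f_new > f_prev:  # restart momentum
            t = 1.0
            v = x.copy()
            grad = obs.gram_matvec(v) - z
            x_new = soft_threshold(v - grad / L, lam1 / L)
            f_new = objective(x_new)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        v = x_new + (t - 1.0) / t_new * (x_new - x)
        step = np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-12)
        x, t, f_prev = x_new, t_new, f_new
        if step < tol:
            break
    else:
        warnings.warn(
            f"FISTA did not converge to tol={tol:g} in {max_iter} iterations",
            FISTAConvergenceWarning)
    return x
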