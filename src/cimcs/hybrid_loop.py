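"""Alternating minimisation between the Ising machine and the classical stage.

L0-regularised compressed sensing is the two-fold problem

    min_{σ∈{0,1}^N} min_{R∈R^N}  ½‖y − A(σ∘R)‖² + λ‖σ‖₀,

whose element-wise expansion is a QUBO Hamiltonian with a Zeeman term.  The
hybrid solver alternates: the CIM optimises the support σ at fixed R, the
CDP solves the restricted least squares for R at fixed σ, while the
threshold η = √(2λ) (Maxwell rule) is ramped down across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .observation import ObservationModel, as_observation
from . import sde_engine
from .sde_engine import CIMConfig, run_cim, threshold_schedule
from . import cdp_solver

__all__ = ["RunResult", "IterationRecord", "run_hybrid",
           "direction_cosine", "rmse", "hamiltonian", "default_r_init"]


@dataclass
class IterationRecord:
    iteration: int
    eta: float
    hamiltonian: float
    direction_cosine: Optional[float] = None
    rmse: Optional[float] = None
    support_size: int = 0


@dataclass
class RunResult:
    """Final state and per-iteration history of one alternating run.

    ``best_sigma``/``best_R`` hold the lowest-energy configuration visited
    across the iterations (best-seen bookkeeping, judged by the QUBO
    energy); ``sigma``/``R`` are the last iterate.
    """
    sigma: np.ndarray
    R: np.ndarray
    records: List[IterationRecord] = field(default_factory=list)
    config: Optional[dict] = None
    model: str = ""
    seed: Optional[int] = None
    best_sigma: Optional[np.ndarray] = None
    best_R: Optional[np.ndarray] = None

    @property
    def final(self) -> IterationRecord:
        return self.records[-1]


def direction_cosine(xi: np.ndarray, sigma: np.ndarray) -> float:
    """Support overlap Σ ξ_r σ_r / √(Σ ξ_r · Σ σ_r) ∈ [0, 1].

    Both supports empty → 1 (they agree); exactly one empty → 0.
    """
    xi = np.asarray(xi, float)
    sigma = np.asarray(sigma, float)
    if xi.shape != sigma.shape:
        raise ValueError("supports must have equal length")
    sx, ss = xi.sum(), sigma.sum()
    if sx == 0 and ss == 0:
        return 1.0
    if sx == 0 or ss == 0:
        return 0.0
    return float((xi * sigma).sum() / np.sqrt(sx * ss))


def rmse(R: np.ndarray, sigma: np.ndarray, x: np.ndarray, xi: np.ndarray) -> float:
    """Root-mean-square error √((1/N) Σ (R_r σ_r − x_r ξ_r)²)."""
    R, sigma = np.asarray(R, float), np.asarray(sigma, float)
    x, xi = np.asarray(x, float), np.asarray(xi, float)
    return float(np.sqrt(np.mean((R * sigma - x * xi) ** 2)))


def hamiltonian(R: np.ndarray, sigma: np.ndarray, A, y=None,
                lam: float = 0.0) -> float:
    """QUBO energy of a configuration (σ, R).

    H = ½‖y − A(σ∘R)‖² + λ‖σ‖₀ − ½‖y‖²
      = Σ_{r<r'} (AᵀA)_{rr'} R_r R_{r'} σ_r σ_{r'}
        + Σ_r (½ Σ_k (A_r^k)² R_r² − (Aᵀy)_r R_r + λ) σ_r.

    The diagonal self-energy ½ d_r R_r² σ_r is linear in the binary σ and
    belongs to the external-field part of the spin Hamiltonian; without it
    the energy is not the stationarity objective the classical stage
    solves.  λ = η²/2 under the Maxwell rule.
    """
    obs = as_observation(A, y)
    sigma = np.asarray(sigma, float)
    w = np.asarray(R, float) * sigma
    quad = 0.5 * (w @ obs.gram_matvec(w))
    return float(quad - obs.zeeman @ w + lam * sigma.sum())


def default_r_init(model: str, obs: ObservationModel) -> np.ndarray:
    """Model-dependent initial signal estimate.

    The open-loop model starts from R = 0: its injection |h| − η is driven
    by the Zeeman term alone and bootstraps a first support.  The CAC
    injection j e (R h − η²/2 √(τ/g²)) vanishes into a uniform negative
    drive at R = 0 (σ would stay empty forever), so the CAC models start
    from the column-normalised matched filter Aᵀy / diag(AᵀA).
    """
    if model == "wigner_ol":
        return np.zeros(obs.n)
    d = np.where(obs.gram_diag > 0, obs.gram_diag, 1.0)
    return obs.zeeman / d


def run_hybrid(model: str, obs: ObservationModel, n_iters: int,
               cfg: CIMConfig, R_init=None, cdp: str = "jacobi",
               cdp_kwargs: Optional[dict] = None,
               rng: Optional[np.random.Generator] = None) -> RunResult:
    """Run the alternating minimisation for ``n_iters`` iterations.

    Parameters
    ----------
    model
        CIM variant: ``wigner_ol``, ``cac_wigner`` or ``positive_p``.
    obs
        The compressed-sensing instance.
    n_iters
        Number of alternating (CIM → CDP) iterations.
    cfg
        SDE/schedule parameters; the threshold ramp uses
        ``cfg.eta_init, cfg.eta_end, cfg.velo``.
    R_init
        Initial signal estimate; an array, or one of ``"default"``,
        ``"zeros"``, ``"matched"``, ``"lasso"``.  ``None`` means
        ``"default"`` (see :func:`default_r_init`).
    cdp
        Least-squares solver for the classical stage, ``"jacobi"`` or
        ``"cgd"``.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cdp_kwargs = dict(cdp_kwargs or {})

    if R_init is None or (isinstance(R_init, str) and R_init == "default"):
        R = default_r_init(model, obs)
    elif isinstance(R_init, str):
        if R_init == "zeros":
            R = np.zeros(obs.n)
        elif R_init == "matched":
            d = np.where(obs.gram_diag > 0, obs.gram_diag, 1.0)
            R = obs.zeeman / d
        elif R_init == "lasso":
            from .baselines import lasso_fista
            R = lasso_fista(obs, lam1=cfg.eta_init ** 2 / 2.0)
        else:
            raise ValueError(f"unknown R_init {R_init!r}")
    else:
        R = np.asarray(R_init, float).copy()

    has_truth = obs.x_true is not None and obs.xi_true is not None
    d_safe = np.where(obs.gram_diag > 0, obs.gram_diag, 1.0)
    records: List[IterationRecord] = []
    sigma = np.zeros(obs.n, dtype=np.int8)
    best_H = None
    best_sigma = best_R = None
    R_cim = R
    for i in range(n_iters):
        eta = threshold_schedule(i, cfg.eta_init, cfg.eta_end, cfg.velo)
        try:
            sigma, _ = run_cim(model, obs, R_cim, eta, cfg, rng=rng)
            if cdp == "jacobi":
                R = cdp_solver.solve_jacobi(obs, None, sigma, R0=R, **cdp_kwargs)
            elif cdp == "cgd":
                R = cdp_solver.solve_cgd(obs, None, sigma, R0=R, **cdp_kwargs)
            else:
                raise ValueError(f"unknown CDP solver {cdp!r}")
        except sde_engine.CIMDivergenceError as exc:
            raise RuntimeError(f"hybrid iteration {i}: {exc}") from exc
        # The CDP masks inactive entries to zero; the CAC injection
        # j e (R h − η²/2 √(τ/g²)) is strictly negative wherever R_r = 0,
        # so a masked R would make the support monotonically shrinking.
        # The signal hypothesis handed to the CIM therefore carries, on the
        # inactive entries, the one-site conditional least-squares value
        # ℍ_r/d_r (the matched filter of the current residual), which lets
        # the machine both add and drop entries as the threshold ramps down.
        # The open-loop injection |h| − η needs no such completion.
        if model == "wigner_ol":
            R_cim = R
        else:
            H_field = cdp_solver.cdp_local_field(R, sigma, obs)
            R_cim = R + (1 - sigma) * H_field / d_safe
        lam = eta ** 2 / 2.0
        rec = IterationRecord(
            iteration=i, eta=eta,
            hamiltonian=hamiltonian(R, sigma, obs, lam=lam),
            support_size=int(sigma.sum()))
        if has_truth:
            rec.direction_cosine = direction_cosine(obs.xi_true, sigma)
            rec.rmse = rmse(R, sigma, obs.x_true, obs.xi_true)
        records.append(rec)
        # best-seen bookkeeping (meaningful on a constant threshold, where
        # the energies of all iterates share one λ)
        if best_H is None or rec.hamiltonian < best_H:
            best_H = rec.hamiltonian
            best_sigma, best_R = sigma.copy(), R.copy()
    return RunResult(sigma=sigma, R=R, records=records,
                     config=cfg.to_dict(), model=model, seed=cfg.seed,
                     best_sigma=best_sigma, best_R=best_R)
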