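"""Coherent-Ising-machine SDE models for QUBO support estimation.

Three phase-space models of a network of degenerate optical parametric
oscillator (DOPO) pulses are integrated with the Euler–Maruyama method:

* ``wigner_ol``   — truncated-Wigner in-phase/quadrature SDEs with an
  open-loop (OL) injection, thresholded local-field feedback;
* ``cac_wigner``  — in-phase Wigner mean/variance SDEs with chaotic
  amplitude control (CAC): a multiplicative error variable e_r forces the
  squared measured amplitude g²μ̃² toward a target τ, destabilising local
  minima of the energy landscape;
* ``positive_p``  — Positive-P mean/fluctuation SDEs with the same CAC loop.

Each pulse encodes one entry of the binary support vector σ of an
L0-regularised compressed-sensing problem; the injection field is the
gradient of the QUBO Hamiltonian with a Zeeman (matched-filter) term.
Under CAC the Zeeman term is scaled by √(τ/g²) so that it balances the
mutual-interaction term once the amplitudes stabilise around ±√(τ/g²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .observation import ObservationModel, as_observation

__all__ = [
    "CIMConfig",
    "WignerOLState",
    "CACWignerState",
    "PositivePState",
    "MeasuredAmplitudes",
    "CIMDivergenceError",
    "pump_schedule_cac",
    "pump_schedule_ol",
    "threshold_schedule",
    "ol_local_field",
    "ol_injection",
    "cac_local_field",
    "cac_injection",
    "measured_amplitudes",
    "step_wigner_ol",
    "step_cac_wigner",
    "step_positive_p",
    "run_cim",
    "MODELS",
]

MODELS = ("wigner_ol", "cac_wigner", "positive_p")


class CIMDivergenceError(RuntimeError):
    """Raised when the SDE state becomes non-finite during integration."""

    def __init__(self, step: int, model: str):
        self.step = step
        self.model = model
        super().__init__(f"{model} integration diverged at step {step}")


@dataclass
class CIMConfig:
    """All SDE, schedule and feedback parameters of one CIM run.

    Times are measured in units of the signal photon lifetime.

    Parameters
    ----------
    g2
        Nonlinear saturation parameter g²; sets the oscillation photon
        number ~τ/g² and the quantum-noise amplitude.  The experiments use
        the low-noise regime g² = 1e-7.
    j
        Normalised out-coupling rate for the homodyne measurement.
    K, K_tilde
        Feedback strength of the CAC injection (K) and of the open-loop
        injection (K̃).
    beta
        Rate of the CAC error-variable dynamics de/dt = −β(g²μ̃² − τ)e.
        Must be fast enough for the error gain to sustain weakly driven
        pulses within the integration window; 0.5 per lifetime sits on a
        broad plateau of support-recovery quality.
    tau
        CAC target for the squared normalised amplitude g²μ̃².
    dt, n_steps
        Euler–Maruyama time increment and number of steps; the CAC models
        default to 0.02 × 1000 (20 lifetimes), the open-loop model uses
        0.1 × 50 (5 lifetimes).
    p_thr, d
        Sigmoid pump schedule parameters for the CAC models: the pump rises
        from p_thr − d to p_thr + d around t = 4.
    eta_init, eta_end, velo
        Linear threshold schedule across alternating iterations
        η_i = max[η_init(1 − i/velo), η_end].
    seed
        Seed for the run's random generator when none is supplied.
    """

    g2: float = 1e-7
    j: float = 1.0
    K: float = 0.01
    K_tilde: float = 0.25
    beta: float = 0.5
    tau: float = 1.0
    dt: float = 0.02
    n_steps: int = 1000
    p_thr: float = 1.0
    d: float = 0.6
    eta_init: float = 0.05
    eta_end: float = 0.05
    velo: int = 51
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.g2 > 0 and self.j > 0 and self.dt > 0 and self.tau > 0
                and self.beta > 0):
            raise ValueError("g2, j, dt, tau and beta must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.eta_init >= self.eta_end >= 0):
            raise ValueError("require eta_init >= eta_end >= 0")
        if self.velo < 1:
            raise ValueError("velo must be >= 1")

    @property
    def g(self) -> float:
        return math.sqrt(self.g2)

    def replace(self, **kw) -> "CIMConfig":
        d = asdict(self)
        d.update(kw)
        return CIMConfig(**d)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CIMConfig":
        """Build from a flat key/value mapping (e.g. a parsed config file)."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown CIM config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

@dataclass
class WignerOLState:
    """In-phase (c) and quadrature (s) normalised amplitudes, open-loop model."""
    c: np.ndarray
    s: np.ndarray


@dataclass
class CACWignerState:
    """Mean amplitudes μ, variances V and CAC error variables e (Wigner)."""
    mu: np.ndarray
    V: np.ndarray
    e: np.ndarray


@dataclass
class PositivePState:
    """Mean amplitudes μ, fluctuation variances n, m and errors e (Positive-P)."""
    mu: np.ndarray
    n: np.ndarray
    m: np.ndarray
    e: np.ndarray


@dataclass
class MeasuredAmplitudes:
    """Homodyne-measured amplitudes μ̃ and the normal draw they share with the drift noise."""
    mu_tilde: np.ndarray
    draw: np.ndarray


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def pump_schedule_cac(t: float, p_thr: float = 1.0, d: float = 0.6) -> float:
    """Sigmoid pump schedule p(t) = (p_thr − d) + 2d / (1 + exp(−(t−4)/2))."""
    return (p_thr - d) + 2.0 * d / (1.0 + math.exp(-(t - 4.0) / 2.0))


def pump_schedule_ol(t: float) -> float:
    """Quadratic open-loop pump schedule p(t) = 1.5 (t/5)²; reaches 1.5 at t = 5."""
    return 1.5 * (t / 5.0) ** 2


def threshold_schedule(i: int, eta_init: float, eta_end: float, velo: int) -> float:
    """Linear threshold ramp η_i = max[η_init (1 − i/velo), η_end]."""
    return max(eta_init * (1.0 - i / velo), eta_end)


# ---------------------------------------------------------------------------
# local fields and injections
# ---------------------------------------------------------------------------

def _heaviside(v: np.ndarray) -> np.ndarray:
    """Heaviside with H(0) = 0 — the support binarisation convention."""
    return (v > 0).astype(float)


def ol_local_field(c: np.ndarray, R: np.ndarray, A, y=None) -> np.ndarray:
    """Open-loop local field h_r = −Σ_{r'≠r} (AᵀA)_{rr'} R_{r'} H(c_{r'}) + (Aᵀy)_r.

    The diagonal exclusion is carried out as a full Gram matvec minus the
    diagonal contribution, costing O(NM) instead of O(N²M).
    """
    obs = as_observation(A, y)
    w = np.asarray(R, float) * _heaviside(np.asarray(c, float))
    return -(obs.gram_matvec(w) - obs.gram_diag * w) + obs.zeeman


def ol_injection(h: np.ndarray, eta: float) -> np.ndarray:
    """Open-loop injection (dc/dt)_inj = |h| − η."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return np.abs(h) - eta


def cac_local_field(mu_tilde: np.ndarray, R: np.ndarray, A, y=None,
                    tau: float = 1.0, g2: float = 1e-7) -> np.ndarray:
    """CAC local field with the √(τ/g²)-scaled Zeeman term.

    h_r = −Σ_{r'≠r} (AᵀA)_{rr'} R_{r'} ½(μ̃_{r'} + √(τ/g²)) + √(τ/g²)(Aᵀy)_r
    """
    obs = as_observation(A, y)
    s = math.sqrt(tau / g2)
    w = np.asarray(R, float) * 0.5 * (np.asarray(mu_tilde, float) + s)
    return -(obs.gram_matvec(w) - obs.gram_diag * w) + s * obs.zeeman


def cac_injection(h: np.ndarray, R: np.ndarray, e: np.ndarray, eta: float,
                  tau: float, g2: float, j: float) -> np.ndarray:
    """CAC injection (dμ/dt)_inj = j e (R h − (η²/2)√(τ/g²))."""
    return j * np.asarray(e, float) * (
        np.asarray(R, float) * np.asarray(h, float)
        - 0.5 * eta ** 2 * math.sqrt(tau / g2)
    )


def measured_amplitudes(mu: np.ndarray, draw: np.ndarray, j: float,
                        dt: float) -> MeasuredAmplitudes:
    """Measured amplitude μ̃ = μ + √(1/4j) W_R under the shared-draw discretisation.

    The white-noise process W_R is represented on the time grid as
    w/√Δt for a standard-normal draw w, the same draw that enters the
    drift noise as √Δt·w, so μ̃ = μ + √(1/(4 j Δt))·w.
    """
    mu_tilde = mu + math.sqrt(1.0 / (4.0 * j * dt)) * draw
    return MeasuredAmplitudes(mu_tilde=mu_tilde, draw=draw)


# ---------------------------------------------------------------------------
# Euler–Maruyama steppers
# ---------------------------------------------------------------------------

def step_wigner_ol(state: WignerOLState, p: float, injection: np.ndarray,
                   cfg: CIMConfig,
                   noise: Tuple[np.ndarray, np.ndarray]) -> WignerOLState:
    """One Euler–Maruyama step of the open-loop Wigner SDEs.

    dc = [−1 + p − (c² + s²)]c dt + K̃·inj dt + g√(c² + s² + ½) dW₁
    ds = [−1 − p − (c² + s²)]s dt            + g√(c² + s² + ½) dW₂
    """
    c, s = state.c, state.s
    dt = cfg.dt
    amp2 = c * c + s * s
    sig = cfg.g * np.sqrt(amp2 + 0.5) * math.sqrt(dt)
    w1, w2 = noise
    c_new = c + ((-1.0 + p - amp2) * c + cfg.K_tilde * injection) * dt + sig * w1
    s_new = s + (-1.0 - p - amp2) * s * dt + sig * w2
    return WignerOLState(c=c_new, s=s_new)


def step_cac_wigner(state: CACWignerState, p: float, injection: np.ndarray,
                    cfg: CIMConfig,
                    noise: np.ndarray) -> Tuple[CACWignerState, MeasuredAmplitudes]:
    """One Euler–Maruyama step of the CAC Wigner mean/variance SDEs.

    dμ = [−(1 − p + j)μ − g²μ³ + K·inj] dt + √j (V − ½) dW
    dV = [−2(1 − p + j)V − 6g²μ²V + 1 + j + 2g²μ² − 2j(V − ½)²] dt
    de = −β(g²μ̃² − τ) e dt,   μ̃ = μ + √(1/4j) W_R  (shared draw)
    """
    mu, V, e = state.mu, state.V, state.e
    dt, g2, j = cfg.dt, cfg.g2, cfg.j
    meas = measured_amplitudes(mu, noise, j, dt)
    mu_new = mu + (-(1.0 - p + j) * mu - g2 * mu ** 3 + cfg.K * injection) * dt \
        + math.sqrt(j) * (V - 0.5) * math.sqrt(dt) * noise
    V_new = V + (-2.0 * (1.0 - p + j) * V - 6.0 * g2 * mu ** 2 * V
                 + 1.0 + j + 2.0 * g2 * mu ** 2 - 2.0 * j * (V - 0.5) ** 2) * dt
    e_new = e - cfg.beta * (g2 * meas.mu_tilde ** 2 - cfg.tau) * e * dt
    return CACWignerState(mu=mu_new, V=V_new, e=e_new), meas


def step_positive_p(state: PositivePState, p: float, injection: np.ndarray,
                    cfg: CIMConfig,
                    noise: np.ndarray) -> Tuple[PositivePState, MeasuredAmplitudes]:
    """One Euler–Maruyama step of the Positive-P SDEs with CAC feedback.

    dμ = [−(1 − p + j)μ − g²μ(μ² + 2n + m) + K·inj] dt + √j (m + n) dW
    dn = [−2(1 + j)n + 2pm − 2g²μ²(2n + m) − j(m + n)²] dt
    dm = [−2(1 + j)m + 2pn − 2g²μ²(2m + n) + p − g²(μ² + m) − j(m + n)²] dt

    The error update de = −β(g²μ̃² − τ)e dt is identical to the Wigner CAC model.
    """
    mu, n, m, e = state.mu, state.n, state.m, state.e
    dt, g2, j = cfg.dt, cfg.g2, cfg.j
    meas = measured_amplitudes(mu, noise, j, dt)
    mn2 = (m + n) ** 2
    mu_new = mu + (-(1.0 - p + j) * mu - g2 * mu * (mu ** 2 + 2.0 * n + m)
                   + cfg.K * injection) * dt \
        + math.sqrt(j) * (m + n) * math.sqrt(dt) * noise
    n_new = n + (-2.0 * (1.0 + j) * n + 2.0 * p * m
                 - 2.0 * g2 * mu ** 2 * (2.0 * n + m) - j * mn2) * dt
    m_new = m + (-2.0 * (1.0 + j) * m + 2.0 * p * n
                 - 2.0 * g2 * mu ** 2 * (2.0 * m + n)
                 + p - g2 * (mu ** 2 + m) - j * mn2) * dt
    e_new = e - cfg.beta * (g2 * meas.mu_tilde ** 2 - cfg.tau) * e * dt
    return PositivePState(mu=mu_new, n=n_new, m=m_new, e=e_new), meas


# ---------------------------------------------------------------------------
# full trajectory
# ---------------------------------------------------------------------------

def run_cim(model: str, obs: ObservationModel, R: np.ndarray, eta: float,
            cfg: CIMConfig, rng: Optional[np.random.Generator] = None,
            record: bool = False):
    """Integrate one CIM trajectory and binarise its final amplitudes.

    Parameters
    ----------
    model
        One of ``wigner_ol``, ``cac_wigner``, ``positive_p``.
    obs
        The compressed-sensing instance (dense or implicit operators).
    R
        Current signal estimate entering the local field.
    eta
        Injection threshold (η = √(2λ) under the Maxwell rule).
    cfg
        SDE and schedule parameters.
    rng
        Random generator; defaults to one seeded from ``cfg.seed``.
    record
        When true, per-step trajectories of the amplitudes, errors and the
        mean normalised squared amplitude are returned.

    Returns
    -------
    sigma : ndarray of 0/1
        Heaviside binarisation of the final measured amplitudes μ̃ (CAC
        models) or final in-phase amplitudes c (open-loop model).
    trajectory : dict
        Empty unless ``record``; otherwise arrays keyed ``amplitude``,
        ``error`` (CAC only) and ``mean_g2_mu_tilde_sq``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown CIM model {model!r}; expected one of {MODELS}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N = obs.n
    R = np.asarray(R, dtype=float)
    dt = cfg.dt
    traj_amp = [] if record else None
    traj_err = [] if record else None
    traj_g2mu2 = [] if record else None

    if model == "wigner_ol":
        state = WignerOLState(c=np.zeros(N), s=np.zeros(N))
        for k in range(cfg.n_steps):
            p = pump_schedule_ol(k * dt)
            h = ol_local_field(state.c, R, obs)
            inj = ol_injection(h, eta)
            w1 = rng.standard_normal(N)
            w2 = rng.standard_normal(N)
            state = step_wigner_ol(state, p, inj, cfg, (w1, w2))
            if not np.all(np.isfinite(state.c)):
                raise CIMDivergenceError(k, model)
            if record:
                traj_amp.append(state.c.copy())
                traj_g2mu2.append(float(np.mean(cfg.g2 * state.c ** 2)))
        final = state.c
    else:
        if model == "cac_wigner":
            state = CACWignerState(mu=np.zeros(N), V=np.full(N, 0.5), e=np.ones(N))
            stepper = step_cac_wigner
        else:
            state = PositivePState(mu=np.zeros(N), n=np.zeros(N),
                                   m=np.zeros(N), e=np.ones(N))
            stepper = step_positive_p
        meas = None
        for k in range(cfg.n_steps):
            p = pump_schedule_cac(k * dt, cfg.p_thr, cfg.d)
            w = rng.standard_normal(N)
            mu_tilde = measured_amplitudes(state.mu, w, cfg.j, dt).mu_tilde
            h = cac_local_field(mu_tilde, R, obs, tau=cfg.tau, g2=cfg.g2)
            inj = cac_injection(h, R, state.e, eta, cfg.tau, cfg.g2, cfg.j)
            state, meas = stepper(state, p, inj, cfg, w)
            if not np.all(np.isfinite(state.mu)):
                raise CIMDivergenceError(k, model)
            if record:
                traj_amp.append(meas.mu_tilde.copy())
                traj_err.append(state.e.copy())
                traj_g2mu2.append(float(np.mean(cfg.g2 * meas.mu_tilde ** 2)))
        final = meas.mu_tilde

    sigma = _heaviside(final).astype(np.int8)
    trajectory = {}
    if record:
        trajectory["amplitude"] = np.asarray(traj_amp)
        trajectory["mean_g2_mu_tilde_sq"] = np.asarray(traj_g2mu2)
        if traj_err:
            trajectory["error"] = np.asarray(traj_err)
    return sigma, trajectory
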