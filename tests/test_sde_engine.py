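"""Unit and property tests for the CIM SDE engine."""

import math

import numpy as np
import pytest

from cimcs import CIMConfig, run_cim, direction_cosine
from cimcs.sde_engine import (
    pump_schedule_cac, pump_schedule_ol, threshold_schedule,
    ol_local_field, ol_injection, cac_local_field, cac_injection,
    step_wigner_ol, step_cac_wigner, step_positive_p,
    WignerOLState, CACWignerState, PositivePState,
)

from conftest import brute_force_local_field


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t, p_thr, d, expected", [
    (4.0, 1.0, 0.6, 1.0),                                 # sigmoid midpoint
    (1e4, 1.0, 0.6, 1.6),                                 # saturation limit
    (0.0, 1.0, 0.4, 0.6 + 0.8 / (1.0 + math.exp(2.0))),   # direct evaluation
])
def test_pump_schedule_cac_values(t, p_thr, d, expected):
    assert pump_schedule_cac(t, p_thr, d) == pytest.approx(expected, abs=1e-12)


def test_pump_schedule_cac_monotone():
    ts = np.linspace(0, 20, 200)
    ps = [pump_schedule_cac(t, 1.0, 0.6) for t in ts]
    assert np.all(np.diff(ps) > 0)


@pytest.mark.parametrize("t, expected", [(5.0, 1.5), (0.0, 0.0), (2.5, 0.375)])
def test_pump_schedule_ol_values(t, expected):
    assert pump_schedule_ol(t) == pytest.approx(expected, abs=1e-12)


def test_threshold_schedule():
    assert threshold_schedule(0, 0.8, 0.18, 51) == pytest.approx(0.8)
    assert threshold_schedule(51, 0.8, 0.18, 51) == pytest.approx(0.18)
    # constant-threshold configuration
    for i in (0, 5, 100):
        assert threshold_schedule(i, 0.022, 0.022, 11) == pytest.approx(0.022)
    etas = [threshold_schedule(i, 0.8, 0.18, 51) for i in range(80)]
    assert np.all(np.diff(etas) <= 0)
    assert etas[-1] == pytest.approx(0.18)


# ---------------------------------------------------------------------------
# local fields and injections vs brute force
# ---------------------------------------------------------------------------

def test_ol_local_field_matches_bruteforce(rng):
    M, N = 8, 12
    A = rng.standard_normal((M, N))
    y = rng.standard_normal(M)
    R = rng.standard_normal(N)
    c = rng.standard_normal(N)
    H = (c > 0).astype(float)
    expected = brute_force_local_field(A, y, R * H)
    got = ol_local_field(c, R, A, y)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_ol_local_field_trivial_cases(rng):
    N, M = 6, 4
    A = np.zeros((M, N))
    y = rng.standard_normal(M)
    assert np.all(ol_local_field(rng.standard_normal(N),
                                 rng.standard_normal(N), A, y) == 0)
    # all c <= 0: interaction term dies, pure matched filter remains
    A = rng.standard_normal((M, N))
    c = -np.abs(rng.standard_normal(N))
    got = ol_local_field(c, rng.standard_normal(N), A, y)
    np.testing.assert_allclose(got, A.T @ y, atol=1e-12)


def test_cac_local_field_matches_bruteforce(rng):
    M, N = 8, 12
    tau, g2 = 1.0, 1e-7
    s = math.sqrt(tau / g2)
    A = rng.standard_normal((M, N))
    y = rng.standard_normal(M)
    R = rng.standard_normal(N)
    mu_tilde = rng.standard_normal(N) * s
    expected = brute_force_local_field(A, np.zeros(M),
                                       R * 0.5 * (mu_tilde + s)) + s * (A.T @ y)
    got = cac_local_field(mu_tilde, R, A, y, tau=tau, g2=g2)
    np.testing.assert_allclose(got, expected, rtol=1e-10)


def test_cac_local_field_zeeman_only(rng):
    """μ̃ = −√(τ/g²) kills the interaction term entirely."""
    M, N = 5, 9
    tau, g2 = 0.21, 1e-7
    s = math.sqrt(tau / g2)
    A = rng.standard_normal((M, N))
    y = rng.standard_normal(M)
    got = cac_local_field(np.full(N, -s), rng.standard_normal(N), A, y,
                          tau=tau, g2=g2)
    np.testing.assert_allclose(got, s * (A.T @ y), rtol=1e-12)


def test_injections():
    h = np.array([0.05, 0.0, -0.3])
    np.testing.assert_allclose(ol_injection(h, 0.05), [0.0, -0.05, 0.25])
    assert ol_injection(np.array([-0.3]), 0.1)[0] == pytest.approx(0.2)

    e = np.array([0.0, 2.0])
    R = np.array([1.0, 1.0])
    h2 = np.array([5.0, 1.0])
    # e = 0 kills the injection; with τ = g² and η = 0 the product is j e R h
    inj = cac_injection(h2, R, e, eta=0.0, tau=1e-7, g2=1e-7, j=1.0)
    np.testing.assert_allclose(inj, [0.0, 2.0])
    # threshold cancellation: R h = η²/2 √(τ/g²)
    s = math.sqrt(1.0 / 1e-6)
    inj = cac_injection(np.array([(0.2 ** 2 / 2) * s]), np.array([1.0]),
                        np.array([3.0]), eta=0.2, tau=1.0, g2=1e-6, j=1.0)
    assert inj[0] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

def _cfg(**kw):
    base = dict(dt=0.02, n_steps=10, g2=1e-7)
    base.update(kw)
    return CIMConfig(**base)


def test_step_wigner_ol_deterministic_fixed_point():
    cfg = _cfg(dt=0.05)
    state = WignerOLState(c=np.array([1.0]), s=np.array([0.0]))
    zeros = np.zeros(1)
    new = step_wigner_ol(state, p=2.0, injection=zeros, cfg=cfg,
                         noise=(zeros, zeros))
    assert new.c[0] == pytest.approx(1.0, abs=1e-14)
    assert new.s[0] == pytest.approx(0.0, abs=1e-14)


def test_step_wigner_ol_pure_injection_drift():
    cfg = _cfg(dt=0.1, K_tilde=0.25)
    v = np.array([0.7, -0.3])
    zeros = np.zeros(2)
    state = WignerOLState(c=zeros.copy(), s=zeros.copy())
    new = step_wigner_ol(state, p=1.0, injection=v, cfg=cfg, noise=(zeros, zeros))
    np.testing.assert_allclose(new.c, 0.25 * v * 0.1, atol=1e-15)


def test_step_wigner_ol_one_step_formula(rng):
    """One Euler–Maruyama step against a hand evaluation of the update rule."""
    cfg = _cfg(dt=0.07, K_tilde=0.4, g2=1e-4)
    c = rng.standard_normal(3)
    s = rng.standard_normal(3)
    inj = rng.standard_normal(3)
    w1, w2 = rng.standard_normal(3), rng.standard_normal(3)
    p = 1.3
    new = step_wigner_ol(WignerOLState(c.copy(), s.copy()), p, inj, cfg, (w1, w2))
    amp2 = c ** 2 + s ** 2
    sig = math.sqrt(1e-4) * np.sqrt(amp2 + 0.5) * math.sqrt(0.07)
    c_exp = c + ((-1 + p - amp2) * c + 0.4 * inj) * 0.07 + sig * w1
    s_exp = s + (-1 - p - amp2) * s * 0.07 + sig * w2
    np.testing.assert_allclose(new.c, c_exp, rtol=1e-13)
    np.testing.assert_allclose(new.s, s_exp, rtol=1e-13)


def test_wigner_noise_free_fixed_point_convergence():
    """Noise- and injection-free dynamics settle at c = √(p−1), s = 0."""
    cfg = _cfg(dt=0.05, g2=1e-12)
    p = 2.0
    state = WignerOLState(c=np.array([0.3]), s=np.array([0.2]))
    zeros = np.zeros(1)
    for _ in range(2000):
        state = step_wigner_ol(state, p, zeros, cfg, (zeros, zeros))
    assert state.c[0] == pytest.approx(math.sqrt(p - 1.0), abs=1e-6)
    assert abs(state.s[0]) < 1e-6


def test_step_cac_wigner_error_dynamics():
    cfg = _cfg(dt=0.02, beta=0.5, tau=1.0, g2=1e-7, j=1.0)
    s = math.sqrt(cfg.tau / cfg.g2)
    zeros = np.zeros(1)
    # g²μ̃² = τ with zero draw → e unchanged
    state = CACWignerState(mu=np.array([s]), V=np.array([0.5]), e=np.array([2.0]))
    new, meas = step_cac_wigner(state, 1.0, zeros, cfg, zeros)
    assert new.e[0] == pytest.approx(2.0, rel=1e-12)
    # g²μ̃² < τ with zero draw → e strictly increases
    state = CACWignerState(mu=np.array([0.0]), V=np.array([0.5]), e=np.array([2.0]))
    new, _ = step_cac_wigner(state, 1.0, zeros, cfg, zeros)
    assert new.e[0] > 2.0


def test_step_cac_wigner_one_step_formula(rng):
    cfg = _cfg(dt=0.02, beta=0.7, tau=0.5, g2=1e-5, j=0.8, K=0.3)
    mu = rng.standard_normal(4) * 10
    V = 0.5 + 0.1 * rng.random(4)
    e = 1.0 + rng.random(4)
    inj = rng.standard_normal(4)
    w = rng.standard_normal(4)
    p = 0.9
    new, meas = step_cac_wigner(CACWignerState(mu.copy(), V.copy(), e.copy()),
                                p, inj, cfg, w)
    dt, g2, j = 0.02, 1e-5, 0.8
    mu_t = mu + math.sqrt(1.0 / (4 * j * dt)) * w
    np.testing.assert_allclose(meas.mu_tilde, mu_t, rtol=1e-13)
    mu_exp = mu + (-(1 - p + j) * mu - g2 * mu ** 3 + 0.3 * inj) * dt \
        + math.sqrt(j) * (V - 0.5) * math.sqrt(dt) * w
    V_exp = V + (-2 * (1 - p + j) * V - 6 * g2 * mu ** 2 * V + 1 + j
                 + 2 * g2 * mu ** 2 - 2 * j * (V - 0.5) ** 2) * dt
    e_exp = e - 0.7 * (g2 * mu_t ** 2 - 0.5) * e * dt
    np.testing.assert_allclose(new.mu, mu_exp, rtol=1e-13)
    np.testing.assert_allclose(new.V, V_exp, rtol=1e-13)
    np.testing.assert_allclose(new.e, e_exp, rtol=1e-13)


def test_step_positive_p_origin_fixed_point():
    cfg = _cfg(dt=0.02)
    zeros = np.zeros(2)
    state = PositivePState(mu=zeros.copy(), n=zeros.copy(), m=zeros.copy(),
                           e=np.ones(2))
    new, _ = step_positive_p(state, p=0.0, injection=zeros, cfg=cfg, noise=zeros)
    np.testing.assert_allclose(new.mu, 0.0)
    np.testing.assert_allclose(new.n, 0.0)
    np.testing.assert_allclose(new.m, 0.0)


def test_step_positive_p_one_step_formula(rng):
    cfg = _cfg(dt=0.03, beta=0.4, tau=0.8, g2=1e-6, j=1.2, K=0.2)
    mu = rng.standard_normal(3) * 5
    n = 0.1 * rng.random(3)
    m = 0.1 * rng.random(3)
    e = 1.0 + rng.random(3)
    inj = rng.standard_normal(3)
    w = rng.standard_normal(3)
    p = 1.1
    new, meas = step_positive_p(
        PositivePState(mu.copy(), n.copy(), m.copy(), e.copy()), p, inj, cfg, w)
    dt, g2, j = 0.03, 1e-6, 1.2
    mn2 = (m + n) ** 2
    mu_exp = mu + (-(1 - p + j) * mu - g2 * mu * (mu ** 2 + 2 * n + m)
                   + 0.2 * inj) * dt + math.sqrt(j) * (m + n) * math.sqrt(dt) * w
    n_exp = n + (-2 * (1 + j) * n + 2 * p * m
                 - 2 * g2 * mu ** 2 * (2 * n + m) - j * mn2) * dt
    m_exp = m + (-2 * (1 + j) * m + 2 * p * n - 2 * g2 * mu ** 2 * (2 * m + n)
                 + p - g2 * (mu ** 2 + m) - j * mn2) * dt
    np.testing.assert_allclose(new.mu, mu_exp, rtol=1e-13)
    np.testing.assert_allclose(new.n, n_exp, rtol=1e-13)
    np.testing.assert_allclose(new.m, m_exp, rtol=1e-13)
    mu_t = mu + math.sqrt(1.0 / (4 * j * dt)) * w
    np.testing.assert_allclose(new.e, e - 0.4 * (g2 * mu_t ** 2 - 0.8) * e * dt,
                               rtol=1e-13)


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------

def _support_instance(N=80, alpha=0.6, a=0.3, seed=0):
    from cimcs import generate_random_cs
    obs = generate_random_cs(N, alpha, a, 0.0, seed=seed)
    return obs, obs.x_true * obs.xi_true


def test_error_variables_stay_positive():
    obs, R = _support_instance()
    cfg = CIMConfig(dt=0.02, n_steps=400)
    _, traj = run_cim("cac_wigner", obs, R, 0.05, cfg,
                      rng=np.random.default_rng(3), record=True)
    assert np.all(traj["error"] > 0)


def test_cac_amplitude_stabilisation():
    """Time-averaged g²μ̃² of the driven pulses stays within 50% of τ over
    the second half of a run (the control loop equalises the amplitudes)."""
    obs, R = _support_instance(N=100, a=0.6)
    cfg = CIMConfig(dt=0.02, n_steps=1000, tau=1.0)
    _, traj = run_cim("cac_wigner", obs, R, 0.05, cfg,
                      rng=np.random.default_rng(4), record=True)
    amp = traj["amplitude"][500:, obs.xi_true.astype(bool)]
    mean_sq = np.mean(cfg.g2 * amp ** 2)
    assert abs(mean_sq - cfg.tau) < 0.5 * cfg.tau


def test_wigner_and_positive_p_supports_agree():
    """The two CAC representations give near-identical supports at g² = 1e-7."""
    obs, R = _support_instance(N=100, seed=5)
    cfg = CIMConfig(dt=0.02, n_steps=1000)
    sig_w, _ = run_cim("cac_wigner", obs, R, 0.05, cfg,
                       rng=np.random.default_rng(9))
    sig_p, _ = run_cim("positive_p", obs, R, 0.05, cfg,
                       rng=np.random.default_rng(9))
    agreement = np.mean(sig_w == sig_p)
    assert agreement >= 0.9


def test_run_cim_support_quality():
    """CAC support estimation reaches high overlap with the truth."""
    obs, R = _support_instance(N=200, alpha=0.6, a=0.6, seed=2)
    cfg = CIMConfig(dt=0.02, n_steps=1000)
    sigma, _ = run_cim("cac_wigner", obs, R, 0.05, cfg,
                       rng=np.random.default_rng(1))
    assert direction_cosine(obs.xi_true, sigma) > 0.9


def test_run_cim_rejects_unknown_model(small_instance):
    with pytest.raises(ValueError):
        run_cim("mean_field", small_instance, np.zeros(12), 0.05, CIMConfig())


def test_run_cim_reproducible(small_instance):
    R = small_instance.x_true * small_instance.xi_true
    cfg = CIMConfig(dt=0.02, n_steps=100, seed=42)
    s1, _ = run_cim("cac_wigner", small_instance, R, 0.05, cfg)
    s2, _ = run_cim("cac_wigner", small_instance, R, 0.05, cfg)
    np.testing.assert_array_equal(s1, s2)


def test_config_validation():
    with pytest.raises(ValueError):
        CIMConfig(g2=-1.0)
    with pytest.raises(ValueError):
        CIMConfig(eta_init=0.1, eta_end=0.2)
    with pytest.raises(ValueError):
        CIMConfig(n_steps=0)
    cfg = CIMConfig.from_mapping({"dt": 0.1, "n_steps": 50})
    assert cfg.dt == 0.1
    with pytest.raises(ValueError):
        CIMConfig.from_mapping({"not_a_key": 1})
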