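# Methods

## Problem

L0-regularised compressed sensing asks for the sparsest explanation of a
set of linear measurements:

    min_{σ∈{0,1}^N} min_{R∈R^N}  ½‖y − A(σ∘R)‖² + λ‖σ‖₀,

with observation matrix A (M×N, M < N), support vector σ and signal values
R.  The optimisation over σ is a quadratic unconstrained binary
optimisation (QUBO) with an external (Zeeman) field, which this package
hands to a simulated coherent Ising machine (CIM) — a network of
degenerate optical parametric oscillator (DOPO) pulses — while the
continuous optimisation over R at fixed σ is a restricted least-squares
problem solved classically.  The two stages alternate; the injection
threshold η is related to the penalty by the Maxwell rule λ = η²/2 and is
ramped down linearly across iterations, η_i = max[η_init(1 − i/velo), η_end].

## CIM models

Three phase-space SDE models are integrated with Euler–Maruyama:

* **Open-loop Wigner** (`wigner_ol`): in-phase/quadrature amplitudes
  (c_r, s_r) with pump p(t) = 1.5(t/5)², injection K̃(|h_r| − η) and a
  local field h whose interaction term binarises the in-phase amplitudes
  with a Heaviside function (H(0) = 0).  Integration: Δt = 0.1 over 5
  photon lifetimes (50 steps).
* **CAC Wigner** (`cac_wigner`): mean/variance dynamics (μ_r, V_r) with
  chaotic amplitude control: a multiplicative error variable obeying
  de_r/dt = −β(g²μ̃_r² − τ)e_r multiplies the injection
  j e_r (R_r h_r − (η²/2)√(τ/g²)), forcing each squared measured amplitude
  toward the target τ and destabilising local minima.  The Zeeman term is
  scaled by √(τ/g²) so interaction and field balance once amplitudes
  stabilise at ±√(τ/g²).  Pump: sigmoid (p_thr − d) + 2d/(1 + e^{−(t−4)/2}).
  Integration: Δt = 0.02 over 20 lifetimes (1000 steps).
* **Positive-P** (`positive_p`): mean amplitudes plus the two fluctuation
  variances (n_r, m_r); same CAC loop.  At g² = 1e-7 its supports agree
  with the Wigner CAC model on ≳90% of entries for matched noise draws.

Measurement discretisation: one standard-normal draw w_r per pulse per
step serves both as the SDE noise increment √Δt·w_r and as the white-noise
sample in the measured amplitude μ̃_r = μ_r + √(1/(4jΔt))·w_r; the support
is the Heaviside binarisation of the final μ̃ (CAC) or final c (open loop).

### Parameter defaults and why

| parameter | default | role |
|---|---|---|
| g² | 1e-7 | saturation / quantum-noise scale (low-noise regime) |
| j | 1 | homodyne out-coupling rate (not printed; order-one choice) |
| K | 0.01 | CAC feedback strength (the value printed for the MRI runs) |
| K̃ | 0.25 | open-loop feedback strength (printed for the MRI runs) |
| β | 0.5 | CAC error-growth rate per lifetime |
| τ | 1 | amplitude target (0.21 or 0.15 in the noisy benchmark presets) |
| Δt, steps | 0.02 × 1000 (CAC), 0.1 × 50 (OL) | stated integration grids |
| p_thr, d | 1, 0.6 (random data) / 0.4 (MRI) | pump schedule |

β is never printed.  The error gain must bridge the gap between the weak
injection drive K·j·e·O(1) and the loss (1 − p + j) ≈ 0.4 within the
20-lifetime window; at K = 0.01 this requires e to grow by ~10²–10³, i.e.
an exponential rate βτ of order one half or more.  Support-recovery
quality is flat across β ∈ [0.5, 5] at τ = 1 and degrades only at the
sluggish corner β ≲ 0.2, so β = 0.5 is the default, and the MRI driver
uses β = 1 (constant-threshold runs leave less time to pin marginal
pulses).  Euler positivity of e is guaranteed in practice because
|β(g²μ̃² − τ)Δt| ≪ 1 in every regime exercised.

## The alternating loop

Each iteration runs one full CIM trajectory at the current threshold η_i,
binarises it into σ, and re-solves the signal by relaxed Jacobi iteration
(random-matrix instances: Δt_c = 0.1, 100 sweeps) or conjugate gradients
on the restricted normal equations (MRI scale, implicit operators, cap
10 000 iterations).  Inactive entries of the CDP solution are zero.

Two reconstruction choices were genuinely open:

* **Initial signal estimate.**  The open-loop model starts from R = 0 (its
  injection |h| − η bootstraps a support from the Zeeman term alone).  The
  CAC injection j e (R_r h_r − (η²/2)√(τ/g²)) collapses to a uniform
  negative drive at R = 0 and the machine would never leave the empty
  support, so the CAC models start from the column-normalised matched
  filter Aᵀy/diag(AᵀA); a LASSO start (used in the MRI pipeline) is also
  selectable.
* **Signal hypothesis handed to the CIM.**  For the same sign reason, a
  σ-masked R would make the CAC support monotonically shrinking, which is
  incompatible with a decreasing threshold schedule (the optimal support
  grows as η falls).  The hybrid loop therefore completes the masked CDP
  solution with the one-site conditional least-squares value ℍ_r/d_r on
  the inactive entries before each CAC CIM call — the matched filter of
  the current residual.  Only σ∘R is ever reported.

The energy recorded per iteration is H = ½‖y − A(σ∘R)‖² + λ‖σ‖₀ − ½‖y‖².
Written as a spin Hamiltonian this contains, besides the r < r' coupling
and the Zeeman term, a diagonal self-energy ½d_r R_r² σ_r that is linear
in the binary σ; it is kept because the CDP stationarity system
R_r d_r = σ_r ℍ_r is the gradient of this energy, not of the form without
the diagonal.  The simulated-annealing baseline uses the same energy with
incremental O(N) single-flip bookkeeping.

## Baselines

* **Simulated annealing**: single-flip Metropolis from the empty support
  (cold start), either zero-temperature (ties accepted with probability ½)
  or geometric cooling from T = 0.02 to 0.00002; one Monte-Carlo step is
  one proposed flip.
* **LASSO**: FISTA with function-value restarts on
  ½xᵀ(AᵀA)x − (Aᵀy)ᵀx + λ₁‖x‖₁, expressed through the Gram operator so the
  identical code runs on the implicit MRI operators.  The step size is the
  inverse of the largest Gram eigenvalue (power iteration).  For the MRI
  threshold sweep the penalty is tied to the shared axis by λ₁ = η²/2.

## Sparse MRI pipeline

The image is reconstructed in the orthogonal full-depth 2-D Haar basis Ψ
from randomly undersampled k-space.  With the unitary DFT F and sampling
selector S, A = SFΨᵀ and the QUBO operators are

    h^z = Re(ΨFᴴSᵀy),
    J̃   = Re(ΨFᴴSᵀSFΨᵀ) + γΨ(Δ_vᵀΔ_v + Δ_hᵀΔ_h)Ψᵀ,   γ = 1e-4,

where Δ_v, Δ_h are periodic second differences.  Both SᵀS and the
smoothness penalty are diagonal in Fourier space, so J̃ is applied as a
single Fourier multiplier between fast transforms; its diagonal is
computed once per mask by transforming the basis vectors.  A hand-tuned
Haar kernel (verified against the PyWavelets path to 1e-12) keeps one
J̃-matvec at ~0.3 ms for 64² pixels.

The coarsest Haar function is exactly the k = 0 Fourier mode; a uniform
random mask misses the DC point with probability 1 − rate and the
approximation coefficient becomes unobservable, putting an identical
RMSE floor ≈ |c₀|/side under every solver.  The demo pipeline therefore
forces the DC point into the mask (point count unchanged); the plain
uniform mask remains the default contract of `make_sampling_mask`.

## Synthetic phantoms

`generate_phantom` emulates a brain-like, Haar-compressible image:
overlapping random ellipses (piecewise-smooth anatomy) plus a multi-scale
texture whose Haar coefficients are heavy-tailed (Student-t, 3 d.o.f.)
with geometric per-level decay — natural images have kurtotic wavelet
marginals, and without the texture the sorted coefficient spectrum kinks
at the ellipse-edge scale, every kept coefficient is recoverable, and the
reconstruction problem collapses to exact recovery for all solvers.  The
image is rescaled to [0.15, 0.85] and sparsified by zeroing the
smallest-magnitude Haar coefficients so that exactly the target fraction
(default 0.212) stays nonzero.  What the phantoms do *not* emulate:
scanner noise, coil sensitivities, partial-volume texture correlations,
complex-valued images.  Passing tests on phantoms therefore demonstrate
the solver mechanics and their relative ordering, not clinical
reconstruction quality.

## Problem sizes used in the shipped experiments

Support-estimation benchmark: N = 500, α = a = 0.6, ν = 0, η = 0.05,
50 instances.  Alternating-minimisation checks: N = 200–500, 51
iterations.  Exhaustive-search agreement: N = 12 (4096 support
enumerations).  Phantom MRI: 64×64, compression 0.4, sparseness 0.212,
10 phantom/mask seeds, per-solver threshold grids at matched effective
selection cutoffs (LASSO {0.001, 0.003, 0.01}, open-loop
{0.0037, 0.005, 0.01}, CAC {0.008, 0.011, 0.022} — the open-loop rule
keeps coefficients above ~η/d, the CAC rule above ~η/√(2d), with d ≈ the
sampling rate, which is also why the threshold axes of the two hybrids
differ by roughly √(2/d)).  Both hybrids run 31 alternating iterations
from one shared, lightly-penalised LASSO solution per instance (tying the
initialisation penalty to each run's own threshold would hand the low-η
runs a systematically richer start), the in-loop conjugate-gradient stage
is capped at 400 iterations at tolerance 1e-6, the lowest-energy iterate
is kept, and the reported support is re-solved to tolerance 1e-10 before
the error is measured.  These sizes keep a full run on a single CPU core
in the minutes range while preserving every qualitative contrast; the
128×128 configuration runs through the same code path.

## Numerical notes and limitations

* Heaviside tie-break H(0) = 0 everywhere (support binarisation and the
  open-loop interaction term).
* All randomness flows from seeded `numpy` generators with fixed draw
  order; runs are bit-reproducible at fixed seed, and experiment drivers
  derive per-sample generators from (seed, sample, solver) keys via CRC32.
* Divergent SDE states (non-finite amplitudes) raise with the step index.
* CG on a support larger than the number of independent measurements is
  rank-deficient; the solver warns and returns the least-residual iterate.
* The statistical-mechanics ground-state curves used as the theoretical
  reference in the original benchmark are out of scope; recovery quality
  is asserted against the generated ground truth instead.
* Physical-hardware wall-clock modelling, negative parametric gain and
  mean-field variants are out of scope.
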