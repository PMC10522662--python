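"""Observation model container for compressed-sensing instances.

An :class:`ObservationModel` bundles the linear measurement y = A(ξ∘x) + w
together with the derived quantities every solver in this package consumes:

* ``zeeman``      — the matched filter Aᵀy (real part for complex data),
* ``gram_matvec`` — v ↦ AᵀA v (plus any quadratic regulariser),
* ``gram_diag``   — the diagonal Σ_k (A_r^k)² of the Gram matrix.

The Gram matrix may be held densely (random Gaussian instances) or as an
implicit fast-transform operator (the sparse-MRI pipeline), so the Ising
local fields, the classical least-squares stage and the baselines all run
unchanged at MRI scale where the dense N×N matrix would be prohibitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["ObservationModel", "as_observation"]


@dataclass
class ObservationModel:
    """A compressed-sensing instance y = A(ξ∘x) + w.

    Parameters
    ----------
    y
        Observed signal, length M.  Complex for k-space data.
    A
        Dense M×N observation matrix, or ``None`` when the instance is
        defined by implicit operators (MRI).
    x_true, xi_true
        Optional ground truth: source values and binary support.
    nu
        Standard deviation of the observation noise used to generate ``y``.
    alpha, a
        Compression ratio M/N and sparseness (bookkeeping only).
    """

    y: np.ndarray
    A: Optional[np.ndarray] = None
    x_true: Optional[np.ndarray] = None
    xi_true: Optional[np.ndarray] = None
    nu: float = 0.0
    alpha: Optional[float] = None
    a: Optional[float] = None
    # implicit-operator hooks (set instead of A for the MRI pipeline)
    n_cols: Optional[int] = None
    matvec_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    gram_matvec_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    gram_diag_fn: Optional[Callable[[], np.ndarray]] = None
    zeeman_fn: Optional[Callable[[], np.ndarray]] = None

    _zeeman: Optional[np.ndarray] = field(default=None, repr=False)
    _gram_diag: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.A is None and self.gram_matvec_fn is None:
            raise ValueError("either a dense A or implicit operators are required")
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float)
            if self.A.ndim != 2:
                raise ValueError("A must be a 2-D matrix")
            if self.y.shape[0] != self.A.shape[0]:
                raise ValueError(
                    f"y has length {self.y.shape[0]} but A has {self.A.shape[0]} rows"
                )

    # -- shapes -----------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of unknowns (DOPO pulses)."""
        return self.A.shape[1] if self.A is not None else int(self.n_cols)

    @property
    def m(self) -> int:
        """Number of measurements."""
        return self.y.shape[0]

    # -- linear algebra ---------------------------------------------------
    def matvec(self, x: np.ndarray) -> np.ndarray:
        """A x."""
        if self.A is not None:
            return self.A @ x
        return self.matvec_fn(x)

    def gram_matvec(self, v: np.ndarray) -> np.ndarray:
        """AᵀA v (plus quadratic-regulariser terms for MRI operators)."""
        if self.gram_matvec_fn is not None:
            return self.gram_matvec_fn(v)
        return self.A.T @ (self.A @ v)

    @property
    def gram_diag(self) -> np.ndarray:
        """Column energies Σ_k (A_r^k)², the Gram diagonal."""
        if self._gram_diag is None:
            if self.gram_diag_fn is not None:
                self._gram_diag = np.asarray(self.gram_diag_fn(), dtype=float)
            else:
                self._gram_diag = np.einsum("kr,kr->r", self.A, self.A)
        return self._gram_diag

    @property
    def zeeman(self) -> np.ndarray:
        """Matched filter Aᵀy — the Zeeman (external-field) vector."""
        if self._zeeman is None:
            if self.zeeman_fn is not None:
                self._zeeman = np.asarray(self.zeeman_fn(), dtype=float)
            else:
                self._zeeman = self.A.T @ self.y
        return self._zeeman

    def gram_dense(self) -> np.ndarray:
        """Materialise the N×N Gram matrix (dense instances, or small N)."""
        if self.A is not None:
            return self.A.T @ self.A
        eye = np.eye(self.n)
        return np.column_stack([self.gram_matvec(eye[:, r]) for r in range(self.n)])

    def residual_sq(self, x: np.ndarray) -> float:
        """‖y − A x‖² (complex-aware)."""
        r = self.y - self.matvec(x)
        return float(np.vdot(r, r).real)


def as_observation(A, y) -> ObservationModel:
    """Coerce ``(A, y)`` into an :class:`ObservationModel`.

    ``A`` may already be an :class:`ObservationModel`, in which case it is
    returned unchanged and ``y`` is ignored.
    """
    if isinstance(A, ObservationModel):
        return A
    return ObservationModel(y=np.asarray(y, dtype=float), A=np.asarray(A, dtype=float))
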