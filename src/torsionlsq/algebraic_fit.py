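"""Exact least-squares torsion fitting via the normal equations.

The objective ``F(K) = ||B K - y||^2`` is a convex quadratic, so its
stationarity conditions form a linear system ``W K = C`` with
``W = B^T B`` and ``C = B^T y`` whose solution is the *global* minimizer.
A bounded (box-constrained) variant restricts every torsion coefficient to
``|k| <= T``; since the objective is convex the constrained optimum is
well-defined and is found with a convex solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .scan_model import DesignSystem

__all__ = ["FourierParams", "FitResult", "solve_global", "solve_bounded",
           "LARGE_COEFF_THRESHOLD"]

#: kJ/mol; torsion coefficients beyond this magnitude tend to destabilize
#: molecular-dynamics integration, so global fits warn when they exceed it.
LARGE_COEFF_THRESHOLD = 20.0


@dataclass(frozen=True)
class FourierParams:
    """Fitted cosine-series coefficients, one row per dihedral type.

    ``k[g, j-1]`` multiplies ``1 + cos(j * phi)`` for type ``g`` (kJ/mol).
    ``offset`` is the fitted global additive constant, if one was included;
    it is not a force-field parameter and is excluded from exports.
    """

    k: np.ndarray
    offset: float | None = None

    def __post_init__(self) -> None:
        k = np.atleast_2d(np.asarray(self.k, dtype=float))
        object.__setattr__(self, "k", k)
        # the scan pipeline uses 3 or 4 terms; smaller counts are allowed so
        # the solvers work on reduced systems
        if not 1 <= k.shape[1] <= 4:
            raise ValueError(f"n_terms must be in 1..4, got {k.shape[1]}")
        if not np.all(np.isfinite(k)):
            raise ValueError("coefficients must be finite")
        if self.offset is not None and not np.isfinite(self.offset):
            raise ValueError("offset must be finite")

    @property
    def n_types(self) -> int:
        return self.k.shape[0]

    @property
    def n_terms(self) -> int:
        return self.k.shape[1]

    def flat(self) -> np.ndarray:
        """Coefficients in design-system column order (type-major)."""
        return self.k.ravel().copy()


@dataclass(frozen=True)
class FitResult:
    """Coefficients plus the residual objective and solver metadata."""

    params: FourierParams
    objective: float
    method: str
    bound_T: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective < -1e-9:
            raise ValueError("objective must be non-negative")


def _unpack(system: DesignSystem, x: np.ndarray) -> FourierParams:
    n = system.n_coeffs
    k = x[:n].reshape(system.n_types, system.n_terms)
    offset = float(x[n]) if system.has_offset else None
    return FourierParams(k=k, offset=offset)


def _objective(system: DesignSystem, x: np.ndarray) -> float:
    r = system.B @ x - system.y
    return float(r @ r)


def _check_system(system: DesignSystem) -> None:
    if system.B.size == 0:
        raise ValueError("empty design system")
    if not np.any(system.B[:, : system.n_coeffs]):
        raise ValueError("degenerate system: design matrix is all zero")
    if system.B.shape[0] < system.B.shape[1]:
        warnings.warn(
            f"under-determined system: {system.B.shape[0]} conformers for "
            f"{system.B.shape[1]} parameters",
            stacklevel=3,
        )


def _warn_large(k: np.ndarray) -> None:
    kmax = float(np.max(np.abs(k)))
    if kmax > LARGE_COEFF_THRESHOLD:
        warnings.warn(
            f"largest |k| = {kmax:.2f} kJ/mol exceeds {LARGE_COEFF_THRESHOLD}; "
            "large torsion coefficients are known to destabilize MD runs — "
            "consider the bounded fit",
            stacklevel=3,
        )


def solve_global(system: DesignSystem) -> FitResult:
    """Unconstrained global minimizer of ``||B K - y||^2``.

    Solves the normal equations ``(B^T B) K = B^T y`` directly.  If
    ``B^T B`` is singular the minimum-norm least-squares solution is
    returned and ``diagnostics["singular"]`` is set.

    Returns
    -------
    FitResult
        With ``method="global"``; ``diagnostics`` reports the condition
        number of ``B^T B`` and its rank.
    """
    _check_system(system)
    W = system.B.T @ system.B
    C = system.B.T @ system.y
    rank = int(np.linalg.matrix_rank(W))
    singular = rank < W.shape[0]
    if singular:
        x = np.linalg.pinv(W) @ C
    else:
        x = np.linalg.solve(W, C)
    params = _unpack(system, x)
    _warn_large(params.k)
    return FitResult(
        params=params,
        objective=_objective(system, x),
        method="global",
        diagnostics={
            "cond_W": float(np.linalg.cond(W)),
            "rank_W": rank,
            "singular": singular,
        },
    )


def solve_bounded(system: DesignSystem, T: float = 20.0) -> FitResult:
    """Box-constrained ("local") minimizer with ``-T <= k_g^j <= T``.

    The offset column, when present, stays unconstrained.  When no bound is
    active this coincides with :func:`solve_global`.

    Parameters
    ----------
    T
        Symmetric bound on every torsion coefficient, kJ/mol (> 0).
    """
    if not T > 0:
        raise ValueError(f"bound T must be positive, got {T}")
    _check_system(system)
    n = system.n_coeffs
    n_cols = system.B.shape[1]
    lo = np.full(n_cols, -np.inf)
    hi = np.full(n_cols, np.inf)
    lo[:n], hi[:n] = -T, T
    res = lsq_linear(system.B, system.y, bounds=(lo, hi), method="bvls", tol=1e-14)
    x = res.x
    n_active = int(np.sum(np.isclose(np.abs(x[:n]), T, atol=1e-9)))
    return FitResult(
        params=_unpack(system, x),
        objective=_objective(system, x),
        method="local",
        bound_T=float(T),
        diagnostics={
            "solver_status": int(res.status),
            "n_active_bounds": n_active,
            "iterations": int(res.nit) if res.nit is not None else -1,
        },
    )
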