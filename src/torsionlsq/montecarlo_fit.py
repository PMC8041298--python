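"""Metropolis-style Monte Carlo baseline for the torsion-fitting objective.

Serves as the stochastic reference against which the exact algebraic
solution is compared: a random walk over coefficient vectors accepts a
proposal with probability 1 when the objective decreases and
``exp(-dF / T)`` when it increases, with the temperature factor ``T``
annealed geometrically to delay premature convergence in local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebraic_fit import FitResult, _objective, _unpack
from .scan_model import DesignSystem

__all__ = ["MCSchedule", "mc_accept_probability", "mc_fit"]


@dataclass(frozen=True)
class MCSchedule:
    """Hyperparameters of a Monte Carlo minimization run.

    ``T_start``/``T_end`` are temperature factors in the units of the
    objective (kJ^2/mol^2); ``proposal_sigma`` is the Gaussian scale of a
    single-coefficient perturbation (kJ/mol); ``bounds`` optionally clips
    coefficients to ``|k| <= bounds``.
    """

    n_iter: int = 50_000
    T_start: float = 100.0
    T_end: float = 0.01
    proposal_sigma: float = 1.0
    seed: int = 0
    bounds: float | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (self.T_start >= self.T_end > 0):
            raise ValueError("need T_start >= T_end > 0")
        if not self.proposal_sigma > 0:
            raise ValueError("proposal_sigma must be positive")
        if self.bounds is not None and not self.bounds > 0:
            raise ValueError("bounds must be positive when given")

    def temperatures(self) -> np.ndarray:
        """Geometric cooling ladder from T_start down to T_end."""
        return np.geomspace(self.T_start, self.T_end, self.n_iter)


def mc_accept_probability(dF: float, T: float) -> float:
    """Metropolis acceptance probability for an objective change ``dF``.

    Returns 1 for any non-increasing move and ``exp(-dF / T)`` for an
    uphill one; ``T`` must be positive.
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if dF <= 0:
        return 1.0
    return float(np.exp(-dF / T))


def mc_fit(
    system: DesignSystem,
    schedule: MCSchedule,
    init: np.ndarray | None = None,
    return_trace: bool = False,
) -> FitResult:
    """Stochastic minimization of ``||B K - y||^2`` by annealed Metropolis walk.

    One coefficient is perturbed per step by a centered Gaussian of scale
    ``proposal_sigma``; when ``schedule.bounds`` is set, torsion
    coefficients are clipped to the box (the offset column is never
    clipped).  The best-so-far vector is returned, so the result can only
    improve with more iterations.  Runs are reproducible for a fixed seed.

    Parameters
    ----------
    init
        Starting coefficient vector in design-column order; zeros by default.
    return_trace
        Attach a per-iteration record (iteration, objective, temperature,
        accepted) under ``diagnostics["trace"]``.
    """
    if system.B.size == 0:
        raise ValueError("empty design system")
    rng = np.random.default_rng(schedule.seed)
    n_cols = system.B.shape[1]
    n_coeffs = system.n_coeffs

    x = np.zeros(n_cols) if init is None else np.asarray(init, dtype=float).copy()
    if x.shape != (n_cols,):
        raise ValueError(f"init must have shape ({n_cols},)")
    if schedule.bounds is not None:
        x[:n_coeffs] = np.clip(x[:n_coeffs], -schedule.bounds, schedule.bounds)

    # incremental residual update: perturbing one coefficient by dk changes
    # the residual by dk * B[:, j]
    r = system.B @ x - system.y
    f = float(r @ r)
    best_x, best_f = x.copy(), f

    temps = schedule.temperatures()
    n_accept = 0
    trace = [] if return_trace else None
    for it in range(schedule.n_iter):
        j = int(rng.integers(n_cols))
        dk = rng.normal(0.0, schedule.proposal_sigma)
        new_kj = x[j] + dk
        if schedule.bounds is not None and j < n_coeffs:
            new_kj = float(np.clip(new_kj, -schedule.bounds, schedule.bounds))
        dk = new_kj - x[j]
        r_new = r + dk * system.B[:, j]
        f_new = float(r_new @ r_new)
        accepted = rng.random() < mc_accept_probability(f_new - f, temps[it])
        if accepted:
            x[j], r, f = new_kj, r_new, f_new
            n_accept += 1
            if f < best_f:
                best_f, best_x = f, x.copy()
        if trace is not None:
            trace.append((it, f, temps[it], accepted))

    diagnostics = {
        "iterations": schedule.n_iter,
        "acceptance_rate": n_accept / schedule.n_iter,
        "final_objective": f,
    }
    if trace is not None:
        diagnostics["trace"] = trace
    return FitResult(
        params=_unpack(system, best_x),
        objective=float(best_f),
        method="monte_carlo",
        bound_T=schedule.bounds,
        diagnostics=diagnostics,
    )
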