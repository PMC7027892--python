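"""Closed-form batch-culture solutions for the three growth laws.

Substituting the yield relation ``S = S_0 - (X - X_0)/Y_xs`` into the
growth law turns the coupled (X, S) system into a single autonomous ODE
in X that separates.  With the shorthand

    A = X_0 + Y_xs * S_0          (total attainable biomass, g/L)
    B = K_s * Y_xs + A

partial fractions give, for the **Monod** law,

    mu_max * t = (B/A) ln(X/X_0) + (K_s Y_xs / A) ln[(A - X_0)/(A - X)]

an implicit relation, strictly increasing in X on (X_0, A); for the
**Logistic** law the familiar explicit sigmoid

    X(t) = X_m / (1 + ((X_m - X_0)/X_0) e^{-mu_max t})

and for the **hybrid Logistic-Monod** law the three-log implicit form

    mu_max * t / X_m =   a ln(X/X_0)
                       + b ln[(A - X_0)/(A - X)]
                       + c ln[(X_m - X_0)/(X_m - X)]

    a = B / (A X_m),   b = K_s Y_xs / (A (X_m - A)),
    c = (B - X_m) / (X_m (A - X_m)).

The hybrid biomass approaches ``X_sup = min(X_m, A)``: whichever of the
carrying capacity and the substrate supply binds first.  Biomass at a
given time is recovered from the implicit forms by bracketed
root-finding, exploiting strict monotonicity of t(X).  Substrate always
follows from conservation, ``S(t) = S_0 - (X(t) - X_0)/Y_xs``.

All exponentials are algebraically bounded before evaluation, so the
explicit logistic forms are overflow-safe for arbitrarily large
``mu_max * t``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .models import (
    BatchConditions,
    BatchTrajectory,
    FeasibilityWarning,
    GrowthParameters,
    ModelKind,
    specific_growth_rate,
)

__all__ = [
    "ImplicitSolution",
    "reachable_biomass_sup",
    "logistic_biomass",
    "logistic_substrate",
    "monod_time_of_biomass",
    "hybrid_time_of_biomass",
    "time_of_biomass",
    "implicit_solution",
    "biomass_at_time",
    "substrate_at_time",
    "sample_trajectory",
]

logger = logging.getLogger(__name__)

# Relative margin keeping root brackets strictly inside (X_0, X_sup).
_BRACKET_EPS = 1e-12
# |X_m - A| below this fraction of X_m is the degenerate hybrid case.
_DEGENERATE_TOL = 1e-9
_DEGENERATE_NUDGE = 1e-6


@dataclass(frozen=True)
class ImplicitSolution:
    """An implicit batch solution: the time-of-biomass map and its domain.

    ``t_of_X`` is strictly increasing on ``(X_0, X_sup)`` with
    ``t_of_X(X_0) = 0`` and ``t_of_X -> +inf`` as ``X -> X_sup``.
    """

    model: ModelKind
    t_of_X: Callable[[float], float]
    X_sup: float


def reachable_biomass_sup(
    model: ModelKind | str, p: GrowthParameters, bc: BatchConditions
) -> float:
    """Least upper bound of the biomass reachable from ``bc`` (g/L)."""
    model = ModelKind.coerce(model)
    A = bc.X_0 + p.Y_xs * bc.S_0
    if model is ModelKind.MONOD:
        return A
    if model is ModelKind.LOGISTIC:
        return p.X_m
    return min(p.X_m, A)


def _check_time(t: float) -> float:
    t = float(t)
    if not math.isfinite(t) or t < 0.0:
        raise ValueError(f"time t must be non-negative and finite, got {t!r}")
    return t


def logistic_biomass(p: GrowthParameters, bc: BatchConditions, t: float) -> float:
    """Explicit logistic biomass X(t), overflow-safe for large ``mu_max * t``."""
    t = _check_time(t)
    # X_m / (1 + ((X_m - X_0)/X_0) e^{-mu t}) is bounded for all t >= 0.
    ratio = (p.X_m - bc.X_0) / bc.X_0
    return p.X_m / (1.0 + ratio * math.exp(-p.mu_max * t))


def logistic_substrate(p: GrowthParameters, bc: BatchConditions, t: float) -> float:
    """Substrate S(t) under logistic growth, by conservation.

    Logistic growth is substrate-blind, so if the carrying capacity
    exceeds what the substrate can supply the predicted S goes negative;
    the value is returned as-is with a logged warning.
    """
    t = _check_time(t)
    S = bc.S_0 - (logistic_biomass(p, bc, t) - bc.X_0) / p.Y_xs
    if S < 0.0:
        logger.warning(
            "logistic substrate is negative (S = %.6g g/L at t = %.6g hr): "
            "carrying capacity exceeds the substrate supply",
            S,
            t,
        )
    return S


def _monod_coefficients(p: GrowthParameters, bc: BatchConditions) -> tuple[float, float, float]:
    A = bc.X_0 + p.Y_xs * bc.S_0
    B = p.K_s * p.Y_xs + A
    return A, B, p.K_s * p.Y_xs


def monod_time_of_biomass(p: GrowthParameters, bc: BatchConditions, X: float) -> float:
    """Time (hr) at which Monod batch biomass first reaches ``X`` (g/L).

    Valid for ``X_0 <= X < X_0 + Y_xs * S_0``; diverges logarithmically at
    the upper end, where the substrate runs out.
    """
    X = float(X)
    A, B, KY = _monod_coefficients(p, bc)
    if not (bc.X_0 <= X < A):
        raise ValueError(
            f"X = {X} g/L outside the reachable interval [{bc.X_0}, {A}) for the Monod model"
        )
    if X == bc.X_0:
        return 0.0
    return (B / A * math.log(X / bc.X_0) + KY / A * math.log((A - bc.X_0) / (A - X))) / p.mu_max


def _hybrid_coefficients(
    p: GrowthParameters, bc: BatchConditions
) -> tuple[float, float, float, float, float]:
    """Partial-fraction coefficients (A, X_m_eff, a, b, c) of the hybrid solution.

    When the carrying capacity coincides with the total attainable biomass
    (X_m == A) two partial-fraction denominators vanish; the removable
    degeneracy is handled by nudging X_m by one part in 10^6 with a warning.
    """
    A = bc.X_0 + p.Y_xs * bc.S_0
    Xm = p.X_m
    if abs(Xm - A) < _DEGENERATE_TOL * Xm:
        Xm = A * (1.0 + _DEGENERATE_NUDGE)
        warnings.warn(
            f"degenerate hybrid configuration X_m = X_0 + Y_xs*S_0 = {A} g/L; "
            f"perturbing X_m to {Xm} g/L to keep the closed form finite",
            FeasibilityWarning,
            stacklevel=3,
        )
    B = p.K_s * p.Y_xs + A
    a = B / (A * Xm)
    b = p.K_s * p.Y_xs / (A * (Xm - A))
    c = (B - Xm) / (Xm * (A - Xm))
    return A, Xm, a, b, c


def hybrid_time_of_biomass(p: GrowthParameters, bc: BatchConditions, X: float) -> float:
    """Time (hr) at which hybrid batch biomass first reaches ``X`` (g/L).

    Valid on ``[X_0, X_sup)`` with ``X_sup = min(X_m, X_0 + Y_xs*S_0)``.
    """
    X = float(X)
    A, Xm, a, b, c = _hybrid_coefficients(p, bc)
    X_sup = min(Xm, A)
    if not (bc.X_0 <= X < X_sup):
        raise ValueError(
            f"X = {X} g/L outside the reachable interval [{bc.X_0}, {X_sup}) for the hybrid model"
        )
    if X == bc.X_0:
        return 0.0
    total = (
        a * math.log(X / bc.X_0)
        + b * math.log((A - bc.X_0) / (A - X))
        + c * math.log((Xm - bc.X_0) / (Xm - X))
    )
    return total * Xm / p.mu_max


def logistic_time_of_biomass(p: GrowthParameters, bc: BatchConditions, X: float) -> float:
    """Closed-form inverse of the logistic sigmoid (valid on ``[X_0, X_m)``)."""
    X = float(X)
    if not (bc.X_0 <= X < p.X_m):
        raise ValueError(
            f"X = {X} g/L outside the reachable interval [{bc.X_0}, {p.X_m}) for the logistic model"
        )
    if X == bc.X_0:
        return 0.0
    return math.log(X * (p.X_m - bc.X_0) / (bc.X_0 * (p.X_m - X))) / p.mu_max


def time_of_biomass(
    model: ModelKind | str, p: GrowthParameters, bc: BatchConditions, X: float
) -> float:
    """Dispatch to the model-specific time-of-biomass relation."""
    model = ModelKind.coerce(model)
    if model is ModelKind.MONOD:
        return monod_time_of_biomass(p, bc, X)
    if model is ModelKind.LOGISTIC:
        return logistic_time_of_biomass(p, bc, X)
    return hybrid_time_of_biomass(p, bc, X)


def implicit_solution(
    model: ModelKind | str, p: GrowthParameters, bc: BatchConditions
) -> ImplicitSolution:
    model = ModelKind.coerce(model)
    return ImplicitSolution(
        model=model,
        t_of_X=lambda X: time_of_biomass(model, p, bc, X),
        X_sup=reachable_biomass_sup(model, p, bc),
    )


def _invert_time(
    model: ModelKind, p: GrowthParameters, bc: BatchConditions, t: float
) -> float:
    """Solve t_of_X(X) = t by bracketed root-finding on (X_0, X_sup)."""
    X_sup = reachable_biomass_sup(model, p, bc)
    lo = bc.X_0 * (1.0 + _BRACKET_EPS)
    if lo >= X_sup or time_of_biomass(model, p, bc, min(lo, X_sup * (1 - _BRACKET_EPS))) >= t:
        # t smaller than the time to cross even the bracket margin.
        return bc.X_0

    # The upper bracket walks toward X_sup until t_of_X exceeds t; past
    # one part in 10^15 of X_sup the asymptote is reached at float precision.
    f = lambda X: time_of_biomass(model, p, bc, X) - t
    hi = None
    for margin in (1e-12, 1e-13, 1e-14, 1e-15):
        candidate = X_sup * (1.0 - margin)
        if candidate <= lo:
            continue
        if f(candidate) > 0.0:
            hi = candidate
            break
    if hi is None:
        return X_sup

    root = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return float(root)


def biomass_at_time(
    model: ModelKind | str, p: GrowthParameters, bc: BatchConditions, t: float
) -> float:
    """Batch biomass X(t) in g/L, exact to <= 1e-10 g/L.

    Logistic uses the explicit sigmoid; Monod and hybrid invert the
    implicit time-of-biomass relation by Brent's method, bracketing with
    the strict monotonicity of t(X).
    """
    model = ModelKind.coerce(model)
    t = _check_time(t)
    if t == 0.0:
        return bc.X_0
    if model is ModelKind.LOGISTIC:
        return logistic_biomass(p, bc, t)
    if bc.S_0 == 0.0:
        return bc.X_0  # no substrate: Monod/hybrid growth never starts
    return _invert_time(model, p, bc, t)


def substrate_at_time(
    model: ModelKind | str, p: GrowthParameters, bc: BatchConditions, t: float
) -> float:
    """Batch substrate S(t) in g/L via conservation, S_0 - (X(t) - X_0)/Y_xs.

    Tiny negative values (above -1e-9 g/L, from inversion round-off) are
    clipped to zero for the substrate-limited models; the logistic model
    may go genuinely negative when the carrying capacity exceeds the
    substrate supply (see :func:`logistic_substrate`).
    """
    model = ModelKind.coerce(model)
    if model is ModelKind.LOGISTIC:
        return logistic_substrate(p, bc, t)
    S = bc.S_0 - (biomass_at_time(model, p, bc, t) - bc.X_0) / p.Y_xs
    if -1e-9 <= S < 0.0:
        return 0.0
    return S


def sample_trajectory(
    model: ModelKind | str,
    p: GrowthParameters,
    bc: BatchConditions,
    t_grid,
) -> BatchTrajectory:
    """Evaluate the analytic solution on a strictly increasing time grid."""
    model = ModelKind.coerce(model)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if t_grid[0] < 0.0:
        raise ValueError("t_grid must start at a non-negative time")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    X = np.array([biomass_at_time(model, p, bc, t) for t in t_grid])
    S = bc.S_0 - (X - bc.X_0) / p.Y_xs
    S[(S < 0.0) & (S >= -1e-9)] = 0.0
    mu = specific_growth_rate(model, p, np.maximum(S, 0.0), X)
    return BatchTrajectory(
        t=t_grid, X=X, S=S, mu=np.asarray(mu), model=model,
        params=p, conditions=bc, provenance="analytic",
    )
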