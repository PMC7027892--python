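"""Chemostat (CSTR) steady states, washout and optimal dilution rates.

At steady state the mass balances

    0 = (mu - D) X                    (biomass)
    0 = D (S_F - S) - mu X / Y_xs     (substrate)

force mu = D on the non-trivial branch, so each growth law yields closed
forms:

* **Monod**:    S* = K_s D / (mu_max - D),  X* = Y_xs (S_F - S*).
* **Logistic**: X* = X_m (mu_max - D) / mu_max,  S* = S_F - X*/Y_xs
  (exactly linear in D; requires X_m <= Y_xs S_F for S* to stay
  non-negative at low D).
* **Hybrid**:   substituting X = Y_xs (S_F - S) into
  mu_max (S/(K_s+S)) (1 - X/X_m) = D gives a quadratic in S,

      mu_max Y_xs S^2 + [mu_max (X_m - Y_xs S_F) - D X_m] S - D K_s X_m = 0,

  whose constant term is negative for D > 0, so exactly one root is
  positive; that root is the physical one and always lies in (0, S_F)
  below washout.

Washout occurs at D_w = mu_max S_F / (K_s + S_F) for Monod and hybrid
(at X = 0 the logistic factor is 1) and at D_w = mu_max for Logistic;
for D >= D_w the washout branch (S* = S_F, X* = 0) is returned rather
than the unphysical analytic continuation.  Biomass productivity is
P = D X*; its maximiser D_opt has closed forms for Monod
(mu_max (1 - sqrt(K_s/(K_s+S_F)))) and Logistic (mu_max / 2) and is
found numerically for the hybrid model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .models import (
    FeasibilityWarning,
    GrowthParameters,
    ModelKind,
    specific_growth_rate,
)

__all__ = [
    "CSTRConditions",
    "SteadyState",
    "DilutionAnalysis",
    "InfeasibleOperationError",
    "steady_state",
    "steady_state_residuals",
    "washout_dilution",
    "optimal_dilution",
    "dilution_sweep",
    "integrate_cstr",
    "SWEEP_CSV_COLUMNS",
]

SWEEP_CSV_COLUMNS = ("D_per_hr", "S_star_g_L", "X_star_g_L", "productivity_g_L_hr", "branch")


class InfeasibleOperationError(ValueError):
    """The requested operating point has no physical steady state."""


@dataclass(frozen=True)
class CSTRConditions:
    """Chemostat operating point: dilution rate D (1/hr) and feed substrate S_F (g/L)."""

    D: float
    S_F: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.D) or self.D < 0.0:
            raise ValueError(f"dilution rate D must be non-negative and finite, got {self.D!r}")
        if not math.isfinite(self.S_F) or self.S_F <= 0.0:
            raise ValueError(f"feed substrate S_F must be positive and finite, got {self.S_F!r}")

    def to_mapping(self) -> dict[str, float]:
        return {"D": self.D, "S_F": self.S_F}

    @classmethod
    def from_mapping(cls, config) -> "CSTRConditions":
        missing = [k for k in ("D", "S_F") if k not in config]
        if missing:
            raise KeyError(f"CSTR-conditions config missing keys: {', '.join(missing)}")
        return cls(D=float(config["D"]), S_F=float(config["S_F"]))


@dataclass(frozen=True)
class SteadyState:
    """Effluent steady state of the chemostat.

    ``branch`` is ``"nontrivial"`` (mu = D, X* > 0) or ``"washout"``
    (X* = 0, S* = S_F).  ``productivity`` is P = D X* in g/L/hr.
    """

    S_star: float
    X_star: float
    productivity: float
    branch: str


@dataclass(frozen=True)
class DilutionAnalysis:
    """Washout and productivity-optimal dilution rates (1/hr) and peak productivity."""

    D_washout: float
    D_optimal: float
    P_max: float


def washout_dilution(model: ModelKind | str, p: GrowthParameters, S_F: float) -> float:
    """Dilution rate above which biomass washes out of the chemostat.

    Monod and hybrid share mu_max S_F/(K_s + S_F): at vanishing biomass
    the logistic self-inhibition factor equals 1, so the hybrid law
    reduces to Monod.  Logistic washout is mu_max itself.
    """
    model = ModelKind.coerce(model)
    if S_F <= 0.0:
        raise ValueError("S_F must be positive")
    if model is ModelKind.LOGISTIC:
        return p.mu_max
    return p.mu_max * S_F / (p.K_s + S_F)


def _hybrid_effluent_substrate(p: GrowthParameters, D: float, S_F: float) -> float:
    # Quadratic a S^2 + b S + c = 0 from mu(S, Y_xs(S_F - S)) = D; c < 0 for
    # D > 0 makes the root product negative: the positive root is physical.
    a = p.mu_max * p.Y_xs
    b = p.mu_max * (p.X_m - p.Y_xs * S_F) - D * p.X_m
    c = -D * p.K_s * p.X_m
    disc = b * b - 4.0 * a * c
    # c <= 0 guarantees disc >= b^2 >= 0; numerically stable root selection:
    sqrt_disc = math.sqrt(disc)
    if b >= 0.0:
        # positive root via the conjugate form avoids cancellation
        return (2.0 * -c) / (b + sqrt_disc) if c != 0.0 else 0.0
    return (-b + sqrt_disc) / (2.0 * a)


def steady_state(
    model: ModelKind | str, p: GrowthParameters, c: CSTRConditions
) -> SteadyState:
    """Closed-form chemostat steady state for the given model and operating point.

    Returns the washout branch for D >= D_w.  For the Logistic model an
    operating point whose steady biomass exceeds the substrate supply
    (possible when X_m > Y_xs S_F, since logistic growth ignores
    substrate) raises :class:`InfeasibleOperationError`.
    """
    model = ModelKind.coerce(model)
    D, S_F = c.D, c.S_F
    D_w = washout_dilution(model, p, S_F)

    if model in (ModelKind.LOGISTIC, ModelKind.HYBRID) and p.X_m > p.Y_xs * S_F:
        warnings.warn(
            f"X_m = {p.X_m} g/L exceeds Y_xs*S_F = {p.Y_xs * S_F} g/L: the carrying "
            "capacity cannot be sustained by the feed",
            FeasibilityWarning,
            stacklevel=2,
        )

    if D >= D_w:
        return SteadyState(S_star=S_F, X_star=0.0, productivity=0.0, branch="washout")

    if model is ModelKind.MONOD:
        S_star = p.K_s * D / (p.mu_max - D)
        X_star = p.Y_xs * (S_F - S_star)
    elif model is ModelKind.LOGISTIC:
        X_star = p.X_m * (p.mu_max - D) / p.mu_max
        S_star = S_F - X_star / p.Y_xs
        if S_star < 0.0:
            raise InfeasibleOperationError(
                f"logistic steady state needs more substrate than the feed supplies "
                f"(S* = {S_star:.6g} g/L at D = {D} 1/hr); the model requires "
                f"X_m <= Y_xs*S_F (here {p.X_m} > {p.Y_xs * S_F})"
            )
    else:  # HYBRID
        S_star = _hybrid_effluent_substrate(p, D, S_F)
        X_star = p.Y_xs * (S_F - S_star)

    return SteadyState(
        S_star=float(S_star),
        X_star=float(X_star),
        productivity=float(D * X_star),
        branch="nontrivial",
    )


def steady_state_residuals(
    model: ModelKind | str, p: GrowthParameters, c: CSTRConditions, ss: SteadyState
) -> tuple[float, float]:
    """Residuals of the two mass balances at a candidate steady state (g/L/hr)."""
    model = ModelKind.coerce(model)
    mu = specific_growth_rate(model, p, max(ss.S_star, 0.0), max(ss.X_star, 0.0))
    r_biomass = (mu - c.D) * ss.X_star
    r_substrate = c.D * (c.S_F - ss.S_star) - mu * ss.X_star / p.Y_xs
    return (float(r_biomass), float(r_substrate))


def optimal_dilution(
    model: ModelKind | str, p: GrowthParameters, S_F: float
) -> DilutionAnalysis:
    """Productivity-maximising dilution rate and the associated peak P = D X*.

    Closed forms for Monod and Logistic; the hybrid optimum is found by
    bounded scalar minimisation of -D X*(D) on (0, D_w) after a coarse
    grid pre-scan confirming unimodality of the productivity curve.
    """
    model = ModelKind.coerce(model)
    D_w = washout_dilution(model, p, S_F)

    if model is ModelKind.MONOD:
        D_opt = p.mu_max * (1.0 - math.sqrt(p.K_s / (p.K_s + S_F)))
    elif model is ModelKind.LOGISTIC:
        D_opt = p.mu_max / 2.0
    else:
        def neg_productivity(D: float) -> float:
            return -steady_state(model, p, CSTRConditions(D=D, S_F=S_F)).productivity

        # pre-scan: the interior grid maximum must beat both edges
        grid = np.linspace(D_w * 1e-6, D_w * (1.0 - 1e-9), 201)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FeasibilityWarning)
            values = np.array([-neg_productivity(D) for D in grid])
            k = int(np.argmax(values))
            if k == 0 or k == grid.size - 1:
                raise RuntimeError(
                    "hybrid productivity curve is not interior-unimodal on (0, D_w)"
                )
            res = minimize_scalar(
                neg_productivity,
                bounds=(grid[k - 1], grid[k + 1]),
                method="bounded",
                options={"xatol": 1e-12},
            )
        D_opt = float(res.x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FeasibilityWarning)
        P_max = steady_state(model, p, CSTRConditions(D=D_opt, S_F=S_F)).productivity
    return DilutionAnalysis(D_washout=D_w, D_optimal=D_opt, P_max=P_max)


def dilution_sweep(
    model: ModelKind | str, p: GrowthParameters, S_F: float, D_grid
):
    """Steady states over an increasing grid of dilution rates.

    Returns a :class:`pandas.DataFrame` with columns
    ``D_per_hr, S_star_g_L, X_star_g_L, productivity_g_L_hr, branch``.
    """
    import pandas as pd

    model = ModelKind.coerce(model)
    D_grid = np.asarray(D_grid, dtype=float)
    if np.any(D_grid < 0.0):
        raise ValueError("dilution rates must be non-negative")
    if D_grid.size > 1 and not np.all(np.diff(D_grid) > 0):
        raise ValueError("D_grid must be strictly increasing")

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FeasibilityWarning)
        for D in D_grid:
            ss = steady_state(model, p, CSTRConditions(D=float(D), S_F=S_F))
            rows.append((D, ss.S_star, ss.X_star, ss.productivity, ss.branch))
    return pd.DataFrame(rows, columns=list(SWEEP_CSV_COLUMNS))


def integrate_cstr(
    model: ModelKind | str,
    p: GrowthParameters,
    c: CSTRConditions,
    initial_state: tuple[float, float],
    horizon: float,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-12,
) -> tuple[float, float]:
    """Integrate the dynamic chemostat balances from a perturbed state.

    Used as a stability cross-check of the closed-form steady states;
    returns the final (X, S).  Not exposed through the CLI.
    """
    model = ModelKind.coerce(model)

    def rhs(t, y):
        X, S = y
        mu = specific_growth_rate(model, p, max(S, 0.0), max(X, 0.0))
        dX = (mu - c.D) * X
        dS = c.D * (c.S_F - S) - mu * X / p.Y_xs
        return (dX, dS)

    sol = solve_ivp(
        rhs, (0.0, horizon), initial_state, method="DOP853", rtol=rel_tol, atol=abs_tol
    )
    if not sol.success:
        raise RuntimeError(f"dynamic CSTR integration failed: {sol.message}")
    return (float(sol.y[0, -1]), float(sol.y[1, -1]))
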