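"""Core growth laws, parameter containers, and the batch ODE right-hand side.

Three unstructured kinetic models of microbial growth are supported, all
expressed through the specific growth rate ``mu = (1/X) dX/dt``:

* **Monod** -- saturation kinetics in a single limiting substrate,
  ``mu = mu_max * S / (K_s + S)``.
* **Logistic** -- self-limiting growth toward a carrying capacity,
  ``mu = mu_max * (1 - X / X_m)``, independent of substrate.
* **Hybrid Logistic-Monod** -- the product of the two factors,
  ``mu = mu_max * (S / (K_s + S)) * (1 - X / X_m)``, capturing the
  transition from a nutrient-limited phase to a self-inhibited phase.

Biomass growth is coupled to substrate consumption through a constant
yield coefficient ``Y_xs`` (g biomass formed per g substrate consumed):
``dS/dt = -(1/Y_xs) dX/dt``.  Units are fixed throughout the package at
g/L for concentrations and hours for time.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelKind",
    "GrowthParameters",
    "BatchConditions",
    "BatchState",
    "BatchTrajectory",
    "FeasibilityWarning",
    "specific_growth_rate",
    "batch_rhs",
    "validate_feasibility",
    "TRAJECTORY_CSV_COLUMNS",
]

#: Canonical CSV header for batch trajectories, shared by the analytic and
#: numeric routes (and the command-line interface).
TRAJECTORY_CSV_COLUMNS = ("time_hr", "biomass_g_L", "substrate_g_L", "mu_per_hr")


class FeasibilityWarning(UserWarning):
    """A parameter set is physically questionable but mathematically valid."""


class ModelKind(str, enum.Enum):
    """Which specific-growth-rate law to use."""

    MONOD = "monod"
    LOGISTIC = "logistic"
    HYBRID = "hybrid"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class GrowthParameters:
    """The four kinetic constants shared by all three growth laws.

    Parameters
    ----------
    mu_max : float
        Maximal specific growth rate (1/hr).  Must be positive.
    K_s : float
        Substrate saturation (half-velocity) constant (g/L).  Ignored by
        the Logistic law.  Must be positive.
    X_m : float
        Carrying capacity, the maximal sustainable biomass (g/L).
        Ignored by the Monod law.  Must be positive.
    Y_xs : float
        Biomass yield on substrate (g/g).  Must be positive; values above
        1 are physically suspect and trigger a warning, not an error.
    """

    mu_max: float
    K_s: float
    X_m: float
    Y_xs: float

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_s", "X_m", "Y_xs"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")
        if self.Y_xs > 1.0:
            warnings.warn(
                f"Y_xs = {self.Y_xs} exceeds 1 g/g; more biomass than substrate "
                "consumed is physically suspect",
                FeasibilityWarning,
                stacklevel=2,
            )

    def to_mapping(self) -> dict[str, float]:
        return {
            "mu_max": self.mu_max,
            "K_s": self.K_s,
            "X_m": self.X_m,
            "Y_xs": self.Y_xs,
        }

    @classmethod
    def from_mapping(cls, config: Mapping[str, float]) -> "GrowthParameters":
        """Build from a flat config mapping (extra keys are ignored)."""
        missing = [k for k in ("mu_max", "K_s", "X_m", "Y_xs") if k not in config]
        if missing:
            raise KeyError(f"growth-parameter config missing keys: {', '.join(missing)}")
        return cls(
            mu_max=float(config["mu_max"]),
            K_s=float(config["K_s"]),
            X_m=float(config["X_m"]),
            Y_xs=float(config["Y_xs"]),
        )


@dataclass(frozen=True)
class BatchConditions:
    """Initial state of a batch culture: biomass ``X_0`` and substrate ``S_0`` (g/L).

    ``X_0`` must be strictly positive (the Logistic and hybrid solutions
    divide by it); ``S_0`` may be zero.
    """

    X_0: float
    S_0: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.X_0) or self.X_0 <= 0.0:
            raise ValueError(f"X_0 must be positive and finite, got {self.X_0!r}")
        if not math.isfinite(self.S_0) or self.S_0 < 0.0:
            raise ValueError(f"S_0 must be non-negative and finite, got {self.S_0!r}")

    def to_mapping(self) -> dict[str, float]:
        return {"X_0": self.X_0, "S_0": self.S_0}

    @classmethod
    def from_mapping(cls, config: Mapping[str, float]) -> "BatchConditions":
        missing = [k for k in ("X_0", "S_0") if k not in config]
        if missing:
            raise KeyError(f"batch-conditions config missing keys: {', '.join(missing)}")
        return cls(X_0=float(config["X_0"]), S_0=float(config["S_0"]))


@dataclass(frozen=True)
class BatchState:
    """One sampled state of a batch culture."""

    t: float
    X: float
    S: float
    mu: float


@dataclass
class BatchTrajectory:
    """Time series of a batch culture: arrays of (t, X, S, mu) samples.

    ``provenance`` records whether the samples came from the closed-form
    solutions (``"analytic"``) or from adaptive ODE integration
    (``"numeric"``).
    """

    t: np.ndarray
    X: np.ndarray
    S: np.ndarray
    mu: np.ndarray
    model: ModelKind
    params: GrowthParameters
    conditions: BatchConditions
    provenance: str = "analytic"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = self.t.size
        if not (self.X.size == self.S.size == self.mu.size == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.provenance not in ("analytic", "numeric"):
            raise ValueError(f"provenance must be 'analytic' or 'numeric', got {self.provenance!r}")

    def __len__(self) -> int:
        return int(self.t.size)

    def states(self) -> Iterable[BatchState]:
        for i in range(len(self)):
            yield BatchState(float(self.t[i]), float(self.X[i]), float(self.S[i]), float(self.mu[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.t,
                "biomass_g_L": self.X,
                "substrate_g_L": self.S,
                "mu_per_hr": self.mu,
            }
        )

    def write_csv(self, path) -> None:
        """Write as CSV with 12 significant digits (lossless round-trip)."""
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def conservation_defect(self) -> float:
        """Max |(X - X_0) - Y_xs (S_0 - S)| over the samples (g/L)."""
        lhs = self.X - self.conditions.X_0
        rhs = self.params.Y_xs * (self.conditions.S_0 - self.S)
        return float(np.max(np.abs(lhs - rhs))) if len(self) else 0.0


def read_trajectory_frame(path) -> pd.DataFrame:
    """Read a trajectory CSV, validating the canonical header."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_CSV_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {', '.join(missing)}")
    return frame


def _check_nonnegative(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


def specific_growth_rate(
    model: ModelKind | str,
    p: GrowthParameters,
    S,
    X,
):
    """Specific growth rate ``mu`` (1/hr) of ``model`` at substrate S, biomass X.

    Accepts scalars or numpy arrays (broadcast).  S and X must be
    non-negative; the result can be negative only for the Logistic or
    hybrid laws when X exceeds the carrying capacity, in which case the
    logistic factor drives biomass back down toward ``X_m``.
    """
    model = ModelKind.coerce(model)
    _check_nonnegative("S", S)
    _check_nonnegative("X", X)
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)

    if model is ModelKind.MONOD:
        rate = p.mu_max * S / (p.K_s + S)
    elif model is ModelKind.LOGISTIC:
        rate = p.mu_max * (1.0 - X / p.X_m) * np.ones_like(S)
    else:  # HYBRID
        rate = p.mu_max * (S / (p.K_s + S)) * (1.0 - X / p.X_m)
    return rate if rate.ndim else float(rate)


def batch_rhs(
    model: ModelKind | str,
    p: GrowthParameters,
    state: Sequence[float],
) -> tuple[float, float]:
    """Right-hand side (dX/dt, dS/dt) of the coupled batch ODE system.

    ``dX/dt = mu * X`` and ``dS/dt = -mu * X / Y_xs``.  For the
    substrate-dependent laws (Monod, hybrid) both derivatives are exactly
    zero at S = 0: substrate depletion is a true fixed point, with no
    epsilon floor.
    """
    model = ModelKind.coerce(model)
    X, S = float(state[0]), float(state[1])
    if S <= 0.0 and model in (ModelKind.MONOD, ModelKind.HYBRID):
        return (0.0, 0.0)
    mu = specific_growth_rate(model, p, max(S, 0.0), max(X, 0.0))
    dX = mu * X
    return (dX, -dX / p.Y_xs)


def validate_feasibility(
    p: GrowthParameters,
    batch: BatchConditions | None = None,
    S_F: float | None = None,
) -> list[str]:
    """Check that the carrying capacity is supportable by the substrate supply.

    If all substrate were converted to biomass at yield ``Y_xs``, a batch
    culture can reach at most ``X_0 + Y_xs * S_0`` and a chemostat at most
    ``Y_xs * S_F``.  A carrying capacity above that bound can never be
    attained, so the logistic factor never vanishes; this is legal but
    usually a misconfiguration.  Returns a (possibly empty) list of
    warning messages; the boundary case of exact equality is allowed.
    """
    messages: list[str] = []
    if batch is not None:
        ceiling = batch.S_0 * p.Y_xs + batch.X_0
        if p.X_m > ceiling:
            messages.append(
                f"carrying capacity X_m = {p.X_m} g/L exceeds the substrate-supported "
                f"batch maximum X_0 + Y_xs*S_0 = {ceiling} g/L"
            )
    if S_F is not None:
        ceiling = S_F * p.Y_xs
        if p.X_m > ceiling:
            messages.append(
                f"carrying capacity X_m = {p.X_m} g/L exceeds the substrate-supported "
                f"CSTR maximum Y_xs*S_F = {ceiling} g/L"
            )
    return messages
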