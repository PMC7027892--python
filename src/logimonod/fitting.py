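"""Parameter estimation from batch time courses, and the synthetic-data generator.

The estimator recovers the kinetic constants (mu_max, K_s, X_m, Y_xs)
from observed (t, X) or (t, X, S) batch data by weighted nonlinear least
squares.  Residuals are relative (log-scale for biomass): a growth curve
spans roughly two orders of magnitude, and an absolute loss would ignore
the early exponential phase entirely.  Optimisation runs in log-parameter
space under box bounds, with a seeded multi-start to reduce the risk of
local minima.  The initial state (X_0, S_0) is co-estimated as nuisance
parameters anchored at the first observation, so noisy first samples do
not bias the kinetic constants.

The generator evaluates the closed-form batch solution on a sampling
schedule and applies independent multiplicative log-normal noise of a
given coefficient of variation to biomass and substrate, which emulates
the roughly constant relative error of OD and assay measurements.  It is
mean-one noise: ``exp(N(-sigma^2/2, sigma^2))`` with
``sigma^2 = ln(1 + cv^2)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import batch_analytic, batch_numeric
from .models import BatchConditions, GrowthParameters, ModelKind

__all__ = [
    "TimeCourseData",
    "FitResult",
    "FitError",
    "ParameterBounds",
    "generate_timecourse",
    "fit_batch",
    "default_bounds",
]

#: Substrate residuals are relative to max(S_obs, floor), where the floor is
#: this fraction of the largest observed substrate — S legitimately reaches 0.
_S_FLOOR_FRACTION = 0.05

_MIN_OBSERVATIONS = 6


class FitError(RuntimeError):
    """All optimisation starts failed to converge."""


@dataclass
class TimeCourseData:
    """Observed batch time course: strictly increasing times, positive biomass.

    ``S`` is optional; individual missing substrate values may be NaN.
    ``noise_model`` and ``seed`` record provenance when the data are
    synthetic.
    """

    t: np.ndarray
    X: np.ndarray
    S: np.ndarray | None = None
    noise_model: str = "none"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.t.size != self.X.size:
            raise ValueError("t and X must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.X <= 0.0):
            raise ValueError("observed biomass must be strictly positive")
        if self.S is not None:
            self.S = np.asarray(self.S, dtype=float)
            if self.S.size != self.t.size:
                raise ValueError("S must match t in length")
            if np.all(np.isnan(self.S)):
                self.S = None

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time_hr": self.t, "biomass_g_L": self.X})
        if self.S is not None:
            frame["substrate_g_L"] = self.S
        return frame

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# noise_model={self.noise_model} seed={self.seed}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path) -> "TimeCourseData":
        frame = pd.read_csv(path, comment="#")
        for col in ("time_hr", "biomass_g_L"):
            if col not in frame.columns:
                raise ValueError(f"time-course CSV missing column {col!r}")
        S = frame["substrate_g_L"].to_numpy() if "substrate_g_L" in frame.columns else None
        return cls(t=frame["time_hr"].to_numpy(), X=frame["biomass_g_L"].to_numpy(), S=S)


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds (inclusive) for the four kinetic constants."""

    mu_max: tuple[float, float] = (1e-3, 10.0)
    K_s: tuple[float, float] = (1e-3, 100.0)
    X_m: tuple[float, float] = (1e-3, 1e3)
    Y_xs: tuple[float, float] = (1e-3, 1.5)

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_s", "X_m", "Y_xs"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi) or not math.isfinite(hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi < inf")


def default_bounds(data: TimeCourseData) -> ParameterBounds:
    """Data-adapted default bounds: X_m confined to (max X_obs, 10 max X_obs]."""
    x_max = float(np.max(data.X))
    return ParameterBounds(X_m=(x_max * (1.0 + 1e-6), x_max * 10.0))


@dataclass
class FitResult:
    """Outcome of a batch fit: estimates, fit quality and diagnostics.

    ``stderr`` holds approximate per-parameter standard errors from the
    Gauss-Newton curvature at the optimum (NaN where not estimable).
    ``weak_X_m`` flags a carrying capacity that the data barely probe
    (largest observed biomass below 80% of the estimate).
    """

    params: GrowthParameters
    conditions: BatchConditions
    rss: float
    stderr: dict[str, float]
    converged: bool
    model: ModelKind
    n_obs: int
    weak_X_m: bool
    start_diagnostics: list[str] = field(default_factory=list)

    def to_mapping(self) -> dict:
        return {
            "model": self.model.value,
            "params": self.params.to_mapping(),
            "initial_conditions": self.conditions.to_mapping(),
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "weak_X_m": self.weak_X_m,
        }


def generate_timecourse(
    model: ModelKind | str,
    p: GrowthParameters,
    bc: BatchConditions,
    schedule,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> TimeCourseData:
    """Synthetic batch observations from the closed-form solution plus noise.

    ``noise_cv`` is the coefficient of variation of mean-one multiplicative
    log-normal noise, applied independently to biomass and substrate.
    Deterministic for a fixed seed.
    """
    model = ModelKind.coerce(model)
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be non-negative")
    traj = batch_analytic.sample_trajectory(model, p, bc, schedule)
    X = traj.X.copy()
    S = traj.S.copy()
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        X = X * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=X.size))
        S = S * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=S.size))
    tag = f"lognormal(cv={noise_cv})" if noise_cv > 0.0 else "none"
    return TimeCourseData(t=traj.t, X=X, S=S, noise_model=tag, seed=seed)


def _free_parameter_names(model: ModelKind, has_substrate: bool) -> list[str]:
    # K_s plays no role in logistic growth and X_m none in Monod growth;
    # Y_xs enters logistic predictions only through substrate.
    names = ["mu_max"]
    if model in (ModelKind.MONOD, ModelKind.HYBRID):
        names.append("K_s")
    if model in (ModelKind.LOGISTIC, ModelKind.HYBRID):
        names.append("X_m")
    if model is not ModelKind.LOGISTIC or has_substrate:
        names.append("Y_xs")
    return names


def _predict(
    model: ModelKind,
    p: GrowthParameters,
    bc: BatchConditions,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    try:
        X = np.array([batch_analytic.biomass_at_time(model, p, bc, ti) for ti in t])
    except (ValueError, RuntimeError):
        # inversion can fail at extreme trial parameters; fall back to the ODE
        grid = t if t[0] == 0.0 else np.concatenate(([0.0], t))
        traj = batch_numeric.integrate_batch(
            model, p, bc, grid,
            settings=batch_numeric.IntegratorSettings(rel_tol=1e-9, abs_tol=1e-11),
        )
        X = traj.X if t[0] == 0.0 else traj.X[1:]
    S = bc.S_0 - (X - bc.X_0) / p.Y_xs
    return X, np.maximum(S, 0.0)


def fit_batch(
    model: ModelKind | str,
    data: TimeCourseData,
    bounds: ParameterBounds | None = None,
    init: GrowthParameters | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Weighted nonlinear least-squares fit of a growth model to batch data.

    Minimises the sum of squared log-residuals of biomass plus squared
    floored-relative residuals of substrate (where observed).  Runs
    ``n_starts`` seeded starts drawn log-uniformly within the bounds (the
    first start is ``init``, or the geometric mid-point of the bounds)
    and returns the best converged result.
    """
    model = ModelKind.coerce(model)
    if len(data) < _MIN_OBSERVATIONS:
        raise ValueError(
            f"at least {_MIN_OBSERVATIONS} observations are required, got {len(data)}"
        )
    bounds = bounds or default_bounds(data)
    has_substrate = data.S is not None

    t0 = float(data.t[0])
    t_shifted = data.t - t0
    X0_anchor = float(data.X[0])
    if has_substrate and np.isfinite(data.S[0]):
        S0_anchor = float(max(data.S[0], 1e-6))
    else:
        S0_anchor = float(np.nanmax(data.S)) if has_substrate else float(np.max(data.X))

    kinetic_names = _free_parameter_names(model, has_substrate)
    free_names = kinetic_names + ["X_0", "S_0"]
    bound_map = {
        "mu_max": bounds.mu_max,
        "K_s": bounds.K_s,
        "X_m": bounds.X_m,
        "Y_xs": bounds.Y_xs,
        "X_0": (X0_anchor / 5.0, X0_anchor * 5.0),
        "S_0": (S0_anchor / 5.0, S0_anchor * 5.0),
    }
    lo = np.log([bound_map[n][0] for n in free_names])
    hi = np.log([bound_map[n][1] for n in free_names])

    fixed = {"mu_max": 1.0, "K_s": 1.0, "X_m": max(np.max(data.X) * 2.0, 1.0), "Y_xs": 0.5}
    if init is not None:
        fixed.update(init.to_mapping())

    s_max = float(np.nanmax(data.S)) if has_substrate else 1.0
    s_floor = max(_S_FLOOR_FRACTION * s_max, 1e-9)
    if has_substrate:
        s_valid = np.isfinite(data.S)

    def unpack(theta: np.ndarray) -> tuple[GrowthParameters, BatchConditions]:
        values = dict(zip(free_names, np.exp(theta)))
        kw = {n: values.get(n, fixed[n]) for n in ("mu_max", "K_s", "X_m", "Y_xs")}
        return (
            GrowthParameters(**kw),
            BatchConditions(X_0=values["X_0"], S_0=values["S_0"]),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p_trial, bc_trial = unpack(theta)
        X_pred, S_pred = _predict(model, p_trial, bc_trial, t_shifted)
        r = list(np.log(np.maximum(X_pred, 1e-300) / data.X))
        if has_substrate:
            denom = np.maximum(data.S[s_valid], s_floor)
            r.extend((S_pred[s_valid] - data.S[s_valid]) / denom)
        return np.asarray(r)

    # starting points: init (or bound mid-point) first, then log-uniform draws
    # from a dedicated generator, independent of any data-noise stream
    rng = np.random.default_rng((int(seed) * 2654435761 + 97) % (2**31 - 1))
    theta0 = np.array(
        [
            math.log(fixed[n]) if (init is not None and n in fixed and n in kinetic_names)
            else 0.5 * (lo[i] + hi[i])
            for i, n in enumerate(free_names)
        ]
    )
    theta0[-2] = math.log(X0_anchor)
    theta0[-1] = math.log(S0_anchor)
    theta0 = np.clip(theta0, lo, hi)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        draw = lo + (hi - lo) * rng.uniform(size=lo.size)
        draw[-2] = math.log(X0_anchor)
        draw[-1] = math.log(S0_anchor)
        starts.append(draw)

    best = None
    diagnostics: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, start in enumerate(starts):
            try:
                res = least_squares(
                    residuals, start, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
                )
            except Exception as exc:  # noqa: BLE001 - per-start diagnostics
                diagnostics.append(f"start {k}: failed ({exc})")
                continue
            diagnostics.append(f"start {k}: cost={res.cost:.6g} status={res.status}")
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res

    if best is None:
        raise FitError("no optimisation start converged; " + "; ".join(diagnostics))

    p_hat, bc_hat = unpack(best.x)
    rss = float(2.0 * best.cost)

    # Gauss-Newton standard errors, mapped from log-space (se_p = p * se_logp)
    stderr = {n: float("nan") for n in ("mu_max", "K_s", "X_m", "Y_xs")}
    dof = best.fun.size - best.x.size
    if dof > 0:
        try:
            JTJ = best.jac.T @ best.jac
            cov = np.linalg.pinv(JTJ) * (rss / dof)
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
            values = np.exp(best.x)
            for i, n in enumerate(free_names):
                if n in stderr:
                    stderr[n] = float(values[i] * se_log[i])
        except np.linalg.LinAlgError:
            pass

    weak = (
        model in (ModelKind.LOGISTIC, ModelKind.HYBRID)
        and float(np.max(data.X)) < 0.8 * p_hat.X_m
    )
    return FitResult(
        params=p_hat,
        conditions=bc_hat,
        rss=rss,
        stderr=stderr,
        converged=True,
        model=model,
        n_obs=len(data),
        weak_X_m=bool(weak),
        start_diagnostics=diagnostics,
    )
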