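# Methods

## Models

All three growth laws are unstructured (biomass is a single pool) and
isothermal, with constant kinetic parameters and a single rate-limiting
substrate coupled through a constant yield:

    dX/dt = mu(S, X) * X
    dS/dt = -(1/Y_xs) * dX/dt

| parameter | meaning                           | units | typical range |
|-----------|-----------------------------------|-------|---------------|
| `mu_max`  | maximal specific growth rate      | 1/hr  | 0.1 – 2       |
| `K_s`     | substrate half-saturation constant| g/L   | 0.1 – 10      |
| `X_m`     | carrying capacity                 | g/L   | 1 – 100       |
| `Y_xs`    | biomass yield on substrate        | g/g   | 0.2 – 1       |

`K_s` is inert under the Logistic law and `X_m` under the Monod law;
both are carried in the shared parameter object so a model comparison
never reshapes the configuration. Yields above 1 g/g are accepted with
a warning (they can be legitimate for rich media where the balanced
substrate is not the main carbon source). A carrying capacity above the
substrate-supported ceiling (X_0 + Y_xs·S_0 in batch, Y_xs·S_F in a
chemostat) is flagged as a feasibility warning, with the boundary case
of exact equality allowed.

## Batch closed forms

Conservation gives S = (A − X)/Y_xs with A = X_0 + Y_xs·S_0, reducing
the coupled system to one separable ODE in X. With B = K_s·Y_xs + A:

- Monod:  mu_max·t = (B/A)·ln(X/X_0) + (K_s·Y_xs/A)·ln[(A−X_0)/(A−X)],
  increasing on (X_0, A) and diverging logarithmically at A (full
  substrate depletion).
- Logistic: the explicit sigmoid X(t) = X_m / (1 + ((X_m−X_0)/X_0)·e^(−mu_max·t)).
  Substrate follows by conservation and may go genuinely negative when
  X_m exceeds the substrate-supported ceiling, since logistic growth is
  substrate-blind; the value is returned with a logged warning.
- Hybrid: mu_max·t/X_m = a·ln(X/X_0) + b·ln[(A−X_0)/(A−X)] +
  c·ln[(X_m−X_0)/(X_m−X)] with a = B/(A·X_m), b = K_s·Y_xs/(A·(X_m−A)),
  c = (B−X_m)/(X_m·(A−X_m)), derived by partial fractions of
  (B−X)/(X·(A−X)·(X_m−X)). Whichever of the two singular factors lies
  lower bounds the trajectory: X_sup = min(X_m, A).

These forms are taken as correct only because they reproduce the
independent ODE integration to ≤1e−6 g/L over a 29-point parameter grid
(observed agreement is ~1e−10 g/L); the numeric route, not the algebra,
is treated as ground truth in the test suite. Limiting behaviour is
built in: X_m → ∞ recovers the Monod relation term-by-term and
K_s → 0 recovers the logistic inverse.

Degenerate case X_m = A: coefficients b and c individually blow up
(the limit itself is finite but a removable complication). Detection at
|X_m − A| < 1e−9·X_m perturbs X_m by one part in 1e6 with a warning,
which changes the trajectory by far less than any stated tolerance.

Biomass at a given time inverts t(X) with Brent's method on
[X_0·(1+1e−12), X_sup·(1−margin)], walking the upper margin down from
1e−12 to 1e−15 relative; if even the tightest margin lies below the
requested time, X_sup is returned — the asymptote has been reached at
float resolution. Inversion tolerance is 1e−12 absolute in X (the
contract is ≤1e−10 g/L). Near the asymptote dt/dX diverges like
1/(X_sup−X), so the *time* round-trip degrades there even though X is
accurate; for the reference Monod setting this happens past roughly
15 hr. All exponentials are algebraically bounded before evaluation, so
no mu_max·t overflows.

## Numerical oracle

`batch_numeric` integrates the raw ODE system with DOP853 at
rtol 1e−10 / atol 1e−12 (Radau is selectable for pathological
parameter sets; the system is non-stiff for realistic ones). The Monod
factor has a corner at S = 0; the right-hand side clamps S at zero,
depletion is an exact fixed point, and a terminal event stops any
decline below S = −1e−12. Crossing times for the implicit-form checks
come from `solve_ivp` event detection on X − X_target. An unreachable
target raises a dedicated `TargetUnreachableError` so it is never
confused with an integration failure.

## Chemostat

On the non-trivial branch mu = D, giving textbook closed forms for
Monod and Logistic. For the hybrid model, substituting
X = Y_xs·(S_F − S) into mu(S, X) = D yields

    mu_max·Y_xs·S^2 + [mu_max·(X_m − Y_xs·S_F) − D·X_m]·S − D·K_s·X_m = 0.

The constant term is negative for D > 0, so exactly one root is
positive; that root is selected (computed with the cancellation-free
conjugate form when the linear coefficient is positive) and always lies
in (0, S_F) below washout. The selected root satisfies both mass
balances to ~1e−15 and is the attractor of the dynamic chemostat ODEs,
which the tests verify by integrating from perturbed states.

Washout: D_w = mu_max·S_F/(K_s + S_F) for Monod and hybrid (at X = 0
the self-inhibition factor is 1, an identity the tests check across a
capacity grid) and D_w = mu_max for Logistic. For D ≥ D_w the washout
branch (S_F, 0) is returned explicitly rather than the negative-biomass
analytic continuation. A Logistic operating point with X_m > Y_xs·S_F
and low D would need S* < 0; this raises an error rather than clamping,
because it indicates a misconfigured model, not a numerical issue.

Optimal dilution: D_opt = mu_max·(1 − sqrt(K_s/(K_s+S_F))) for Monod
and mu_max/2 for Logistic — standard results, verified in the tests
against grid maximisation rather than assumed. The hybrid optimum has
no convenient closed form and is found by bounded scalar minimisation
of −D·X*(D) bracketed by a 201-point pre-scan that also guards the
unimodality assumption.

## Parameter estimation

The loss is the sum of squared log-residuals of biomass plus squared
relative residuals of substrate, the natural weighting when measurement
error is multiplicative (OD-style readings). Substrate residuals are
floored at 5% of the largest observed value to avoid infinite weight as
S → 0. Optimisation runs in log-parameter space (positivity for free)
with `scipy.optimize.least_squares` under box bounds; default bounds
are mu_max ∈ (0, 10], K_s ∈ (0, 100], X_m ∈ (max X_obs, 10·max X_obs],
Y_xs ∈ (0, 1.5]. Eight starts by default: the supplied initial guess
(or the geometric mid-point of the bounds) plus log-uniform draws from
a dedicated seeded generator, independent of the data-noise stream.
The initial state (X_0, S_0) is co-estimated as nuisance parameters
anchored within a factor of five of the first observation, so a noisy
first sample does not bias the kinetics. Parameters a model cannot see
(K_s for Logistic, X_m for Monod, Y_xs for Logistic without substrate
data) are excluded from the free set. Standard errors come from the
Gauss–Newton curvature at the optimum and are approximate. A carrying
capacity estimate is flagged as weakly identified when the largest
observed biomass is below 80% of it.

Identifiability in practice: with 40 observations over 25 hr and 2%
multiplicative noise at the reference batch setting, mu_max, X_m and
Y_xs recover to ~1%, while K_s — which only shapes the curve where
S ≈ K_s — carries a standard error of roughly 6%. Expectations of
K_s accuracy much below that level at this noise level are not
realistic for any estimator under this design.

## Synthetic data

The generator evaluates the closed-form trajectory on a sampling
schedule and multiplies each observation by mean-one log-normal noise,
exp(N(−σ²/2, σ²)) with σ² = ln(1 + cv²), independently for X and S,
from a single `numpy` Generator seeded by the caller. It emulates the
proportional error of optical-density and enzymatic assays. It does
**not** emulate lag or death phases, autocorrelated drift, sampling-
volume effects, below-detection censoring, or measurement error in
time — so recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to real-world artefacts.

## Design choices

- Substrate is always computed from the conservation identity rather
  than its own implicit relation; on the reachable interval the biomass
  solution is unique, so the two routes coincide and the identity is
  cheaper and better conditioned.
- Trajectory and sweep CSVs print 12 significant digits, making text
  round-trips lossless at working precision and golden-file comparisons
  meaningful.
- Config files may be YAML or JSON (parsed by one YAML reader); CLI
  flags override file values; unknown keys are rejected rather than
  ignored.

## Known limitations

- No lag/death phases, product-formation kinetics, substrate or product
  inhibition terms, multi-substrate kinetics, fed-batch feeds, or
  temperature/pH dependence of parameters.
- Chemostat support covers steady states and their stability check, not
  transient start-up as a user-facing feature; no recycle or
  multi-stage configurations.
- Standard errors are curvature-based approximations, not bootstrap or
  Bayesian intervals.
- The hybrid time-of-biomass relation is evaluated in its partial-
  fraction form; extremely small K_s·Y_xs (below ~1e−12 g/L) pushes
  coefficient b toward 0·∞ territory and relies on the logistic limit
  being taken analytically, as the tests do.
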