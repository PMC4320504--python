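"""Four-parameter estimation for one recovery curve.

The procedure mirrors classical time-domain process identification:

1. *Graphical initialisation* — lag time from the undershoot turning
   point (or the slope-break of the re-warming onset), the pole from the
   63%-of-final-value rise time, the gain from the steady-state output
   over the set point, and the disturbance from the open-loop asymptote.
2. *Simplex refinement* — Nelder-Mead on the mean-squared-error cost,
   with quadratic penalties for leaving the search space.
3. *Bounded nonlinear least squares* — trust-region refinement of
   (LT, a, d, K) within the search-space box; T and r are measured
   inputs and are never fitted.

Fits whose final cost exceeds 1 (mean squared misfit above ~1 degC RMS)
are excluded from downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .model import simulate_response
from .series import DeviationSeries, ModelParams, ReferenceSignal

__all__ = [
    "SearchSpace",
    "FitResult",
    "cost_function",
    "graphical_init",
    "simplex_refine",
    "fit_nls",
    "fit_curve",
    "exclude_poor_fits",
    "EXCLUSION_THRESHOLD",
]

#: Fits with mean-squared cost strictly above this are excluded.
EXCLUSION_THRESHOLD = 1.0

_PENALTY_WEIGHT = 1e3


@dataclass(frozen=True)
class SearchSpace:
    """Admissible box for (LT, a, d, K)."""

    lt_bounds: tuple[float, float] = (0.0, 22.0)
    a_bounds: tuple[float, float] = (0.01, 30.0)
    d_bounds: tuple[float, float] = (-5.0, 10.0)
    k_bounds: tuple[float, float] = (-5.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("lt_bounds", "a_bounds", "d_bounds", "k_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array(
            [self.lt_bounds[0], self.a_bounds[0], self.d_bounds[0], self.k_bounds[0]]
        )

    @property
    def upper(self) -> np.ndarray:
        return np.array(
            [self.lt_bounds[1], self.a_bounds[1], self.d_bounds[1], self.k_bounds[1]]
        )

    def clip(self, params: ModelParams) -> ModelParams:
        x = np.clip(params.as_array(), self.lower, self.upper)
        return ModelParams.from_array(x)

    def contains(self, params: ModelParams, atol: float = 1e-9) -> bool:
        x = params.as_array()
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )

    def center(self) -> ModelParams:
        return ModelParams.from_array((self.lower + self.upper) / 2.0)


@dataclass
class FitResult:
    """Estimate for one curve, with provenance and quality flags."""

    params: ModelParams
    cost: float
    n_points: int
    converged: bool
    excluded: bool = field(default=False)
    init_params: ModelParams | None = None

    def __post_init__(self) -> None:
        self.excluded = self.cost > EXCLUSION_THRESHOLD


def cost_function(observed: DeviationSeries, simulated: DeviationSeries) -> float:
    """Mean squared misfit f = (1/NE) sum_i (y*_i - y^e_i)^2, in degC^2."""
    yo = observed.values
    ys = simulated.values
    if yo.size != ys.size:
        raise ValueError(f"length mismatch: {yo.size} vs {ys.size}")
    if yo.size < 4:
        raise ValueError("cost needs at least 4 points")
    return float(np.mean((ys - yo) ** 2))


def _mse(observed: np.ndarray, simulated: np.ndarray) -> float:
    return float(np.mean((simulated - observed) ** 2))


def graphical_init(
    recovery: DeviationSeries, ref: ReferenceSignal, space: SearchSpace | None = None
) -> ModelParams:
    """Graphical time-domain initial guess for (LT, a, d, K).

    LT from the undershoot turning point (curve minimum) or, when no
    undershoot exists, the largest slope break (second difference) that
    marks the re-warming onset; a from the 63%-rise time after LT; the
    whole-loop gain (final value over the set point r) is mapped onto the
    controller gain via K0 = gain * a0 because the plant itself has
    unitary gain; d from the pre-switch extremum, which estimates the
    open-loop asymptote.  Everything is clipped into the search space.
    """
    space = space or SearchSpace()
    v = recovery.values
    t = recovery.grid.times
    n = v.size
    if n < 8:
        raise ValueError("graphical initialisation needs at least 8 samples")
    scale = float(np.ptp(v))
    if scale < 1e-9:
        warnings.warn("flat curve: falling back to search-space centre", stacklevel=2)
        return space.center()
    y_final = float(np.mean(v[-3:]))

    i_min = int(np.argmin(v))
    undershoot = v[i_min] < min(0.0, v[0]) - 0.02 * scale
    if undershoot:
        i_lt = i_min
    else:
        d2 = np.diff(v, n=2)
        if d2.size and float(np.max(d2)) > 0.02 * scale:
            # switch sits just before the largest upward slope break
            i_lt = int(np.argmax(d2)) + 1
        else:
            i_lt = n - 1  # no re-warming onset: clips to the LT upper bound
    lt0 = float(t[i_lt])

    v_lt = float(v[i_lt])
    target = v_lt + 0.632 * (y_final - v_lt)
    tau = 0.0
    rest = v[i_lt:]
    crossed = rest >= target if y_final >= v_lt else rest <= target
    hits = np.nonzero(crossed)[0]
    if hits.size and hits[0] > 0:
        tau = float(hits[0]) * recovery.grid.dt
    a0 = 1.0 / tau if tau > 0 else space.a_bounds[1]

    gain0 = y_final / ref.r if abs(ref.r) > 1e-12 else 1.0
    k0 = gain0 * a0
    d0 = v_lt
    return space.clip(
        ModelParams(lag_time=lt0, pole=a0, disturbance=d0, integral_gain=k0)
    )


def _objective(
    x: np.ndarray,
    observed: np.ndarray,
    grid,
    r: float,
    space: SearchSpace,
) -> float:
    lo, hi = space.lower, space.upper
    xc = np.clip(x, lo, hi)
    violation = np.maximum(0.0, lo - x) + np.maximum(0.0, x - hi)
    sim = simulate_response(ModelParams.from_array(xc), r, grid)
    return _mse(observed, sim.values) + _PENALTY_WEIGHT * float(np.sum(violation**2))


def simplex_refine(
    recovery: DeviationSeries,
    ref: ReferenceSignal,
    init: ModelParams,
    space: SearchSpace | None = None,
    max_iter: int = 500,
) -> ModelParams:
    """Nelder-Mead refinement of the graphical guess (deterministic).

    Out-of-box proposals are penalised quadratically; the incumbent is
    clipped back into the box on return and is never worse (in cost)
    than the clipped initial guess.
    """
    space = space or SearchSpace()
    obs = recovery.values
    grid = recovery.grid
    res = minimize(
        _objective,
        init.as_array(),
        args=(obs, grid, ref.r, space),
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": 1e-4,  # the NLS stage polishes; no need to converge tighter
            "fatol": 1e-10,
            "adaptive": False,
        },
    )
    refined = space.clip(ModelParams.from_array(res.x))
    init_clipped = space.clip(init)
    cost_ref = _mse(obs, simulate_response(refined, ref.r, grid).values)
    cost_init = _mse(obs, simulate_response(init_clipped, ref.r, grid).values)
    return refined if cost_ref <= cost_init else init_clipped


def fit_nls(
    recovery: DeviationSeries,
    ref: ReferenceSignal,
    init: ModelParams,
    space: SearchSpace | None = None,
    max_iterations: int = 200,
) -> FitResult:
    """Bound-constrained trust-region least squares over (LT, a, d, K).

    The residual vector is scaled by 1/sqrt(NE) so the reported cost is
    the mean squared error; T and r are fixed measured inputs.  Returns
    the best of the refined and initial points, so the cost never
    increases across the pipeline.
    """
    space = space or SearchSpace()
    obs = recovery.values
    grid = recovery.grid
    ne = obs.size
    lo, hi = space.lower, space.upper
    eps = 1e-9 * np.maximum(1.0, np.abs(hi - lo))
    x0 = np.clip(init.as_array(), lo + eps, hi - eps)
    sqrt_ne = np.sqrt(ne)

    def residuals(x: np.ndarray) -> np.ndarray:
        sim = simulate_response(ModelParams.from_array(x), ref.r, grid)
        return (sim.values - obs) / sqrt_ne

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-8,
                ftol=1e-10,
                gtol=1e-12,
                max_nfev=max_iterations * (len(x0) + 1),
            )
            x_best, converged = res.x, bool(res.status > 0)
        except Exception as exc:  # singular Jacobian at a degenerate optimum
            warnings.warn(f"least-squares refinement failed: {exc}", stacklevel=2)
            x_best, converged = x0, False

    cand = space.clip(ModelParams.from_array(x_best))
    cost_cand = _mse(obs, simulate_response(cand, ref.r, grid).values)
    init_clipped = space.clip(init)
    cost_init = _mse(obs, simulate_response(init_clipped, ref.r, grid).values)
    if cost_init < cost_cand:
        cand, cost_cand = init_clipped, cost_init
        converged = False
    return FitResult(
        params=cand,
        cost=cost_cand,
        n_points=ne,
        converged=converged,
        init_params=init,
    )


def fit_curve(
    recovery: DeviationSeries,
    ref: ReferenceSignal,
    space: SearchSpace | None = None,
) -> FitResult:
    """Full estimation pipeline: graphical init -> simplex -> bounded NLS."""
    space = space or SearchSpace()
    init = graphical_init(recovery, ref, space)
    refined = simplex_refine(recovery, ref, init, space)
    result = fit_nls(recovery, ref, refined, space)
    result.init_params = init
    return result


def exclude_poor_fits(
    fits: list[FitResult], threshold: float = EXCLUSION_THRESHOLD
) -> list[FitResult]:
    """Drop fits whose cost is strictly above the threshold (cost == 1 kept)."""
    for f in fits:
        f.excluded = f.cost > threshold
    retained = [f for f in fits if not f.excluded]
    return retained
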