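"""Two-unit homeostatic feedback model of post-exercise skin re-warming.

The thermoregulatory response is modelled as a supervisor plus a feedback
executor.  The executor is a first-order unitary-gain plant

    dy/dt = a * (u - y),        u = m + d,

driven by an integral controller acting on the output error e = r - y,

    dm/dt = K * (r - y).

The supervisor keeps the loop *open* during the lag time (t < LT): the
controller is disabled (m = 0) and only the passive heat-exchange input d
drives the plant, giving the closed form y(t) = d * (1 - exp(-a t)).  At
t = LT the loop closes and the integral action steers y toward the
reference r (basal minus post-exercise temperature), with zero
steady-state error for K > 0.

Everything here operates on deviation coordinates (see
:mod:`thermofit.series`); the coupled closed-loop system is linear
time-invariant and is solved exactly by eigendecomposition, with a
matrix-exponential fallback for the critically damped boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .series import (
    ControlState,
    DeviationSeries,
    InvalidParameterError,
    ModelParams,
    TemperatureSeries,
    TimeGrid,
)

__all__ = [
    "simulate_open_loop",
    "simulate_closed_loop",
    "simulate_response",
    "to_absolute",
]

# Relative eigenvalue gap below which the closed-loop system is treated as
# critically damped and propagated by matrix exponentials instead.
_DEGENERATE_GAP = 1e-7


def simulate_open_loop(params: ModelParams, grid: TimeGrid) -> DeviationSeries:
    """Open-loop response: plant driven by the constant disturbance only.

    Closed form ``y(t) = d * (1 - exp(-a t))`` with zero initial
    conditions; the controller is disabled during the lag time.
    """
    if grid.t0 != 0:
        raise InvalidParameterError("open-loop grid must start at t0 = 0")
    if params.pole < 0:
        raise InvalidParameterError(f"plant pole must be >= 0, got {params.pole}")
    t = grid.times
    y = params.disturbance * (1.0 - np.exp(-params.pole * t))
    return DeviationSeries(grid=grid, values=y)


def _closed_loop_trajectory(
    a: float, k: float, d: float, r: float, y0: float, m0: float, tau: np.ndarray
) -> np.ndarray:
    """Exact solution of dy = a(m+d-y), dm = K(r-y) at local times tau >= 0."""
    if k == 0.0:
        # Controller inert: plant relaxes toward m0 + d (or holds if a = 0).
        if a == 0.0:
            return np.full_like(tau, y0, dtype=float)
        target = m0 + d
        return target + (y0 - target) * np.exp(-a * tau)
    if a <= 0.0:
        raise InvalidParameterError(
            f"closed loop with K != 0 requires a stable plant pole a > 0, got a={a}"
        )
    disc = complex(a * a - 4.0 * a * k)
    sq = np.sqrt(disc)
    lam1 = (-a + sq) / 2.0
    lam2 = (-a - sq) / 2.0
    if abs(lam1 - lam2) <= _DEGENERATE_GAP * max(1.0, abs(lam1)):
        return _closed_loop_expm(a, k, d, r, y0, m0, tau)
    # Steady state (r, r - d); modes v_i = (1, -K/lam_i).
    dy0 = y0 - r
    dm0 = m0 - (r - d)
    c1 = (lam1 * dy0 + a * dm0) / (lam1 - lam2)
    c2 = dy0 - c1
    y = r + (c1 * np.exp(lam1 * tau) + c2 * np.exp(lam2 * tau)).real
    return y


def _closed_loop_expm(
    a: float, k: float, d: float, r: float, y0: float, m0: float, tau: np.ndarray
) -> np.ndarray:
    """Matrix-exponential propagation of the augmented affine system."""
    M = np.array(
        [
            [-a, a, a * d],
            [-k, 0.0, k * r],
            [0.0, 0.0, 0.0],
        ]
    )
    order = np.argsort(tau)
    z = np.array([y0, m0, 1.0])
    out = np.empty_like(tau, dtype=float)
    t_prev = 0.0
    for idx in order:
        step = tau[idx] - t_prev
        if step > 0:
            z = expm(M * step) @ z
            t_prev = tau[idx]
        out[idx] = z[0]
    return out


def simulate_closed_loop(
    params: ModelParams, r: float, grid: TimeGrid, init: ControlState
) -> DeviationSeries:
    """Closed-loop response from the state supplied at ``grid.t0``.

    Solves the coupled system dy/dt = a(m + d - y), dm/dt = K(r - y); for
    K > 0 the integral action drives y to r with zero steady-state error.
    """
    if not np.isfinite(r):
        raise InvalidParameterError("reference r must be finite")
    tau = grid.times - grid.t0
    y = _closed_loop_trajectory(
        params.pole, params.integral_gain, params.disturbance, r, init.y, init.m, tau
    )
    return DeviationSeries(grid=grid, values=y)


def simulate_response(params: ModelParams, r: float, grid: TimeGrid) -> DeviationSeries:
    """Full supervised response: open loop on [0, LT), closed loop after.

    The closed-loop phase is initialised from the open-loop closed form
    evaluated *exactly* at LT (y is continuous across the switch) with the
    integrator reset, m(LT) = 0.  If LT reaches past the grid the whole
    response is open-loop.
    """
    if grid.t0 != 0:
        raise InvalidParameterError("response grid must start at t0 = 0")
    lt = params.lag_time
    if lt >= grid.t_end:
        return simulate_open_loop(params, grid)
    t = grid.times
    y = np.empty_like(t)
    open_mask = t < lt
    if params.pole < 0:
        raise InvalidParameterError(f"plant pole must be >= 0, got {params.pole}")
    y[open_mask] = params.disturbance * (1.0 - np.exp(-params.pole * t[open_mask]))
    y_switch = params.disturbance * (1.0 - np.exp(-params.pole * max(lt, 0.0)))
    tau = t[~open_mask] - max(lt, 0.0)
    y[~open_mask] = _closed_loop_trajectory(
        params.pole, params.integral_gain, params.disturbance, r, y_switch, 0.0, tau
    )
    return DeviationSeries(grid=grid, values=y)


def to_absolute(dev: DeviationSeries, y0: float, **meta) -> TemperatureSeries:
    """Restore absolute temperatures by adding the post-exercise value y0.

    Inverse of :func:`thermofit.preprocessing.deviation_transform`.
    """
    if not np.isfinite(y0):
        raise InvalidParameterError("y0 must be finite")
    return TemperatureSeries(grid=dev.grid, values=dev.values + y0, **meta)
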