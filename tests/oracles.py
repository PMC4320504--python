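"""Independent numeric oracles for the switched feedback model.

These integrate the raw differential equations by brute force and share
no code with the production solver (which is an exact eigendecomposition
of the linear system).  The fixed-step RK4 integrator refines its step
below dt/100 whenever the local dynamics are fast, so the oracle's own
error stays well under the comparison tolerances.
"""

from __future__ import annotations

import math

import numpy as np


def rk4_switched(
    lt: float,
    a: float,
    d: float,
    k: float,
    r: float,
    times: np.ndarray,
    base_substep: float | None = None,
) -> np.ndarray:
    """Brute-force RK4 integration of the switched open/closed-loop system.

    Open loop (t < LT): dy/dt = a (d - y), controller off.
    Closed loop (t >= LT): dy/dt = a (m + d - y), dm/dt = K (r - y),
    with y continuous across the switch and m(LT) = 0.
    """
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    omega = max(a, math.sqrt(abs(a * k)), 1e-6)
    h_max = min(dt / 100.0, 0.01 / omega) if base_substep is None else base_substep

    def f_open(y: float, m: float) -> tuple[float, float]:
        return a * (d - y), 0.0

    def f_closed(y: float, m: float) -> tuple[float, float]:
        return a * (m + d - y), k * (r - y)

    # breakpoints: all sample times plus the switch instant
    events = sorted(set(times.tolist()) | ({lt} if 0.0 < lt < times[-1] else set()))
    out = {}
    y, m = 0.0, 0.0
    t = times[0]
    if t == 0.0:
        out[0.0] = y
    closed = lt <= 0.0
    if closed and lt <= 0.0:
        y, m = 0.0, 0.0
    for t_next in events:
        if t_next <= t:
            if t_next == lt and not closed:
                closed, m = True, 0.0
            continue
        span = t_next - t
        n_sub = max(1, int(math.ceil(span / h_max)))
        h = span / n_sub
        f = f_closed if closed else f_open
        for _ in range(n_sub):
            k1y, k1m = f(y, m)
            k2y, k2m = f(y + 0.5 * h * k1y, m + 0.5 * h * k1m)
            k3y, k3m = f(y + 0.5 * h * k2y, m + 0.5 * h * k2m)
            k4y, k4m = f(y + h * k3y, m + h * k3m)
            y += h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
            m += h / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        t = t_next
        if t == lt and not closed:
            closed, m = True, 0.0  # integrator reset at the switch
        out[t] = y
    return np.array([out[t] for t in times])


def rk4_first_order(a: float, d: float, times: np.ndarray, n_sub: int = 1000):
    """Fixed-step RK4 for dy/dt = a (d - y), y(0) = 0 (open-loop plant)."""
    times = np.asarray(times, dtype=float)
    y = 0.0
    out = [0.0]
    for t0, t1 in zip(times[:-1], times[1:]):
        h = (t1 - t0) / n_sub
        for _ in range(n_sub):
            k1 = a * (d - y)
            k2 = a * (d - (y + 0.5 * h * k1))
            k3 = a * (d - (y + 0.5 * h * k2))
            k4 = a * (d - (y + h * k3))
            y += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y)
    return np.array(out)
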