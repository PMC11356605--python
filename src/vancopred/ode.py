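"""High-accuracy numerical oracle for the two-compartment infusion model.

Integrates the exact system the closed-form engine solves,

    dA1/dt = R(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2
    dE/dt  = k10 A1                      (cumulative eliminated amount)

segment by segment between infusion on/off events so that R(t) is constant
within every integration interval. This module exists to validate the
analytical superposition solution (and its mass balance); it is not used by
the analysis pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .cohort import Regimen
from .pk import PKParameters

__all__ = ["ode_concentration", "ode_state"]


def _infusion_rate(regimen: Regimen, t: float) -> float:
    rate = 0.0
    for d in regimen.doses:
        if d.start_h <= t < d.start_h + d.duration_h:
            rate += d.amount_mg / d.duration_h
    return rate


def ode_state(
    params: PKParameters,
    regimen: Regimen,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """State trajectory (A1, A2, cumulative eliminated E) at requested times.

    ``times`` must be non-negative; returns an array of shape (len(times), 3).
    """
    regimen.validate()
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]

    events = {0.0}
    for d in regimen.doses:
        events.add(d.start_h)
        events.add(d.start_h + d.duration_h)
    breakpoints = sorted(events | set(t_sorted.tolist()))

    k10, k12, k21 = params.k10, params.k12, params.k21

    def rhs(_t, y, rate):
        a1, a2, _ = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2, k10 * a1]

    y = np.zeros(3)
    out = np.zeros((t_sorted.size, 3))
    want = {}
    for i, t in enumerate(t_sorted):
        want.setdefault(t, []).append(i)
    for t in want.get(0.0, []):
        out[t] = y
    for left, right in zip(breakpoints[:-1], breakpoints[1:]):
        if left >= t_sorted[-1]:
            break
        rate = _infusion_rate(regimen, 0.5 * (left + right))
        targets = [t for t in want if left < t <= right]
        sol = solve_ivp(
            rhs, (left, right), y, args=(rate,), method="DOP853",
            rtol=rtol, atol=atol, dense_output=bool(targets),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed on [{left}, {right}]: {sol.message}")
        for t in targets:
            for i in want[t]:
                out[i] = sol.sol(t)
        y = sol.y[:, -1]
    result = np.empty_like(out)
    result[order] = out
    return result


def ode_concentration(
    params: PKParameters,
    regimen: Regimen,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Central-compartment concentration (ug/mL) by numerical integration."""
    scalar = np.isscalar(times)
    arr = np.atleast_1d(np.asarray(times, dtype=float))
    state = ode_state(params, regimen, arr, rtol=rtol, atol=atol)
    conc = state[:, 0] / params.v1
    return float(conc[0]) if scalar else conc
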