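"""The Bertalanffy-Putter growth law and its forward simulation.

The model is the two-term first-order ODE

    dv/dt = p * v**a - q * v**b,        a < b,

a family that contains the classical Verhulst/logistic law (a=1, b=2) and the
Gompertz law (a=1, b -> 1+) as special cases. The exponent pair (a, b) sets
the *type* of growth; the coefficient pair (p, q) sets its scale. For p, q > 0
the equation has a stable positive equilibrium at v_eq = (p/q)**(1/(b-a)).

Fitted coefficients are allowed to be negative: a negative q is a diagnostic
for a badly-modelled region of exponent space, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import TrajectoryEscapeError
from .trajectories import GradientSeries, Trajectory

__all__ = [
    "BPParams",
    "bp_rhs",
    "bp_terms",
    "simulate_bp",
    "analytic_gradients",
    "exponential_solution",
    "logistic_solution",
    "equilibrium_volume",
]


@dataclass(frozen=True)
class BPParams:
    """Bertalanffy-Putter parameters.

    p : growth coefficient (per day * volume**(1-a)); may be negative when fitted.
    q : decay coefficient (per day * volume**(1-b)); may be negative when fitted.
    a : growth exponent, dimensionless, >= 0.
    b : decay exponent, dimensionless, with a < b.
    """

    p: float
    q: float
    a: float
    b: float

    def __post_init__(self):
        for name in ("p", "q", "a", "b"):
            val = float(getattr(self, name))
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
            object.__setattr__(self, name, val)
        if self.a < 0 or self.b < 0:
            raise ValueError(f"exponents must be non-negative, got a={self.a}, b={self.b}")
        if not self.a < self.b:
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")


def _check_positive_volume(v):
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be strictly positive (v**a undefined otherwise)")
    return v


def bp_terms(v, a: float, b: float):
    """Term values (v**a, v**b) of the condensed linear-in-coefficients model.

    The fitted linear coefficients (c1, c2) map to model parameters as
    p = c1, q = -c2.
    """
    v = _check_positive_volume(v)
    return v**a, v**b


def bp_rhs(v, params: BPParams):
    """Growth rate p*v**a - q*v**b at volume v (scalar or array)."""
    ta, tb = bp_terms(v, params.a, params.b)
    return params.p * ta - params.q * tb


def equilibrium_volume(params: BPParams) -> float:
    """Positive equilibrium (p/q)**(1/(b-a)); inf when q <= 0 < p, nan if p <= 0."""
    if params.p <= 0:
        return np.nan
    if params.q <= 0:
        return np.inf
    return float((params.p / params.q) ** (1.0 / (params.b - params.a)))


def simulate_bp(
    params: BPParams,
    v0: float,
    t_grid,
    rtol: float = 1e-10,
    atol_factor: float = 1e-12,
    guard: tuple[float, float] = (1e-6, 1e6),
) -> Trajectory:
    """Integrate the growth ODE from v(t0) = v0 and sample it at ``t_grid``.

    Uses adaptive 4/5-order Runge-Kutta with tight tolerances so that the
    simulated "truth" is far more accurate than any finite-difference gradient
    computed from it. Absolute tolerance is ``atol_factor * v0``.

    Raises
    ------
    TrajectoryEscapeError
        If the volume leaves ``(guard[0]*v0, guard[1]*v0)``, signalling
        blow-up or extinction for this parameter set.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 3 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with length >= 3")
    v0 = float(v0)
    if v0 <= 0:
        raise ValueError(f"v0 must be positive, got {v0}")
    v_min, v_max = guard[0] * v0, guard[1] * v0

    def rhs(_t, v):
        return [params.p * v[0] ** params.a - params.q * v[0] ** params.b]

    def hit_floor(_t, v):
        return v[0] - v_min

    def hit_ceiling(_t, v):
        return v[0] - v_max

    hit_floor.terminal = True
    hit_ceiling.terminal = True

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [v0],
        method="RK45",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol_factor * v0,
        events=[hit_floor, hit_ceiling],
        dense_output=False,
    )
    if sol.status == 1:  # terminated by a guard event
        t_event = min(
            (ev[0] for ev in sol.t_events if len(ev)), default=float("nan")
        )
        raise TrajectoryEscapeError(
            f"trajectory left guard bounds ({v_min:.3e}, {v_max:.3e}) "
            f"at t = {t_event:.4g} days",
            time=t_event,
        )
    if not sol.success:
        raise TrajectoryEscapeError(f"integration failed: {sol.message}")
    return Trajectory(t_grid, sol.y[0])


def analytic_gradients(traj: Trajectory, params: BPParams) -> GradientSeries:
    """Exact model gradients dv/dt at the trajectory's volumes.

    Test/analysis hook: substitutes the true right-hand side for
    finite-difference estimates, isolating the fitting machinery from
    differentiation error.
    """
    return GradientSeries(traj.times, bp_rhs(traj.volumes, params))


def exponential_solution(p: float, v0: float, t):
    """Closed form for q = 0, a = 1: v(t) = v0 * exp(p t)."""
    return v0 * np.exp(p * np.asarray(t, dtype=float))


def logistic_solution(p: float, q: float, v0: float, t):
    """Closed form for a = 1, b = 2 (Verhulst): v = p / (q + (p/v0 - q) e^{-pt})."""
    t = np.asarray(t, dtype=float)
    return p / (q + (p / v0 - q) * np.exp(-p * t))
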