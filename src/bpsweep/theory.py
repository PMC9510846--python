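"""Gradient-flow convergence experiments for toy network models.

Two toys motivate the white-box fitting approach by showing how opaque even
the simplest trained models are:

* a *linear* model y = sum_m w_m z_m with fixed term values z and weights
  adjusted by continuous gradient flow on the loss

      L = |y - y'|**m + beta * sum_m |w_m|**n ;

  for the m=1, n=2 loss the flow can converge either to the target
  ("absolute convergence") or — whenever |y'| exceeds S/(2 beta) with
  S = sum_m z_m**2 — to the *information-free* value of magnitude S/(2 beta),
  which carries no information about the target at all. For even m = n the
  converged output has the closed form y = y' / (1 + beta**(1/(n-1)) / S_n)
  with S_n = sum_m |z_m|**(n/(n-1)).

* a two-layer *ReLU* network y = sum_k c_k max(v_k, 0) + delta with
  v_k = a_ki x_i + a_kj x_j + b_k, trained with the m = n = 2 loss, where
  stationarity with an active hidden node pins the error |y - y'| to a
  beta-dependent value; the module maps convergence empirically via the
  gradient-magnitude stopping rule.

Gradient flows are integrated with an adaptive stiff-capable scheme (LSODA)
and a terminal event on the stopping criterion max_w |dL/dw| < epsilon.
Subgradient conventions: sign(0) = 0 in the m=1 error term; the ReLU
derivative at 0 is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ToyLinearModel",
    "LossSpec",
    "ToyReluNetwork",
    "ConvergenceReport",
    "loss_value",
    "simulate_linear_flow",
    "predicted_even_power_convergence",
    "information_free_value",
    "simulate_relu_flow",
]


@dataclass(frozen=True)
class LossSpec:
    """Loss hyperparameters: error exponent m, regularization exponent n,
    regularization strength beta >= 0, learning rate alpha > 0."""

    m: int = 2
    n: int = 2
    beta: float = 0.0
    alpha: float = 1.0

    def __post_init__(self):
        if not (isinstance(self.m, int) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass
class ToyLinearModel:
    """Linear guess y = sum_m w_m z_m with fixed term values z."""

    term_values: np.ndarray
    target: float
    weights: np.ndarray

    def __post_init__(self):
        self.term_values = np.atleast_1d(np.asarray(self.term_values, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.term_values.shape != self.weights.shape:
            raise ValueError("term_values and weights must have the same shape")
        self.target = float(self.target)

    @property
    def guess(self) -> float:
        return float(self.weights @ self.term_values)


def _sign0(x):
    """sign with the subgradient convention sign(0) = 0."""
    return np.sign(x)


def loss_value(model: ToyLinearModel, spec: LossSpec) -> float:
    """L = |y - y'|**m + beta * sum |w|**n."""
    err = abs(model.guess - model.target) ** spec.m
    reg = spec.beta * np.sum(np.abs(model.weights) ** spec.n)
    return float(err + reg)


def _linear_grad(w: np.ndarray, z: np.ndarray, target: float, spec: LossSpec) -> np.ndarray:
    y = w @ z
    e = y - target
    if spec.m == 1:
        err_part = _sign0(e) * z
    else:
        err_part = spec.m * np.abs(e) ** (spec.m - 1) * _sign0(e) * z
    if spec.n == 1:
        reg_part = spec.beta * _sign0(w)
    else:
        reg_part = spec.beta * spec.n * np.abs(w) ** (spec.n - 1) * _sign0(w)
    return err_part + reg_part


@dataclass
class ConvergenceReport:
    """Outcome of a simulated gradient flow."""

    converged: bool
    t_end: float
    final_weights: np.ndarray
    final_guess: float
    final_grad_norm: float
    times: np.ndarray = field(repr=False)
    losses: np.ndarray = field(repr=False)
    stopped_on: str = "t_max"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "loss": self.losses})


def _simulate_flow(grad_fn, loss_fn, guess_fn, w0, alpha, t_max, epsilon,
                   target=None, target_tol=None, n_report=200) -> ConvergenceReport:
    def rhs(_t, w):
        return -alpha * grad_fn(w)

    def stop(_t, w):
        return float(np.max(np.abs(grad_fn(w)))) - epsilon

    stop.terminal = True
    stop.direction = -1
    events = [stop]

    w0 = np.asarray(w0, dtype=float)
    if stop(0.0, w0) < 0:  # already stationary to within epsilon
        return ConvergenceReport(
            converged=True,
            t_end=0.0,
            final_weights=w0.copy(),
            final_guess=float(guess_fn(w0)),
            final_grad_norm=float(np.max(np.abs(grad_fn(w0)))),
            times=np.array([0.0]),
            losses=np.array([loss_fn(w0)]),
            stopped_on="gradient",
        )

    if target_tol is not None:
        # For the m=1 loss the flow reaches y = y' in finite time and then
        # slides along the sign discontinuity, where the one-sided gradient
        # never falls below epsilon; stop on target proximity instead.
        def hit_target(_t, w):
            return abs(guess_fn(w) - target) - target_tol

        hit_target.terminal = True
        hit_target.direction = -1
        events.append(hit_target)

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        np.asarray(w0, dtype=float),
        method="LSODA",
        t_eval=np.linspace(0.0, t_max, n_report),
        events=events,
        rtol=1e-9,
        atol=1e-12,
    )
    stopped_on = "t_max"
    if sol.status == 1:
        fired = [k for k, ev in enumerate(sol.t_events) if len(ev)]
        k = min(fired, key=lambda k: sol.t_events[k][0])
        t_end = float(sol.t_events[k][0])
        w_end = sol.y_events[k][0]
        converged = True
        stopped_on = "gradient" if k == 0 else "target"
        mask = sol.t <= t_end
        times = np.append(sol.t[mask], t_end)
        traj = np.vstack([sol.y[:, mask].T, w_end])
    else:
        t_end = float(sol.t[-1])
        w_end = sol.y[:, -1]
        converged = False
        times = sol.t
        traj = sol.y.T
    losses = np.array([loss_fn(w) for w in traj])
    return ConvergenceReport(
        converged=converged,
        t_end=t_end,
        final_weights=np.asarray(w_end),
        final_guess=float(guess_fn(w_end)),
        final_grad_norm=float(np.max(np.abs(grad_fn(w_end)))),
        times=times,
        losses=losses,
        stopped_on=stopped_on,
    )


def simulate_linear_flow(
    model: ToyLinearModel,
    spec: LossSpec,
    t_max: float = 1e4,
    epsilon: float = 1e-8,
    target_tol: Optional[float] = None,
) -> ConvergenceReport:
    """Integrate dw/dt = -alpha dL/dw until max |dL/dw| < epsilon or t_max.

    ``target_tol``, if given, adds a second terminal event on
    |y - y'| < target_tol; needed to detect absolute convergence under the
    m = 1 loss, whose flow reaches the target in finite time and then slides
    on the sign discontinuity without the gradient ever vanishing one-sidedly.
    Non-convergence within t_max is reported, not raised.
    """
    z = model.term_values

    return _simulate_flow(
        grad_fn=lambda w: _linear_grad(w, z, model.target, spec),
        loss_fn=lambda w: loss_value(
            ToyLinearModel(z, model.target, w), spec
        ),
        guess_fn=lambda w: w @ z,
        w0=model.weights,
        alpha=spec.alpha,
        t_max=t_max,
        epsilon=epsilon,
        target=model.target,
        target_tol=target_tol,
    )


def predicted_even_power_convergence(
    y_prime: float, beta: float, n: int, term_values
) -> float:
    """Closed-form converged output for the even-power m = n loss:

        y = y' / (1 + beta**(1/(n-1)) / sum_m |z_m|**(n/(n-1))).

    beta = 0 recovers absolute convergence y = y'; beta -> inf drives y to 0.
    """
    if n < 2 or n % 2:
        raise ValueError(f"n must be even and >= 2, got {n}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = np.atleast_1d(np.asarray(term_values, dtype=float))
    s = np.sum(np.abs(z) ** (n / (n - 1)))
    return float(y_prime / (1.0 + beta ** (1.0 / (n - 1)) / s))


def information_free_value(beta: float, term_values) -> float:
    """Magnitude S/(2 beta), S = sum z**2, of the information-free fixed point
    of the m=1, n=2 flow; the output converges there (with the sign of the
    target) whenever |y'| exceeds it."""
    z = np.atleast_1d(np.asarray(term_values, dtype=float))
    return float(np.sum(z**2) / (2.0 * beta))


@dataclass
class ToyReluNetwork:
    """Two-input, one-hidden-layer ReLU network.

    Hidden node k outputs v_k = a_i[k]*x_i + a_j[k]*x_j + b[k]; the guess is
    y = sum_k c[k]*max(v_k, 0) + delta.
    """

    x_i: float
    x_j: float
    a_i: np.ndarray
    a_j: np.ndarray
    b: np.ndarray
    c: np.ndarray
    delta: float
    target: float

    def __post_init__(self):
        self.a_i = np.atleast_1d(np.asarray(self.a_i, dtype=float))
        self.a_j = np.atleast_1d(np.asarray(self.a_j, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        k = len(self.a_i)
        if not (len(self.a_j) == len(self.b) == len(self.c) == k):
            raise ValueError("hidden-layer weight arrays must share one length")

    @property
    def n_hidden(self) -> int:
        return len(self.a_i)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.a_i, self.a_j, self.b, self.c, [self.delta]])

    def hidden(self, w: np.ndarray):
        k = self.n_hidden
        a_i, a_j, b = w[:k], w[k : 2 * k], w[2 * k : 3 * k]
        return a_i * self.x_i + a_j * self.x_j + b

    def guess_from(self, w: np.ndarray) -> float:
        k = self.n_hidden
        c, delta = w[3 * k : 4 * k], w[4 * k]
        v = self.hidden(w)
        return float(c @ np.maximum(v, 0.0) + delta)


def _relu_grad(net: ToyReluNetwork, w: np.ndarray, beta: float) -> np.ndarray:
    k = net.n_hidden
    c = w[3 * k : 4 * k]
    v = net.hidden(w)
    phi = np.maximum(v, 0.0)
    act = (v > 0.0).astype(float)  # ReLU subgradient at 0 is 0
    e = net.guess_from(w) - net.target
    g = np.empty_like(w)
    g[:k] = 2.0 * e * c * act * net.x_i + 2.0 * beta * w[:k]
    g[k : 2 * k] = 2.0 * e * c * act * net.x_j + 2.0 * beta * w[k : 2 * k]
    g[2 * k : 3 * k] = 2.0 * e * c * act + 2.0 * beta * w[2 * k : 3 * k]
    g[3 * k : 4 * k] = 2.0 * e * phi + 2.0 * beta * c
    g[4 * k] = 2.0 * e + 2.0 * beta * w[4 * k]
    return g


def simulate_relu_flow(
    net: ToyReluNetwork,
    spec: LossSpec,
    t_max: float = 1e4,
    epsilon: float = 1e-8,
) -> ConvergenceReport:
    """Gradient flow for the ReLU toy under the m = n = 2 loss.

    Reports whether the gradient-magnitude stopping rule was met by t_max;
    used to map the non-convergent target band empirically.
    """
    if spec.m != 2 or spec.n != 2:
        raise ValueError("the ReLU toy is analyzed with the m = n = 2 loss")

    def loss_fn(w):
        e = net.guess_from(w) - net.target
        return float(e * e + spec.beta * np.sum(w * w))

    return _simulate_flow(
        grad_fn=lambda w: _relu_grad(net, w, spec.beta),
        loss_fn=loss_fn,
        guess_fn=net.guess_from,
        w0=net.pack(),
        alpha=spec.alpha,
        t_max=t_max,
        epsilon=epsilon,
    )
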